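"""Channel weight maps from trained networks, and grand-averaged ERP/SME checks.

The absolute value of an input-to-spatial-layer kernel weight measures a
channel's discriminant capability: absolute values are averaged over maps and
over models (e.g. one trained model per participant or per seed) and then
range-scaled to [0, 1].  The grand-averaged ERP report averages each
participant's per-class ERPs first and the individual averages second (equal
participant weighting), and tests the remembered-forgotten window-mean
difference across participants with a paired t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .network import NetworkParams
from .preprocessing import WINDOWS
from .types import EpochSet, FORGOTTEN, REMEMBERED


@dataclass
class ChannelWeightMap:
    """Per-channel discriminant scores, range-scaled to [0, 1]."""

    channel_names: tuple[str, ...]
    scores: np.ndarray
    window: str = "entire"
    n_models: int = 1

    def as_frame(self) -> pd.DataFrame:
        order = np.lexsort((np.arange(len(self.scores)), -self.scores))
        return pd.DataFrame(
            {
                "channel": [self.channel_names[i] for i in order],
                "score": self.scores[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )


@dataclass
class SMEReport:
    """Grand-averaged per-class ERPs and window-mean statistics."""

    times: np.ndarray
    channel_names: tuple[str, ...]
    grand_remembered: np.ndarray  # (channels, samples)
    grand_forgotten: np.ndarray
    window_stats: pd.DataFrame  # columns: window, mean_remembered, mean_forgotten, diff, t, p
    n_participants: int


def weight_map(
    models: Sequence[NetworkParams],
    channel_names: Sequence[str],
    window: str = "entire",
) -> ChannelWeightMap:
    """Average |spatial kernel| over maps and models, then min-max scale.

    Absolute values are taken before any averaging so that oppositely signed
    kernels cannot cancel; the result is invariant to per-map sign flips and
    to model ordering.
    """
    if not models:
        raise ValueError("at least one trained model is required")
    channel_names = tuple(channel_names)
    per_model = []
    for params in models:
        k = np.abs(np.asarray(params.spatial_kernels))  # (n_maps, M)
        if k.shape[1] != len(channel_names):
            raise ValueError("kernel length does not match channel count")
        per_model.append(k.mean(axis=0))
    raw = np.mean(per_model, axis=0)
    lo, hi = raw.min(), raw.max()
    scores = (raw - lo) / (hi - lo) if hi > lo else np.zeros_like(raw)
    return ChannelWeightMap(
        channel_names=channel_names, scores=scores, window=window, n_models=len(models)
    )


def top_channels(wmap: ChannelWeightMap, k: int = 3) -> list:
    """The k highest-scoring channel names, ties broken by montage order."""
    if k > len(wmap.channel_names):
        raise ValueError("k exceeds the number of channels")
    order = np.lexsort((np.arange(len(wmap.scores)), -wmap.scores))
    return [wmap.channel_names[i] for i in order[:k]]


def grand_average_sme(
    epoch_sets: Sequence[EpochSet],
    channels: Optional[Sequence[str]] = None,
) -> SMEReport:
    """Grand-averaged ERPs per class and paired t-tests on window means.

    Each participant contributes one per-class average ERP; participants
    missing a class are excluded with a warning.  Window-mean amplitudes (over
    the selected channels) in the pre- and during-stimulus windows are
    compared between classes with a two-sided paired t-test across
    participants.  A zero-variance difference yields t = nan and is reported
    as no effect.
    """
    usable = []
    for i, ep in enumerate(epoch_sets):
        if np.any(ep.labels == REMEMBERED) and np.any(ep.labels == FORGOTTEN):
            usable.append(ep)
        else:
            warnings.warn(f"participant {i} lacks one class; excluded from grand average")
    if len(usable) < 1:
        raise ValueError("no participant has both classes")

    ref = usable[0]
    names = tuple(ref.channel_names[i] for i in ref.eeg_channel_indices)
    if channels is None:
        sel = np.arange(len(names))
    else:
        sel = np.array([names.index(ch) for ch in channels], dtype=int)

    ind_rem, ind_forg = [], []
    for ep in usable:
        eeg = ep.data[:, ep.eeg_channel_indices, :]
        ind_rem.append(eeg[ep.labels == REMEMBERED].mean(axis=0))
        ind_forg.append(eeg[ep.labels == FORGOTTEN].mean(axis=0))
    grand_rem = np.mean(ind_rem, axis=0)
    grand_forg = np.mean(ind_forg, axis=0)
    times = ref.times

    rows = []
    for window in ("pre", "during"):
        w0, w1 = WINDOWS[window]
        mask = (times >= w0) & (times < w1)
        rem = np.array([erp[np.ix_(sel, np.flatnonzero(mask))].mean() for erp in ind_rem])
        forg = np.array([erp[np.ix_(sel, np.flatnonzero(mask))].mean() for erp in ind_forg])
        diff = rem - forg
        if len(usable) >= 2 and np.std(diff) > 0:
            t, p = sp_stats.ttest_rel(rem, forg)
        else:
            t, p = np.nan, np.nan
        rows.append(
            {
                "window": window,
                "mean_remembered": rem.mean(),
                "mean_forgotten": forg.mean(),
                "diff": diff.mean(),
                "t": t,
                "p": p,
                "significant": bool(p < 0.05) if np.isfinite(p) else False,
            }
        )
    return SMEReport(
        times=times,
        channel_names=names,
        grand_remembered=grand_rem,
        grand_forgotten=grand_forg,
        window_stats=pd.DataFrame(rows),
        n_participants=len(usable),
    )
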