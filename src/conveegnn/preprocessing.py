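"""ERP preprocessing chain: from continuous recording to model-ready matrices.

The chain runs in a fixed order:

1. re-reference to linked mastoids,
2. zero-phase band-pass 0.05-15 Hz,
3. regression-based EOG (blink) correction on the continuous data,
4. segmentation into [-0.1, 2.9) s trials around each cue,
5. baseline correction against the 100 ms pre-cue window,
6. artifact rejection (any scalp sample beyond +/-50 microvolts, or a marked
   movement trial),

followed by input preparation: decimation to 25 Hz, cropping to the analysis
window, exclusion of the EOG channels, and per-channel z-normalization whose
statistics are estimated on training trials only and reused for held-out
trials.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy import signal as sp_signal

from .types import (
    EpochSet,
    ModelInputs,
    NormalizationStats,
    RawSession,
    label_trials,
)

#: Analysis windows (seconds relative to cue onset), half-open [t0, t1).
WINDOWS = {
    "entire": (-0.1, 2.9),
    "pre": (0.3, 1.5),
    "during": (1.5, 2.7),
}

REJECTION_THRESHOLD_UV = 50.0


def rereference(session: RawSession) -> RawSession:
    """Re-reference every non-EOG channel to the mean of the mastoid channels."""
    montage = session.montage
    if not montage.mastoid_channels:
        raise ValueError("montage has no mastoid channels to re-reference to")
    mast_idx = [montage.index(ch) for ch in montage.mastoid_channels]
    reference = session.signal[mast_idx].mean(axis=0)
    out = session.signal.copy()
    eog = set(montage.eog_channels)
    for i, ch in enumerate(montage.channel_names):
        if ch not in eog:
            out[i] = out[i] - reference
    return session.with_signal(out, "rereference")


def bandpass(session: RawSession, low: float = 0.05, high: float = 15.0) -> RawSession:
    """Zero-phase 8th-order Butterworth band-pass, applied forward-backward."""
    fs = session.sampling_rate
    if not (0 < low < high < fs / 2):
        raise ValueError(f"invalid band edges ({low}, {high}) at fs={fs}")
    sos = sp_signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    out = sp_signal.sosfiltfilt(sos, session.signal, axis=1)
    return session.with_signal(np.ascontiguousarray(out), "bandpass")


def regress_out_eog(session: RawSession) -> RawSession:
    """Remove blink/eye-movement contamination by least-squares regression.

    Propagation factors from VEOG and HEOG to each scalp channel are estimated
    over the whole continuous recording and the fitted EOG contribution is
    subtracted.  An EOG channel with (near-)zero variance is skipped with a
    warning; the EOG channels themselves are left unmodified.
    """
    montage = session.montage
    if not montage.eog_channels:
        raise ValueError("montage has no EOG channels")
    regressors = []
    for ch in montage.eog_channels:
        x = session.signal[montage.index(ch)]
        if np.var(x) < 1e-12:
            warnings.warn(f"EOG channel {ch} is flat; skipped in regression")
            continue
        regressors.append(x - x.mean())
    out = session.signal.copy()
    if regressors:
        X = np.column_stack(regressors)
        eog = set(montage.eog_channels)
        eeg_rows = [i for i, ch in enumerate(montage.channel_names) if ch not in eog]
        Y = session.signal[eeg_rows].T  # samples x channels
        coef, *_ = np.linalg.lstsq(X, Y - Y.mean(axis=0), rcond=None)
        out[eeg_rows] = (Y - X @ coef).T
    return session.with_signal(out, "regress_out_eog")


def segment(session: RawSession, t0: float = -0.1, t1: float = 2.9) -> EpochSet:
    """Cut one epoch per trial over the half-open interval [t0, t1) around the cue.

    Labels are attached from the memory-test responses.  Trials whose window
    would run past either end of the recording are flagged rejected("edge").
    """
    fs = session.sampling_rate
    n_samples = session.signal.shape[1]
    start_off = int(round(t0 * fs))
    length = int(round((t1 - t0) * fs))

    cues = session.events[session.events["kind"] == "cue"]
    words = set(session.events.loc[session.events["kind"] == "word", "trial_id"])
    resp = dict(zip(session.responses["trial_id"], session.responses["key"]))
    move = dict(zip(session.annotations["trial_id"], session.annotations["movement"]))

    kept_data, kept_ids, kept_keys, kept_move = [], [], [], []
    rejected: dict[int, str] = {}
    for trial_id, onset in zip(cues["trial_id"], cues["onset_sample"]):
        trial_id = int(trial_id)
        if trial_id not in words:
            raise ValueError(f"trial {trial_id} has a cue but no word event")
        start = int(onset) + start_off
        stop = start + length
        if start < 0 or stop > n_samples:
            rejected[trial_id] = "edge"
            continue
        kept_data.append(session.signal[:, start:stop])
        kept_ids.append(trial_id)
        kept_keys.append(resp.get(trial_id, None))
        kept_move.append(bool(move.get(trial_id, False)))

    n = len(kept_data)
    data = (
        np.stack(kept_data)
        if n
        else np.empty((0, session.montage.n_channels, length))
    )
    labels = np.full(n, -1, dtype=int)
    has_key = [k is not None for k in kept_keys]
    if any(has_key):
        idx = np.flatnonzero(has_key)
        labels[idx] = label_trials([kept_keys[i] for i in idx])

    return EpochSet(
        data=data,
        sampling_rate=fs,
        t_start=t0,
        channel_names=session.montage.channel_names,
        labels=labels,
        trial_ids=np.asarray(kept_ids, dtype=int),
        movement=np.asarray(kept_move, dtype=bool),
        eog_channels=session.montage.eog_channels,
        rejected=rejected,
        provenance=session.provenance + ("segment",),
    )


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each trial/channel's mean over the pre-cue window [t_start, 0)."""
    if epochs.t_start >= 0:
        raise ValueError("epochs do not include a pre-cue baseline window")
    n_base = int(round(-epochs.t_start * epochs.sampling_rate))
    data = epochs.data.copy()
    if epochs.n_trials:
        data -= data[:, :, :n_base].mean(axis=2, keepdims=True)
    out = epochs.copy()
    out.data = data
    out.provenance = epochs.provenance + ("baseline_correct",)
    return out


def reject_artifacts(
    epochs: EpochSet, threshold: float = REJECTION_THRESHOLD_UV
) -> EpochSet:
    """Drop trials with scalp drift beyond +/-threshold or a movement mark.

    The amplitude check uses strict inequality (a peak of exactly +/-threshold
    is retained) and ignores EOG channels.  Retained trials are unmodified.
    """
    eeg_idx = epochs.eeg_channel_indices
    keep = []
    rejected = dict(epochs.rejected)
    for i in range(epochs.n_trials):
        peak = np.abs(epochs.data[i, eeg_idx]).max() if eeg_idx.size else 0.0
        if peak > threshold:
            rejected[int(epochs.trial_ids[i])] = "amplitude"
        elif epochs.movement[i]:
            rejected[int(epochs.trial_ids[i])] = "movement"
        else:
            keep.append(i)
    out = epochs.subset(keep, step="reject_artifacts")
    out.rejected = rejected
    return out


def _antialias_decimate(data: np.ndarray, fs: float, factor: int) -> np.ndarray:
    """Low-pass at 0.8 x target Nyquist, then keep every ``factor``-th sample."""
    target = fs / factor
    sos = sp_signal.butter(8, 0.8 * target / 2, btype="low", fs=fs, output="sos")
    smooth = sp_signal.sosfiltfilt(sos, data, axis=-1)
    return np.ascontiguousarray(smooth[..., ::factor])


def _decimated(epochs: EpochSet, target_rate: float, naive: bool) -> np.ndarray:
    """EOG-free decimated data for all trials, cached on the epoch set.

    Decimation is label-independent and identical for every cross-validation
    fold, so it is computed once per (rate, flavor) and memoized on the
    ``EpochSet`` instance (callers must not mutate ``epochs.data`` afterwards).
    """
    fs = epochs.sampling_rate
    factor_f = fs / target_rate
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9 or factor < 1:
        raise ValueError(f"sampling rate {fs} is not an integer multiple of {target_rate}")
    cache = getattr(epochs, "_decim_cache", None)
    if cache is None:
        cache = {}
        epochs._decim_cache = cache
    key = (target_rate, naive)
    if key not in cache:
        data = epochs.data[:, epochs.eeg_channel_indices, :]
        if factor > 1:
            data = data[..., ::factor] if naive else _antialias_decimate(data, fs, factor)
        cache[key] = data
    return cache[key]


def prepare_input(
    epochs: EpochSet,
    window: str = "entire",
    target_rate: float = 25.0,
    stats: Optional[NormalizationStats] = None,
    naive_decimate: bool = False,
    trials=None,
) -> ModelInputs:
    """Decimate, crop to the analysis window, drop EOG, and z-normalize.

    At the default rates the entire window gives T = 75 samples per channel
    and the pre/during windows give T = 30.  When ``stats`` is supplied (a
    training set's per-channel mean/SD) it is used verbatim, so held-out
    trials never contribute to the normalization; otherwise statistics are
    computed from the given trials and returned on the result.  ``trials``
    restricts the output (and any computed statistics) to a subset of trial
    positions without redoing the decimation.
    """
    if window not in WINDOWS:
        raise ValueError(f"unknown window {window!r}; expected one of {sorted(WINDOWS)}")
    eeg_idx = epochs.eeg_channel_indices
    channel_names = tuple(epochs.channel_names[i] for i in eeg_idx)
    data = _decimated(epochs, target_rate, naive_decimate)
    idx = np.arange(epochs.n_trials) if trials is None else np.asarray(trials, int)
    data = data[idx]

    w0, w1 = WINDOWS[window]
    i0_f = (w0 - epochs.t_start) * target_rate
    i1_f = (w1 - epochs.t_start) * target_rate
    if abs(i0_f - round(i0_f)) > 1e-6 or abs(i1_f - round(i1_f)) > 1e-6:
        raise ValueError(f"window {window!r} bounds are not sample-aligned at {target_rate} Hz")
    i0, i1 = int(round(i0_f)), int(round(i1_f))
    if i0 < 0 or i1 > data.shape[-1]:
        raise ValueError(f"window {window!r} exceeds the epoch span")
    X = data[..., i0:i1].copy()

    if stats is None:
        if X.shape[0] == 0:
            raise ValueError("cannot compute normalization statistics from zero trials")
        mean = X.mean(axis=(0, 2))
        sd = X.std(axis=(0, 2))
        sd = np.where(sd > 0, sd, 1.0)
        stats = NormalizationStats(mean=mean, sd=sd, channel_names=channel_names)
    elif stats.channel_names != channel_names:
        raise ValueError("supplied normalization stats are for different channels")
    X = (X - stats.mean[None, :, None]) / stats.sd[None, :, None]

    return ModelInputs(
        X=X,
        window=window,
        sampling_rate=target_rate,
        channel_names=channel_names,
        labels=epochs.labels[idx].copy(),
        trial_ids=epochs.trial_ids[idx].copy(),
        stats=stats,
    )


def preprocess_session(
    session: RawSession,
    low: float = 0.05,
    high: float = 15.0,
    threshold: float = REJECTION_THRESHOLD_UV,
) -> EpochSet:
    """Run steps 1-6 in order and return artifact-free, labeled epochs."""
    s = rereference(session)
    s = bandpass(s, low=low, high=high)
    s = regress_out_eog(s)
    epochs = segment(s)
    epochs = baseline_correct(epochs)
    return reject_artifacts(epochs, threshold=threshold)
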