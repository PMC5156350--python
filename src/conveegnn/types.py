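"""Shared data containers for the memory-decoding pipeline.

The pipeline moves through three in-memory representations:

``RawSession``
    A continuous multichannel recording (microvolts) plus its event table
    (cue/word onsets), the memory-test responses (keys 1-5), movement
    annotations, and the montage metadata.
``EpochSet``
    Segmented trials (trials x channels x samples) with class labels and a
    rejection log.
``ModelInputs``
    Decimated, windowed, z-normalized matrices ready for a classifier,
    together with the normalization statistics that produced them.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

# Class codes used throughout: a trial later judged "definitely familiar" or
# "possibly familiar" (keys 1-2) is remembered; keys 3-5 are forgotten.
REMEMBERED = 1
FORGOTTEN = 0

LABEL_NAMES = {REMEMBERED: "remembered", FORGOTTEN: "forgotten"}

#: 32-channel cap in 10/10 labels: 30 scalp channels (incl. TP9/TP10 at the
#: mastoids) plus vertical and horizontal EOG.
DEFAULT_CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
    "VEOG", "HEOG",
)


@dataclass(frozen=True)
class Montage:
    """Channel layout: which channels exist, which are EOG, which are mastoids."""

    channel_names: tuple[str, ...]
    eog_channels: tuple[str, ...] = ("VEOG", "HEOG")
    mastoid_channels: tuple[str, ...] = ("TP9", "TP10")

    def __post_init__(self) -> None:
        names = set(self.channel_names)
        if len(names) != len(self.channel_names):
            raise ValueError("duplicate channel names in montage")
        for ch in self.eog_channels:
            if ch not in names:
                raise ValueError(f"EOG channel {ch!r} not in montage")
        for ch in self.mastoid_channels:
            if ch not in names:
                raise ValueError(f"mastoid channel {ch!r} not in montage")
        if set(self.eog_channels) & set(self.mastoid_channels):
            raise ValueError("EOG and mastoid channel sets must be disjoint")

    @classmethod
    def default(cls) -> "Montage":
        return cls(channel_names=DEFAULT_CHANNELS)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    @property
    def eeg_channels(self) -> tuple[str, ...]:
        """All non-EOG channels, in montage order."""
        eog = set(self.eog_channels)
        return tuple(ch for ch in self.channel_names if ch not in eog)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)


@dataclass
class RawSession:
    """Continuous recording in microvolts with its event bookkeeping.

    ``events`` has columns (trial_id, onset_sample, kind) with kind in
    {"cue", "word"}; ``responses`` has (trial_id, key) with key in 1..5;
    ``annotations`` has (trial_id, movement) with a boolean movement flag.
    ``truth_labels`` (simulator only) maps trial order to class codes.
    """

    signal: np.ndarray  # (n_channels, n_samples), microvolts
    sampling_rate: float
    events: pd.DataFrame
    responses: pd.DataFrame
    annotations: pd.DataFrame
    montage: Montage
    truth_labels: Optional[np.ndarray] = None
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != self.montage.n_channels:
            raise ValueError("signal rows do not match montage channel count")
        onsets = np.asarray(self.events["onset_sample"], dtype=int)
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")

    def channel(self, name: str) -> np.ndarray:
        return self.signal[self.montage.index(name)]

    def with_signal(self, signal: np.ndarray, step: str) -> "RawSession":
        """Copy of this session with a new signal and a provenance tag."""
        return replace(self, signal=signal, provenance=self.provenance + (step,))

    @property
    def trial_ids(self) -> np.ndarray:
        cues = self.events[self.events["kind"] == "cue"]
        return np.asarray(cues["trial_id"], dtype=int)


@dataclass
class EpochSet:
    """Segmented trials: data is (n_trials, n_channels, n_samples)."""

    data: np.ndarray
    sampling_rate: float
    t_start: float
    channel_names: tuple[str, ...]
    labels: np.ndarray  # class codes, -1 where unknown
    trial_ids: np.ndarray
    movement: np.ndarray  # per retained trial, bool
    eog_channels: tuple[str, ...] = ()
    rejected: dict[int, str] = field(default_factory=dict)  # trial_id -> reason
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x samples)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        n = self.data.shape[0]
        if not (len(self.labels) == len(self.trial_ids) == len(self.movement) == n):
            raise ValueError("per-trial metadata does not match trial count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.n_samples) / self.sampling_rate

    @property
    def eeg_channel_indices(self) -> np.ndarray:
        eog = set(self.eog_channels)
        return np.array([i for i, ch in enumerate(self.channel_names) if ch not in eog], dtype=int)

    def subset(self, idx: Sequence[int], step: str = "subset") -> "EpochSet":
        idx = np.asarray(idx, dtype=int)
        return EpochSet(
            data=self.data[idx].copy(),
            sampling_rate=self.sampling_rate,
            t_start=self.t_start,
            channel_names=self.channel_names,
            labels=self.labels[idx].copy(),
            trial_ids=self.trial_ids[idx].copy(),
            movement=self.movement[idx].copy(),
            eog_channels=self.eog_channels,
            rejected=dict(self.rejected),
            provenance=self.provenance + (step,),
        )

    def copy(self) -> "EpochSet":
        return copy.deepcopy(self)


@dataclass
class NormalizationStats:
    """Per-channel mean/SD used for z-normalization of model inputs."""

    mean: np.ndarray  # (n_channels,)
    sd: np.ndarray  # (n_channels,)
    channel_names: tuple[str, ...]


@dataclass
class ModelInputs:
    """Classifier-ready input matrices for a set of trials.

    ``X`` is (n_trials, n_channels, T); each trial is one input matrix whose
    rows are channels and columns are decimated time samples.
    """

    X: np.ndarray
    window: str  # "entire", "pre" or "during"
    sampling_rate: float
    channel_names: tuple[str, ...]
    labels: np.ndarray
    trial_ids: np.ndarray
    stats: NormalizationStats

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]


def label_trials(keys) -> np.ndarray:
    """Map memory-test response keys to class codes.

    Keys 1-2 ("definitely familiar", "possibly familiar") mark a studied word
    as remembered; keys 3-5 (uncertain through definitely unfamiliar) mark it
    forgotten.
    """
    keys = np.asarray(keys, dtype=int)
    if keys.size and (keys.min() < 1 or keys.max() > 5):
        bad = keys[(keys < 1) | (keys > 5)][0]
        raise ValueError(f"response key out of range 1..5: {bad}")
    return np.where(keys <= 2, REMEMBERED, FORGOTTEN)
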