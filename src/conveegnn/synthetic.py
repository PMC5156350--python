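"""Synthetic auditory-memory EEG sessions with a planted subsequent-memory effect.

The simulator emulates the statistical structure of a cued auditory word-study
task recorded with a 32-channel cap at 500 Hz: a cue at t = 0 s, the word at
t = 1.5 s, trials spanning [-0.1, 2.9) s around the cue and tiled with a fixed
0.6 s inter-trial interval.  Remembered trials carry a negative-going shift on
a set of frontal channels during the cue-word interval and a positive-going
shift while the word is presented, on top of 1/f background noise, white
noise, theta-band oscillation, class-independent cue/word evoked responses,
blinks mirrored on the VEOG channel, and occasional slow drift trials that
exceed the +/-50 microvolt artifact criterion.

Ground-truth class labels are kept on the session and also encoded in the
memory-test response keys (remembered -> keys 1-2, forgotten -> keys 3-5), so
the full label-recovery path is exercised downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    EpochSet,
    FORGOTTEN,
    Montage,
    RawSession,
    REMEMBERED,
)

#: Analysis windows in seconds relative to cue onset.  "pre" covers late
#: cue-word anticipation, "during" the word presentation, "entire" the whole
#: epoch.
PRE_WINDOW = (0.3, 1.5)
DURING_WINDOW = (1.5, 2.7)
ENTIRE_WINDOW = (-0.1, 2.9)

#: Blink propagation factors: fraction of the VEOG blink amplitude reaching
#: each scalp channel, decreasing from frontal to posterior rows.  Chosen so
#: that regression on the EOG channels can recover and remove the artifact.
BLINK_GAINS = {
    "Fp": 0.35, "F": 0.20, "FC": 0.12, "C": 0.08, "T": 0.06,
    "CP": 0.05, "TP": 0.03, "P": 0.03, "O": 0.02,
}

#: Scalp gain applied to the class-independent evoked responses (stronger
#: fronto-centrally, weaker posteriorly).
_TOPO_GAINS = {
    "Fp": 1.0, "F": 1.0, "FC": 0.9, "C": 0.8, "T": 0.7,
    "CP": 0.6, "TP": 0.4, "P": 0.5, "O": 0.4,
}


def _row_prefix(name: str) -> str:
    """Longest electrode-row prefix of a 10/10 label (e.g. 'FC5' -> 'FC')."""
    for p in ("Fp", "FC", "CP", "TP", "F", "C", "T", "P", "O"):
        if name.startswith(p):
            return p
    return ""


def blink_gain(channel: str) -> float:
    if channel == "VEOG":
        return 1.0
    if channel == "HEOG":
        return 0.10
    return BLINK_GAINS.get(_row_prefix(channel), 0.02)


def _topo_gain(channel: str) -> float:
    return _TOPO_GAINS.get(_row_prefix(channel), 0.5)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated session.

    Amplitudes are in microvolts, times in seconds, rates in events per
    second.  ``pre_effect`` is signed and negative by default: remembered
    trials shift downward before the word.  ``noise_sigma`` is the total
    per-channel background noise SD (split between 1/f and white components).
    """

    n_trials: int = 100
    p_remembered: float = 0.5
    sampling_rate: float = 500.0
    cue_time: float = 0.0
    word_time: float = 1.5
    trial_span: tuple[float, float] = ENTIRE_WINDOW
    isi: float = 0.6
    effect_channels: tuple[str, ...] = ("Fp1", "Fp2", "F7", "F3", "F8")
    pre_effect: float = -2.0
    during_effect: float = 2.0
    theta_freq: float = 6.0
    theta_amp: float = 2.0
    theta_amp_diff: float = 0.0
    noise_sigma: float = 9.0
    pink_fraction: float = 0.8
    one_over_f_exponent: float = 1.0
    blink_rate: float = 0.10
    blink_amp: float = 100.0
    drift_trial_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_remembered <= 1.0:
            raise ValueError("p_remembered must be in [0, 1]")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0.0 <= self.drift_trial_fraction <= 1.0:
            raise ValueError("drift_trial_fraction must be in [0, 1]")
        if self.trial_span[1] <= self.trial_span[0]:
            raise ValueError("trial_span must be increasing")
        if self.isi < 0:
            raise ValueError("negative inter-trial interval: trials would overlap")
        if not (self.trial_span[0] <= self.cue_time < self.word_time < self.trial_span[1]):
            raise ValueError("cue/word times must fall inside trial_span")

    @property
    def trial_period(self) -> float:
        """Cue-to-cue spacing: epoch span plus the inter-trial interval."""
        return (self.trial_span[1] - self.trial_span[0]) + self.isi


def one_over_f_noise(rng: np.random.Generator, n: int, alpha: float) -> np.ndarray:
    """Unit-SD Gaussian noise with a 1/f^alpha amplitude spectrum."""
    n_freq = n // 2 + 1
    spectrum = rng.normal(size=n_freq) + 1j * rng.normal(size=n_freq)
    f = np.arange(n_freq, dtype=float)
    f[0] = 1.0
    spectrum *= f ** (-alpha / 2.0)
    spectrum[0] = 0.0
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _background(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    """Per-channel background: mix of 1/f and white noise with SD noise_sigma."""
    if cfg.noise_sigma == 0:
        return np.zeros(n)
    pink = one_over_f_noise(rng, n, cfg.one_over_f_exponent)
    white = rng.normal(size=n)
    return cfg.noise_sigma * (
        np.sqrt(cfg.pink_fraction) * pink + np.sqrt(1.0 - cfg.pink_fraction) * white
    )


def _gaussian_bump(t: np.ndarray, center: float, width: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / width) ** 2)


def _evoked_template(t: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Class-independent evoked response: cue and word N1/P2-like complexes."""
    cue, word = cfg.cue_time, cfg.word_time
    out = _gaussian_bump(t, cue + 0.12, 0.04, -3.0)
    out += _gaussian_bump(t, cue + 0.25, 0.07, 4.0)
    out += _gaussian_bump(t, word + 0.12, 0.05, -4.0)
    out += _gaussian_bump(t, word + 0.35, 0.09, 5.0)
    return out


def _class_effect(t: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Additive shift applied on effect channels for remembered trials only."""
    out = np.zeros_like(t)
    out[(t >= PRE_WINDOW[0]) & (t < PRE_WINDOW[1])] += cfg.pre_effect
    out[(t >= DURING_WINDOW[0]) & (t < DURING_WINDOW[1])] += cfg.during_effect
    return out


def _draw_labels(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    return np.where(rng.random(cfg.n_trials) < cfg.p_remembered, REMEMBERED, FORGOTTEN)


def _draw_keys(rng: np.random.Generator, labels: np.ndarray) -> np.ndarray:
    """Remembered trials respond with key 1 or 2, forgotten with 3-5."""
    keys = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        keys[i] = rng.integers(1, 3) if lab == REMEMBERED else rng.integers(3, 6)
    return keys


def _trial_content(
    t: np.ndarray,
    label: int,
    phase: float,
    cfg: SimConfig,
    channels: tuple[str, ...],
    effect_idx: np.ndarray,
) -> np.ndarray:
    """Deterministic-per-trial signal (channels x samples) excluding noise."""
    evoked = _evoked_template(t, cfg)
    theta = cfg.theta_amp * np.sin(2 * np.pi * cfg.theta_freq * t + phase)
    out = np.empty((len(channels), len(t)))
    for c, name in enumerate(channels):
        g = _topo_gain(name)
        out[c] = g * (evoked + theta)
    if label == REMEMBERED:
        eff = _class_effect(t, cfg)
        out[effect_idx] += eff
        if cfg.theta_amp_diff:
            during = (t >= DURING_WINDOW[0]) & (t < DURING_WINDOW[1])
            extra = cfg.theta_amp_diff * np.sin(2 * np.pi * cfg.theta_freq * t + phase)
            out[effect_idx] += np.where(during, extra, 0.0)
    return out


def _effect_indices(channels: tuple[str, ...], cfg: SimConfig) -> np.ndarray:
    missing = [ch for ch in cfg.effect_channels if ch not in channels]
    if missing:
        raise ValueError(f"effect channels not in montage: {missing}")
    return np.array([channels.index(ch) for ch in cfg.effect_channels], dtype=int)


def simulate_session(cfg: SimConfig, montage: Optional[Montage] = None) -> RawSession:
    """Generate one continuous recording with events, responses and artifacts.

    Deterministic given ``cfg.seed``.  Trials are tiled sequentially; drift is
    planted on exactly ``round(drift_trial_fraction * n_trials)`` trials as a
    slow ramp exceeding +/-50 microvolts; blinks follow a Poisson process and
    appear on VEOG at full amplitude and on scalp channels attenuated
    front-to-back.
    """
    montage = montage or Montage.default()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    channels = montage.channel_names
    effect_idx = _effect_indices(channels, cfg)

    lead_in = max(1.0, -cfg.trial_span[0] + 0.5)
    duration = lead_in + cfg.n_trials * cfg.trial_period + 1.0
    n_samples = int(round(duration * fs))
    span_samples = int(round((cfg.trial_span[1] - cfg.trial_span[0]) * fs))

    labels = _draw_labels(rng, cfg)
    keys = _draw_keys(rng, labels)

    signal = np.empty((len(channels), n_samples))
    eog = set(montage.eog_channels)
    for c, name in enumerate(channels):
        sigma_scale = 0.5 if name in eog else 1.0
        signal[c] = sigma_scale * _background(rng, n_samples, cfg)

    # trial-locked content
    cue_samples = np.empty(cfg.n_trials, dtype=int)
    eeg_rows = [i for i, ch in enumerate(channels) if ch not in eog]
    eeg_names = tuple(channels[i] for i in eeg_rows)
    eff_idx_eeg = _effect_indices(eeg_names, cfg)
    t_rel = cfg.trial_span[0] + np.arange(span_samples) / fs
    for i in range(cfg.n_trials):
        cue_t = lead_in + i * cfg.trial_period - cfg.trial_span[0]
        cue_samples[i] = int(round(cue_t * fs))
        start = cue_samples[i] + int(round(cfg.trial_span[0] * fs))
        phase = rng.uniform(0, 2 * np.pi)
        content = _trial_content(t_rel, labels[i], phase, cfg, eeg_names, eff_idx_eeg)
        signal[np.ix_(eeg_rows, np.arange(start, start + span_samples))] += content

    # blinks: Poisson events over the recording, mirrored on VEOG
    if cfg.blink_rate > 0 and cfg.blink_amp != 0:
        n_blinks = rng.poisson(cfg.blink_rate * duration)
        blink_times = np.sort(rng.uniform(0.3, duration - 0.3, size=n_blinks))
        half = int(round(0.25 * fs))
        t_blink = np.arange(-half, half + 1) / fs
        waveform = np.exp(-0.5 * (t_blink / 0.06) ** 2)
        for bt in blink_times:
            center = int(round(bt * fs))
            sl = slice(center - half, center + half + 1)
            for c, name in enumerate(channels):
                signal[c, sl] += cfg.blink_amp * blink_gain(name) * waveform

    # drift trials: slow ramp crossing +/-50 microvolts on one scalp channel
    n_drift = int(round(cfg.drift_trial_fraction * cfg.n_trials))
    drift_trials = rng.choice(cfg.n_trials, size=n_drift, replace=False) if n_drift else []
    for i in drift_trials:
        start = cue_samples[i] + int(round(cfg.trial_span[0] * fs))
        row = eeg_rows[rng.integers(len(eeg_rows))]
        amp = rng.uniform(60.0, 85.0) * rng.choice([-1.0, 1.0])
        signal[row, start:start + span_samples] += np.linspace(0.0, amp, span_samples)

    word_offset = int(round((cfg.word_time - cfg.cue_time) * fs))
    events = pd.DataFrame(
        {
            "trial_id": np.repeat(np.arange(cfg.n_trials), 2),
            "onset_sample": np.column_stack(
                [cue_samples, cue_samples + word_offset]
            ).ravel(),
            "kind": ["cue", "word"] * cfg.n_trials,
        }
    )
    responses = pd.DataFrame({"trial_id": np.arange(cfg.n_trials), "key": keys})
    annotations = pd.DataFrame(
        {"trial_id": np.arange(cfg.n_trials), "movement": np.zeros(cfg.n_trials, bool)}
    )
    return RawSession(
        signal=signal,
        sampling_rate=fs,
        events=events,
        responses=responses,
        annotations=annotations,
        montage=montage,
        truth_labels=labels,
        provenance=("simulate",),
    )


def simulate_epochs(cfg: SimConfig, montage: Optional[Montage] = None) -> EpochSet:
    """Directly emit segmented, artifact-free, baseline-corrected epochs.

    Equivalent in structure to running the preprocessing chain on a
    blink/drift-free session: EOG channels are excluded, trials span
    ``cfg.trial_span`` at the raw sampling rate, and each trial/channel has
    zero mean over the pre-cue baseline window.  Intended for fast tests and
    classifier experiments; it skips the band-pass filter (the decimation
    stage applies its own anti-alias low-pass downstream).
    """
    montage = montage or Montage.default()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    channels = montage.eeg_channels
    effect_idx = _effect_indices(channels, cfg)

    span_samples = int(round((cfg.trial_span[1] - cfg.trial_span[0]) * fs))
    t_rel = cfg.trial_span[0] + np.arange(span_samples) / fs

    labels = _draw_labels(rng, cfg)
    data = np.empty((cfg.n_trials, len(channels), span_samples))
    for i in range(cfg.n_trials):
        phase = rng.uniform(0, 2 * np.pi)
        trial = _trial_content(t_rel, labels[i], phase, cfg, channels, effect_idx)
        for c in range(len(channels)):
            trial[c] += _background(rng, span_samples, cfg)
        data[i] = trial

    baseline = (t_rel >= cfg.trial_span[0]) & (t_rel < cfg.cue_time)
    if baseline.any():
        data -= data[:, :, baseline].mean(axis=2, keepdims=True)

    return EpochSet(
        data=data,
        sampling_rate=fs,
        t_start=cfg.trial_span[0],
        channel_names=channels,
        labels=labels,
        trial_ids=np.arange(cfg.n_trials),
        movement=np.zeros(cfg.n_trials, bool),
        eog_channels=(),
        rejected={},
        provenance=("simulate_epochs",),
    )


def write_session(session: RawSession, path, format: str = "brainvision") -> list:
    """Write a session to disk (EDF or BrainVision + CSV sidecars).

    Thin wrapper over the writers in :mod:`conveegnn.io`.
    """
    from . import io as _io

    return _io.write_session(session, path, format=format)
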