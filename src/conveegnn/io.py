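"""Readers, writers, run configuration and the full-experiment driver.

Sessions are written as EDF (16-bit, per-channel physical scaling) or
BrainVision triplets (.vhdr/.vmrk/.eeg, IEEE float32), always accompanied by
plain-text sidecars that carry the exact event bookkeeping: ``events.csv``
(trial_id, onset_sample, kind), ``responses.csv`` (trial_id, key),
``annotations.csv`` (trial_id, movement) and ``meta.json`` (sampling rate,
montage roles, exact sample count, truth labels when simulated).  Reading goes
through mne for the signal and through the sidecars for events, so a written
session round-trips up to the format's quantization.

Epoch sets and trained models are stored as single-file ``.npz`` containers
with a JSON metadata entry.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import EpochSet, Montage, RawSession
from .network import NetworkConfig, NetworkParams
from .synthetic import SimConfig

_EDF_DIG_MAX = 32767


# ---------------------------------------------------------------------------
# session writers
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(session: RawSession, path: Path) -> None:
    """Minimal EDF writer: 1-second data records, int16 samples.

    The recording is zero-padded to a whole number of records; the exact
    sample count is recorded in the meta.json sidecar so readers can crop.
    """
    fs = session.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    rec_len = int(round(fs))
    n_ch, n_samples = session.signal.shape
    n_records = int(np.ceil(n_samples / rec_len))

    pmax = np.maximum(np.abs(session.signal).max(axis=1), 1e-6) * 1.0001
    padded = np.zeros((n_ch, n_records * rec_len))
    padded[:, :n_samples] = session.signal
    digital = np.round(padded / pmax[:, None] * _EDF_DIG_MAX).astype("<i2")

    with open(path, "wb") as f:
        f.write(_edf_field("0", 8))
        f.write(_edf_field("X X X X", 80))
        f.write(_edf_field("Startdate 01-JAN-2000 synthetic", 80))
        f.write(_edf_field("01.01.00", 8))
        f.write(_edf_field("00.00.00", 8))
        f.write(_edf_field(256 * (n_ch + 1), 8))
        f.write(_edf_field("", 44))
        f.write(_edf_field(n_records, 8))
        f.write(_edf_field(1, 8))
        f.write(_edf_field(n_ch, 4))
        for ch in session.montage.channel_names:
            f.write(_edf_field(ch, 16))
        for _ in range(n_ch):
            f.write(_edf_field("", 80))
        for _ in range(n_ch):
            f.write(_edf_field("uV", 8))
        for p in pmax:
            f.write(_edf_field(f"{-p:.6g}"[:8], 8))
        for p in pmax:
            f.write(_edf_field(f"{p:.6g}"[:8], 8))
        for _ in range(n_ch):
            f.write(_edf_field(-_EDF_DIG_MAX, 8))
        for _ in range(n_ch):
            f.write(_edf_field(_EDF_DIG_MAX, 8))
        for _ in range(n_ch):
            f.write(_edf_field("", 80))
        for _ in range(n_ch):
            f.write(_edf_field(rec_len, 8))
        for _ in range(n_ch):
            f.write(_edf_field("", 32))
        for r in range(n_records):
            f.write(digital[:, r * rec_len:(r + 1) * rec_len].tobytes())


def _write_brainvision(session: RawSession, base: Path) -> None:
    """BrainVision triplet: text header/markers, float32 multiplexed data."""
    name = base.name
    fs = session.sampling_rate
    n_ch = session.signal.shape[0]
    header = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        f"MarkerFile={name}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / fs:g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(session.montage.channel_names, start=1):
        header.append(f"Ch{i}={ch},,1,µV")
    base.with_suffix(".vhdr").write_text("\n".join(header) + "\n", encoding="utf-8")

    markers = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20000101000000000000",
    ]
    stim = {"cue": "S  1", "word": "S  2"}
    for j, (_, row) in enumerate(session.events.iterrows(), start=2):
        pos = int(row["onset_sample"]) + 1  # BrainVision positions are 1-based
        markers.append(f"Mk{j}=Stimulus,{stim[row['kind']]},{pos},1,0")
    base.with_suffix(".vmrk").write_text("\n".join(markers) + "\n", encoding="utf-8")

    session.signal.T.astype("<f4").tofile(base.with_suffix(".eeg"))


def write_session(session: RawSession, path, format: str = "brainvision") -> list:
    """Write a session plus CSV/JSON sidecars; returns the created file paths.

    ``path`` is a directory; the signal file is named ``session.edf`` or
    ``session.vhdr/.vmrk/.eeg`` inside it.
    """
    fmt = format.lower()
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    created = []
    if fmt == "edf":
        signal_file = out / "session.edf"
        _write_edf(session, signal_file)
        created.append(signal_file)
    elif fmt == "brainvision":
        base = out / "session"
        _write_brainvision(session, base)
        created += [base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg")]
    else:
        raise ValueError(f"unsupported format {format!r}; use 'edf' or 'brainvision'")

    session.events.to_csv(out / "events.csv", index=False)
    session.responses.to_csv(out / "responses.csv", index=False)
    session.annotations.to_csv(out / "annotations.csv", index=False)
    meta = {
        "sampling_rate": session.sampling_rate,
        "n_samples": int(session.signal.shape[1]),
        "channel_names": list(session.montage.channel_names),
        "eog_channels": list(session.montage.eog_channels),
        "mastoid_channels": list(session.montage.mastoid_channels),
        "truth_labels": (
            [int(x) for x in session.truth_labels]
            if session.truth_labels is not None
            else None
        ),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    created += [out / n for n in ("events.csv", "responses.csv", "annotations.csv", "meta.json")]
    return created


# ---------------------------------------------------------------------------
# session reader
# ---------------------------------------------------------------------------

def _canonical_names(names: Sequence[str], reference: Sequence[str]) -> list:
    """Case-insensitive normalization of channel labels to 10/10 spellings."""
    lookup = {r.lower(): r for r in reference}
    return [lookup.get(n.lower(), n) for n in names]


def read_session(path) -> RawSession:
    """Read an EDF or BrainVision session written by :func:`write_session`.

    ``path`` may be the directory, the .edf file, or the .vhdr file; the CSV
    and JSON sidecars are expected alongside the signal file.  Signals are
    returned in microvolts; event pairing (one cue and one word per trial) is
    validated.
    """
    import mne

    p = Path(path)
    if p.is_dir():
        candidates = sorted(p.glob("*.vhdr")) + sorted(p.glob("*.edf"))
        if not candidates:
            raise FileNotFoundError(f"no .vhdr or .edf file in {p}")
        p = candidates[0]
    folder = p.parent

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if p.suffix.lower() == ".edf":
            raw = mne.io.read_raw_edf(p, preload=True, verbose="error")
        elif p.suffix.lower() == ".vhdr":
            raw = mne.io.read_raw_brainvision(p, preload=True, verbose="error")
        else:
            raise ValueError(f"unsupported session file {p.name!r}")
        signal = raw.get_data(units="uV")

    meta_file = folder / "meta.json"
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    if "n_samples" in meta:
        signal = signal[:, : meta["n_samples"]]

    from .types import DEFAULT_CHANNELS

    names = _canonical_names(raw.ch_names, meta.get("channel_names", DEFAULT_CHANNELS))
    eog = tuple(meta.get("eog_channels") or [ch for ch in names if "EOG" in ch.upper()])
    mastoid = tuple(
        meta.get("mastoid_channels") or [ch for ch in names if ch in ("TP9", "TP10")]
    )
    montage = Montage(tuple(names), eog_channels=eog, mastoid_channels=mastoid)

    events = pd.read_csv(folder / "events.csv")
    responses_file = folder / "responses.csv"
    responses = (
        pd.read_csv(responses_file)
        if responses_file.exists()
        else pd.DataFrame({"trial_id": [], "key": []})
    )
    ann_file = folder / "annotations.csv"
    annotations = (
        pd.read_csv(ann_file)
        if ann_file.exists()
        else pd.DataFrame(
            {"trial_id": events["trial_id"].unique(), "movement": False}
        )
    )

    # validate cue/word pairing
    for trial_id, group in events.groupby("trial_id"):
        kinds = sorted(group["kind"])
        if kinds != ["cue", "word"]:
            raise ValueError(f"trial {trial_id} does not have exactly one cue and one word event")

    truth = meta.get("truth_labels")
    return RawSession(
        signal=signal,
        sampling_rate=float(meta.get("sampling_rate", raw.info["sfreq"])),
        events=events,
        responses=responses,
        annotations=annotations,
        montage=montage,
        truth_labels=np.asarray(truth, int) if truth is not None else None,
        provenance=("read",),
    )


# ---------------------------------------------------------------------------
# epoch and model containers (.npz with a JSON metadata entry)
# ---------------------------------------------------------------------------

def save_epochs(epochs: EpochSet, path) -> None:
    meta = {
        "sampling_rate": epochs.sampling_rate,
        "t_start": epochs.t_start,
        "channel_names": list(epochs.channel_names),
        "eog_channels": list(epochs.eog_channels),
        "rejected": {str(k): v for k, v in epochs.rejected.items()},
        "provenance": list(epochs.provenance),
    }
    np.savez(
        path,
        data=epochs.data,
        labels=epochs.labels,
        trial_ids=epochs.trial_ids,
        movement=epochs.movement,
        meta=np.array(json.dumps(meta)),
    )


def load_epochs(path) -> EpochSet:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        return EpochSet(
            data=z["data"],
            sampling_rate=meta["sampling_rate"],
            t_start=meta["t_start"],
            channel_names=tuple(meta["channel_names"]),
            labels=z["labels"],
            trial_ids=z["trial_ids"],
            movement=z["movement"],
            eog_channels=tuple(meta["eog_channels"]),
            rejected={int(k): v for k, v in meta["rejected"].items()},
            provenance=tuple(meta["provenance"]),
        )


def save_model(path, cfg: NetworkConfig, params: NetworkParams) -> None:
    arrays = {
        "spatial_kernels": params.spatial_kernels,
        "spatial_bias": params.spatial_bias,
        "temporal_bias": params.temporal_bias,
        "hidden_weights": params.hidden_weights,
        "hidden_bias": params.hidden_bias,
        "output_weights": params.output_weights,
        "output_bias": params.output_bias,
    }
    for m, k in enumerate(params.temporal_kernels):
        arrays[f"temporal_kernel_{m}"] = k
    arrays["config"] = np.array(json.dumps(asdict(cfg)))
    np.savez(path, **arrays)


def load_model(path) -> tuple[NetworkConfig, NetworkParams]:
    with np.load(path, allow_pickle=False) as z:
        cfg_dict = json.loads(str(z["config"]))
        cfg_dict["map_sizes"] = tuple(cfg_dict["map_sizes"])
        cfg = NetworkConfig(**cfg_dict)
        params = NetworkParams(
            spatial_kernels=z["spatial_kernels"],
            spatial_bias=z["spatial_bias"],
            temporal_kernels=[z[f"temporal_kernel_{m}"] for m in range(cfg.n_maps)],
            temporal_bias=z["temporal_bias"],
            hidden_weights=z["hidden_weights"],
            hidden_bias=z["hidden_bias"],
            output_weights=z["output_weights"],
            output_bias=z["output_bias"],
        )
    return cfg, params


# ---------------------------------------------------------------------------
# run configuration and full experiment
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Declarative description of a full synthetic experiment."""

    n_participants: int = 9
    windows: tuple[str, ...] = ("entire", "pre", "during")
    models: tuple[str, ...] = (
        "conveegnn", "lda", "ann1", "ann2", "svm", "svm+lda", "cwt+svm"
    )
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    network: dict = field(default_factory=dict)  # NetworkConfig overrides
    use_continuous: bool = False  # simulate full sessions + preprocessing chain
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("windows", "models"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_dict(self) -> dict:
        return asdict(self)


def _participant_epochs(config: RunConfig, participant: int) -> EpochSet:
    from . import preprocessing, synthetic

    seed = (config.seed * 1_000 + participant) % (2**31 - 1)
    sim_cfg = SimConfig(**{**config.sim, "seed": seed})
    if config.use_continuous:
        session = synthetic.simulate_session(sim_cfg)
        return preprocessing.preprocess_session(session)
    return synthetic.simulate_epochs(sim_cfg)


def run_experiment(config: RunConfig) -> dict:
    """Simulate, evaluate every model x window, analyze channels; write reports.

    Writes ``report.csv`` (one row per participant x model x window),
    ``summary.csv`` (averages per model x window), ``channel_map.csv`` (weight
    map per window from per-participant networks trained on all trials) and
    ``log.json``.  Returns the paths and in-memory frames.
    """
    from . import channels as channel_analysis
    from . import network as net
    from .evaluation import cross_validate
    from .preprocessing import prepare_input

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    epoch_sets = [
        _participant_epochs(config, p) for p in range(config.n_participants)
    ]

    rows = []
    for p, epochs in enumerate(epoch_sets):
        for window in config.windows:
            for model in config.models:
                kwargs = dict(config.network) if model == "conveegnn" else {}
                result = cross_validate(
                    epochs, model, window=window,
                    seed=(config.seed * 7_919 + p) % (2**31 - 1), **kwargs,
                )
                rows.append(
                    {
                        "participant": f"P{p:02d}",
                        "model": model,
                        "window": window,
                        "accuracy": result.accuracy,
                        "n": result.n_total,
                        "p_value": result.p_value,
                        "significant": result.significant,
                    }
                )
    report = pd.DataFrame(rows)
    summary = (
        report.groupby(["model", "window"])
        .agg(accuracy=("accuracy", "mean"), significant=("significant", "sum"))
        .reset_index()
    )

    # channel weight maps from one network per participant per window
    map_rows = []
    for window in config.windows:
        models = []
        for p, epochs in enumerate(epoch_sets):
            inputs = prepare_input(epochs, window)
            cfg = replace(
                NetworkConfig(T=inputs.X.shape[2], n_channels=inputs.X.shape[1],
                              **config.network),
                seed=(config.seed * 104_729 + p) % (2**31 - 1),
            )
            models.append(net.train(inputs.X, inputs.labels, cfg).params)
        wmap = channel_analysis.weight_map(models, inputs.channel_names, window=window)
        frame = wmap.as_frame()
        frame.insert(0, "window", window)
        map_rows.append(frame)
    channel_map = pd.concat(map_rows, ignore_index=True)

    report.to_csv(out_dir / "report.csv", index=False)
    summary.to_csv(out_dir / "summary.csv", index=False)
    channel_map.to_csv(out_dir / "channel_map.csv", index=False)
    log = {
        "config": config.to_dict(),
        "n_trials_per_participant": [int(ep.n_trials) for ep in epoch_sets],
        "n_rejected_per_participant": [len(ep.rejected) for ep in epoch_sets],
        "package_version": __import__("conveegnn").__version__,
    }
    (out_dir / "log.json").write_text(json.dumps(log, indent=1))
    return {
        "report": report,
        "summary": summary,
        "channel_map": channel_map,
        "out_dir": out_dir,
    }
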