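"""Preprocessing oracles: re-reference, band-pass, EOG regression,
segmentation, baseline, rejection, and input preparation."""

import numpy as np
import pandas as pd
import pytest

from conveegnn import SimConfig, simulate_epochs, simulate_session
from conveegnn.preprocessing import (
    bandpass,
    baseline_correct,
    prepare_input,
    preprocess_session,
    regress_out_eog,
    reject_artifacts,
    rereference,
    segment,
)
from conveegnn.types import Montage, RawSession


def _session_from_signal(signal, fs=500.0, n_trials=0):
    montage = Montage.default()
    events = pd.DataFrame({"trial_id": [], "onset_sample": [], "kind": []})
    responses = pd.DataFrame({"trial_id": [], "key": []})
    annotations = pd.DataFrame({"trial_id": [], "movement": []})
    return RawSession(
        signal=signal, sampling_rate=fs, events=events, responses=responses,
        annotations=annotations, montage=montage, truth_labels=None,
        provenance=(),
    )


# ---------------------------------------------------------------- rereference

def test_rereference_zero_mastoids_noop():
    montage = Montage.default()
    sig = np.random.default_rng(0).normal(size=(montage.n_channels, 100))
    for ch in montage.mastoid_channels:
        sig[montage.index(ch)] = 0.0
    s = _session_from_signal(sig)
    out = rereference(s)
    np.testing.assert_allclose(out.signal, sig)


def test_rereference_constant_mastoids_shift():
    """Mastoids at +4 and +6 uV shift every non-EOG channel by -5 uV."""
    montage = Montage.default()
    sig = np.zeros((montage.n_channels, 50))
    m1, m2 = montage.mastoid_channels
    sig[montage.index(m1)] = 4.0
    sig[montage.index(m2)] = 6.0
    out = rereference(_session_from_signal(sig))
    eog = set(montage.eog_channels)
    for i, ch in enumerate(montage.channel_names):
        if ch in (m1, m2):
            np.testing.assert_allclose(out.signal[i], sig[montage.index(ch)] - 5.0)
        elif ch not in eog:
            np.testing.assert_allclose(out.signal[i], -5.0)
        else:
            np.testing.assert_allclose(out.signal[i], 0.0)


# ------------------------------------------------------------------- bandpass

def _sine_session(freq, fs=500.0, seconds=20.0):
    t = np.arange(int(fs * seconds)) / fs
    sig = np.tile(np.sin(2 * np.pi * freq * t), (32, 1))
    return _session_from_signal(sig, fs), t


def _amplitude_at(signal, freq, fs):
    spec = np.abs(np.fft.rfft(signal))
    f = np.fft.rfftfreq(len(signal), 1 / fs)
    return spec[np.argmin(np.abs(f - freq))]


def test_bandpass_50hz_attenuated_40db():
    s, _ = _sine_session(50.0)
    out = bandpass(s)
    a_in = _amplitude_at(s.signal[0], 50.0, 500.0)
    a_out = _amplitude_at(out.signal[0], 50.0, 500.0)
    assert 20 * np.log10(a_in / a_out) >= 40.0


def test_bandpass_5hz_preserved():
    s, _ = _sine_session(5.0)
    out = bandpass(s)
    a_in = _amplitude_at(s.signal[0], 5.0, 500.0)
    a_out = _amplitude_at(out.signal[0], 5.0, 500.0)
    assert abs(a_out / a_in - 1.0) < 0.05


def test_bandpass_removes_dc():
    sig = np.full((32, 5000), 100.0)
    out = bandpass(_session_from_signal(sig))
    assert abs(out.signal[0].mean()) < 0.5


def test_bandpass_zero_phase():
    """Peak latency of a smooth in-band pulse is preserved within 1 sample."""
    fs = 500.0
    t = np.arange(int(10 * fs)) / fs
    pulse = np.exp(-0.5 * ((t - 5.0) / 0.1) ** 2)
    sig = np.tile(pulse, (32, 1))
    out = bandpass(_session_from_signal(sig, fs))
    assert abs(int(np.argmax(out.signal[0])) - int(np.argmax(pulse))) <= 1


def test_bandpass_invalid_edges():
    s, _ = _sine_session(5.0)
    with pytest.raises(ValueError):
        bandpass(s, low=10.0, high=5.0)
    with pytest.raises(ValueError):
        bandpass(s, low=0.0, high=15.0)


# ---------------------------------------------------------------- EOG removal

def test_eog_regression_recovers_propagation():
    """EEG = 0.3 * VEOG + noise -> post-correction |corr with VEOG| < 0.1."""
    montage = Montage.default()
    rng = np.random.default_rng(1)
    n = 20000
    veog = np.zeros(n)
    for c in rng.integers(500, n - 500, size=30):  # blink train
        w = np.exp(-0.5 * ((np.arange(-125, 126)) / 30.0) ** 2)
        veog[c - 125:c + 126] += 100.0 * w
    sig = rng.normal(size=(montage.n_channels, n))
    sig[montage.index("VEOG")] = veog
    fz = montage.index("Fz")
    sig[fz] = 0.3 * veog + rng.normal(size=n)
    out = regress_out_eog(_session_from_signal(sig))
    corr = np.corrcoef(out.signal[fz], veog)[0, 1]
    assert abs(corr) < 0.1
    # EOG channel itself is unmodified
    np.testing.assert_array_equal(out.signal[montage.index("VEOG")], veog)


def test_eog_regression_orthogonal_channel_unchanged():
    montage = Montage.default()
    rng = np.random.default_rng(2)
    n = 10000
    sig = np.zeros((montage.n_channels, n))
    t = np.arange(n) / 500.0
    sig[montage.index("VEOG")] = np.sin(2 * np.pi * 1.0 * t)
    sig[montage.index("HEOG")] = np.sin(2 * np.pi * 2.0 * t)
    pz = montage.index("Pz")
    sig[pz] = np.cos(2 * np.pi * 7.0 * t)  # orthogonal to both
    out = regress_out_eog(_session_from_signal(sig))
    np.testing.assert_allclose(out.signal[pz], sig[pz], atol=1e-6)


def test_eog_flat_channel_skipped_with_warning():
    montage = Montage.default()
    sig = np.random.default_rng(3).normal(size=(montage.n_channels, 2000))
    sig[montage.index("VEOG")] = 0.0
    sig[montage.index("HEOG")] = 0.0
    with pytest.warns(UserWarning):
        out = regress_out_eog(_session_from_signal(sig))
    np.testing.assert_array_equal(out.signal, sig)


# ---------------------------------------------------- segmentation & baseline

def test_segment_epoch_length(clean_session):
    ep = segment(clean_session)
    assert ep.data.shape[2] == 1500  # (2.9 - (-0.1)) * 500
    assert ep.n_trials == 10
    assert np.all(ep.labels >= 0)


def test_segment_edge_trial_rejected(clean_session):
    """A cue too close to the recording start is flagged rejected('edge')."""
    s = clean_session
    first_cue = int(s.events.loc[s.events["kind"] == "cue", "onset_sample"].iloc[0])
    short = s.with_signal(s.signal, "crop")
    short.signal = s.signal[:, first_cue - 10:]
    short.events = s.events.copy()
    short.events["onset_sample"] = s.events["onset_sample"] - (first_cue - 10)
    ep = segment(short)
    assert ep.rejected.get(0) == "edge"
    assert 0 not in ep.trial_ids


def test_baseline_correct_zero_mean(small_epochs):
    ep = baseline_correct(small_epochs)
    n_base = int(round(0.1 * ep.sampling_rate))
    means = ep.data[:, :, :n_base].mean(axis=2)
    np.testing.assert_allclose(means, 0.0, atol=1e-9)


# ----------------------------------------------------------------- rejection

def test_reject_exact_count_and_strict_threshold(small_epochs):
    ep = small_epochs.copy()
    ep.data = ep.data.copy()
    # plant 3 super-threshold trials and one exactly at threshold
    ep.data[1, 5, 100] = 80.0
    ep.data[4, 2, 50] = -120.0
    ep.data[7, 0, 10] = 51.0
    ep.data[:, :, :] = np.clip(ep.data, -49.0, 49.0)  # everything else under
    ep.data[1, 5, 100] = 80.0
    ep.data[4, 2, 50] = -120.0
    ep.data[7, 0, 10] = 51.0
    ep.data[9, 3, 33] = 50.0  # exactly +/- threshold: retained (strict >)
    out = reject_artifacts(ep)
    rejected_ids = {tid for tid, why in out.rejected.items() if why == "amplitude"}
    assert rejected_ids == {int(ep.trial_ids[i]) for i in (1, 4, 7)}
    assert int(ep.trial_ids[9]) in out.trial_ids


def test_reject_movement_trials(small_epochs):
    ep = small_epochs.copy()
    ep.data = np.clip(ep.data.copy(), -49.0, 49.0)
    ep.movement = ep.movement.copy()
    ep.movement[3] = True
    out = reject_artifacts(ep)
    assert out.rejected[int(ep.trial_ids[3])] == "movement"
    assert out.n_trials == ep.n_trials - 1


# ------------------------------------------------------------- prepare_input

def test_prepare_input_shapes(small_epochs):
    for window, T in [("entire", 75), ("pre", 30), ("during", 30)]:
        inp = prepare_input(small_epochs, window)
        assert inp.X.shape == (small_epochs.n_trials, 30, T)


def test_prepare_input_train_only_stats(small_epochs):
    """Held-out trials are normalized with training statistics verbatim."""
    train = prepare_input(small_epochs, "entire", trials=np.arange(15))
    test = prepare_input(small_epochs, "entire", stats=train.stats,
                         trials=np.arange(15, 20))
    np.testing.assert_array_equal(test.stats.mean, train.stats.mean)
    # training data is exactly z-normalized; held-out data generally is not
    np.testing.assert_allclose(train.X.mean(axis=(0, 2)), 0.0, atol=1e-9)
    np.testing.assert_allclose(train.X.std(axis=(0, 2)), 1.0, atol=1e-9)
    assert not np.allclose(test.X.mean(axis=(0, 2)), 0.0, atol=1e-6)


def test_prepare_input_naive_vs_antialias(small_epochs):
    naive = prepare_input(small_epochs, "entire", naive_decimate=True)
    aa = prepare_input(small_epochs, "entire", naive_decimate=False)
    assert naive.X.shape == aa.X.shape
    assert not np.allclose(naive.X, aa.X)


def test_prepare_input_unknown_window(small_epochs):
    with pytest.raises(ValueError):
        prepare_input(small_epochs, "middle")


def test_preprocess_session_end_to_end(small_session):
    ep = preprocess_session(small_session)
    assert ep.data.shape[1:] == (32, 1500)
    assert ep.n_trials + len(ep.rejected) == 12
    # drift trials (5% of 12 -> 1) must have been rejected
    assert any(why == "amplitude" for why in ep.rejected.values())
    inp = prepare_input(ep, "entire")
    assert inp.X.shape[1:] == (30, 75)
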