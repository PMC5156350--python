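"""Comparison classifiers behind a single fit/predict contract.

Every classifier (including the convolutional network itself) exposes
``fit(epochs, train_idx, seed)`` and ``predict(epochs, idx)`` over an
:class:`~conveegnn.types.EpochSet`, doing all of its own feature extraction
inside the fold, so the cross-validation driver treats them uniformly:

* ``conveegnn`` -- the convolutional network on decimated window matrices.
* ``lda``      -- linear discriminant analysis on the flattened matrices
  (pooled covariance, shrinkage-stabilized).
* ``ann1``/``ann2`` -- fully connected networks (10, resp. 20+10 hidden
  neurons; scaled tanh on the first hidden layer, logistic elsewhere),
  trained with the same SGD/early-stopping machinery as the convolutional
  network.
* ``svm``      -- soft-margin SVM with a cubic polynomial kernel, C chosen on
  an internal validation split.
* ``svm+lda``  -- classifier fusion: CSP log-variance spectral features of the
  pre- and during-stimulus windows each feed a cubic-polynomial SVM, an LDA
  reads the downsampled during-window amplitudes, and the three standardized
  decision values are averaged.
* ``cwt+svm``  -- Morlet continuous-wavelet band power (theta 4.00 Hz, theta
  6.42 Hz, alpha 11.26 Hz) per window and scalp region, classified by an
  L1-regularized linear SVM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import warnings

import numpy as np
import pywt
from scipy import linalg as sp_linalg
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, LinearSVC

from .network import (
    NetworkConfig,
    fit_sgd,
    one_hot_target,
    predict_many,
    stratified_split,
)
from .preprocessing import WINDOWS, prepare_input
from .types import EpochSet, FORGOTTEN, REMEMBERED

#: Scalp regions used for the wavelet features (intersected with the montage).
CHANNEL_GROUPS = {
    "frontal": ("Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"),
    "central": ("FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8"),
    "posterior": (
        "CP5", "CP1", "CP2", "CP6", "TP9", "TP10",
        "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2",
    ),
}

CWT_BAND_CENTERS_HZ = (4.00, 6.42, 11.26)
#: Complex Morlet with ~6 cycles of effective support.
CWT_WAVELET = "cmor2.0-1.0"


@dataclass(frozen=True)
class BaselineSpec:
    """Name plus hyperparameter overrides for one comparison classifier."""

    name: str
    hyperparameters: dict = field(default_factory=dict)


def _window_T(window: str, target_rate: float = 25.0) -> int:
    w0, w1 = WINDOWS[window]
    return int(round((w1 - w0) * target_rate))


class ConvEEGNNClassifier:
    """The convolutional network behind the common fold contract."""

    def __init__(self, window: str = "entire", cfg: Optional[NetworkConfig] = None,
                 naive_decimate: bool = False, **cfg_overrides):
        self.window = window
        self.naive_decimate = naive_decimate
        base = cfg or NetworkConfig()
        self.cfg_template = replace(base, T=_window_T(window), **cfg_overrides)
        self.stats = None
        self.result = None
        self.cfg = None

    def fit(self, epochs: EpochSet, train_idx, seed: int = 0):
        from .network import train as train_network

        inputs = prepare_input(epochs, self.window, trials=train_idx,
                               naive_decimate=self.naive_decimate)
        self.stats = inputs.stats
        self.cfg = replace(self.cfg_template, n_channels=inputs.X.shape[1], seed=seed)
        self.result = train_network(inputs.X, inputs.labels, self.cfg)
        return self

    def predict(self, epochs: EpochSet, idx) -> np.ndarray:
        inputs = prepare_input(epochs, self.window, trials=idx, stats=self.stats,
                               naive_decimate=self.naive_decimate)
        return predict_many(self.result.params, self.cfg, inputs.X)


def _flat_features(epochs: EpochSet, idx, window: str, stats=None):
    inputs = prepare_input(epochs, window, stats=stats, trials=idx)
    n = inputs.X.shape[0]
    return inputs.X.reshape(n, -1), inputs.labels, inputs.stats


class ShrinkageLDA:
    """Fisher discriminant with a Ledoit-Wolf-shrunk pooled covariance.

    The pooled within-class covariance S is shrunk toward its scaled identity
    target, S* = (1 - lambda) S + lambda mu I with mu = tr(S)/p, and the
    discriminant direction w = S*^{-1} (m1 - m0) is obtained through the
    Woodbury identity on the n x n Gram matrix, so the fit stays cheap (and
    well-posed) when features far outnumber trials.  ``shrinkage`` is the
    Ledoit-Wolf estimate by default ("auto") or a fixed value in [0, 1]; a
    singular covariance with shrinkage 0 falls back to an automatic ridge
    with a warning.
    """

    def __init__(self, shrinkage="auto"):
        self.shrinkage = shrinkage

    @staticmethod
    def _ledoit_wolf_lambda(Xc: np.ndarray) -> float:
        """Shrinkage intensity from centered data, via the Gram matrix only."""
        n, p = Xc.shape
        G = Xc @ Xc.T
        mu = np.trace(G) / (n * p)
        s_norm2 = float(np.sum(G * G)) / n**2  # ||S||_F^2
        d2 = s_norm2 - p * mu**2
        if d2 <= 0:
            return 1.0
        b2_bar = float(np.sum(np.diag(G) ** 2)) / n**2 - s_norm2 / n
        b2 = min(max(b2_bar, 0.0), d2)
        return b2 / d2

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ShrinkageLDA":
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("two classes required")
        self.classes_ = classes
        m0 = X[y == classes[0]].mean(axis=0)
        m1 = X[y == classes[1]].mean(axis=0)
        Xc = X.copy()
        Xc[y == classes[0]] -= m0
        Xc[y == classes[1]] -= m1
        n, p = Xc.shape

        lam = (
            self._ledoit_wolf_lambda(Xc)
            if self.shrinkage == "auto"
            else float(self.shrinkage)
        )
        mu = float(np.einsum("ij,ij->", Xc, Xc)) / (n * p)
        if mu <= 0:
            mu = 1.0
        if lam <= 0 and p >= n:
            warnings.warn("singular pooled covariance; applying automatic ridge")
            lam = 1e-3
        self.lambda_ = lam

        d = m1 - m0
        if lam >= 1.0:
            w = d / mu
        elif lam <= 0:
            S = Xc.T @ Xc / n
            w = np.linalg.solve(S, d)
        else:
            # S*^{-1} d = (1/(lam mu)) [d - Xc' (n lam mu/(1-lam) I + G)^{-1} Xc d]
            G = Xc @ Xc.T
            ridge = n * lam * mu / (1.0 - lam)
            z = np.linalg.solve(G + ridge * np.eye(n), Xc @ d)
            w = (d - Xc.T @ z) / (lam * mu)
        n0, n1 = np.sum(y == classes[0]), np.sum(y == classes[1])
        self.coef_ = w
        self.intercept_ = -0.5 * w @ (m0 + m1) + np.log(n1 / n0)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.coef_ + self.intercept_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) > 0, self.classes_[1], self.classes_[0])


class LDAClassifier:
    """Fisher discriminant on flattened input matrices.

    The pooled covariance is shrinkage-stabilized (Ledoit-Wolf), which keeps
    the fit well-posed when features outnumber trials.
    """

    def __init__(self, window: str = "entire", shrinkage="auto"):
        self.window = window
        self.shrinkage = shrinkage

    def fit(self, epochs, train_idx, seed: int = 0):
        X, y, self.stats = _flat_features(epochs, train_idx, self.window)
        self.model = ShrinkageLDA(shrinkage=self.shrinkage).fit(X, y)
        return self

    def predict(self, epochs, idx):
        X, _, _ = _flat_features(epochs, idx, self.window, stats=self.stats)
        return self.model.predict(X).astype(int)


class _DenseCore:
    """Fully connected net: scaled tanh on the first hidden layer, logistic after."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator,
                 a: float = 1.7159, b: float = 2.0 / 3.0, init: str = "uniform"):
        self.sizes = list(sizes)
        self.a, self.b = a, b
        self.W, self.bias = [], []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            bound = 1.0 / np.sqrt(n_in)
            if init == "uniform":
                self.W.append(rng.uniform(-bound, bound, size=(n_out, n_in)))
                self.bias.append(rng.uniform(-bound, bound, size=n_out))
            else:
                self.W.append(rng.normal(0, bound, size=(n_out, n_in)))
                self.bias.append(rng.normal(0, bound, size=n_out))

    def forward(self, x: np.ndarray):
        activations = [x]
        for layer, (W, b) in enumerate(zip(self.W, self.bias)):
            u = W @ activations[-1] + b
            if layer == 0:
                activations.append(self.a * np.tanh(self.b * u))
            else:
                activations.append(1.0 / (1.0 + np.exp(-u)))
        return activations

    def output_and_error(self, x, target) -> float:
        z = self.forward(x)[-1]
        d = z - target
        return 0.5 * float(d @ d)

    def step(self, x, target, lr: float) -> float:
        acts = self.forward(x)
        z = acts[-1]
        d = z - target
        err = 0.5 * float(d @ d)
        delta = d * z * (1.0 - z)
        for layer in range(len(self.W) - 1, -1, -1):
            gW = np.outer(delta, acts[layer])
            gb = delta
            if layer > 0:
                upstream = self.W[layer].T @ delta
                x_prev = acts[layer]
                if layer == 1:  # derivative of the scaled tanh layer
                    ab = self.a * self.b
                    delta = upstream * (ab - (self.b / self.a) * x_prev**2)
                else:
                    delta = upstream * x_prev * (1.0 - x_prev)
            self.W[layer] -= lr * gW
            self.bias[layer] -= lr * gb
        return err

    def snapshot(self):
        return ([W.copy() for W in self.W], [b.copy() for b in self.bias])

    def restore(self, params):
        self.W = [W.copy() for W in params[0]]
        self.bias = [b.copy() for b in params[1]]

    def n_params(self) -> int:
        return int(sum(W.size + b.size for W, b in zip(self.W, self.bias)))


class ANNClassifier:
    """Fully connected baseline sharing the SGD/early-stopping machinery."""

    def __init__(self, hidden: tuple[int, ...] = (10,), window: str = "entire",
                 learning_rate: float = 0.01, max_epochs: int = 500,
                 patience: int = 20, val_fraction: float = 0.3):
        self.hidden = tuple(hidden)
        self.window = window
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction

    def fit(self, epochs, train_idx, seed: int = 0):
        X, y, self.stats = _flat_features(epochs, train_idx, self.window)
        rng = np.random.default_rng(seed)
        self.core = _DenseCore([X.shape[1], *self.hidden, 2], rng)
        result = fit_sgd(self.core, X, y, self.learning_rate, self.max_epochs,
                         self.patience, self.val_fraction, rng)
        self.core.restore(result.params)
        self.result = result
        return self

    def predict(self, epochs, idx):
        X, _, _ = _flat_features(epochs, idx, self.window, stats=self.stats)
        out = np.array([self.core.forward(x)[-1] for x in X])
        return np.where(out[:, 0] > out[:, 1], FORGOTTEN, REMEMBERED)


class SVMClassifier:
    """Cubic-polynomial-kernel SVM; C picked on an internal validation split."""

    def __init__(self, window: str = "entire", degree: int = 3,
                 C_grid: tuple[float, ...] = (0.1, 1.0, 10.0)):
        self.window = window
        self.degree = degree
        self.C_grid = tuple(C_grid)

    def _make(self, C: float) -> SVC:
        return SVC(kernel="poly", degree=self.degree, coef0=1.0, gamma="scale", C=C)

    def fit(self, epochs, train_idx, seed: int = 0):
        X, y, self.stats = _flat_features(epochs, train_idx, self.window)
        best_C = self.C_grid[0]
        if len(self.C_grid) > 1:
            rng = np.random.default_rng(seed)
            tr, val = stratified_split(y, 0.3, rng)
            if len(val) and len(np.unique(y[tr])) == 2:
                scores = []
                for C in self.C_grid:
                    m = self._make(C).fit(X[tr], y[tr])
                    scores.append(np.mean(m.predict(X[val]) == y[val]))
                best_C = self.C_grid[int(np.argmax(scores))]
        self.model = self._make(best_C).fit(X, y)
        self.C_ = best_C
        return self

    def predict(self, epochs, idx):
        X, _, _ = _flat_features(epochs, idx, self.window, stats=self.stats)
        return self.model.predict(X).astype(int)


# ---------------------------------------------------------------------------
# CSP: spatial filters from the two-class covariance generalized eigenproblem.
# ---------------------------------------------------------------------------

def _class_covariance(X: np.ndarray, ridge: float) -> np.ndarray:
    """Average trace-normalized per-trial covariance, ridge-stabilized."""
    n_ch = X.shape[1]
    cov = np.zeros((n_ch, n_ch))
    for trial in X:
        c = trial @ trial.T / trial.shape[1]
        tr = np.trace(c)
        if tr > 0:
            cov += c / tr
    cov /= len(X)
    return cov + ridge * np.eye(n_ch)


def csp_filters(Xa: np.ndarray, Xb: np.ndarray, n_pairs: int = 2,
                ridge: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Common-spatial-pattern filters maximizing class variance ratios.

    Solves Ca v = lambda (Ca + Cb) v; returns the filters (rows: top ``n_pairs``
    eigenvectors then bottom ``n_pairs``) and all eigenvalues in descending
    order.  Filters are scaled so the projected composite covariance is the
    identity, hence the per-class projected variances of a filter pair sum to 1.
    """
    Ca = _class_covariance(Xa, ridge)
    Cb = _class_covariance(Xb, ridge)
    w, V = sp_linalg.eigh(Ca, Ca + Cb)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pick = list(range(n_pairs)) + list(range(len(w) - n_pairs, len(w)))
    return V[:, pick].T, w


def _log_var_features(filters: np.ndarray, X: np.ndarray) -> np.ndarray:
    proj = np.einsum("fc,ncs->nfs", filters, X)
    return np.log(proj.var(axis=2) + 1e-12)


def _crop_window(epochs: EpochSet, window: str) -> np.ndarray:
    """EEG-channel data restricted to an analysis window at the native rate."""
    w0, w1 = WINDOWS[window]
    fs = epochs.sampling_rate
    i0 = int(round((w0 - epochs.t_start) * fs))
    i1 = int(round((w1 - epochs.t_start) * fs))
    return epochs.data[:, epochs.eeg_channel_indices, i0:i1]


class SVMLDAFusion:
    """Three-branch fusion: two CSP+SVM spectral branches and one LDA branch.

    Spectral branches read CSP log-variance features of the pre- and
    during-stimulus windows; the temporal branch reads downsampled
    during-window amplitudes.  Fused decision = mean of the three decision
    values standardized on the training trials (``vote="majority"`` switches
    to a majority vote).
    """

    def __init__(self, n_pairs: int = 2, degree: int = 3, C: float = 1.0,
                 vote: str = "mean", window: str = "entire"):
        # `window` accepted for interface uniformity; branches fix their own.
        self.n_pairs = n_pairs
        self.degree = degree
        self.C = C
        if vote not in ("mean", "majority"):
            raise ValueError("vote must be 'mean' or 'majority'")
        self.vote = vote

    def fit(self, epochs, train_idx, seed: int = 0):
        train_idx = np.asarray(train_idx, int)
        y = epochs.labels[train_idx]
        self.branches = []
        for window in ("pre", "during"):
            X = _crop_window(epochs, window)[..., :]
            Xtr = X[train_idx]
            filters, _ = csp_filters(Xtr[y == FORGOTTEN], Xtr[y == REMEMBERED],
                                     n_pairs=self.n_pairs)
            feats = _log_var_features(filters, Xtr)
            scaler = StandardScaler().fit(feats)
            svm = SVC(kernel="poly", degree=self.degree, coef0=1.0, gamma="scale",
                      C=self.C).fit(scaler.transform(feats), y)
            self.branches.append(("csp", window, filters, scaler, svm))
        flat, y_lda, stats = _flat_features(epochs, train_idx, "during")
        lda = ShrinkageLDA(shrinkage="auto").fit(flat, y_lda)
        self.branches.append(("lda", "during", None, stats, lda))
        # standardization of decision values on the training trials
        self.decision_stats = []
        for d in self._raw_decisions(epochs, train_idx):
            self.decision_stats.append((d.mean(), d.std() or 1.0))
        return self

    def _raw_decisions(self, epochs, idx):
        idx = np.asarray(idx, int)
        decisions = []
        for kind, window, filters, scaler, model in self.branches:
            if kind == "csp":
                X = _crop_window(epochs, window)[idx]
                feats = scaler.transform(_log_var_features(filters, X))
                decisions.append(model.decision_function(feats))
            else:
                flat, _, _ = _flat_features(epochs, idx, window, stats=scaler)
                decisions.append(model.decision_function(flat))
        return decisions

    def decision_function(self, epochs, idx) -> np.ndarray:
        ds = self._raw_decisions(epochs, idx)
        z = [(d - m) / s for d, (m, s) in zip(ds, self.decision_stats)]
        return np.mean(z, axis=0)

    def predict(self, epochs, idx):
        if self.vote == "majority":
            votes = np.stack([(d >= 0).astype(int) for d in self._raw_decisions(epochs, idx)])
            return np.where(votes.sum(axis=0) >= 2, REMEMBERED, FORGOTTEN)
        fused = self.decision_function(epochs, idx)
        return np.where(fused >= 0, REMEMBERED, FORGOTTEN)


class CWTSVMClassifier:
    """Morlet wavelet band-power features classified by a 1-norm linear SVM.

    Features: mean wavelet power in each (band x window x scalp region) cell,
    18 in total; the L1 penalty induces a sparse weighting.  Feature
    extraction is per-trial (no cross-trial statistics), so it is computed
    once per epoch set and shared across folds; scaling and fitting use the
    training trials only.  If the penalty drives every coefficient to zero
    the classifier falls back to the training majority class.
    """

    def __init__(self, C: float = 1.0, window: str = "entire",
                 bands: tuple[float, ...] = CWT_BAND_CENTERS_HZ):
        # `window` accepted for interface uniformity; features use pre+during.
        self.C = C
        self.bands = tuple(bands)
        self._cache: dict[int, np.ndarray] = {}

    def _features(self, epochs: EpochSet) -> np.ndarray:
        key = id(epochs)
        if key not in self._cache:
            fs = epochs.sampling_rate
            scales = np.array(
                [pywt.frequency2scale(CWT_WAVELET, f / fs) for f in self.bands]
            )
            eeg_idx = epochs.eeg_channel_indices
            names = [epochs.channel_names[i] for i in eeg_idx]
            groups = [
                [i for i, ch in enumerate(names) if ch in CHANNEL_GROUPS[g]]
                for g in ("frontal", "central", "posterior")
            ]
            data = epochs.data[:, eeg_idx, :]
            coef, _ = pywt.cwt(data, scales, CWT_WAVELET,
                               sampling_period=1.0 / fs, axis=-1, method="fft")
            power = np.abs(coef) ** 2  # (bands, trials, channels, samples)
            times = epochs.times
            feats = []
            for window in ("pre", "during"):
                w0, w1 = WINDOWS[window]
                mask = (times >= w0) & (times < w1)
                for b in range(len(self.bands)):
                    for grp in groups:
                        feats.append(power[b][:, grp][:, :, mask].mean(axis=(1, 2)))
            self._cache[key] = np.column_stack(feats)
        return self._cache[key]

    def fit(self, epochs, train_idx, seed: int = 0):
        train_idx = np.asarray(train_idx, int)
        X = self._features(epochs)[train_idx]
        y = epochs.labels[train_idx]
        self.scaler = StandardScaler().fit(X)
        self.model = LinearSVC(penalty="l1", dual=False, C=self.C, max_iter=10000)
        self.model.fit(self.scaler.transform(X), y)
        counts = np.bincount(y, minlength=2)
        self.majority = REMEMBERED if counts[REMEMBERED] >= counts[FORGOTTEN] else FORGOTTEN
        return self

    def predict(self, epochs, idx):
        idx = np.asarray(idx, int)
        if np.all(self.model.coef_ == 0):
            return np.full(len(idx), self.majority, dtype=int)
        X = self.scaler.transform(self._features(epochs)[idx])
        return self.model.predict(X).astype(int)


_REGISTRY = {
    "conveegnn": ConvEEGNNClassifier,
    "lda": LDAClassifier,
    "ann1": lambda **kw: ANNClassifier(hidden=kw.pop("hidden", (10,)), **kw),
    "ann2": lambda **kw: ANNClassifier(hidden=kw.pop("hidden", (20, 10)), **kw),
    "svm": SVMClassifier,
    "svm+lda": SVMLDAFusion,
    "cwt+svm": CWTSVMClassifier,
}

MODEL_NAMES = tuple(_REGISTRY)


def make_classifier(spec, **kwargs):
    """Build a classifier from a name or a :class:`BaselineSpec`."""
    if isinstance(spec, BaselineSpec):
        name, params = spec.name, {**spec.hyperparameters, **kwargs}
    else:
        name, params = spec, kwargs
    if name not in _REGISTRY:
        raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
    return _REGISTRY[name](**params)
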