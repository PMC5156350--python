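"""ConvEEGNN: a five-layer convolutional network for single-trial EEG.

Topology
--------
* ``L_in``: the input matrix I (N_ch channels x T time samples).
* ``L_c``: spatial convolution.  Each of ``N_c`` feature maps has one kernel
  of length M = N_ch spanning all channels at a single time index; sliding it
  over time with stride 1 (no padding) yields a map of length S = T.  A map is
  a learned channel combination applied at every time point.
* ``L_cs``: temporal convolution + subsampling.  Map m convolves its ``L_c``
  map with a kernel of length K_m = T / P_m at stride K_m (non-overlapping
  receptive fields), producing P_m outputs: simultaneous temporal filtering
  and downsampling.
* ``L_h``: fully connected, Q neurons (default 10), logistic activation.
* ``L_out``: two logistic neurons (Z_0, Z_1).  Z_0 > Z_1 predicts forgotten,
  otherwise remembered (ties fall to remembered).

``L_c``/``L_cs`` use the scaled hyperbolic tangent f(u) = a tanh(b u) with
a = 1.7159 and b = 2/3.  Training minimizes E = 1/2 ||Z - t||^2 by per-sample
stochastic gradient descent with one-hot targets (forgotten -> (1, 0),
remembered -> (0, 1)), a stratified 70/30 train/validation split, cyclic
duplication of the minority class in the training split, and early stopping
on the validation mean-square error.

Parameter counts per layer: L_c has N_c (M + 1); L_cs has sum_m (K_m + 1);
L_h has Q (sum_m P_m + 1); L_out has 2 (Q + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .types import FORGOTTEN, REMEMBERED


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the network and its training loop.

    ``map_sizes`` lists P_m for each of the ``n_maps`` spatio-temporal map
    pairs; every P_m must divide T so that K_m = T / P_m is integral.
    """

    n_channels: int = 30
    T: int = 75
    n_maps: int = 1
    map_sizes: tuple[int, ...] = (3,)
    q_hidden: int = 10
    a: float = 1.7159
    b: float = 2.0 / 3.0
    learning_rate: float = 0.05
    max_epochs: int = 150
    patience: int = 25
    val_fraction: float = 0.3
    n_restarts: int = 5
    init: str = "uniform"  # or "gaussian"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_maps < 1:
            raise ValueError("n_maps must be >= 1")
        if len(self.map_sizes) != self.n_maps:
            raise ValueError("map_sizes must have one entry per map")
        for p in self.map_sizes:
            if p < 1 or self.T % p != 0:
                raise ValueError(f"map size {p} must divide T={self.T}")
        if self.init not in ("uniform", "gaussian"):
            raise ValueError("init must be 'uniform' or 'gaussian'")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")

    @property
    def kernel_sizes(self) -> tuple[int, ...]:
        """K_m = T / P_m for each map."""
        return tuple(self.T // p for p in self.map_sizes)

    @property
    def n_features(self) -> int:
        """Total L_cs output size feeding L_h."""
        return int(sum(self.map_sizes))


@dataclass
class NetworkParams:
    """All trainable kernels, weights and biases."""

    spatial_kernels: np.ndarray  # (n_maps, M)
    spatial_bias: np.ndarray  # (n_maps,)
    temporal_kernels: list  # n_maps arrays of length K_m
    temporal_bias: np.ndarray  # (n_maps,)
    hidden_weights: np.ndarray  # (Q, sum P_m)
    hidden_bias: np.ndarray  # (Q,)
    output_weights: np.ndarray  # (2, Q)
    output_bias: np.ndarray  # (2,)

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            spatial_kernels=self.spatial_kernels.copy(),
            spatial_bias=self.spatial_bias.copy(),
            temporal_kernels=[k.copy() for k in self.temporal_kernels],
            temporal_bias=self.temporal_bias.copy(),
            hidden_weights=self.hidden_weights.copy(),
            hidden_bias=self.hidden_bias.copy(),
            output_weights=self.output_weights.copy(),
            output_bias=self.output_bias.copy(),
        )

    def arrays(self) -> list:
        """All parameter arrays in a fixed order (views, not copies)."""
        return [
            self.spatial_kernels,
            self.spatial_bias,
            *self.temporal_kernels,
            self.temporal_bias,
            self.hidden_weights,
            self.hidden_bias,
            self.output_weights,
            self.output_bias,
        ]

    def axpy(self, alpha: float, other: "NetworkParams") -> None:
        """In-place self += alpha * other (used for SGD updates)."""
        for dst, src in zip(self.arrays(), other.arrays()):
            dst += alpha * src

    def to_vector(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in self.arrays()])

    def from_vector(self, vec: np.ndarray) -> None:
        pos = 0
        for a in self.arrays():
            a.flat[:] = vec[pos:pos + a.size]
            pos += a.size


@dataclass
class ForwardTrace:
    """Pre-activations and activations of every layer for one input."""

    I: np.ndarray
    u_spatial: np.ndarray  # (n_maps, T)
    x_spatial: np.ndarray
    u_temporal: list  # per map, length P_m
    x_temporal: list
    features: np.ndarray  # concatenated L_cs outputs
    u_hidden: np.ndarray
    x_hidden: np.ndarray
    u_out: np.ndarray
    outputs: np.ndarray  # (Z_0, Z_1)


@dataclass
class TrainResult:
    params: NetworkParams
    history: list  # per-epoch (train_mse, val_mse)
    stopped_epoch: int  # epoch index of the best validation error
    best_val_mse: float


def count_params(cfg: NetworkConfig) -> dict:
    """Trainable-parameter and connection counts per layer."""
    M = cfg.n_channels
    K = cfg.kernel_sizes
    P = cfg.map_sizes
    params = {
        "L_c": cfg.n_maps * (M + 1),
        "L_cs": int(sum(k + 1 for k in K)),
        "L_h": cfg.q_hidden * (cfg.n_features + 1),
        "L_out": 2 * (cfg.q_hidden + 1),
    }
    connections = {
        "L_c": cfg.T * cfg.n_maps * (M + 1),
        "L_cs": int(sum(p * (k + 1) for p, k in zip(P, K))),
    }
    return {"params": params, "connections": connections}


def _init_array(rng, shape, n_inputs: int, kind: str) -> np.ndarray:
    bound = 1.0 / np.sqrt(n_inputs)
    if kind == "uniform":
        return rng.uniform(-bound, bound, size=shape)
    return rng.normal(0.0, bound, size=shape)


def init_params(cfg: NetworkConfig, rng: Optional[np.random.Generator] = None) -> NetworkParams:
    """Draw every weight of a neuron with n inputs from [-1/sqrt(n), +1/sqrt(n)].

    (Or a zero-mean Gaussian with SD 1/sqrt(n) when ``cfg.init == 'gaussian'``.)
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    M = cfg.n_channels
    k = cfg.init
    return NetworkParams(
        spatial_kernels=_init_array(rng, (cfg.n_maps, M), M, k),
        spatial_bias=_init_array(rng, (cfg.n_maps,), M, k),
        temporal_kernels=[_init_array(rng, (km,), km, k) for km in cfg.kernel_sizes],
        temporal_bias=np.array(
            [_init_array(rng, (), km, k) for km in cfg.kernel_sizes], dtype=float
        ),
        hidden_weights=_init_array(rng, (cfg.q_hidden, cfg.n_features), cfg.n_features, k),
        hidden_bias=_init_array(rng, (cfg.q_hidden,), cfg.n_features, k),
        output_weights=_init_array(rng, (2, cfg.q_hidden), cfg.q_hidden, k),
        output_bias=_init_array(rng, (2,), cfg.q_hidden, k),
    )


def zero_grads(cfg: NetworkConfig) -> NetworkParams:
    return NetworkParams(
        spatial_kernels=np.zeros((cfg.n_maps, cfg.n_channels)),
        spatial_bias=np.zeros(cfg.n_maps),
        temporal_kernels=[np.zeros(km) for km in cfg.kernel_sizes],
        temporal_bias=np.zeros(cfg.n_maps),
        hidden_weights=np.zeros((cfg.q_hidden, cfg.n_features)),
        hidden_bias=np.zeros(cfg.q_hidden),
        output_weights=np.zeros((2, cfg.q_hidden)),
        output_bias=np.zeros(2),
    )


def _sigmoid(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-u))


def forward(params: NetworkParams, cfg: NetworkConfig, I: np.ndarray) -> ForwardTrace:
    """Feedforward pass for a single N_ch x T input matrix."""
    I = np.asarray(I, dtype=float)
    if I.shape != (cfg.n_channels, cfg.T):
        raise ValueError(f"input shape {I.shape} != ({cfg.n_channels}, {cfg.T})")
    a, b = cfg.a, cfg.b

    u1 = params.spatial_kernels @ I + params.spatial_bias[:, None]
    x1 = a * np.tanh(b * u1)

    u2, x2 = [], []
    for m, (P, K) in enumerate(zip(cfg.map_sizes, cfg.kernel_sizes)):
        blocks = x1[m].reshape(P, K)
        um = blocks @ params.temporal_kernels[m] + params.temporal_bias[m]
        u2.append(um)
        x2.append(a * np.tanh(b * um))
    features = np.concatenate(x2)

    uh = params.hidden_weights @ features + params.hidden_bias
    xh = _sigmoid(uh)
    uo = params.output_weights @ xh + params.output_bias
    z = _sigmoid(uo)
    return ForwardTrace(
        I=I, u_spatial=u1, x_spatial=x1, u_temporal=u2, x_temporal=x2,
        features=features, u_hidden=uh, x_hidden=xh, u_out=uo, outputs=z,
    )


def backward(
    params: NetworkParams, cfg: NetworkConfig, trace: ForwardTrace, target: np.ndarray
) -> NetworkParams:
    """Gradients of E = 1/2 ||Z - t||^2 with respect to every parameter.

    Shared-kernel gradients are accumulated over every position of the map.
    """
    a, b = cfg.a, cfg.b
    ab = a * b
    g = zero_grads(cfg)

    dz = trace.outputs - np.asarray(target, dtype=float)
    duo = dz * trace.outputs * (1.0 - trace.outputs)
    g.output_weights[:] = np.outer(duo, trace.x_hidden)
    g.output_bias[:] = duo

    dxh = params.output_weights.T @ duo
    duh = dxh * trace.x_hidden * (1.0 - trace.x_hidden)
    g.hidden_weights[:] = np.outer(duh, trace.features)
    g.hidden_bias[:] = duh

    dfeat = params.hidden_weights.T @ duh
    pos = 0
    du1 = np.empty_like(trace.u_spatial)
    for m, (P, K) in enumerate(zip(cfg.map_sizes, cfg.kernel_sizes)):
        dx2 = dfeat[pos:pos + P]
        pos += P
        # f(u) = a tanh(b u)  =>  f'(u) = a b (1 - tanh^2) = a b - (b/a) x^2
        du2 = dx2 * (ab - (b / a) * trace.x_temporal[m] ** 2)
        blocks = trace.x_spatial[m].reshape(P, K)
        g.temporal_kernels[m][:] = du2 @ blocks
        g.temporal_bias[m] = du2.sum()
        dx1 = (du2[:, None] * params.temporal_kernels[m][None, :]).ravel()
        du1[m] = dx1 * (ab - (b / a) * trace.x_spatial[m] ** 2)
    g.spatial_kernels[:] = du1 @ trace.I.T
    g.spatial_bias[:] = du1.sum(axis=1)
    return g


def sample_error(outputs: np.ndarray, target: np.ndarray) -> float:
    d = outputs - target
    return 0.5 * float(d @ d)


def one_hot_target(label: int) -> np.ndarray:
    """Forgotten -> (1, 0); remembered -> (0, 1)."""
    return np.array([1.0, 0.0]) if label == FORGOTTEN else np.array([0.0, 1.0])


def predict(params: NetworkParams, cfg: NetworkConfig, I: np.ndarray) -> int:
    """Decision rule: forgotten iff Z_0 > Z_1, otherwise remembered."""
    z = forward(params, cfg, I).outputs
    return FORGOTTEN if z[0] > z[1] else REMEMBERED


def predict_many(params: NetworkParams, cfg: NetworkConfig, X: np.ndarray) -> np.ndarray:
    return np.array([predict(params, cfg, I) for I in X], dtype=int)


def stratified_split(
    labels: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled split; validation gets round(val_fraction * n_class)."""
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * len(idx)))
        n_val = min(n_val, len(idx) - 1)  # keep at least one training sample
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.array(train_idx, int)), np.sort(np.array(val_idx, int))


def balance_by_duplication(labels: np.ndarray) -> np.ndarray:
    """Indices with the minority class duplicated cyclically to match the majority."""
    idx0 = np.flatnonzero(labels == FORGOTTEN)
    idx1 = np.flatnonzero(labels == REMEMBERED)
    if len(idx0) == 0 or len(idx1) == 0:
        raise ValueError("both classes must be present in the training data")
    minority, majority = (idx0, idx1) if len(idx0) < len(idx1) else (idx1, idx0)
    deficit = len(majority) - len(minority)
    extra = np.resize(minority, deficit) if deficit else np.empty(0, int)
    return np.concatenate([idx0, idx1, extra.astype(int)])


class _ConvCore:
    """Forward/backward/update triple for the shared SGD loop."""

    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.params = init_params(cfg, rng)

    def output_and_error(self, x: np.ndarray, target: np.ndarray) -> float:
        return sample_error(forward(self.params, self.cfg, x).outputs, target)

    def step(self, x: np.ndarray, target: np.ndarray, lr: float) -> float:
        trace = forward(self.params, self.cfg, x)
        grads = backward(self.params, self.cfg, trace, target)
        self.params.axpy(-lr, grads)
        return sample_error(trace.outputs, target)

    def snapshot(self) -> NetworkParams:
        return self.params.copy()


def fit_sgd(
    core,
    X: np.ndarray,
    labels: np.ndarray,
    learning_rate: float,
    max_epochs: int,
    patience: int,
    val_fraction: float,
    rng: np.random.Generator,
    split: Optional[tuple] = None,
) -> TrainResult:
    """Per-sample SGD with stratified validation split, class balancing by
    duplication, epoch-wise reshuffling, and early stopping on validation MSE.

    Shared by ConvEEGNN and the dense baseline networks: ``core`` must expose
    ``step``, ``output_and_error`` and ``snapshot``.  ``split`` supplies a
    fixed (train_idx, val_idx) pair so several restarts can be compared on
    the same validation set.
    """
    labels = np.asarray(labels, int)
    if len(np.unique(labels[labels >= 0])) < 2:
        raise ValueError("training requires at least one sample of each class")
    if split is None:
        train_idx, val_idx = stratified_split(labels, val_fraction, rng)
    else:
        train_idx, val_idx = split
    if len(val_idx) == 0:
        val_idx = train_idx  # degenerate tiny sets: validate on training data
    train_idx = train_idx[balance_by_duplication(labels[train_idx])]
    targets = {i: one_hot_target(labels[i]) for i in np.unique(np.r_[train_idx, val_idx])}

    best_params = core.snapshot()
    best_val = np.inf
    stopped_epoch = -1
    wait = 0
    history = []
    for epoch in range(max_epochs):
        order = rng.permutation(len(train_idx))
        train_err = 0.0
        for j in order:
            i = train_idx[j]
            train_err += core.step(X[i], targets[i], learning_rate)
        train_mse = train_err / len(train_idx)
        val_mse = float(
            np.mean([core.output_and_error(X[i], targets[i]) for i in val_idx])
        )
        history.append((train_mse, val_mse))
        if val_mse < best_val:
            best_val = val_mse
            best_params = core.snapshot()
            stopped_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break
    return TrainResult(
        params=best_params,
        history=history,
        stopped_epoch=stopped_epoch,
        best_val_mse=best_val,
    )


def train(X: np.ndarray, labels: np.ndarray, cfg: NetworkConfig) -> TrainResult:
    """Train a ConvEEGNN on (n_trials, N_ch, T) inputs with class-code labels.

    Stochastic gradient descent on this loss surface is sensitive to the
    starting point, so ``cfg.n_restarts`` independent initializations are
    trained against one shared stratified validation split and the run with
    the lowest validation MSE is returned.
    """
    X = np.asarray(X, float)
    rng = np.random.default_rng(cfg.seed)
    split = stratified_split(np.asarray(labels, int), cfg.val_fraction, rng)
    best: Optional[TrainResult] = None
    for _ in range(cfg.n_restarts):
        core = _ConvCore(cfg, rng)
        res = fit_sgd(
            core, X, labels,
            cfg.learning_rate, cfg.max_epochs, cfg.patience, cfg.val_fraction,
            rng, split=split,
        )
        if best is None or res.best_val_mse < best.best_val_mse:
            best = res
    return best
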