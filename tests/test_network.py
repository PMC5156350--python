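"""Network oracles: naive-reference forward pass, finite-difference
gradients, parameter-count formulas, shift covariance, training machinery."""

import numpy as np
import pytest

from conveegnn.network import (
    NetworkConfig,
    NetworkParams,
    backward,
    balance_by_duplication,
    count_params,
    forward,
    init_params,
    one_hot_target,
    predict,
    predict_many,
    sample_error,
    stratified_split,
    train,
)
from conveegnn.types import FORGOTTEN, REMEMBERED


def naive_forward(params, cfg, I):
    """Literal triple-loop reference implementation of the five layers."""
    a, b = cfg.a, cfg.b

    def f(u):
        return a * np.tanh(b * u)

    def sigma(u):
        return 1.0 / (1.0 + np.exp(-u))

    # L_c: one kernel per map spanning all channels at a single time index,
    # slid over time with stride 1.
    x1 = np.zeros((cfg.n_maps, cfg.T))
    for m in range(cfg.n_maps):
        for s in range(cfg.T):
            u = params.spatial_bias[m]
            for ch in range(cfg.n_channels):
                u += params.spatial_kernels[m, ch] * I[ch, s]
            x1[m, s] = f(u)

    # L_cs: non-overlapping temporal kernels, stride K_m.
    feats = []
    for m, (P, K) in enumerate(zip(cfg.map_sizes, cfg.kernel_sizes)):
        for p in range(P):
            u = params.temporal_bias[m]
            for k in range(K):
                u += params.temporal_kernels[m][k] * x1[m, p * K + k]
            feats.append(f(u))
    feats = np.array(feats)

    xh = np.zeros(cfg.q_hidden)
    for q in range(cfg.q_hidden):
        u = params.hidden_bias[q]
        for j in range(len(feats)):
            u += params.hidden_weights[q, j] * feats[j]
        xh[q] = sigma(u)

    z = np.zeros(2)
    for o in range(2):
        u = params.output_bias[o]
        for q in range(cfg.q_hidden):
            u += params.output_weights[o, q] * xh[q]
        z[o] = sigma(u)
    return z


def finite_difference_gradient(params, cfg, I, target, eps=1e-5):
    """Central finite differences of the sample error over every parameter."""
    vec = params.to_vector()
    fd = np.empty_like(vec)
    probe = init_params(cfg, np.random.default_rng(0))
    for j in range(len(vec)):
        v = vec.copy()
        v[j] += eps
        probe.from_vector(v)
        hi = sample_error(forward(probe, cfg, I).outputs, target)
        v[j] -= 2 * eps
        probe.from_vector(v)
        lo = sample_error(forward(probe, cfg, I).outputs, target)
        fd[j] = (hi - lo) / (2 * eps)
    return fd


def _random_config(rng):
    n_ch = int(rng.integers(2, 8))
    n_maps = int(rng.integers(1, 4))
    T = int(rng.choice([6, 12, 24, 30]))
    divisors = [p for p in range(1, T + 1) if T % p == 0]
    sizes = tuple(int(rng.choice(divisors)) for _ in range(n_maps))
    return NetworkConfig(
        n_channels=n_ch, T=T, n_maps=n_maps, map_sizes=sizes,
        q_hidden=int(rng.integers(2, 8)), seed=int(rng.integers(0, 1000)),
    )


def test_forward_matches_naive_reference():
    rng = np.random.default_rng(0)
    for _ in range(25):
        cfg = _random_config(rng)
        params = init_params(cfg, rng)
        I = rng.normal(size=(cfg.n_channels, cfg.T))
        z = forward(params, cfg, I).outputs
        z_ref = naive_forward(params, cfg, I)
        np.testing.assert_allclose(z, z_ref, atol=1e-12, rtol=0)


def test_gradients_match_finite_differences():
    cfg = NetworkConfig(n_channels=4, T=12, n_maps=2, map_sizes=(3, 4), seed=0)
    rng = np.random.default_rng(1)
    for _ in range(5):
        params = init_params(cfg, rng)
        I = rng.normal(size=(cfg.n_channels, cfg.T))
        target = one_hot_target(int(rng.integers(0, 2)))
        grads = backward(params, cfg, forward(params, cfg, I), target)
        g = grads.to_vector()
        fd = finite_difference_gradient(params, cfg, I, target)
        # normalized max error: relative to the gradient's largest component
        scale = max(np.abs(g).max(), np.abs(fd).max(), 1e-8)
        assert np.max(np.abs(g - fd)) / scale < 1e-6


STANDARD_STRUCTURES = [
    (1, (3,)), (1, (5,)), (1, (15,)), (1, (25,)),
    (2, (3, 3)), (2, (5, 5)), (2, (15, 15)), (2, (25, 25)),
    (2, (3, 5)), (2, (3, 15)), (2, (3, 25)),
]


@pytest.mark.parametrize("n_maps,sizes", STANDARD_STRUCTURES)
def test_parameter_count_formulas(n_maps, sizes):
    """Counts equal N_c(M+1), sum(K_m+1), Q(sum P_m + 1), 2(Q+1)."""
    cfg = NetworkConfig(n_channels=30, T=75, n_maps=n_maps, map_sizes=sizes)
    counts = count_params(cfg)["params"]
    M, Q = 30, 10
    K = [75 // p for p in sizes]
    assert counts["L_c"] == n_maps * (M + 1)
    assert counts["L_cs"] == sum(k + 1 for k in K)
    assert counts["L_h"] == Q * (sum(sizes) + 1)
    assert counts["L_out"] == 2 * (Q + 1)
    # counts must also equal the true number of trainable array elements
    params = init_params(cfg)
    assert sum(counts.values()) == params.to_vector().size


def test_connection_counts():
    cfg = NetworkConfig(n_channels=30, T=75, n_maps=1, map_sizes=(3,))
    conn = count_params(cfg)["connections"]
    assert conn["L_c"] == 75 * 1 * 31
    assert conn["L_cs"] == 3 * (25 + 1)


def test_shift_covariance():
    """Delaying the input by one sample shifts the L_c map by one position."""
    cfg = NetworkConfig(n_channels=5, T=20, n_maps=2, map_sizes=(4, 5), seed=3)
    rng = np.random.default_rng(4)
    params = init_params(cfg, rng)
    I = rng.normal(size=(cfg.n_channels, cfg.T))
    shifted = np.roll(I, 1, axis=1)
    x = forward(params, cfg, I).x_spatial
    x_s = forward(params, cfg, shifted).x_spatial
    np.testing.assert_allclose(x_s[:, 1:], x[:, :-1], atol=1e-12)


def test_decision_rule_and_targets():
    assert np.array_equal(one_hot_target(FORGOTTEN), [1.0, 0.0])
    assert np.array_equal(one_hot_target(REMEMBERED), [0.0, 1.0])
    cfg = NetworkConfig(n_channels=2, T=4, map_sizes=(2,), n_maps=1, q_hidden=2)
    params = init_params(cfg)
    # force the output layer: Z_0 > Z_1 -> forgotten
    params.output_weights[:] = 0.0
    params.output_bias[:] = [2.0, -2.0]
    assert predict(params, cfg, np.zeros((2, 4))) == FORGOTTEN
    params.output_bias[:] = [-2.0, 2.0]
    assert predict(params, cfg, np.zeros((2, 4))) == REMEMBERED
    params.output_bias[:] = [0.5, 0.5]  # tie falls to remembered
    assert predict(params, cfg, np.zeros((2, 4))) == REMEMBERED


def test_invalid_map_size_rejected():
    with pytest.raises(ValueError):
        NetworkConfig(T=75, n_maps=1, map_sizes=(4,))
    with pytest.raises(ValueError):
        NetworkConfig(n_maps=2, map_sizes=(3,))


def test_init_bounds():
    cfg = NetworkConfig(n_channels=30, T=75)
    params = init_params(cfg, np.random.default_rng(0))
    bound = 1.0 / np.sqrt(30)
    assert np.all(np.abs(params.spatial_kernels) <= bound)
    bound_h = 1.0 / np.sqrt(cfg.n_features)
    assert np.all(np.abs(params.hidden_weights) <= bound_h)


def test_stratified_split_proportions():
    labels = np.array([0] * 10 + [1] * 20)
    tr, va = stratified_split(labels, 0.3, np.random.default_rng(0))
    assert len(np.intersect1d(tr, va)) == 0
    assert len(tr) + len(va) == 30
    assert (labels[va] == 0).sum() == 3 and (labels[va] == 1).sum() == 6


def test_balance_by_duplication():
    labels = np.array([0, 0, 0, 1, 1, 1, 1, 1, 1, 1])
    idx = balance_by_duplication(labels)
    bal = labels[idx]
    assert (bal == 0).sum() == (bal == 1).sum() == 7
    # every original sample still present
    assert set(idx) == set(range(10))
    with pytest.raises(ValueError):
        balance_by_duplication(np.array([1, 1, 1]))


def test_training_learns_separable_data():
    """A strongly separated two-class problem is fit well above chance."""
    rng = np.random.default_rng(0)
    n, n_ch, T = 40, 4, 12
    labels = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, n_ch, T))
    X[labels == 1, 0, :] += 3.0
    cfg = NetworkConfig(n_channels=n_ch, T=T, n_maps=1, map_sizes=(3,),
                        max_epochs=60, n_restarts=2, seed=0)
    res = train(X, labels, cfg)
    acc = np.mean(predict_many(res.params, cfg, X) == labels)
    assert acc >= 0.9
    assert res.best_val_mse < 0.1


def test_training_deterministic():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(20, 3, 6))
    labels = np.array([0, 1] * 10)
    cfg = NetworkConfig(n_channels=3, T=6, map_sizes=(2,), max_epochs=10,
                        n_restarts=2, seed=5)
    r1 = train(X, labels, cfg)
    r2 = train(X, labels, cfg)
    np.testing.assert_array_equal(r1.params.to_vector(), r2.params.to_vector())


def test_training_requires_both_classes():
    X = np.zeros((5, 3, 6))
    cfg = NetworkConfig(n_channels=3, T=6, map_sizes=(2,))
    with pytest.raises(ValueError):
        train(X, np.ones(5, dtype=int), cfg)
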