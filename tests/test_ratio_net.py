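"""The network's combinatorics, scale robustness, determinism, training and
ensemble contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ratioage import (
    RatioNetConfig,
    age_group_bias,
    build_dense_net,
    build_ratio_net,
    predict_ensemble,
    ratio_expand,
    rmse,
    train_ensemble,
    train_single,
)
from ratioage.ratio_net import EnsembleModel, member_seeds, ratio_pairs

FAST = dict(epochs=30, batch_size=50, seed=3)


def _toy_data(n=200, p=20, seed=0, beta_scale=2.0):
    rng = np.random.default_rng(seed)
    x = rng.lognormal(0, 0.5, size=(n, p))
    beta = np.zeros(p)
    beta[:3] = beta_scale
    y = 30 + np.log(x) @ beta + rng.normal(0, 1, n)
    return (x[: n // 2], y[: n // 2]), (x[n // 2 :], y[n // 2 :])


# ---------------------------------------------------------------------------
# ratio expansion


def test_twelve_nodes_give_66_ratios():
    assert len(ratio_expand(np.arange(1.0, 13.0))) == 66


def test_pairwise_ratios_lexicographic():
    assert np.allclose(ratio_expand([2.0, 4.0, 8.0]), [0.5, 0.25, 0.5])


@settings(derandomize=True, max_examples=30)
@given(n=st.integers(2, 40))
def test_ratio_width_formula(n):
    v = np.linspace(1, 2, n)
    assert len(ratio_expand(v)) == n * (n - 1) // 2


def test_ratio_scale_cancellation_exact():
    rng = np.random.default_rng(1)
    v = rng.normal(size=(10, 8))
    for c in (0.25, 4.0, 1024.0):  # power-of-two scales: bit-identical quotients
        assert np.array_equal(ratio_expand(v), ratio_expand(c * v))
    for c in (0.01, 3.0, 1e4):
        assert np.allclose(ratio_expand(v), ratio_expand(c * v), rtol=1e-12)


def test_ratio_epsilon_stabilizes_zero_denominator():
    out = ratio_expand(np.array([1.0, 0.0]), epsilon=1e-6)
    assert out[0] == 1e6


def test_ratio_requires_two_values():
    with pytest.raises(ValueError, match="at least 2"):
        ratio_expand(np.array([1.0]))


# ---------------------------------------------------------------------------
# architecture


def test_parameter_count_matches_closed_form():
    p = 500
    net = build_ratio_net(RatioNetConfig(), p)
    count = sum(param.value.size for param in net.params())
    expected = (
        (p * 12 + 12)          # compression layer
        + (66 + 66)            # batch norm after the ratio layer
        + (66 * 33 + 33) + (33 + 33)   # hidden 1 + its batch norm
        + (33 * 33 + 33) + (33 + 33)   # hidden 2 + its batch norm
        + (33 * 1 + 1)         # output
    )
    assert count == expected


def test_minimal_compression_gives_single_ratio():
    cfg = RatioNetConfig(n_compress=2)
    assert cfg.ratio_width == 1
    net = build_ratio_net(cfg, 10)
    out = net.forward(np.random.default_rng(0).lognormal(size=(4, 10)))
    assert out.shape == (4, 1)


def test_same_seed_identical_initialization():
    a = build_ratio_net(RatioNetConfig(seed=9), 50)
    b = build_ratio_net(RatioNetConfig(seed=9), 50)
    for pa, pb in zip(a.params(), b.params()):
        assert np.array_equal(pa.value, pb.value)


def test_invalid_configs_rejected():
    for bad in (
        dict(n_compress=1),
        dict(dropout=1.0),
        dict(weight_decays=(0.5, 0.0, -0.1, 0.01, 0.0)),
        dict(checkpoint_policy="nope"),
        dict(ratio_epsilon=-1e-9),
    ):
        with pytest.raises(ValueError):
            build_ratio_net(RatioNetConfig(**bad), 10)


def test_pre_normalization_activations_scale_invariant():
    """With no first-layer offset and epsilon 0, the ratio activations for x
    and c*x agree at machine precision: the common scale cancels."""
    cfg = RatioNetConfig(first_layer_bias=False, ratio_epsilon=0.0, seed=4)
    net = build_ratio_net(cfg, 25)
    lin, ratio = net.layers[1], net.layers[2]
    rng = np.random.default_rng(8)
    x = rng.lognormal(0, 1, size=(100, 25))
    base = ratio.forward(lin.forward(x, False, None), False, None)
    for c in (1e-3, 0.5, 7.0, 1e5):
        scaled = ratio.forward(lin.forward(c * x, False, None), False, None)
        assert np.allclose(scaled, base, rtol=1e-9, atol=0)


# ---------------------------------------------------------------------------
# training


def test_zero_epochs_returns_initialization():
    train, dev = _toy_data()
    cfg = RatioNetConfig(epochs=0, seed=5)
    net = build_ratio_net(cfg, 20)
    init = [p.value.copy() for p in net.params()]
    net, hist = train_single(net, train, dev, cfg)
    assert hist.empty
    for p, v in zip(net.params(), init):
        assert np.array_equal(p.value, v)


def test_training_is_deterministic():
    train, dev = _toy_data()
    cfg = RatioNetConfig(**FAST)
    _, h1 = train_single(build_ratio_net(cfg, 20), train, dev, cfg)
    _, h2 = train_single(build_ratio_net(cfg, 20), train, dev, cfg)
    pd.testing.assert_frame_equal(h1, h2)


def test_training_beats_constant_mean_predictor():
    train, dev = _toy_data(n=400, seed=2)
    cfg = RatioNetConfig(epochs=150, batch_size=50, seed=1)
    net, hist = train_single(build_ratio_net(cfg, 20), train, dev, cfg)
    baseline = rmse(np.full(len(dev[1]), train[1].mean()), dev[1])
    dev_rmse = np.sqrt(hist["dev_loss"].iloc[-1])
    assert dev_rmse < baseline
    assert list(hist.columns) == ["epoch", "train_loss", "dev_loss"]
    assert len(hist) == 150


def test_best_dev_checkpoint_no_worse_than_final():
    train, dev = _toy_data(n=300, seed=6)
    cfg_final = RatioNetConfig(epochs=60, batch_size=50, seed=2)
    cfg_best = RatioNetConfig(epochs=60, batch_size=50, seed=2,
                              checkpoint_policy="best_dev")
    _, hist = train_single(build_ratio_net(cfg_final, 20), train, dev, cfg_final)
    net_best, _ = train_single(build_ratio_net(cfg_best, 20), train, dev, cfg_best)
    best_rmse = rmse(net_best.predict(dev[0]), dev[1])
    assert best_rmse <= np.sqrt(hist["dev_loss"].iloc[-1]) + 1e-9


def test_feature_mismatch_rejected():
    train, dev = _toy_data()
    cfg = RatioNetConfig(**FAST)
    net = build_ratio_net(cfg, 7)
    with pytest.raises(ValueError, match="feature"):
        train_single(net, train, dev, cfg)


# ---------------------------------------------------------------------------
# ensemble


@pytest.fixture(scope="module")
def small_ensemble():
    train, dev = _toy_data(n=300, seed=10)
    cfg = RatioNetConfig(epochs=40, batch_size=50, seed=20)
    return train_ensemble(train, dev, cfg, k=5), train, dev


def test_ensemble_members_distinct_and_histories_kept(small_ensemble):
    model, _, dev = small_ensemble
    assert model.n_members == 5
    assert len(set(model.member_seeds)) == 5
    assert len(model.histories) == 5
    assert all(np.isfinite(h["dev_loss"]).all() for h in model.histories)


def test_ensemble_mean_is_member_average(small_ensemble):
    model, _, dev = small_ensemble
    preds = predict_ensemble(model, dev)
    members = preds.member_predictions().to_numpy()
    assert np.allclose(preds.mean.to_numpy(), members.mean(axis=1))
    assert (preds.se.to_numpy() > 0).all()


def test_single_member_ensemble_equals_member(small_ensemble):
    _, train, dev = small_ensemble
    cfg = RatioNetConfig(epochs=20, batch_size=50, seed=30)
    model = train_ensemble(train, dev, cfg, k=1)
    preds = predict_ensemble(model, dev)
    assert np.allclose(preds.mean.to_numpy(), model.members[0].predict(dev[0]))
    assert np.allclose(preds.se.to_numpy(), 0.0)


def test_identical_members_zero_standard_error(small_ensemble):
    model, _, dev = small_ensemble
    clone = EnsembleModel(
        members=[model.members[0]] * 3,
        member_seeds=[0, 0, 0],
        histories=model.histories[:1] * 3,
        config=model.config,
    )
    preds = predict_ensemble(clone, dev)
    assert np.allclose(preds.se.to_numpy(), 0.0)


def test_prediction_invariant_to_sample_order(small_ensemble):
    model, _, dev = small_ensemble
    x, y = dev
    perm = np.random.default_rng(3).permutation(len(x))
    direct = predict_ensemble(model, (x, y)).mean.to_numpy()
    permuted = predict_ensemble(model, (x[perm], y[perm])).mean.to_numpy()
    assert np.allclose(direct[perm], permuted)


def test_ensemble_mse_never_exceeds_mean_member_mse(small_ensemble):
    """Averaging K predictors cannot increase squared error (Jensen)."""
    model, _, dev = small_ensemble
    preds = predict_ensemble(model, dev)
    members = preds.member_predictions().to_numpy()
    member_mse = np.mean((members - dev[1][:, None]) ** 2, axis=0)
    ensemble_mse = np.mean((preds.mean.to_numpy() - dev[1]) ** 2)
    assert ensemble_mse <= member_mse.mean() + 1e-12


def test_member_seeds_deterministic_and_distinct():
    a = member_seeds(42, 10)
    assert a == member_seeds(42, 10)
    assert len(set(a)) == 10
    assert all(0 <= s < 2**31 for s in a)


def test_save_load_round_trip(small_ensemble, tmp_path):
    model, _, dev = small_ensemble
    path = tmp_path / "ensemble.npz"
    model.save(path)
    back = EnsembleModel.load(path)
    assert np.allclose(
        predict_ensemble(back, dev).mean, predict_ensemble(model, dev).mean
    )


# ---------------------------------------------------------------------------
# evaluation


def test_rmse_examples():
    assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))
    truth = np.array([20.0, 30.0, 40.0])
    assert rmse(truth + 5, truth) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        rmse([], [])


def test_age_group_bias_constant_offset():
    truth = np.linspace(20, 60, 50)
    table, accel = age_group_bias(truth + 5.0, truth, bin_width=10)
    assert np.allclose(table["mean_residual"], 5.0)
    # a uniform shift cancels out of the bin-relative acceleration score
    _, accel_unshifted = age_group_bias(truth, truth, bin_width=10)
    assert np.allclose(accel, accel_unshifted, atol=1e-9)


def test_age_group_bias_unbiased_predictor():
    truth = np.linspace(20, 60, 50)
    table, _ = age_group_bias(truth, truth, bin_width=10)
    assert np.allclose(table["mean_residual"], 0.0)
    assert table["n"].sum() == 50


def test_regression_to_mean_on_skewed_cohort():
    """A weak-signal predictor shrinks to the mean: old bins under-, young
    bins over-predicted."""
    rng = np.random.default_rng(12)
    truth = 15 + rng.lognormal(np.log(14), 0.5, size=2000)
    pred = truth.mean() + 0.3 * (truth - truth.mean()) + rng.normal(0, 2, truth.shape)
    table, _ = age_group_bias(pred, truth, bin_width=10)
    assert table["mean_residual"].iloc[-1] < 0  # oldest bin under-predicted
    assert table["mean_residual"].iloc[0] > 0  # youngest bin over-predicted
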