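"""Dense convolutional classifier: structure, gradients, training, search."""

import numpy as np
import pytest

from tkrisk.nn import (
    DenseNetConfig,
    SearchSpace,
    TrainConfig,
    build_model,
    predict_risk,
    random_search,
    train_epochwise,
)
from tkrisk.nn import layers as L

TINY = DenseNetConfig(
    dimensionality=3,
    initial_filters=4,
    growth_rate=4,
    block_config=(1, 1),
    bottleneck_layers=2,
    dropout_rate=0.0,
    init_kernel=3,
    seed=0,
)


def blob_data(n, shape=(8, 12, 12), effect=3.0, seed=0):
    """Two-class volumes: class 1 carries a bright corner blob."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.normal(0, 1, size=(n,) + shape).astype(np.float32)
    X[y == 1, 2:6, 3:9, 3:9] += effect
    return X, y


class TestArchitecture:
    def test_identical_configs_identical_signature(self):
        a = build_model(TINY)
        b = build_model(TINY)
        assert a.architecture_signature() == b.architecture_signature()

    def test_doubling_growth_strictly_more_parameters(self):
        import dataclasses

        bigger = dataclasses.replace(TINY, growth_rate=8)
        assert build_model(bigger).n_parameters() > build_model(TINY).n_parameters()

    def test_desk_scale_forward_two_finite_scores(self):
        model = build_model(DenseNetConfig.desk_scale(seed=1))
        out = model.forward(np.zeros((1, 24, 48, 48), dtype=np.float32))
        assert out.shape == (1, 2)
        assert np.isfinite(out).all()

    def test_paper_scale_config_constructible(self):
        cfg = DenseNetConfig(dimensionality=2)
        model = build_model(cfg)
        sig = model.architecture_signature()
        assert len(sig) > 100  # 121-layer-class network
        # final feature width follows the dense/transition arithmetic
        ch = cfg.initial_filters
        for i, n in enumerate(cfg.block_config):
            ch += n * cfg.growth_rate
            if i < len(cfg.block_config) - 1:
                ch //= 2
        assert sig[-1][1][0] == (ch, 2)

    def test_2d_variant_runs(self):
        cfg = DenseNetConfig(
            dimensionality=2, initial_filters=4, growth_rate=4,
            block_config=(1, 1), bottleneck_layers=2, init_kernel=3, seed=0,
        )
        out = build_model(cfg).forward(np.zeros((2, 24, 24), dtype=np.float32))
        assert out.shape == (2, 2)

    def test_dimensionality_mismatch_raises(self):
        model = build_model(TINY)
        with pytest.raises(ValueError, match="spatial"):
            model.forward(np.zeros((2, 3, 4, 5, 6, 7)))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            DenseNetConfig(dimensionality=4)
        with pytest.raises(ValueError):
            DenseNetConfig(block_config=())
        with pytest.raises(ValueError):
            DenseNetConfig(dropout_rate=1.0)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        model = build_model(TINY)
        X = np.random.default_rng(2).normal(size=(3, 8, 12, 12)).astype(np.float32)
        y = np.array([0, 1, 1])

        def loss_fn():
            logits = model.forward(X, train=True)
            return L.weighted_cross_entropy(logits, y, (0.7, 0.3))

        for mod in model.parameterized_modules():
            for p in mod.params():
                p.grad[...] = 0.0
        _, grad = loss_fn()
        model.backward(grad)
        rng = np.random.default_rng(0)
        checked = 0
        for mod in model.parameterized_modules():
            for p in mod.params():
                flat = p.value.ravel()
                i = int(rng.integers(flat.size))
                eps = np.float32(1e-2)
                old = flat[i]
                flat[i] = old + eps
                lp, _ = loss_fn()
                flat[i] = old - eps
                lm, _ = loss_fn()
                flat[i] = old
                numeric = (lp - lm) / (2 * eps)
                analytic = float(p.grad.ravel()[i])
                assert numeric == pytest.approx(analytic, rel=0.15, abs=5e-3)
                checked += 1
        assert checked >= 10

    def test_weighted_loss_half_weights_is_half_unweighted(self):
        rng = np.random.default_rng(1)
        logits = rng.normal(size=(6, 2))
        y = np.array([0, 1, 0, 1, 1, 0])
        lw, _ = L.weighted_cross_entropy(logits, y, (0.5, 0.5))
        lu, _ = L.weighted_cross_entropy(logits, y, (1.0, 0.0))
        lu2, _ = L.weighted_cross_entropy(logits, y, (0.0, 1.0))
        # (0.5, 0.5) = half of the (1,0)+(0,1) decomposition
        assert lw == pytest.approx(0.5 * (lu + lu2), rel=1e-6)


class TestTraining:
    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        model = build_model(TINY)
        params = [p for m in model.parameterized_modules() for p in m.params()]
        before = [p.value.copy() for p in params]
        X, y = blob_data(16)
        train_epochwise(
            model, (X, y), (X, y),
            TrainConfig(learning_rate=0.0, max_epochs=2, batch_size=8),
        )
        for a, p in zip(before, params):
            np.testing.assert_array_equal(a, p.value)

    def test_learns_separable_blobs(self):
        X, y = blob_data(100, seed=3)
        Xv, yv = blob_data(40, seed=4)
        model = build_model(TINY)
        model, history = train_epochwise(
            model, (X, y), (Xv, yv),
            TrainConfig(learning_rate=3e-3, max_epochs=20, patience=3,
                        batch_size=10, seed=0),
        )
        probs = model.predict_proba(X)[:, 1]
        acc = ((probs >= 0.5).astype(int) == y).mean()
        assert acc >= 0.95
        assert len(history) <= 20

    def test_frozen_layers_bitwise_unchanged(self):
        model = build_model(TINY)
        mods = model.parameterized_modules()
        before = {id(p): p.value.copy() for m in mods for p in m.params()}
        X, y = blob_data(16)
        train_epochwise(
            model, (X, y), (X, y),
            TrainConfig(learning_rate=1e-2, max_epochs=2, batch_size=8,
                        frozen_layers=len(mods) - 1),
        )
        for mod in mods:
            for p in mod.params():
                same = np.array_equal(before[id(p)], p.value)
                if mod is model.head:
                    assert not same  # only the classification head moved
                else:
                    assert same

    def test_partial_freeze_updates_only_tail(self):
        model = build_model(TINY)
        mods = model.parameterized_modules()
        model.set_frozen(len(mods) - 3)  # train last 2 trunk layers + head
        frozen = [m for m in mods[:-1] if not m.trainable]
        assert len(frozen) == len(mods) - 3

    def test_early_stopping_on_rising_validation_loss(self):
        # high LR on noise labels makes validation loss bounce; the loop
        # must halt at the first rise (patience 1) and keep the best epoch
        rng = np.random.default_rng(5)
        X = rng.normal(size=(24, 8, 12, 12)).astype(np.float32)
        y = rng.integers(0, 2, 24)
        y[:2] = [0, 1]
        model = build_model(TINY)
        model, history = train_epochwise(
            model, (X, y), (X[:12], y[:12]),
            TrainConfig(learning_rate=0.05, max_epochs=30, patience=1, seed=1),
        )
        losses = history["val_loss"].to_numpy()
        rises = np.flatnonzero(np.diff(losses) > 0)
        if rises.size:  # stopped exactly at the first rise
            assert len(losses) == rises[0] + 2

    def test_single_class_training_rejected(self):
        X, _ = blob_data(8)
        with pytest.raises(ValueError, match="single class"):
            train_epochwise(build_model(TINY), (X, np.zeros(8, int)),
                            (X, np.zeros(8, int)), TrainConfig(max_epochs=1))

    def test_predict_risk_contract(self):
        model = build_model(TINY)
        vol = np.random.default_rng(0).normal(size=(8, 12, 12))
        r1 = predict_risk(model, vol)
        r2 = predict_risk(model, vol)
        assert 0.0 <= r1 <= 1.0
        assert r1 == r2

    def test_trained_model_separates_classes_held_out(self):
        X, y = blob_data(80, seed=6)
        Xt, yt = blob_data(30, seed=7)
        model = build_model(TINY)
        model, _ = train_epochwise(
            model, (X, y), (Xt, yt),
            TrainConfig(learning_rate=3e-3, max_epochs=12, patience=3,
                        batch_size=10, seed=2),
        )
        risks = predict_risk(model, Xt)
        assert risks[yt == 1].mean() > risks[yt == 0].mean()


class TestRandomSearch:
    def _space(self, n_iter=3):
        return SearchSpace(
            lr_range=(1e-4, 1e-2),
            dropout_range=(0.0, 0.2),
            w_tkr_range=(0.5, 0.9),
            frozen_choices=("last-2", "all-but-head"),
            n_iter=n_iter,
            subset_fraction=0.5,
            seed=3,
        )

    def test_single_iteration_returns_sampled_config(self):
        X, y = blob_data(24, seed=8)
        model = build_model(TINY)
        config, report = random_search(
            self._space(1), model, (X, y), (X, y), max_epochs=1, batch_size=8
        )
        assert len(report) == 1
        assert config.learning_rate == report.loc[0, "learning_rate"]

    def test_seed_determinism(self):
        X, y = blob_data(24, seed=9)
        a, ra = random_search(self._space(3), build_model(TINY), (X, y), (X, y),
                              max_epochs=1, batch_size=8)
        b, rb = random_search(self._space(3), build_model(TINY), (X, y), (X, y),
                              max_epochs=1, batch_size=8)
        assert a == b
        assert ra.equals(rb)

    def test_returns_argmax_of_report(self):
        X, y = blob_data(40, seed=10)
        config, report = random_search(
            self._space(4), build_model(TINY), (X, y), (X, y),
            max_epochs=2, batch_size=8,
        )
        best = report.loc[report["score"].idxmax()]
        assert config.learning_rate == best["learning_rate"]
        # ties (if any) resolve to the earliest iteration
        top = report[report["score"] == report["score"].max()]
        assert best["iteration"] == top["iteration"].min()
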