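import numpy as np
import pytest

from topobrain.ensemble import (
    DEFAULT_ROSTER,
    EnsembleConfig,
    fit_stacked_ensemble,
    rfe_select,
)
from topobrain.hybridnet import HybridNet, HybridNetConfig, fit_hybrid_net


def planted_features(rng, n=200, informative=0):
    """Ten features, one of which linearly separates the two classes."""
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, 10))
    X[:, informative] += 3.0 * y
    return X, y


class TestRFE:
    def test_planted_informative_feature_is_retained(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = planted_features(rng, informative=seed % 10)
            kept = rfe_select(X, y, n_selected=5, seed=seed)
            hits += (seed % 10) in kept
        assert hits >= 19  # the separating feature essentially always survives

    def test_selecting_all_features_is_identity(self, rng):
        X, y = planted_features(rng)
        assert rfe_select(X, y, n_selected=10).tolist() == list(range(10))

    def test_single_class_is_rejected(self, rng):
        X = rng.standard_normal((20, 10))
        with pytest.raises(ValueError, match="class"):
            rfe_select(X, np.zeros(20), n_selected=5)

    def test_deterministic_given_seed(self, rng):
        X, y = planted_features(rng, n=60)
        assert np.array_equal(rfe_select(X, y, seed=5),
                              rfe_select(X, y, seed=5))


class TestStackedEnsemble:
    def test_separable_classes_reach_perfect_held_out_accuracy(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100)
        X = rng.standard_normal((100, 10))
        X[:, 3] = rng.uniform(0, 1, 100) + 3.0 * y  # margin of 2 on feature 3
        model, report = fit_stacked_ensemble(X, y, EnsembleConfig(seed=0))
        assert report["held_out_accuracy"] == 1.0
        assert len(report["stack_members"]) == 5
        assert len(report["selected_features"]) == 5
        assert set(report["cv_ranking"]) == set(DEFAULT_ROSTER)

    def test_noise_features_stay_near_chance(self):
        """Random labels, noise features: pooled held-out accuracy within
        3 binomial standard errors of 0.5 over 8 seeds."""
        hits = total = 0
        for seed in range(8):
            rng = np.random.default_rng(400 + seed)
            X = rng.standard_normal((50, 10))
            y = rng.integers(0, 2, 50)
            if min(np.bincount(y)) < 5:
                continue
            _, report = fit_stacked_ensemble(X, y, EnsembleConfig(seed=seed))
            hits += report["held_out_accuracy"] * report["n_test"]
            total += report["n_test"]
        se = np.sqrt(0.25 / total)
        assert abs(hits / total - 0.5) < 3 * se

    def test_report_is_reproducible(self):
        rng = np.random.default_rng(1)
        X, y = planted_features(rng, n=60)
        _, r1 = fit_stacked_ensemble(X, y, EnsembleConfig(seed=9))
        _, r2 = fit_stacked_ensemble(X, y, EnsembleConfig(seed=9))
        assert r1 == r2

    def test_substitution_is_recorded(self, rng):
        X, y = planted_features(rng, n=60)
        _, report = fit_stacked_ensemble(X, y, EnsembleConfig(seed=2))
        assert report["substitutions"] == {"catboost": "hist_gradient_boosting"}

    def test_class_below_fold_count_is_rejected(self, rng):
        X = rng.standard_normal((7, 10))
        y = np.array([0, 0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="cv_folds"):
            fit_stacked_ensemble(X, y, EnsembleConfig(seed=0))


def tiny_net_config(**kw):
    base = dict(n_trials=1, max_epochs=4, seed=0)
    base.update(kw)
    return HybridNetConfig(**base)


class TestHybridNet:
    def test_forward_pass_outputs_probabilities(self, rng):
        net = HybridNet(34, HybridNetConfig(), seed=0)
        X = rng.standard_normal((3, 34, 34))
        probs = net.forward(X)
        assert probs.shape == (3, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(probs >= 0)

    def test_parameter_count_matches_the_layer_arithmetic(self):
        n = 34
        net = HybridNet(n, HybridNetConfig(), seed=0)
        conv = ((1 * 9 * 16 + 16) + (16 * 9 * 32 + 32) + (32 * 9 * 64 + 64)
                + (64 * 9 * 128 + 128) + (128 * 9 * 256 + 256))
        flat = n * n * 256 + 256
        dense = (512 * 128 + 128) + (128 * 64 + 64) + (64 * 32 + 32)
        head = 32 * 2 + 2
        assert net.parameter_count() == conv + flat + dense + head

    def test_single_class_is_rejected(self, rng):
        mats = {f"s{i}": rng.standard_normal((6, 6)) for i in range(8)}
        labels = {s: "HC" for s in mats}
        with pytest.raises(ValueError, match="2 classes"):
            fit_hybrid_net(mats, labels, tiny_net_config())

    def test_inconsistent_matrix_sizes_are_rejected(self, rng):
        mats = {"s0": rng.standard_normal((6, 6)),
                "s1": rng.standard_normal((7, 7))}
        with pytest.raises(ValueError, match="size"):
            fit_hybrid_net(mats, {"s0": "A", "s1": "B"}, tiny_net_config())

    def test_fit_is_reproducible(self, rng):
        mats = {f"s{i}": rng.standard_normal((6, 6)) for i in range(12)}
        labels = {s: ("A" if i < 6 else "B")
                  for i, s in enumerate(mats)}
        _, r1 = fit_hybrid_net(mats, labels, tiny_net_config(seed=4))
        _, r2 = fit_hybrid_net(mats, labels, tiny_net_config(seed=4))
        assert r1 == r2

    def test_gradients_match_finite_differences(self):
        """Backprop through both branches agrees with numerical gradients."""
        rng = np.random.default_rng(3)
        net = HybridNet(5, HybridNetConfig(
            conv_filters_block1=(2, 3, 4), conv_filters_block2=(4, 5),
            flat_branch_width=6, dense_widths=(5, 4, 3), dropout=0.0),
            seed=1)
        X = rng.standard_normal((2, 5, 5))
        y = np.array([0, 1])
        net.forward(X, train=True, rng=rng)
        net.backward(y)
        grads = {k: v.copy() for k, v in net.gradients().items()}
        params = net.parameters()
        eps = 1e-6
        for key in ["flat.W", "conv1_0.W", "conv2_1.W", "dense_0.W",
                    "head.b"]:
            p = params[key]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + eps
            lp = net.loss(X, y)
            p[idx] = orig - eps
            lm = net.loss(X, y)
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[key][idx] == pytest.approx(num, abs=1e-5, rel=1e-3)

    def test_planted_block_structure_is_recovered(self):
        """Matrices whose upper block is shifted for one class are learnable:
        pooled held-out accuracy beats chance by 3 binomial s.e."""
        hits = total = 0
        for seed in range(10):
            rng = np.random.default_rng(500 + seed)
            mats, labels = {}, {}
            for i in range(28):
                cls = i % 2
                m = rng.standard_normal((10, 10))
                m = (m + m.T) / 2
                if cls:
                    m[:5, :5] += 1.5
                mats[f"s{i}"] = m
                labels[f"s{i}"] = cls
            cfg = HybridNetConfig(n_trials=2, max_epochs=25, seed=seed)
            _, report = fit_hybrid_net(mats, labels, cfg)
            hits += report["held_out_accuracy"] * report["n_test"]
            total += report["n_test"]
        se = np.sqrt(0.25 / total)
        assert hits / total > 0.5 + 3 * se
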