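import numpy as np
import pandas as pd
import pytest

from eegscreen.classify import (
    MLPConfig,
    StandardizationStats,
    TrainedModel,
    predict_trials,
    standardize,
    train_lda,
    train_mlp,
    train_qda,
    tune_mlp,
)
from eegscreen.core import ConfigurationError


def blobs(rng, n=120, sep=6.0):
    """Three well-separated Gaussian blobs in 2-D."""
    y = np.repeat(["HC", "MCI", "AD"], n // 3)
    centres = {"HC": (0, 0), "MCI": (sep, 0), "AD": (0, sep)}
    x = np.vstack([rng.normal(centres[c], 1.0, size=(1, 2))[0] for c in y])
    return x, y


def xor3(rng, n_per=60, noise=0.25):
    """Three classes arranged so no linear boundary separates them."""
    y = []
    pts = []
    corners = {"HC": [(0, 0), (4, 4)], "MCI": [(0, 4), (4, 0)],
               "AD": [(2, 2)]}
    for cls, cs in corners.items():
        for c in cs:
            pts.append(rng.normal(c, noise, size=(n_per, 2)))
            y += [cls] * n_per
    return np.vstack(pts), np.array(y)


class TestStandardize:
    def test_training_split_zero_mean_unit_sd(self, rng):
        df = pd.DataFrame(rng.normal(3, 2, (50, 2)), columns=["a", "b"])
        stats = StandardizationStats.fit(df, ["a", "b"])
        out = standardize(df, stats)
        assert np.allclose(out[["a", "b"]].mean(), 0.0, atol=1e-9)
        assert np.allclose(out[["a", "b"]].std(ddof=1), 1.0, atol=1e-9)

    def test_double_application_not_identity(self, rng):
        df = pd.DataFrame(rng.normal(3, 2, (50, 2)), columns=["a", "b"])
        stats = StandardizationStats.fit(df, ["a", "b"])
        once = standardize(df, stats)
        twice = standardize(once, stats)
        assert not np.allclose(once[["a", "b"]], twice[["a", "b"]])

    def test_roundtrip_inverse(self, rng):
        df = pd.DataFrame(rng.normal(0, 5, (30, 2)), columns=["a", "b"])
        stats = StandardizationStats.fit(df, ["a", "b"])
        back = stats.invert(stats.apply(df))
        assert np.allclose(back[["a", "b"]], df[["a", "b"]], atol=1e-9)

    def test_zero_sd_feature_raises(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ConfigurationError, match="zero-variance"):
            StandardizationStats.fit(df, ["a", "b"])


class TestLDA:
    def test_separable_blobs(self, rng):
        x, y = blobs(rng)
        model = train_lda(x, y)
        pred, _ = predict_trials(model, x)
        assert (pred == y).mean() >= 0.95

    def test_linear_decision_regions_are_convex(self, rng):
        x, y = blobs(rng)
        mask = y != "AD"  # binary sub-problem
        model = train_lda(x[mask], y[mask])
        p1 = np.array([-1.0, -1.0])
        p2 = np.array([1.5, 0.5])
        l1, _ = predict_trials(model, p1[None, :])
        l2, _ = predict_trials(model, p2[None, :])
        if l1[0] == l2[0]:
            for t in (0.25, 0.5, 0.75):
                mid, _ = predict_trials(model, ((1 - t) * p1 + t * p2)[None, :])
                assert mid[0] == l1[0]

    def test_self_consistency_error_matches_posterior_uncertainty(self, rng):
        x, y = blobs(rng, sep=2.5)
        model = train_lda(x, y)
        # simulate a large sample from the fitted model's own Gaussians
        sims, labels = [], []
        for i, cls in enumerate(model.classes):
            sims.append(rng.multivariate_normal(
                model.means[i], model.covariances, size=4000))
            labels += [cls] * 4000
        sims = np.vstack(sims)
        labels = np.asarray(labels)
        pred, post = predict_trials(model, sims)
        err = (pred != labels).mean()
        bayes = float((1.0 - post.max(axis=1)).mean())
        assert abs(err - bayes) < 0.02

    def test_single_class_raises(self, rng):
        x = rng.standard_normal((10, 2))
        with pytest.raises(ValueError):
            train_lda(x, np.array(["HC"] * 10))


class TestQDA:
    def test_variance_coded_classes_beat_lda(self, rng):
        # same means, very different spreads: quadratic boundaries required
        n = 300
        x = np.vstack([rng.normal(0, 0.3, (n, 2)), rng.normal(0, 3.0, (n, 2))])
        y = np.array(["HC"] * n + ["MCI"] * n)
        qda_pred, _ = predict_trials(train_qda(x, y), x)
        lda_pred, _ = predict_trials(train_lda(x, y), x)
        assert (qda_pred == y).mean() > (lda_pred == y).mean()

    def test_identical_sample_covariances_degenerate_to_lda(self, rng):
        base = rng.standard_normal((60, 2))
        base -= base.mean(axis=0)  # identical per-class residuals
        x = np.vstack([base + (0, 0), base + (4, 0), base + (0, 4)])
        y = np.repeat(["HC", "MCI", "AD"], 60)
        qda = train_qda(x, y)
        lda = train_lda(x, y)
        probe = rng.uniform(-2, 6, size=(200, 2))
        ql, _ = predict_trials(qda, probe)
        ll, _ = predict_trials(lda, probe)
        assert (ql == ll).all()

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError):
            train_qda(rng.standard_normal((10, 2)), np.array(["AD"] * 10))


class TestMLP:
    def test_nonlinear_capacity_beats_lda(self, rng):
        x, y = xor3(rng)
        x = (x - x.mean(axis=0)) / x.std(axis=0)  # standardized inputs
        cfg = MLPConfig(n_hidden=8, weight_decay=0.0, rng_seed=0,
                        max_iterations=1500)
        mlp_pred, _ = predict_trials(train_mlp(x, y, cfg), x)
        lda_pred, _ = predict_trials(train_lda(x, y), x)
        assert (mlp_pred == y).mean() >= 0.95
        assert (lda_pred == y).mean() <= 0.80

    def test_posteriors_sum_to_one(self, rng):
        x, y = blobs(rng)
        model = train_mlp(x, y, MLPConfig(n_hidden=4, weight_decay=1.0))
        _, post = predict_trials(model, x)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_seed_determinism(self, rng):
        x, y = blobs(rng)
        cfg = MLPConfig(n_hidden=5, weight_decay=2.0, rng_seed=7)
        m1 = train_mlp(x, y, cfg)
        m2 = train_mlp(x, y, cfg)
        for a, b in zip(m1.coefs, m2.coefs):
            np.testing.assert_array_equal(a, b)
        m3 = train_mlp(x, y, MLPConfig(n_hidden=5, weight_decay=2.0,
                                       rng_seed=8))
        assert any(not np.array_equal(a, b)
                   for a, b in zip(m1.coefs, m3.coefs))

    def test_huge_weight_decay_shrinks_to_constant_posteriors(self, rng):
        x, y = blobs(rng)
        model = train_mlp(x, y, MLPConfig(n_hidden=5, weight_decay=1e6))
        _, post = predict_trials(model, x)
        assert post.to_numpy().std(axis=0).max() < 0.02

    def test_two_class_input_raises(self, rng):
        x = rng.standard_normal((20, 2))
        y = np.array(["HC", "MCI"] * 10)
        with pytest.raises(ConfigurationError):
            train_mlp(x, y, MLPConfig(n_hidden=2))

    def test_serialization_roundtrip_preserves_predictions(self, rng):
        x, y = blobs(rng)
        model = train_mlp(x, y, MLPConfig(n_hidden=4, weight_decay=1.0))
        clone = TrainedModel.from_dict(model.to_dict())
        np.testing.assert_allclose(clone.predict_proba(x),
                                   model.predict_proba(x), atol=1e-12)


class TestPermutationEquivariance:
    @pytest.mark.parametrize("trainer", [
        train_lda, train_qda,
        lambda x, y: train_mlp(x, y, MLPConfig(n_hidden=4, weight_decay=0.5,
                                               rng_seed=0)),
    ], ids=["lda", "qda", "mlp"])
    def test_relabelling_permutes_predictions(self, rng, trainer):
        x, y = blobs(rng)
        swap = {"HC": "AD", "AD": "HC", "MCI": "MCI"}
        y_swapped = np.array([swap[c] for c in y])
        p1, _ = predict_trials(trainer(x, y), x)
        p2, _ = predict_trials(trainer(x, y_swapped), x)
        assert (np.array([swap[c] for c in p1]) == p2).mean() > 0.97


class TestPredictTrials:
    def test_point_at_class_mean(self, rng):
        x, y = blobs(rng, sep=8.0)
        model = train_lda(x, y)
        for i, cls in enumerate(model.classes):
            lab, _ = predict_trials(model, model.means[i][None, :])
            assert lab[0] == cls

    def test_order_invariance(self, rng):
        x, y = blobs(rng)
        model = train_qda(x, y)
        pred, _ = predict_trials(model, x)
        perm = rng.permutation(len(x))
        pred_perm, _ = predict_trials(model, x[perm])
        assert (pred_perm == pred[perm]).all()

    def test_feature_mismatch_raises(self, rng):
        x, y = blobs(rng)
        df = pd.DataFrame(x, columns=["a", "b"])
        model = train_lda(df, y)
        with pytest.raises(ConfigurationError):
            predict_trials(model, df.rename(columns={"b": "c"}))


class TestTuneMLP:
    def _table(self, rng, n_subj_per_group=4, trials=8):
        rows = []
        for g_idx, grp in enumerate(("HC", "MCI", "AD")):
            for s in range(n_subj_per_group):
                centre = {"HC": (0, 0), "MCI": (3, 0), "AD": (0, 3)}[grp]
                pts = rng.normal(centre, 1.0, size=(trials, 2))
                for p in pts:
                    rows.append({"subject_id": f"{grp}{s}", "group": grp,
                                 "x0": p[0], "x1": p[1]})
        return pd.DataFrame(rows)

    def test_single_point_grid_returned(self, rng):
        table = self._table(rng)
        cfg = tune_mlp(table, ["x0", "x1"], grid_u=[5.0], grid_nh=[3],
                       n_restarts=1, cv="group", n_folds=2,
                       max_iterations=60)
        assert (cfg.weight_decay, cfg.n_hidden) == (5.0, 3)

    def test_nonlinear_boundary_needs_hidden_units(self, rng):
        rows = []
        for grp, corners in {"HC": [(0, 0), (4, 4)], "MCI": [(0, 4), (4, 0)],
                             "AD": [(2, 2)]}.items():
            for s in range(4):
                for c in corners:
                    pts = rng.normal(c, 0.3, size=(6, 2))
                    for p in pts:
                        rows.append({"subject_id": f"{grp}{s}", "group": grp,
                                     "x0": p[0], "x1": p[1]})
        table = pd.DataFrame(rows)
        cfg = tune_mlp(table, ["x0", "x1"], grid_u=[0.0], grid_nh=[1, 6],
                       n_restarts=2, cv="group", n_folds=2,
                       max_iterations=400)
        assert cfg.n_hidden >= 2

    def test_empty_grid_raises(self, rng):
        with pytest.raises(ConfigurationError):
            tune_mlp(self._table(rng), ["x0", "x1"], grid_u=[], grid_nh=[1])

    def test_default_config_matches_documented_optimum(self):
        cfg = MLPConfig()
        assert (cfg.weight_decay, cfg.n_hidden, cfg.n_restarts) == (45.0, 11, 30)
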