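import numpy as np
import pandas as pd
import pytest

from rimla.classify import (
    balanced_accuracy_per_class,
    balanced_draw,
    evaluate,
    krippendorff_alpha,
    multiclass_auc,
    permutation_importance,
    split_data,
    train_balanced_forest,
    vif,
)
from rimla.core import CLASS_ORDER, child_rng


def _table(n=200, seed=0, separable=True):
    """Four-class problem; if separable, class index is encoded in feature 0."""
    rng = np.random.default_rng(seed)
    y = rng.choice(CLASS_ORDER, size=n)
    code = {c: i for i, c in enumerate(CLASS_ORDER)}
    x0 = np.array([code[c] for c in y], dtype=float)
    if not separable:
        x0 = rng.normal(size=n)
    return pd.DataFrame(
        {
            "f0": x0 + (rng.normal(scale=0.01, size=n) if separable else 0.0),
            "f1": rng.normal(size=n),
            "f2": rng.normal(size=n),
            "rimla_label": y,
        }
    )


class TestSplit:
    def test_sizes_and_disjointness(self):
        t = _table(120)
        tr, te = split_data(t, n_train=80, seed=1)
        assert len(tr) == 80 and len(te) == 40

    def test_both_parts_contain_every_class(self):
        t = _table(60, seed=2)
        tr, te = split_data(t, n_train=40, seed=2)
        assert set(tr["rimla_label"]) == set(te["rimla_label"]) == set(CLASS_ORDER)

    def test_deterministic_for_fixed_seed(self):
        t = _table(100, seed=3)
        a1, _ = split_data(t, n_train=60, seed=5)
        a2, _ = split_data(t, n_train=60, seed=5)
        pd.testing.assert_frame_equal(a1, a2)

    def test_oversized_train_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            split_data(_table(50), n_train=50)

    def test_impossible_split_rejected(self):
        t = _table(20, seed=4)
        t.loc[0, "rimla_label"] = "new"
        t.loc[1:, "rimla_label"] = "stable"  # a singleton class cannot be in both
        with pytest.raises(ValueError, match="every class"):
            split_data(t, n_train=10, seed=4)


class TestBalancedDraw:
    def test_exact_composition(self):
        y = np.array(["a"] * 90 + ["b"] * 10)
        idx = {c: np.flatnonzero(y == c) for c in ("a", "b")}
        draw = balanced_draw(idx, ("a", "b"), 250, child_rng(0, "d"))
        assert draw.size == 500
        assert (y[draw] == "a").sum() == 250 and (y[draw] == "b").sum() == 250

    def test_draws_with_replacement_from_small_class(self):
        y = np.array(["a"] * 99 + ["b"])
        idx = {c: np.flatnonzero(y == c) for c in ("a", "b")}
        draw = balanced_draw(idx, ("a", "b"), 50, child_rng(1, "d"))
        assert (y[draw] == "b").sum() == 50  # singleton class is resampled


class TestForest:
    def test_separable_data_classified_perfectly(self):
        t = _table(300, seed=6, separable=True)
        tr, te = split_data(t, n_train=200, seed=6)
        model = train_balanced_forest(
            tr[["f0", "f1", "f2"]].to_numpy(), tr["rimla_label"].to_numpy(str),
            n_trees=25, per_tree=100, seed=6,
        )
        yhat = model.predict(te[["f0", "f1", "f2"]].to_numpy())
        assert (yhat == te["rimla_label"].to_numpy(str)).all()

    def test_probabilities_are_a_distribution(self):
        t = _table(200, seed=7, separable=False)
        model = train_balanced_forest(
            t[["f0", "f1", "f2"]].to_numpy(), t["rimla_label"].to_numpy(str),
            n_trees=10, per_tree=80, seed=7,
        )
        p = model.predict_proba(t[["f0", "f1", "f2"]].to_numpy())
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(p >= 0)

    def test_classes_follow_canonical_order(self):
        t = _table(200, seed=8)
        model = train_balanced_forest(
            t[["f0"]].to_numpy(), t["rimla_label"].to_numpy(str),
            n_trees=2, per_tree=40, seed=8,
        )
        assert tuple(model.classes_) == CLASS_ORDER

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            train_balanced_forest(np.ones((10, 2)), np.array(["stable"] * 10))

    def test_deterministic_for_fixed_seed(self):
        t = _table(150, seed=9, separable=False)
        X = t[["f0", "f1", "f2"]].to_numpy()
        y = t["rimla_label"].to_numpy(str)
        p1 = train_balanced_forest(X, y, n_trees=8, per_tree=60, seed=4).predict_proba(X)
        p2 = train_balanced_forest(X, y, n_trees=8, per_tree=60, seed=4).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)


class TestBalancedAccuracy:
    def test_perfect_prediction_scores_one(self):
        y = np.array(["a", "a", "b", "b", "c"])
        ba = balanced_accuracy_per_class(y, y, classes=["a", "b", "c"])
        assert all(v == 1.0 for v in ba.values())

    def test_constant_prediction_on_balanced_labels_scores_half(self):
        y = np.array(["a"] * 10 + ["b"] * 10)
        yhat = np.array(["a"] * 20)
        ba = balanced_accuracy_per_class(y, yhat, classes=["a", "b"])
        assert ba["a"] == 0.5 and ba["b"] == 0.5

    def test_complement_prediction_scores_zero(self):
        y = np.array(["a"] * 5 + ["b"] * 5)
        yhat = np.array(["b"] * 5 + ["a"] * 5)
        ba = balanced_accuracy_per_class(y, yhat, classes=["a", "b"])
        assert ba["a"] == 0.0 and ba["b"] == 0.0


class TestMulticlassAuc:
    def test_perfect_scores_give_auc_one(self):
        y = np.repeat(["a", "b", "c"], 10)
        probs = np.zeros((30, 3))
        probs[np.arange(30), np.repeat([0, 1, 2], 10)] = 1.0
        assert multiclass_auc(probs, y, ["a", "b", "c"]) == 1.0

    def test_random_scores_are_near_half(self):
        rng = np.random.default_rng(10)
        y = rng.choice(["a", "b", "c"], size=3000)
        probs = rng.dirichlet(np.ones(3), size=3000)
        assert abs(multiclass_auc(probs, y, ["a", "b", "c"]) - 0.5) < 0.05

    def test_two_class_case_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        y = rng.choice(["neg", "pos"], size=200)
        s = rng.normal(size=200) + (y == "pos")
        probs = np.column_stack([1 - s, s])  # column 1 scores "pos"
        got = multiclass_auc(probs, y, ["neg", "pos"])
        want = roc_auc_score((y == "pos").astype(int), s)
        assert got == pytest.approx(want, rel=1e-9)


class TestKrippendorff:
    def test_perfect_agreement_is_one(self):
        y = np.array(["a", "b", "c", "a", "b", "c"])
        alpha, p = krippendorff_alpha(y, y, n_permutations=200, seed=0)
        assert alpha == pytest.approx(1.0)
        assert p < 0.05

    def test_hand_computed_value(self):
        # y=[a,a,b,b], yhat=[a,b,b,b]: D_o=1/4, D_e=15/28 -> alpha=8/15
        y = np.array(["a", "a", "b", "b"])
        yhat = np.array(["a", "b", "b", "b"])
        alpha, _ = krippendorff_alpha(y, yhat, n_permutations=100, seed=0)
        assert alpha == pytest.approx(8 / 15, rel=1e-12)

    def test_shuffled_labels_have_alpha_near_zero(self):
        rng = np.random.default_rng(12)
        y = rng.choice(["a", "b", "c", "d"], size=500)
        yhat = rng.permutation(y)
        alpha, p = krippendorff_alpha(y, yhat, n_permutations=500, seed=1)
        assert abs(alpha) < 0.1
        assert p > 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            krippendorff_alpha(np.array([]), np.array([]))


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        X = np.column_stack([np.tile([1.0, -1], 8), np.repeat([1.0, -1], 8)])
        v = vif(X, ["a", "b"])
        np.testing.assert_allclose(v["vif"], 1.0, atol=1e-10)

    def test_known_r2_gives_exact_vif(self):
        # x1 = x0 + e constructed so R^2 = 0.9 exactly -> VIF = 10
        x0 = np.array([1.0, -1, 1, -1, 1, -1, 1, -1]) * 3.0
        e = np.array([1.0, 1, -1, -1, 1, 1, -1, -1])  # orthogonal to x0, mean 0
        x1 = x0 + e  # var explained 72, residual 8 -> R^2 = 0.9
        v = vif(np.column_stack([x0, x1]))
        assert v.loc[1, "vif"] == pytest.approx(10.0, rel=1e-9)

    def test_exact_collinearity_reports_infinity(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=30)
        v = vif(np.column_stack([a, 2 * a, rng.normal(size=30)]))
        assert np.isinf(v.loc[0, "vif"]) and np.isinf(v.loc[1, "vif"])
        assert np.isfinite(v.loc[2, "vif"])

    def test_matches_statsmodels(self):
        from statsmodels.stats.outliers_influence import (
            variance_inflation_factor,
        )

        rng = np.random.default_rng(14)
        X = rng.normal(size=(100, 4))
        X[:, 3] += 0.8 * X[:, 0]
        Xc = np.column_stack([np.ones(100), X])
        want = [variance_inflation_factor(Xc, j + 1) for j in range(4)]
        np.testing.assert_allclose(vif(X)["vif"], want, rtol=1e-8)


class TestPermutationImportance:
    def _model_and_data(self, seed=15):
        rng = np.random.default_rng(seed)
        n = 400
        y = rng.choice(["a", "b"], size=n)
        X = np.column_stack([
            (y == "a") + rng.normal(scale=0.1, size=n),  # signal
            rng.normal(size=n),                          # noise
        ])
        model = train_balanced_forest(X, y, ["signal", "noise"],
                                      n_trees=20, per_tree=100, seed=seed)
        return model, X, y

    def test_signal_feature_ranks_first(self):
        model, X, y = self._model_and_data()
        imp = permutation_importance(model, X, y, n_perm=10, seed=0)
        by = imp.set_index("feature")["importance_mean"]
        assert by["signal"] > 0.3
        assert by["signal"] > by["noise"]

    def test_noise_feature_importance_is_small(self):
        model, X, y = self._model_and_data()
        imp = permutation_importance(model, X, y, n_perm=20, seed=0)
        by = imp.set_index("feature")
        assert abs(by.loc["noise", "importance_mean"]) < 0.05

    def test_single_permutation_has_zero_sd(self):
        model, X, y = self._model_and_data()
        imp = permutation_importance(model, X, y, n_perm=1, seed=0)
        assert (imp["importance_sd"] == 0.0).all()

    def test_duplicated_feature_dilutes_importance(self):
        # a tree can recover the signal from the copy, so permuting one
        # column of the pair costs less than permuting a unique signal
        rng = np.random.default_rng(16)
        n = 400
        y = rng.choice(["a", "b"], size=n)
        sig = (y == "a") + rng.normal(scale=0.1, size=n)
        X1 = np.column_stack([sig, rng.normal(size=n)])
        X2 = np.column_stack([sig, sig.copy(), rng.normal(size=n)])
        m1 = train_balanced_forest(X1, y, n_trees=30, per_tree=100, seed=1)
        m2 = train_balanced_forest(X2, y, n_trees=30, per_tree=100, seed=1)
        i1 = permutation_importance(m1, X1, y, n_perm=10, seed=2)
        i2 = permutation_importance(m2, X2, y, n_perm=10, seed=2)
        unique = i1.loc[i1["feature"] == "f0", "importance_mean"].iloc[0]
        shared = i2.loc[i2["feature"] == "f0", "importance_mean"].iloc[0]
        assert shared < unique


class TestEvaluate:
    def test_report_on_structured_cohort(self):
        from rimla.synth import FEATURE_PROFILES, SynthConfig, gen_feature_table

        cfg = SynthConfig(seed=42)
        table = gen_feature_table(cfg, 600, n_patients=40)
        feats = list(FEATURE_PROFILES)
        rep = evaluate(table, feats, n_train=450, n_trees=60, per_tree=200,
                       n_perm=3, seed=42)
        assert rep.multiclass_auc > 0.7
        assert rep.krippendorff_alpha > 0.2
        assert rep.krippendorff_p < 0.01
        assert set(rep.balanced_accuracy) == set(CLASS_ORDER)
        assert rep.confusion.to_numpy().sum() == 150
        assert len(rep.vif) == len(feats)
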