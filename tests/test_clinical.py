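"""Tabular branch: preprocessing, imbalance handling, selection, explanation."""

import numpy as np
import pandas as pd
import pytest

from mmrecur import clinical, cv, synth
from mmrecur.shapley import shapley_values


def _df(cols: dict) -> pd.DataFrame:
    return pd.DataFrame(cols)


class TestPreprocess:
    def _prep(self, values, names=("a",)):
        p = clinical.Preprocessor(feature_names=names)
        return p, p.fit_transform(_df({n: v for n, v in zip(names, values)}))

    def test_minmax_scaling(self):
        _, X = self._prep([[10.0, 20.0, 30.0]])
        assert np.allclose(X.ravel(), [0.0, 0.5, 1.0])

    def test_mean_imputation_before_scaling(self):
        _, X = self._prep([[10.0, np.nan, 30.0]])
        assert np.allclose(X.ravel(), [0.0, 0.5, 1.0])

    def test_constant_column_scales_to_zero(self):
        _, X = self._prep([[7.0, 7.0, 7.0]])
        assert np.allclose(X, 0.0)

    def test_all_missing_column_raises_with_name(self):
        p = clinical.Preprocessor(feature_names=("bad_col",))
        with pytest.raises(ValueError, match="bad_col"):
            p.fit(_df({"bad_col": [np.nan, np.nan]}))

    def test_validation_values_clamped(self):
        p = clinical.Preprocessor(feature_names=("a",))
        p.fit(_df({"a": [0.0, 10.0]}))
        X = p.transform(_df({"a": [-5.0, 15.0]}))
        assert X.min() == 0.0 and X.max() == 1.0

    def test_training_data_always_in_unit_interval(self, small_cohort):
        p = clinical.Preprocessor()
        X = p.fit_transform(small_cohort)
        assert X.min() >= 0.0 and X.max() <= 1.0


class TestClassWeights:
    def test_positive_scale_ratio(self):
        y = np.array([0] * 84 + [1] * 16)
        w, scale = clinical.class_weights(y)
        assert scale == 84 / 16 == 5.25

    def test_balanced_labels_equal_weights(self):
        w, scale = clinical.class_weights(np.array([0, 1] * 10))
        assert np.allclose(w, w[0]) and scale == 1.0

    def test_weight_mass_equal_across_classes(self):
        y = np.array([0] * 30 + [1] * 10)
        w, _ = clinical.class_weights(y)
        assert np.isclose(w[y == 0].sum(), w[y == 1].sum())

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            clinical.class_weights(np.ones(5, int))


def _cohort_and_plan(spec, seed=0):
    cohort = synth.generate_cohort(spec)
    pseudo = cv.pseudo_label(cohort, seed=seed, n_estimators=100)
    plan = cv.make_folds(cohort, k=5, seed=seed, side_scores=pseudo.scores)
    return cohort, plan, pseudo


class TestTrainSelect:
    def test_tree_family_beats_logistic_on_interaction(self):
        # outcome = XOR-style interaction of two features: no linear signal
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 250
            a, b = rng.random(n) > 0.5, rng.random(n) > 0.5
            y = (a ^ b).astype(float)
            cohort = pd.DataFrame(
                {
                    "patient_id": [f"P{i}" for i in range(n)],
                    **{f: rng.random(n) for f in synth.CLINICAL_FEATURES},
                    "outcome": y,
                    "censored": 0,
                    "has_imaging": 0,
                }
            )
            cohort["ki67"] = a.astype(float) * 100
            cohort["bmi"] = b.astype(float) * 10 + 20
            plan = cv.make_folds(cohort, k=5, seed=seed)
            pseudo = cv.PseudoLabelSet(labels={}, scores={})
            sel = clinical.train_select(
                cohort, plan, pseudo, seed=seed,
                families=("random_forest", "logistic_regression"),
            )
            lr_auc = sel.per_family["logistic_regression"].mean_auc
            if sel.best_family != "logistic_regression" and sel.best.mean_auc > lr_auc:
                wins += 1
        assert wins >= 4

    def test_pure_noise_auc_near_half(self):
        rng = np.random.default_rng(0)
        n = 400
        cohort = pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                **{f: rng.random(n) for f in synth.CLINICAL_FEATURES},
                "outcome": (rng.random(n) < 0.3).astype(float),
                "censored": 0,
                "has_imaging": 0,
            }
        )
        plan = cv.make_folds(cohort, k=5, seed=0)
        sel = clinical.train_select(cohort, plan, cv.PseudoLabelSet({}, {}), seed=0)
        assert 0.4 <= sel.best.mean_auc <= 0.6

    def test_selection_deterministic(self):
        spec = synth.CohortSpec(n=300, n_imaging=0, seed=4)
        cohort, plan, pseudo = _cohort_and_plan(spec, seed=4)
        s1 = clinical.train_select(cohort, plan, pseudo, seed=1)
        s2 = clinical.train_select(cohort, plan, pseudo, seed=1)
        assert s1.best_family == s2.best_family
        assert s1.best.scores.equals(s2.best.scores)

    def test_out_of_fold_scores_exclude_censored(self, small_cohort):
        pseudo = cv.pseudo_label(small_cohort, seed=0, n_estimators=100)
        plan = cv.make_folds(small_cohort, k=5, seed=0, side_scores=pseudo.scores)
        res = clinical.train_family("random_forest", small_cohort, plan, pseudo, seed=0)
        cv.audit_evaluation_purity(res.scores, small_cohort)
        cv.audit_no_fold_leakage(res.scores, plan)


class TestExplain:
    def test_null_player_gets_zero_attribution(self):
        # a model that reads only feature 0
        predict = lambda X: X[:, 0]
        X = np.random.default_rng(0).random((20, 3))
        rep = shapley_values(predict, X, X[:5], n_permutations=5, seed=0)
        assert np.allclose(rep.values.iloc[:, 1], 0.0)
        assert np.allclose(rep.values.iloc[:, 2], 0.0)

    def test_single_feature_efficiency_exact(self):
        predict = lambda X: 3.0 * X[:, 0]
        X = np.array([[0.0], [1.0]])
        rep = shapley_values(predict, X, np.array([[0.5]]), n_permutations=1, seed=0)
        assert np.allclose(
            rep.values.iloc[:, 0].to_numpy(), rep.predictions - rep.base_value
        )

    def test_efficiency_holds_for_forest(self, small_cohort):
        pseudo = cv.pseudo_label(small_cohort, seed=0, n_estimators=100)
        plan = cv.make_folds(small_cohort, k=5, seed=0, side_scores=pseudo.scores)
        res = clinical.train_family("random_forest", small_cohort, plan, pseudo, seed=0)
        rep = clinical.explain(res, small_cohort.head(120), n_permutations=3, seed=0)
        assert rep.efficiency_residual().max() < 1e-6

    def test_dominant_bmi_ranked_first(self):
        hits = 0
        for seed in range(5):
            spec = synth.CohortSpec(
                n=350,
                n_imaging=0,
                missingness={},
                coefficients={"bmi": -3.0, "age": 0.0, "her2": 0.0, "log_volume": 0.0},
                seed=seed,
            )
            cohort, plan, pseudo = _cohort_and_plan(spec, seed=seed)
            res = clinical.train_family("random_forest", cohort, plan, pseudo, seed=seed)
            rep = clinical.explain(res, cohort, n_permutations=3, seed=seed)
            if rep.ranking.index[0] == "bmi":
                hits += 1
        assert hits >= 4

    def test_complete_cases_restriction(self, small_cohort):
        pseudo = cv.pseudo_label(small_cohort, seed=0, n_estimators=100)
        plan = cv.make_folds(small_cohort, k=5, seed=0, side_scores=pseudo.scores)
        res = clinical.train_family("random_forest", small_cohort, plan, pseudo, seed=0)
        rep = clinical.explain(
            res, small_cohort, n_permutations=2, seed=0, complete_cases_only=True
        )
        n_complete = (
            small_cohort[small_cohort["censored"] == 0]
            .loc[:, list(synth.CLINICAL_FEATURES)]
            .notna()
            .all(axis=1)
            .sum()
        )
        assert len(rep.values) == n_complete
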