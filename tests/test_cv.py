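"""Fold stratification, cross-cohort correlation and pseudo-labeling."""

import numpy as np
import pandas as pd
import pytest

from mmrecur import cv, synth


def _cohort(n_pos=50, n_neg=250, n_cens=0, n_imaging=0, seed=0):
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg + n_cens
    y = np.array([1] * n_pos + [0] * n_neg + [0] * n_cens, dtype=float)
    censored = np.array([0] * (n_pos + n_neg) + [1] * n_cens)
    y[censored == 1] = np.nan
    has_imaging = np.zeros(n, int)
    has_imaging[rng.choice(n, size=n_imaging, replace=False)] = 1
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "outcome": y,
            "censored": censored,
            "has_imaging": has_imaging,
        }
    )
    return df.sample(frac=1.0, random_state=seed).reset_index(drop=True)


class TestMakeFolds:
    def test_exact_stratification_when_divisible(self):
        plan = cv.make_folds(_cohort(50, 250), k=5, seed=1)
        counts = plan.counts(_cohort(50, 250))
        assert (counts["positives"] == 10).all()
        assert (counts["negatives"] == 50).all()

    def test_positive_counts_differ_by_at_most_one(self):
        cohort = _cohort(53, 247, n_cens=40, n_imaging=60, seed=3)
        plan = cv.make_folds(cohort, k=5, seed=3)
        counts = plan.counts(cohort)
        assert counts["positives"].max() - counts["positives"].min() <= 1
        assert counts["negatives"].max() - counts["negatives"].min() <= 1

    def test_imaging_subset_also_stratified(self):
        cohort = _cohort(50, 250, n_imaging=100, seed=2)
        plan = cv.make_folds(cohort, k=5, seed=2)
        img = cohort[cohort["has_imaging"] == 1].copy()
        counts = plan.counts(img)
        assert counts["positives"].max() - counts["positives"].min() <= 1

    def test_cross_cohort_same_fold(self):
        cohort = _cohort(50, 250, n_imaging=100, seed=4)
        plan = cv.make_folds(cohort, k=5, seed=4)
        # the imaging cohort inherits the clinical assignment: same mapping
        img_ids = cohort.loc[cohort["has_imaging"] == 1, "patient_id"]
        assert all(plan.fold_of(p) == plan.assignment[p] for p in img_ids)
        cv.audit_cross_cohort(plan, cohort["patient_id"].tolist(), img_ids.tolist())

    def test_two_seeds_differ_but_keep_counts(self):
        cohort = _cohort(50, 250, seed=5)
        p1 = cv.make_folds(cohort, k=5, seed=1)
        p2 = cv.make_folds(cohort, k=5, seed=2)
        assert p1.assignment != p2.assignment
        assert p1.counts(cohort).equals(p2.counts(cohort))

    def test_deterministic_given_seed(self):
        cohort = _cohort(50, 250, n_cens=30, seed=6)
        assert cv.make_folds(cohort, 5, seed=9).assignment == cv.make_folds(
            cohort, 5, seed=9
        ).assignment

    def test_insufficient_positives_rejected(self):
        with pytest.raises(cv.FoldError):
            cv.make_folds(_cohort(3, 100), k=5, seed=0)

    def test_censored_balanced_across_folds(self):
        cohort = _cohort(50, 250, n_cens=100, seed=7)
        plan = cv.make_folds(cohort, k=5, seed=7)
        counts = plan.counts(cohort)
        assert counts["censored"].max() - counts["censored"].min() <= 1


class TestPseudoLabels:
    def test_no_censored_patients_empty_set(self):
        cohort = synth.generate_cohort(
            synth.CohortSpec(n=100, n_imaging=0, censoring_rate=0.0, seed=1)
        )
        pseudo = cv.pseudo_label(cohort, seed=0)
        assert pseudo.labels == {} and pseudo.scores == {}

    def test_archetype_censored_patient_gets_positive_label(self):
        # separable cohort: outcome entirely driven by a huge BMI effect
        spec = synth.CohortSpec(
            n=600,
            n_imaging=0,
            censoring_rate=0.3,
            missingness={},
            coefficients={"bmi": -6.0, "age": 0.0, "her2": 0.0, "log_volume": 0.0},
            seed=8,
        )
        cohort = synth.generate_cohort(spec)
        pseudo = cv.pseudo_label(cohort, seed=0)
        cens = cohort[cohort["censored"] == 1]
        lowest_bmi = cens.nsmallest(5, "bmi")["patient_id"]
        highest_bmi = cens.nlargest(5, "bmi")["patient_id"]
        assert np.mean([pseudo.scores[p] for p in lowest_bmi]) > np.mean(
            [pseudo.scores[p] for p in highest_bmi]
        )
        assert all(pseudo.labels[p] in (0, 1) for p in cens["patient_id"])

    def test_every_censored_patient_labeled(self, small_cohort):
        pseudo = cv.pseudo_label(small_cohort, seed=0)
        cens = set(small_cohort.loc[small_cohort["censored"] == 1, "patient_id"])
        assert set(pseudo.labels) == cens

    def test_validation_sets_never_contain_censored(self, small_cohort):
        pseudo = cv.pseudo_label(small_cohort, seed=0)
        plan = cv.make_folds(small_cohort, k=5, seed=0, side_scores=pseudo.scores)
        cens = set(small_cohort.loc[small_cohort["censored"] == 1, "patient_id"])
        for f in range(1, 6):
            val_ids = {
                p
                for p in small_cohort.loc[small_cohort["censored"] == 0, "patient_id"]
                if plan.fold_of(p) == f
            }
            assert not (val_ids & cens)

    def test_training_labels_merge(self, small_cohort):
        pseudo = cv.pseudo_label(small_cohort, seed=0)
        labels = cv.training_labels(small_cohort, pseudo)
        assert set(labels) == set(small_cohort["patient_id"])
        unc = small_cohort[small_cohort["censored"] == 0]
        assert all(labels[p] == int(o) for p, o in zip(unc["patient_id"], unc["outcome"]))

    def test_per_fold_mode_runs(self, small_cohort):
        plan = cv.make_folds(small_cohort, k=5, seed=0)
        pseudo = cv.pseudo_label(small_cohort, seed=0, fold_plan=plan, n_estimators=50)
        assert len(pseudo.labels) == int((small_cohort["censored"] == 1).sum())


class TestSerialization:
    def test_fold_plan_roundtrip(self, tmp_path, small_cohort):
        plan = cv.make_folds(small_cohort, k=5, seed=0)
        plan.to_csv(tmp_path / "folds.csv")
        back = cv.FoldPlan.from_csv(tmp_path / "folds.csv", k=5, seed=0)
        assert back.assignment == plan.assignment

    def test_pseudo_labels_roundtrip(self, tmp_path, small_cohort):
        pseudo = cv.pseudo_label(small_cohort, seed=0, n_estimators=50)
        pseudo.to_csv(tmp_path / "pseudo.csv")
        back = cv.PseudoLabelSet.from_csv(tmp_path / "pseudo.csv")
        assert back.labels == pseudo.labels
        assert all(np.isclose(back.scores[p], pseudo.scores[p]) for p in pseudo.scores)


class TestAudits:
    def test_purity_audit_catches_censored_scores(self, small_cohort):
        cens_id = small_cohort.loc[small_cohort["censored"] == 1, "patient_id"].iloc[0]
        rows = pd.DataFrame({"patient_id": [cens_id], "fold": [1], "raw_score": [0.5]})
        with pytest.raises(AssertionError):
            cv.audit_evaluation_purity(rows, small_cohort)

    def test_leakage_audit_catches_wrong_fold(self, small_cohort):
        plan = cv.make_folds(small_cohort, k=5, seed=0)
        unc = small_cohort[small_cohort["censored"] == 0].iloc[0]
        wrong = 1 + plan.fold_of(unc["patient_id"]) % 5
        rows = pd.DataFrame(
            {"patient_id": [unc["patient_id"]], "fold": [wrong], "raw_score": [0.5]}
        )
        with pytest.raises(AssertionError):
            cv.audit_no_fold_leakage(rows, plan)
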