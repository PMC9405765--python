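"""Evaluation stack against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from mmrecur import evaluate as ev

score_label_lists = st.lists(
    st.tuples(st.integers(0, 10), st.booleans()), min_size=4, max_size=40
)


def pairwise_auc_oracle(scores, labels):
    """Exhaustive concordance count over all positive-negative pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def threshold_oracle(scores, labels, target):
    """Enumerate every distinct threshold; emulate the operating-point rule."""
    n_pos, n_neg = (labels == 1).sum(), (labels == 0).sum()
    best = None
    for t in np.unique(scores):
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n_pos
        if sens >= target and (best is None or t > best[0]):
            best = (t,)
    t = best[0]
    pred = scores >= t
    tp = (pred & (labels == 1)).sum()
    fp = (pred & (labels == 0)).sum()
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    ppv = tp / pred.sum() if pred.sum() else 0.0
    tn, fn = n_neg - fp, n_pos - tp
    npv = tn / (tn + fn) if tn + fn else 0.0
    f1 = 2 * ppv * sens / (ppv + sens) if ppv + sens else 0.0
    return t, sens, spec, f1, (sens + spec) / 2, ppv, npv


class TestAuc:
    def test_perfect_separation(self):
        assert ev.auc(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0])) == 1.0

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(0)
        s = rng.random(5000)
        y = (rng.random(5000) < 0.4).astype(int)
        assert abs(ev.auc(s, y) - 0.5) < 0.03

    def test_eight_patient_exact_concordance(self):
        s = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.7, 0.2, 0.9])
        y = np.array([0, 0, 1, 1, 0, 1, 0, 1])
        assert np.isclose(ev.auc(s, y), pairwise_auc_oracle(s, y))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        s = np.round(rng.random(n), 1)  # coarse grid forces ties
        y = np.zeros(n, int)
        y[rng.choice(n, size=max(1, n // 4), replace=False)] = 1
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        assert np.isclose(ev.auc(s, y), pairwise_auc_oracle(s, y))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.auc(np.array([0.1, 0.2]), np.array([1, 1]))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(pairs=score_label_lists)
    def test_auc_equals_pairwise_concordance_property(self, pairs):
        scores = np.array([p / 10.0 for p, _ in pairs])
        labels = np.array([int(b) for _, b in pairs])
        assume(0 < labels.sum() < len(labels))
        assert np.isclose(ev.auc(scores, labels), pairwise_auc_oracle(scores, labels))


class TestAucCi:
    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(1)
        s = rng.random(100)
        y = (s + 0.3 * rng.normal(size=100) > 0.5).astype(int)
        point, (lo, hi) = ev.auc_ci(s, y, n_boot=500, seed=0)
        assert lo <= point <= hi

    def test_ci_width_shrinks_with_n(self):
        widths = []
        for n in (50, 200, 800):
            rng = np.random.default_rng(42)
            s = rng.random(n)
            y = (s + 0.4 * rng.normal(size=n) > 0.5).astype(int)
            _, (lo, hi) = ev.auc_ci(s, y, n_boot=500, seed=1)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        s, y = rng.random(60), (rng.random(60) < 0.4).astype(int)
        assert ev.auc_ci(s, y, n_boot=200, seed=7) == ev.auc_ci(s, y, n_boot=200, seed=7)


class TestOperatingPoints:
    def test_perfect_classifier(self):
        s = np.array([0.9, 0.95, 0.85, 0.1, 0.2, 0.15, 0.05, 0.12, 0.18, 0.02])
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        m = ev.metrics_at_sensitivity(s, y, 0.90)
        assert m.achieved_sensitivity == 1.0
        assert m.specificity == 1.0
        assert m.balanced_accuracy == 1.0
        assert m.npv == 1.0

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("target", [0.87, 0.90, 0.93])
    def test_random_scores_match_threshold_oracle(self, seed, target):
        rng = np.random.default_rng(seed)
        s = np.round(rng.random(30), 2)
        y = np.zeros(30, int)
        y[rng.choice(30, size=8, replace=False)] = 1
        m = ev.metrics_at_sensitivity(s, y, target)
        t, sens, spec, f1, ba, ppv, npv = threshold_oracle(s, y, target)
        assert m.threshold == t
        assert np.isclose(m.achieved_sensitivity, sens)
        assert np.isclose(m.specificity, spec)
        assert np.isclose(m.f1, f1)
        assert np.isclose(m.balanced_accuracy, ba)
        assert np.isclose(m.ppv, ppv)
        assert np.isclose(m.npv, npv)

    def test_identity_invariants(self):
        rng = np.random.default_rng(3)
        s = rng.random(40)
        y = (rng.random(40) < 0.3).astype(int)
        m = ev.metrics_at_sensitivity(s, y, 0.9)
        assert np.isclose(m.balanced_accuracy, (m.achieved_sensitivity + m.specificity) / 2)
        if m.ppv + m.achieved_sensitivity > 0:
            assert np.isclose(
                m.f1, 2 * m.ppv * m.achieved_sensitivity / (m.ppv + m.achieved_sensitivity)
            )

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(pairs=score_label_lists, target=st.sampled_from([0.87, 0.90, 0.93]))
    def test_metric_identities_property(self, pairs, target):
        scores = np.array([p / 10.0 for p, _ in pairs])
        labels = np.array([int(b) for _, b in pairs])
        assume(0 < labels.sum() < len(labels))
        m = ev.metrics_at_sensitivity(scores, labels, target)
        assert np.isclose(m.balanced_accuracy, (m.achieved_sensitivity + m.specificity) / 2)
        for v in (m.achieved_sensitivity, m.specificity, m.f1, m.ppv, m.npv):
            assert 0.0 <= v <= 1.0

    def test_constant_scores_degenerate(self):
        s = np.full(20, 0.5)
        y = np.array([1] * 5 + [0] * 15)
        m = ev.metrics_at_sensitivity(s, y, 0.9)
        assert m.achieved_sensitivity == 1.0
        assert m.specificity == 0.0


class TestMcNemar:
    def test_symmetric_discordance_p_one(self):
        y = np.zeros(4, int)
        a = np.array([0, 0, 0, 1])  # one a-only error
        b = np.array([0, 0, 1, 0])  # one b-only error
        p, sig = ev.mcnemar_bonferroni(a, b, y)
        assert p == 1.0 and not sig

    def test_ten_zero_exact_binomial(self):
        y = np.zeros(30, int)
        a = y.copy()
        b = y.copy()
        b[:10] = 1  # b wrong on 10, a correct: b=10, c=0
        p, sig = ev.mcnemar_bonferroni(a, b, y)
        assert np.isclose(p, 2 * 0.5**10)
        assert np.isclose(p, 0.001953, atol=1e-6)
        assert sig  # 0.001953 < 0.0042

    def test_five_three_matches_binomial_tail(self):
        y = np.zeros(20, int)
        a = y.copy()
        b = y.copy()
        a[:3] = 1  # a wrong where b right: c = 3
        b[10:15] = 1  # b wrong where a right: b = 5
        p, sig = ev.mcnemar_bonferroni(a, b, y)
        n = 8
        oracle = min(1.0, 2 * sum(binom.pmf(k, n, 0.5) for k in range(0, 4)))
        assert np.isclose(p, oracle)
        assert not sig

    def test_chi2_branch_for_large_discordance(self):
        y = np.zeros(100, int)
        a = y.copy()
        b = y.copy()
        b[:30] = 1  # b+c = 30 >= 25 -> continuity-corrected chi-square
        p, sig = ev.mcnemar_bonferroni(a, b, y)
        from scipy.stats import chi2

        expected = chi2.sf((abs(30 - 0) - 1) ** 2 / 30, df=1)
        assert np.isclose(p, expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.mcnemar_bonferroni(np.zeros(3), np.zeros(4), np.zeros(3))


class TestSubgroups:
    def test_candidate_enumeration_is_432(self):
        cells = ev.enumerate_subgroups()
        assert len(cells) == 432
        assert len({tuple(c.values()) for c in cells}) == 432

    def _toy(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        cohort = pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "age": 45.0,
                "cancer_subtype": 2.0,
                "histological_type": 1.0,
                "tumor_grade": 3.0,
                "ki67": 40.0,
                "outcome": (rng.random(n) < 0.4).astype(float),
                "censored": 0,
            }
        )
        scores = pd.DataFrame({"patient_id": cohort["patient_id"], "score": rng.random(n)})
        return cohort, scores

    def test_small_cell_excluded(self):
        cohort, scores = self._toy(n=9)
        cells = ev.subgroup_scan(cohort, scores, n_boot=50)
        assert all(not c.analyzed for c in cells)

    def test_single_outcome_cell_excluded(self):
        cohort, scores = self._toy(n=12)
        cohort["outcome"] = 0.0
        cells = ev.subgroup_scan(cohort, scores, n_boot=50)
        assert all(not c.analyzed for c in cells)

    def test_analyzed_cells_sorted_by_auc(self, small_cohort):
        rng = np.random.default_rng(0)
        unc = small_cohort[small_cohort["censored"] == 0]
        scores = pd.DataFrame(
            {
                "patient_id": unc["patient_id"],
                "score": np.clip(
                    unc["outcome"].to_numpy() * 0.4 + rng.random(len(unc)) * 0.6, 0, 1
                ),
            }
        )
        cells = ev.subgroup_scan(small_cohort, scores, n_boot=50, seed=0)
        assert len(cells) == 432
        analyzed = [c for c in cells if c.analyzed]
        assert len(analyzed) >= 1
        aucs = [c.auc for c in analyzed]
        assert aucs == sorted(aucs, reverse=True)

    def test_membership_reproducible_from_level_definitions(self, small_cohort):
        rng = np.random.default_rng(1)
        unc = small_cohort[small_cohort["censored"] == 0]
        scores = pd.DataFrame({"patient_id": unc["patient_id"], "score": rng.random(len(unc))})
        cells = ev.subgroup_scan(small_cohort, scores, n_boot=50, seed=0)
        df = small_cohort.merge(scores, on="patient_id")
        df = df[df["censored"] == 0]
        for cell in [c for c in cells if c.analyzed][:3]:
            mask = np.ones(len(df), bool)
            for name, lab in cell.levels.items():
                fn = dict(ev.SUBGROUP_FACTORS[name])[lab]
                mask &= fn(df).to_numpy()
            assert mask.sum() == cell.n_patients

    def test_age_boundary_conventions(self):
        d = pd.DataFrame({"age": [50.0, 60.0, 55.0]})
        bands = {lab: fn(d).to_numpy() for lab, fn in ev.SUBGROUP_FACTORS["age"]}
        assert bands["<=50"][0] and not bands["50-60"][0]
        assert bands[">=60"][1] and not bands["50-60"][1]
        assert bands["50-60"][2]


def test_bonferroni_threshold_prints_00042():
    assert round(ev.bonferroni_threshold(0.05, 12), 4) == 0.0042


def test_roc_coordinates_consistent_with_auc():
    rng = np.random.default_rng(0)
    s = rng.random(80)
    y = (s + 0.4 * rng.normal(size=80) > 0.5).astype(int)
    roc = ev.roc_coordinates(s, y)
    assert roc["fpr"].iloc[0] == 0.0 and roc["tpr"].iloc[-1] == 1.0
    assert np.isclose(np.trapezoid(roc["tpr"], roc["fpr"]), ev.auc(s, y))
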