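"""ROC/AUC, Spearman, group tables, logistic battery, infarct correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import sdindex as sd
from sdindex.clinical import outcome_indicator


def _u_auc(scores, labels):
    """Independent AUC oracle: tie-averaged Mann-Whitney U / (n1*n0)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = 0.0
    for p in pos:
        wins += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation_auc_one(self):
        res = sd.roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == pytest.approx(1.0)

    def test_chance_level_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        assert sd.roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_one_class_absent_errors(self):
        with pytest.raises(ValueError):
            sd.roc_auc([1.0, 2.0], [1, 1])

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_trapezoid_equals_u_statistic_identity(self, seed):
        """AUC from the threshold sweep equals U/(n1*n0) with midrank
        ties, on arbitrary random instances."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.integers(0, 6, size=n).astype(float)  # force ties
        labels = np.zeros(n, int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        res = sd.roc_auc(scores, labels)
        assert res.auc == pytest.approx(_u_auc(scores, labels), abs=1e-10)

    def test_negated_scores_flip_auc_without_ties(self, rng):
        scores = rng.normal(size=50)
        labels = (rng.random(50) < 0.4).astype(int)
        labels[0], labels[1] = 0, 1
        a = sd.roc_auc(scores, labels).auc
        b = sd.roc_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-10)

    def test_sensitivity_specificity_monotone_sweep(self, rng):
        scores = rng.normal(size=60)
        labels = (rng.random(60) < 0.5).astype(int)
        labels[:2] = [0, 1]
        res = sd.roc_auc(scores, labels)
        assert np.all(np.diff(res.sensitivity) >= 0)
        assert np.all(np.diff(res.specificity) <= 0)


class TestSpearman:
    def test_strictly_monotone_gives_one(self):
        rho, _ = sd.spearman([1, 2, 5, 9], [10, 20, 21, 40])
        assert rho == pytest.approx(1.0)

    def test_hand_rank_case(self):
        """x={1,2,3}, y={3,1,2}: d = (-2, 1, 1), rho = 1 - 6*6/24 = -0.5."""
        rho, p = sd.spearman([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)
        # exact enumeration over 3! rank assignments: rho distribution is
        # {1, .5, .5, -.5, -.5, -1}, so |rho| >= 0.5 always -> p = 1
        assert p == pytest.approx(1.0)

    def test_exact_enumeration_perfect_order_n4(self):
        """n=4 without ties, perfectly concordant: only the two perfect
        orders reach |rho| = 1, so the exact p is 2/24."""
        rho, p = sd.spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)

    def test_invariant_to_monotone_transforms(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        r1, _ = sd.spearman(x, y)
        r2, _ = sd.spearman(np.exp(x), y ** 3)
        assert r1 == pytest.approx(r2)

    def test_constant_vector_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            sd.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSummarizeGroups:
    def test_poor_outcome_percentages_from_printed_counts(self):
        """52-patient strata with 19 and 5 poor outcomes give 36.5% and
        9.6%."""
        records = pd.DataFrame({
            "stratum": ["SDI-H"] * 52 + ["SDI-L"] * 52,
            "poor_outcome": [1] * 19 + [0] * 33 + [1] * 5 + [0] * 47,
        })
        table = sd.summarize_groups(records, "stratum")
        row = table.loc["poor_outcome"]
        assert row["pct_a"] == pytest.approx(36.5, abs=0.05)
        assert row["pct_b"] == pytest.approx(9.6, abs=0.05)
        assert row["p_value"] < 0.05

    def test_identical_groups_give_p_one(self, rng):
        base = rng.normal(size=20)
        records = pd.DataFrame({
            "grp": ["a"] * 20 + ["b"] * 20,
            "val": np.concatenate([base, base]),
        })
        table = sd.summarize_groups(records, "grp")
        assert table.loc["val", "p_value"] > 0.95

    def test_fisher_exact_matches_hypergeometric_enumeration(self):
        """2x2 table {1,9;8,2} (an expected cell is 4.5 < 5): Fisher p
        equals the two-sided hypergeometric tail sum."""
        records = pd.DataFrame({
            "grp": ["a"] * 10 + ["b"] * 10,
            "flag": [1] + [0] * 9 + [1] * 8 + [0] * 2,
        })
        table = sd.summarize_groups(records, "grp")
        # enumerate P(X = k) for X ~ Hypergeom(N=20, K=9 flags, n=10 in a)
        hyp = stats.hypergeom(20, 9, 10)
        p_obs = hyp.pmf(1)
        p_exact = sum(hyp.pmf(k) for k in range(11) if hyp.pmf(k) <= p_obs + 1e-12)
        assert table.loc["flag", "test"] == "fisher"
        assert table.loc["flag", "p_value"] == pytest.approx(p_exact, abs=1e-9)

    def test_empty_group_rejected(self):
        records = pd.DataFrame({"grp": ["a", "a"], "v": [1.0, 2.0]})
        with pytest.raises(ValueError):
            sd.summarize_groups(records, "grp")


class TestLogistic:
    def test_or_equals_cross_product_ratio_on_2x2(self):
        """Binary predictor from cells (19, 33, 5, 47): the fitted OR is
        the cross-product ratio (19*47)/(33*5)."""
        x = [1] * 52 + [0] * 52
        y = [1] * 19 + [0] * 33 + [1] * 5 + [0] * 47
        res = sd.logistic_fit(pd.DataFrame({"x": x}), y)
        expected = (19 * 47) / (33 * 5)
        assert res.table.loc["x", "odds_ratio"] == pytest.approx(expected, abs=1e-6)
        assert res.table.loc["x", "ci_low"] < expected < res.table.loc["x", "ci_high"]
        assert res.converged

    def test_all_zero_outcome_errors(self):
        with pytest.raises(ValueError, match="events"):
            sd.logistic_fit(pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]}), [0, 0, 0, 0])

    def test_intercept_only_balanced_outcome(self):
        res = sd.logistic_fit(pd.DataFrame(index=range(40)), [0, 1] * 20)
        assert res.table.loc["const", "estimate"] == pytest.approx(0.0, abs=1e-8)
        assert res.table.loc["const", "odds_ratio"] == pytest.approx(1.0, abs=1e-8)

    def test_perfect_separation_raises_with_covariate(self):
        x = np.r_[np.zeros(10), np.ones(10)]
        y = x.astype(int)
        with pytest.raises(ValueError, match="separation"):
            sd.logistic_fit(pd.DataFrame({"sep": x}), y)


class TestUnivariateScreen:
    def _records(self, rng, n=187, beta=0.0):
        z = rng.normal(size=n)
        noise_cov = rng.normal(size=n)
        logit = -1.2 + beta * z
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        return pd.DataFrame({
            "planted": z,
            "noise": noise_cov,
            "nihss_in": np.where(y == 1, 10, 3),
            "mrs_out": np.where(y == 1, 4, 1),
        })

    def test_planted_strong_covariate_included(self):
        hits = 0
        for seed in range(10):
            rec = self._records(np.random.default_rng(seed), beta=np.log(2))
            passed, _ = sd.univariate_screen(rec, "unfavorable")
            hits += "planted" in passed
        assert hits >= 9  # OR 2 per SD at n=187 passes P<0.20 nearly always

    def test_independent_covariate_mostly_excluded(self):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rec = self._records(np.random.default_rng(100 + seed), beta=np.log(2))
            passed, _ = sd.univariate_screen(rec, "unfavorable")
            hits += "noise" in passed
        # null covariate passes at the nominal ~20% screen rate; 13+/30
        # would be a gross miscalibration (P < 0.3% at rate 0.2)
        assert hits <= 12

    def test_outcome_scores_never_predictors(self, rng):
        rec = self._records(rng, beta=1.0)
        passed, audit = sd.univariate_screen(rec, "unfavorable")
        assert "mrs_out" not in passed and "nihss_in" not in passed
        assert "mrs_out" not in audit.index

    def test_p_in_one_passes_everything_testable(self, rng):
        rec = self._records(rng, beta=1.0)
        passed, audit = sd.univariate_screen(rec, "unfavorable", p_in=1.0)
        assert set(passed) == set(audit.index[~audit["separated"]])

    def test_outcome_definitions(self):
        rec = pd.DataFrame({"nihss_in": [7, 8], "mrs_out": [2, 3]})
        assert outcome_indicator(rec, "severe").tolist() == [0, 1]
        assert outcome_indicator(rec, "unfavorable").tolist() == [0, 1]


class TestInfarctCorrection:
    def test_no_edema_reduces_to_direct_areas(self):
        v = sd.correct_infarct([2.0, 3.0], [10.0, 11.0], [10.0, 11.0], 0.5)
        assert v == pytest.approx((2.0 + 3.0) * 0.5)

    def test_hand_arithmetic_single_section(self):
        """direct 5, ipsi 12, contra 10, interval 0.4: corrected area
        5 - (12 - 10) = 3, volume 1.2."""
        assert sd.correct_infarct([5.0], [12.0], [10.0], 0.4) == pytest.approx(1.2)

    def test_zero_direct_lesion_gives_zero_volume(self):
        assert sd.correct_infarct([0.0, 0.0], [10.0, 9.0], [10.0, 9.0], 0.4) == 0.0

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError, match="equal lengths"):
            sd.correct_infarct([1.0], [1.0, 2.0], [1.0], 0.4)

    def test_correction_floored_at_zero(self):
        # severe swelling larger than the lesion cannot go negative
        assert sd.correct_infarct([1.0], [20.0], [10.0], 1.0) == 0.0
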