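"""Correlation, ROC, cutoff, sample-size and t-test machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sstats

from prognostrack.stats import (
    SampleSizeSpec,
    categorize_effect,
    cutoff_performance,
    cutoff_sweep,
    kendall_tau,
    roc_auc,
    sample_size_correlation,
    tau_to_r,
    welch_t_test,
)


def kendall_tau_b_oracle(x, y):
    """O(n^2) concordant/discordant pair count with tie correction."""
    n = len(x)
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    nx = sum(
        t * (t - 1) / 2 for t in np.unique(np.asarray(x), return_counts=True)[1]
    )
    ny = sum(
        t * (t - 1) / 2 for t in np.unique(np.asarray(y), return_counts=True)[1]
    )
    return (conc - disc) / math.sqrt((n0 - nx) * (n0 - ny))


def auc_pair_oracle(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestKendallTau:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        assert kendall_tau(x, x).tau == pytest.approx(1.0)

    def test_perfect_reversal(self):
        x = np.arange(10.0)
        assert kendall_tau(x, -x).tau == pytest.approx(-1.0)

    def test_tied_vectors_match_pair_count_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 20))
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            res = kendall_tau(x, y)
            assert res.tau == pytest.approx(kendall_tau_b_oracle(x, y), abs=1e-12)

    def test_missing_pairs_deleted(self):
        x = np.array([1, 2, 3, 4, np.nan, 6.0])
        y = np.array([1, 2, 3, np.nan, 5, 6.0])
        assert kendall_tau(x, y).n_pairs == 4

    def test_zero_variance_undefined(self):
        res = kendall_tau(np.ones(5), np.arange(5.0))
        assert res.category == "undefined" and math.isnan(res.tau)

    @given(st.integers(0, 2**31 - 1))
    def test_antisymmetry_and_monotone_invariance(self, seed):
        g = np.random.default_rng(seed)
        x = g.integers(0, 6, 12).astype(float)
        y = g.integers(0, 6, 12).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        t = kendall_tau(x, y).tau
        assert kendall_tau(x, -y).tau == pytest.approx(-t, abs=1e-12)
        assert kendall_tau(np.exp(x), y).tau == pytest.approx(t, abs=1e-12)


class TestEffectTranslation:
    @pytest.mark.parametrize(
        "tau,r", [(0.0, 0.0), (1.0, 1.0), (0.5, math.sqrt(2) / 2), (-1.0, -1.0)]
    )
    def test_greiner_closed_forms(self, tau, r):
        assert tau_to_r(tau) == pytest.approx(r)

    @pytest.mark.parametrize(
        "tau,label",
        [(0.35, "large"), (-0.4, "large"), (0.34, "moderate"), (0.20, "moderate"),
         (0.19, "small"), (0.0, "small")],
    )
    def test_effect_bands(self, tau, label):
        assert categorize_effect(tau) == label


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0 and res.strength == "outstanding"

    def test_all_tied_scores_give_half(self):
        res = roc_auc(np.ones(10), [0, 1] * 5)
        assert res.auc == 0.5 and res.strength == "none"

    def test_matches_exhaustive_pair_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 25))
            scores = rng.integers(0, 8, n).astype(float)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            res = roc_auc(scores, labels)
            assert res.auc == pytest.approx(auc_pair_oracle(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.standard_normal(60)
        labels = rng.integers(0, 2, 60)
        assert roc_auc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_complement_identity(self, rng):
        scores = rng.integers(0, 5, 40).astype(float)
        labels = rng.integers(0, 2, 40)
        a = roc_auc(scores, labels).auc
        b = roc_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.standard_normal(50)
        labels = rng.integers(0, 2, 50)
        assert roc_auc(np.exp(scores), labels).auc == pytest.approx(
            roc_auc(scores, labels).auc
        )

    def test_one_class_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            roc_auc([1.0, 2.0], [1, 1])

    def test_strength_bands(self):
        from prognostrack.stats import auc_strength

        assert auc_strength(0.69) == "none"
        assert auc_strength(0.7) == "acceptable"
        assert auc_strength(0.8) == "excellent"
        assert auc_strength(0.9) == "outstanding"


class TestCutoffPerformance:
    def test_contingency_table_oracle(self):
        # TP=9, FN=3, FP=7, TN=18 at cutoff 4 with score >= 4 positive
        scores = np.array([4.0] * 9 + [3.0] * 3 + [4.0] * 7 + [3.0] * 18)
        labels = np.array([1] * 12 + [0] * 25)
        perf = cutoff_performance(scores, labels, 4.0)
        assert perf.sensitivity == pytest.approx(9 / 12)
        assert perf.specificity == pytest.approx(18 / 25)
        assert perf.lr_pos == pytest.approx((9 / 12) / (7 / 25))
        assert perf.lr_neg == pytest.approx((3 / 12) / (18 / 25))
        assert perf.interpretation == "sometimes useful"

    def test_perfect_split(self):
        perf = cutoff_performance([1, 1, 5, 5], [0, 0, 1, 1], 3.0)
        assert perf.sensitivity == 1.0 and perf.specificity == 1.0
        assert math.isinf(perf.lr_pos)

    def test_sweep_endpoints(self, rng):
        scores = rng.integers(0, 10, 30).astype(float)
        labels = rng.integers(0, 2, 30)
        if labels.sum() in (0, 30):
            labels[0] = 1 - labels[0]
        sweep = cutoff_sweep(scores, labels)
        assert sweep[0].sensitivity == 1.0 and sweep[0].specificity == 0.0
        assert sweep[-1].sensitivity == 0.0 and sweep[-1].specificity == 1.0


class TestSampleSize:
    def test_reproduces_published_design_values(self):
        assert sample_size_correlation(SampleSizeSpec(0.40, 0.05, 0.80, 0.10)) == 51
        assert sample_size_correlation(SampleSizeSpec(0.50, 0.05, 0.80, 0.10)) == 32

    def test_monotonicity(self):
        base = SampleSizeSpec(0.30, 0.05, 0.80, 0.10)
        n = sample_size_correlation(base)
        assert sample_size_correlation(SampleSizeSpec(0.40, 0.05, 0.80, 0.10)) < n
        assert sample_size_correlation(SampleSizeSpec(0.30, 0.01, 0.80, 0.10)) > n
        assert sample_size_correlation(SampleSizeSpec(0.30, 0.05, 0.90, 0.10)) > n
        assert sample_size_correlation(SampleSizeSpec(0.30, 0.05, 0.80, 0.20)) > n

    def test_power_by_monte_carlo(self, rng):
        """The returned n actually delivers ~80 % power at the target r."""
        r = 0.30
        n = sample_size_correlation(SampleSizeSpec(r, 0.05, 0.80, 0.0))
        cov = np.array([[1, r], [r, 1]])
        hits = 0
        reps = 4000
        for _ in range(reps):
            xy = rng.multivariate_normal([0, 0], cov, size=n)
            if sstats.pearsonr(xy[:, 0], xy[:, 1]).pvalue < 0.05:
                hits += 1
        assert hits / reps == pytest.approx(0.80, abs=0.04)

    def test_invalid_r_rejected(self):
        with pytest.raises(ValueError, match="target correlation"):
            SampleSizeSpec(1.2)


class TestWelch:
    def test_identical_groups(self):
        t, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_separated_groups(self, rng):
        a = rng.normal(0, 0.1, 20)
        b = a + 100.0
        _, p = welch_t_test(a, b)
        assert p < 1e-3

    def test_matches_hand_formula(self):
        a = np.array([1.0, 2.0, 4.0, 3.0, 5.0])
        b = np.array([2.0, 6.0, 7.0, 9.0])
        t, _ = welch_t_test(a, b)
        se = math.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
        assert t == pytest.approx((a.mean() - b.mean()) / se, abs=1e-9)

    def test_degenerate_equal_constants(self):
        assert welch_t_test([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
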