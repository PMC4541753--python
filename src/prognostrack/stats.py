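"""Statistical machinery for prognostic screening-tool validation.

Kendall rank correlation (tau-b) with the Pearson-equivalence translation
r = sin(pi * tau / 2) and effect-size labels; ROC/AUC with Hanley-McNeil
confidence intervals and ability-strength labels; cutoff sensitivity,
specificity and likelihood ratios; Welch two-sample comparison of baseline
characteristics; and the Fisher-z sample-size calculation for a
correlation design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

# Effect-size bands on |tau| (the published bands leave (0.19, 0.20) open;
# the boundary is taken at 0.20: |tau| >= 0.20 is at least moderate).
LARGE_TAU = 0.34
MODERATE_TAU = 0.20

# AUC ability-strength bands
AUC_ACCEPTABLE = 0.7
AUC_EXCELLENT = 0.8
AUC_OUTSTANDING = 0.9

# Decisive likelihood-ratio bounds
LR_POS_DECISIVE = 10.0
LR_NEG_DECISIVE = 0.1


@dataclass(frozen=True)
class CorrelationResult:
    tau: float
    p_value: float
    n_pairs: int
    r_equiv: float
    category: str  # large | moderate | small | undefined


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    p_value: float
    strength: str  # none | acceptable | excellent | outstanding
    positive_class: str
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CutoffPerformance:
    cutoff: float
    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float
    interpretation: str


@dataclass(frozen=True)
class SampleSizeSpec:
    target_r: float
    alpha: float = 0.05
    power: float = 0.80
    attrition: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.target_r < 1:
            raise ValueError("target correlation must lie strictly in (0, 1)")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if not 0 <= self.attrition < 1:
            raise ValueError("attrition must lie in [0, 1)")


def tau_to_r(tau: float) -> float:
    """Pearson-equivalent correlation for a Kendall tau: r = sin(pi*tau/2).

    Exact for bivariate normal data (Greiner's relation); used to translate
    rank correlations onto the familiar r scale.
    """
    if abs(tau) > 1:
        raise ValueError("|tau| must be <= 1")
    return math.sin(math.pi * tau / 2.0)


def categorize_effect(tau: float) -> str:
    """Effect-size label for |tau|: large > 0.34, moderate >= 0.20, else small."""
    a = abs(tau)
    if a > 1:
        raise ValueError("|tau| must be <= 1")
    if a > LARGE_TAU:
        return "large"
    if a >= MODERATE_TAU:
        return "moderate"
    return "small"


def kendall_tau(x, y) -> CorrelationResult:
    """Kendall tau-b between two paired variables with pairwise deletion.

    Pairs with a missing value in either variable are dropped.  Tau-b
    corrects for ties; the two-sided p-value uses the tie-corrected normal
    approximation.  A zero-variance variable yields an undefined result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("kendall_tau needs at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(math.nan, math.nan, n, math.nan, "undefined")
    res = sstats.kendalltau(x, y, variant="b", method="asymptotic")
    tau = float(res.statistic)
    return CorrelationResult(
        tau=tau,
        p_value=float(res.pvalue),
        n_pairs=n,
        r_equiv=tau_to_r(tau),
        category=categorize_effect(tau),
    )


# ---------------------------------------------------------------------------
# ROC / AUC


def _auc_mann_whitney(scores_pos: np.ndarray, scores_neg: np.ndarray) -> float:
    """AUC as the rank statistic P(s+ > s-) + 0.5 P(s+ = s-)."""
    all_scores = np.concatenate([scores_pos, scores_neg])
    ranks = sstats.rankdata(all_scores)
    n_pos, n_neg = scores_pos.size, scores_neg.size
    r_pos = ranks[:n_pos].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def _delong_se(scores_pos: np.ndarray, scores_neg: np.ndarray, auc: float) -> float:
    # placement values: V10_i = P(s- < s+_i) + 0.5 P(s- = s+_i)
    v10 = np.array(
        [np.mean((scores_neg < s) + 0.5 * (scores_neg == s)) for s in scores_pos]
    )
    v01 = np.array(
        [np.mean((scores_pos > s) + 0.5 * (scores_pos == s)) for s in scores_neg]
    )
    var = np.var(v10, ddof=1) / scores_pos.size + np.var(v01, ddof=1) / scores_neg.size
    return math.sqrt(max(var, 0.0))


def auc_strength(auc: float) -> str:
    """Ability-strength label: 0.7-0.8 acceptable, 0.8-0.9 excellent, >=0.9 outstanding."""
    if auc >= AUC_OUTSTANDING:
        return "outstanding"
    if auc >= AUC_EXCELLENT:
        return "excellent"
    if auc >= AUC_ACCEPTABLE:
        return "acceptable"
    return "none"


def roc_auc(
    scores, labels, positive_class: str = "present", ci_method: str = "hanley-mcneil"
) -> ROCResult:
    """Empirical AUC with 95 % CI and a test against the chance value 0.5.

    Pairs with missing score or label are dropped.  The AUC is the
    tie-corrected rank statistic (the probability a random positive scores
    above a random negative, counting ties as half).  The CI uses the
    Hanley-McNeil standard error by default ('delong' available); the
    p-value is a two-sided z-test of AUC = 0.5 on the same standard error.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    lab = labels.astype(float)
    keep = np.isfinite(scores) & np.isfinite(lab)
    scores, lab = scores[keep], lab[keep]
    pos = scores[lab == 1]
    neg = scores[lab == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError(
            f"ROC needs both classes non-empty (got {pos.size} positive, "
            f"{neg.size} negative)"
        )
    auc = float(_auc_mann_whitney(pos, neg))
    if ci_method == "hanley-mcneil":
        se = _hanley_mcneil_se(auc, pos.size, neg.size)
    elif ci_method == "delong":
        se = _delong_se(pos, neg, auc)
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    z975 = sstats.norm.ppf(0.975)
    lo = max(0.0, auc - z975 * se)
    hi = min(1.0, auc + z975 * se)
    if se > 0:
        p = 2.0 * sstats.norm.sf(abs(auc - 0.5) / se)
    else:
        p = 0.0 if auc != 0.5 else 1.0
    return ROCResult(
        auc=auc,
        ci95=(float(lo), float(hi)),
        p_value=float(p),
        strength=auc_strength(auc),
        positive_class=positive_class,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def roc_curve_points(scores, labels) -> np.ndarray:
    """(cutoff, sensitivity, 1-specificity) triples over all observed cutoffs."""
    rows = [
        (c.cutoff, c.sensitivity, 1.0 - c.specificity) for c in cutoff_sweep(scores, labels)
    ]
    return np.array(rows)


# ---------------------------------------------------------------------------
# Cutoff performance


def interpret_lrs(lr_pos: float, lr_neg: float) -> str:
    """Clinical reading of the likelihood-ratio pair."""
    if lr_pos > LR_POS_DECISIVE:
        return "strongly increases probability"
    if lr_neg < LR_NEG_DECISIVE:
        return "strongly decreases probability"
    return "sometimes useful"


def cutoff_performance(scores, labels, cutoff: float) -> CutoffPerformance:
    """Sensitivity, specificity and likelihood ratios at one cutoff.

    Test-positive means score >= cutoff.  LR+ = sens/(1-spec) (infinite at
    spec = 1); LR- = (1-sens)/spec (NaN, flagged, at spec = 0).
    """
    scores = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(float)
    keep = np.isfinite(scores) & np.isfinite(lab)
    scores, lab = scores[keep], lab[keep]
    pos = lab == 1
    neg = lab == 0
    if not pos.any() or not neg.any():
        raise ValueError("cutoff_performance needs both classes non-empty")
    test_pos = scores >= cutoff
    tp = int(np.sum(test_pos & pos))
    fn = int(np.sum(~test_pos & pos))
    fp = int(np.sum(test_pos & neg))
    tn = int(np.sum(~test_pos & neg))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    lr_pos = math.inf if spec == 1.0 else sens / (1.0 - spec)
    lr_neg = math.nan if spec == 0.0 else (1.0 - sens) / spec
    return CutoffPerformance(
        cutoff=float(cutoff),
        sensitivity=sens,
        specificity=spec,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        interpretation=interpret_lrs(lr_pos, lr_neg if not math.isnan(lr_neg) else 1.0),
    )


def cutoff_sweep(scores, labels) -> list[CutoffPerformance]:
    """Performance at every observed score plus one cutoff beyond each end."""
    scores = np.asarray(scores, dtype=float)
    finite = scores[np.isfinite(scores)]
    uniq = np.unique(finite)
    step = (uniq[-1] - uniq[0]) / max(uniq.size - 1, 1) or 1.0
    cutoffs = np.concatenate([[uniq[0] - step], uniq, [uniq[-1] + step]])
    return [cutoff_performance(scores, labels, c) for c in cutoffs]


# ---------------------------------------------------------------------------
# Design and baseline comparisons


def sample_size_correlation(spec: SampleSizeSpec) -> int:
    """Participants needed to detect a correlation, Fisher-z approximation.

    n0 = ((z_{1-alpha/2} + z_{1-power}) / atanh(r))^2 + 3, kept unrounded;
    the attrition-inflated total n0 * (1 + attrition) is then rounded
    half-up to the nearest integer.  This inflate-then-round order matters:
    it yields 51 for r = 0.40 and 32 for r = 0.50 at alpha 0.05, power
    0.80, attrition 10 %, whereas ceiling before inflating does not.
    """
    z_a = sstats.norm.ppf(1.0 - spec.alpha / 2.0)
    z_b = sstats.norm.ppf(spec.power)
    n0 = ((z_a + z_b) / math.atanh(spec.target_r)) ** 2 + 3.0
    return int(math.floor(n0 * (1.0 + spec.attrition) + 0.5))


def welch_t_test(a, b) -> tuple[float, float]:
    """Welch (unequal-variance) two-sample t-test; returns (t, two-sided p).

    Used to compare baseline characteristics between groups (males vs
    females; completers vs lost to follow-up).  Two constant groups with
    equal means return (0, 1) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return (0.0, 1.0)
        return (math.copysign(math.inf, a.mean() - b.mean()), 0.0)
    t, p = sstats.ttest_ind(a, b, equal_var=False)
    return (float(t), float(p))


def pooled_t_test(a, b) -> tuple[float, float]:
    """Student (pooled-variance) variant, for sensitivity analyses."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t, p = sstats.ttest_ind(a[np.isfinite(a)], b[np.isfinite(b)], equal_var=True)
    return (float(t), float(p))
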