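"""Evaluation statistics: agreement, exact intervals, ROC/DeLong, comparisons.

All count-based metrics are returned as :class:`MetricResult`, carrying the
integer counts they were computed from together with an exact
(Clopper–Pearson) confidence interval.  Percentages are rendered on the
0–100 scale, rounded half away from zero, which is the convention used
throughout the reported tables of this workflow.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .schema import ValidationError

__all__ = [
    "MetricResult", "ConfusionCounts", "cohens_kappa", "exact_binomial_ci",
    "proportion_metric", "diagnostic_metrics", "roc_auc_delong",
    "delong_paired_test", "spearman_rho", "group_compare",
    "percent_difference", "round_percent", "collapse_one_vs_rest",
]


def round_percent(fraction: float, decimals: int = 0) -> float:
    """Render a fraction in [0, 1] as a percentage, rounding half away from zero."""
    x = fraction * 100.0 * 10 ** decimals
    r = math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1)
    return r / 10 ** decimals


@dataclass(frozen=True)
class MetricResult:
    """A point estimate with its confidence interval and provenance counts."""

    name: str
    estimate: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95
    method: str = ""
    numerator: int | None = None
    denominator: int | None = None
    p_value: float | None = None

    def __post_init__(self):
        if not (self.ci_low <= self.estimate + 1e-12 and
                self.estimate <= self.ci_high + 1e-12):
            raise ValidationError(
                f"{self.name}: estimate {self.estimate} outside CI "
                f"[{self.ci_low}, {self.ci_high}]")

    @property
    def percent(self) -> float:
        return round_percent(self.estimate)

    @property
    def percent_1dp(self) -> float:
        return round_percent(self.estimate, 1)

    @property
    def ci_percent(self) -> tuple[float, float]:
        return round_percent(self.ci_low), round_percent(self.ci_high)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------


def collapse_one_vs_rest(labels, positive) -> np.ndarray:
    """Collapse a multiclass label vector to positive-vs-rest."""
    arr = np.asarray(labels, dtype=object)
    return np.where(arr == positive, str(positive), "rest")


def cohens_kappa(labels_a, labels_b, class_set=None, ci_level: float = 0.95) -> MetricResult:
    """Chance-corrected agreement between two raters.

    κ = (p_o − p_e) / (1 − p_e) with p_e from the product of the raters'
    marginals.  The degenerate case p_e = 1 (both raters constant and equal)
    is defined as perfect agreement, κ = 1, with a warning.  The confidence
    interval uses the large-sample standard error
    sqrt(p_o (1 − p_o) / (n (1 − p_e)²)).
    """
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValidationError("label vectors must be aligned, 1-D and non-empty")
    classes = sorted(set(a) | set(b)) if class_set is None else list(class_set)
    if not (set(a) | set(b)) <= set(classes):
        raise ValidationError("labels outside the declared class set")
    idx = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    table = np.zeros((k, k))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    n = table.sum()
    po = np.trace(table) / n
    pe = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if pe >= 1.0 - 1e-12:
        warnings.warn("both raters constant and equal; kappa defined as 1")
        return MetricResult("cohens_kappa", 1.0, 1.0, 1.0, ci_level, "kappa_degenerate")
    kappa = (po - pe) / (1 - pe)
    se = math.sqrt(max(po * (1 - po), 0.0) / (n * (1 - pe) ** 2))
    z = sps.norm.ppf(0.5 + ci_level / 2)
    return MetricResult("cohens_kappa", kappa, max(-1.0, kappa - z * se),
                        min(1.0, kappa + z * se), ci_level, "kappa_asymptotic")


# ---------------------------------------------------------------------------
# exact binomial machinery
# ---------------------------------------------------------------------------


def exact_binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson two-sided interval via the beta-quantile construction."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValidationError("successes must be in [0, n]")
    low, high = proportion_confint(successes, n, alpha=1 - level, method="beta")
    # statsmodels returns NaN at the boundary cases; the exact limits are 0/1
    low = 0.0 if successes == 0 else float(low)
    high = 1.0 if successes == n else float(high)
    return low, high


def proportion_metric(name: str, successes: int, n: int, level: float = 0.95) -> MetricResult:
    low, high = exact_binomial_ci(successes, n, level)
    return MetricResult(name, successes / n, low, high, level,
                        "exact_binomial", successes, n)


def diagnostic_metrics(counts: ConfusionCounts, level: float = 0.95) -> dict[str, MetricResult]:
    """Sensitivity, specificity, PPV, NPV and accuracy with exact CIs.

    Metrics whose denominator is zero are omitted (with a warning) rather
    than reported as 0/0.
    """
    pairs = {
        "sensitivity": (counts.tp, counts.tp + counts.fn),
        "specificity": (counts.tn, counts.tn + counts.fp),
        "ppv": (counts.tp, counts.tp + counts.fp),
        "npv": (counts.tn, counts.tn + counts.fn),
        "accuracy": (counts.tp + counts.tn, counts.total),
    }
    out = {}
    for name, (k, n) in pairs.items():
        if n == 0:
            warnings.warn(f"{name}: zero denominator, metric omitted")
            continue
        out[name] = proportion_metric(name, k, n, level)
    return out


# ---------------------------------------------------------------------------
# ROC / DeLong
# ---------------------------------------------------------------------------


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong_components(score_matrix: np.ndarray, m: int):
    """Structural components for ROC AUCs of r classifiers.

    ``score_matrix`` is (r, N) with the first ``m`` columns the positive
    class.  Returns (aucs, covariance matrix of the AUC estimates).
    """
    n = score_matrix.shape[1] - m
    v01 = np.empty((score_matrix.shape[0], m))
    v10 = np.empty((score_matrix.shape[0], n))
    aucs = np.empty(score_matrix.shape[0])
    for r, sc in enumerate(score_matrix):
        tx = _midrank(sc[:m])
        ty = _midrank(sc[m:])
        tz = _midrank(sc)
        aucs[r] = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    s01 = np.cov(v01) if m > 1 else np.zeros((len(aucs), len(aucs)))
    s10 = np.cov(v10) if n > 1 else np.zeros((len(aucs), len(aucs)))
    cov = np.atleast_2d(s01) / m + np.atleast_2d(s10) / n
    return aucs, cov


def _split_by_label(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValidationError("scores and labels must be aligned 1-D vectors")
    if y.all() or (~y).all():
        raise ValidationError("both classes must be present")
    return np.concatenate([s[y], s[~y]]), int(y.sum())


def roc_auc_delong(scores, labels, ci_level: float = 0.95) -> MetricResult:
    """ROC AUC by the Mann–Whitney construction with DeLong variance.

    ``labels`` is a binary vector (truthy = positive class); ties in the
    scores are handled by midranks.
    """
    ordered, m = _split_by_label(scores, labels)
    aucs, cov = _delong_components(ordered[None, :], m)
    auc = float(aucs[0])
    se = math.sqrt(max(float(cov[0, 0]), 0.0))
    z = sps.norm.ppf(0.5 + ci_level / 2)
    return MetricResult("roc_auc", auc, max(0.0, auc - z * se),
                        min(1.0, auc + z * se), ci_level, "auc_delong")


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided DeLong test for a paired AUC difference.

    Returns ``(auc_a − auc_b, p)``.  A zero-variance difference (e.g.
    identical score vectors) yields p = 1 when the difference is 0.
    """
    a, m = _split_by_label(scores_a, labels)
    b, m2 = _split_by_label(scores_b, labels)
    if m != m2 or len(a) != len(b):
        raise ValidationError("paired score vectors must share the labels")
    aucs, cov = _delong_components(np.vstack([a, b]), m)
    diff = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    if var <= 1e-16:
        if abs(diff) < 1e-12:
            return 0.0, 1.0
        warnings.warn("zero variance with nonzero AUC difference")
        return diff, 0.0
    z = diff / math.sqrt(var)
    return diff, float(2 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# correlations and group comparisons
# ---------------------------------------------------------------------------


def spearman_rho(x, y, ci_level: float = 0.95) -> MetricResult:
    """Spearman rank correlation with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValidationError("need aligned 1-D vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("Spearman correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    rho = float(rho)
    n = len(x)
    if n > 3 and abs(rho) < 1.0:
        zse = 1.06 / math.sqrt(n - 3)
        zc = sps.norm.ppf(0.5 + ci_level / 2)
        zr = math.atanh(rho)
        lo, hi = math.tanh(zr - zc * zse), math.tanh(zr + zc * zse)
    else:
        lo = hi = rho
    return MetricResult("spearman_rho", rho, lo, hi, ci_level,
                        "spearman_fisher_z", p_value=float(p))


_SHAPIRO_CAP = 5000  # validity limit of the Shapiro–Wilk implementation


def group_compare(values, group_labels, alpha: float = 0.05,
                  m_tests: int = 1) -> tuple[str, float, float]:
    """Shapiro–Wilk-gated two-group comparison with Bonferroni adjustment.

    Both groups normal at ``alpha`` → two-sample t-test; otherwise
    Mann–Whitney U (midranks, continuity correction).  Returns
    ``(test_used, p, p_bonferroni)`` with p_bonferroni = min(1, m_tests·p).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(group_labels, dtype=object)
    groups = sorted(set(g))
    if len(groups) != 2:
        raise ValidationError("exactly two groups required")
    x, y = v[g == groups[0]], v[g == groups[1]]
    if len(x) < 3 or len(y) < 3:
        raise ValidationError("each group needs n >= 3")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return "degenerate", 1.0, 1.0
        raise ValidationError("both groups constant with different values")
    normal = True
    for sample in (x, y):
        if np.ptp(sample) == 0:
            normal = False
            break
        if sps.shapiro(sample[:_SHAPIRO_CAP]).pvalue <= alpha:
            normal = False
            break
    if normal:
        test, p = "t-test", float(sps.ttest_ind(x, y).pvalue)
    else:
        test, p = "mann-whitney", float(
            sps.mannwhitneyu(x, y, alternative="two-sided", use_continuity=True).pvalue)
    return test, p, min(1.0, m_tests * p)


def percent_difference(mean_ref: float, mean_other: float) -> float:
    """100·(ref − other)/ref, to 2 decimals, with the first group as anchor."""
    if mean_ref == 0:
        raise ValidationError("percent difference undefined for a zero reference mean")
    return round(100.0 * (mean_ref - mean_other) / mean_ref, 2)
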