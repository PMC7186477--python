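"""ROC metrics, correlated-AUC comparison, contingency tests and ICC."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .errors import CohortError, DimensionError, EmptyRegionError, ExpectedCountError


# ---------------------------------------------------------------------------
# DeLong machinery (shared with modeling)
# ---------------------------------------------------------------------------


def delong_components(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus the DeLong structural components V10 (per positive) and
    V01 (per negative); ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise CohortError("both classes are required to compute an AUC")
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = v10.size, v01.size
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return s10 / m + s01 / n


def delong_auc_ci(
    scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """AUC with a DeLong-variance normal-approximation CI, clipped to [0, 1]."""
    auc, v10, v01 = delong_components(scores, labels)
    se = np.sqrt(delong_variance(v10, v01))
    z = stats.norm.ppf(1 - alpha / 2)
    return auc, float(max(auc - z * se, 0.0)), float(min(auc + z * se, 1.0))


# ---------------------------------------------------------------------------
# ROC metrics
# ---------------------------------------------------------------------------


@dataclass
class ROCResult:
    auc: float
    ci_lower: float
    ci_upper: float
    sensitivity: float  # percent, at the operating point
    specificity: float  # percent
    accuracy: float  # percent
    threshold: float  # NaN when flagged (degenerate scores)


def roc_metrics(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """AUC (pair counting), DeLong CI and Youden-maximum operating point.

    Youden ties are broken toward higher specificity. Constant score
    vectors give AUC 0.5 with a flagged operating point.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.ptp(scores) == 0:
        return ROCResult(0.5, float("nan"), float("nan"), float("nan"),
                         float("nan"), float("nan"), float("nan"))
    auc, lo, hi = delong_auc_ci(scores, y)
    fpr, tpr, thresholds = roc_curve(y, scores)
    youden = tpr - fpr
    best = np.flatnonzero(youden >= youden.max() - 1e-12)
    k = best[np.argmin(fpr[best])]  # max J, then max specificity
    threshold = float(thresholds[k])
    pred = scores >= threshold
    sens = 100.0 * float(tpr[k])
    spec = 100.0 * float(1.0 - fpr[k])
    acc = 100.0 * float((pred == (y == 1)).mean())
    return ROCResult(auc, lo, hi, sens, spec, acc, threshold)


def compare_auc(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """DeLong's paired z-test for two correlated AUCs (two-sided p)."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise DimensionError("paired score vectors must have equal length")
    auc_a, va10, va01 = delong_components(scores_a, labels)
    auc_b, vb10, vb01 = delong_components(scores_b, labels)
    m, n = va10.size, va01.size
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 1e-15:
        if abs(diff) < 1e-12:
            return 0.0, 1.0
        return float("nan"), float("nan")  # degenerate variance: flagged
    z = diff / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------


def expected_counts(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


def chi_square_yates(table) -> float:
    """Upper-tail p of the Yates continuity-corrected 2x2 chi-square."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise DimensionError("chi_square_yates requires a 2x2 table")
    if (t < 0).any() or t.sum() == 0:
        raise DimensionError("counts must be non-negative with a positive total")
    expected = expected_counts(t)
    if (expected < 5).any():
        raise ExpectedCountError(
            "expected count below 5; use fisher_exact for this table"
        )
    adj = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    statistic = float((adj**2 / expected).sum())
    return float(stats.chi2.sf(statistic, df=1))


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for an r x 2 table.

    2x2 tables use the hypergeometric formulation; larger tables sum the
    conditional probabilities of all margin-compatible tables at most as
    probable as the observed one (exact enumeration; counts are small in
    clinical characteristic tables).
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[1] != 2:
        raise DimensionError("fisher_exact requires an r x 2 table")
    if t.shape[0] == 2:
        return float(stats.fisher_exact(t, alternative="two-sided")[1])

    rows = t.sum(axis=1)
    col1 = int(t[:, 0].sum())
    total = int(t.sum())

    def log_prob(firsts: tuple[int, ...]) -> float:
        lp = -_log_comb(total, col1)
        for r, a in zip(rows, firsts):
            lp += _log_comb(int(r), a)
        return lp

    observed = log_prob(tuple(int(v) for v in t[:, 0]))
    p_total = 0.0

    def recurse(i: int, remaining: int, prefix: tuple[int, ...]) -> None:
        nonlocal p_total
        if i == len(rows) - 1:
            if 0 <= remaining <= rows[i]:
                lp = log_prob(prefix + (remaining,))
                if lp <= observed + 1e-9:
                    p_total += np.exp(lp)
            return
        upper = min(int(rows[i]), remaining)
        for a in range(0, upper + 1):
            recurse(i + 1, remaining - a, prefix + (a,))

    recurse(0, col1, ())
    return float(min(p_total, 1.0))


def _log_comb(n: int, k: int) -> float:
    from scipy.special import gammaln

    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


# ---------------------------------------------------------------------------
# Interobserver agreement
# ---------------------------------------------------------------------------

ICC_BANDS = ((0.4, "poor"), (0.6, "moderate"), (0.8, "good"), (1.0, "excellent"))


def icc_agreement(ratings: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure."""
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise DimensionError("ratings must be (n_items, n_raters >= 2)")
    n, k = x.shape
    if n < 3:
        raise CohortError("icc_agreement needs at least 3 items")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or (msr == 0 and mse == 0):
        return float("nan")  # zero between-item variance: flagged
    return float((msr - mse) / denom)


def icc_band(icc: float) -> str:
    """Agreement band: 0-0.4 poor, 0.41-0.6 moderate, 0.61-0.8 good,
    0.81-1 excellent."""
    if not np.isfinite(icc):
        raise EmptyRegionError("ICC is flagged/undefined")
    for upper, name in ICC_BANDS:
        if icc <= upper:
            return name
    return "excellent"
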