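"""Diagnostic-performance statistics.

Positive detection rates with two-sided confidence intervals, the Youden
index used to rank candidate cut-offs, ROC analysis of the censored Ct
score, and two-arm comparisons of positivity rates.

The interval method is the Wilson score interval *with continuity
correction*: it reproduces, to the printed decimal, every interval in the
assay's reported performance tables (e.g. 4/6 -> 24.1–94.0%, 49/55 ->
77.1–95.5%, 59/65 -> 80.3–96.2%), which plain Wilson and Clopper–Pearson
do not.  Plain Wilson and Clopper–Pearson remain available for comparison
and delegate to :mod:`statsmodels`.

For ROC curves the score is a censored Ct: non-amplified samples sit at
exactly 50.0 cycles, so a large point mass of controls lies at the upper
end of the scale.  Lower scores indicate disease.  The AUC equals the
two-sample rank statistic (ties counted half), and its confidence interval
uses DeLong's asymptotic variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "detection_rate",
    "wilson_cc_interval",
    "proportion_ci",
    "youden",
    "RocCurve",
    "roc_curve",
    "delong_auc_ci",
    "compare_positivity",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as in the printed report tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def detection_rate(n_positive: int, n_valid: int) -> float:
    """Positive detection rate ``n_positive / n_valid`` as a proportion."""
    if n_valid <= 0:
        raise ZeroDivisionError("detection rate undefined for n_valid = 0")
    if not 0 <= n_positive <= n_valid:
        raise ValueError("need 0 <= n_positive <= n_valid")
    return n_positive / n_valid


def wilson_cc_interval(
    n_positive: int, n_valid: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Continuity-corrected Wilson score interval for a binomial proportion.

    Two-sided at the given confidence, clamped to ``[0, 1]``; the lower
    bound is exactly 0 when ``n_positive == 0`` and the upper bound exactly
    1 when ``n_positive == n_valid``.
    """
    if n_valid <= 0:
        raise ValueError("n_valid must be positive")
    if not 0 <= n_positive <= n_valid:
        raise ValueError("need 0 <= n_positive <= n_valid")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    z = sps.norm.ppf(1 - (1 - confidence) / 2)
    n = n_valid
    p = n_positive / n
    z2 = z * z
    if n_positive == 0:
        low = 0.0
    else:
        low = (2 * n * p + z2 - 1
               - z * math.sqrt(z2 - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))
               ) / (2 * (n + z2))
    if n_positive == n_valid:
        high = 1.0
    else:
        high = (2 * n * p + z2 + 1
                + z * math.sqrt(z2 + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))
                ) / (2 * (n + z2))
    return (max(low, 0.0), min(high, 1.0))


def proportion_ci(
    n_positive: int,
    n_valid: int,
    confidence: float = 0.95,
    method: Literal["wilson_cc", "wilson", "clopper_pearson"] = "wilson_cc",
) -> tuple[float, float]:
    """Binomial proportion CI; ``wilson_cc`` is the default used everywhere."""
    if method == "wilson_cc":
        return wilson_cc_interval(n_positive, n_valid, confidence)
    from statsmodels.stats.proportion import proportion_confint

    sm_method = {"wilson": "wilson", "clopper_pearson": "beta"}[method]
    low, high = proportion_confint(n_positive, n_valid, alpha=1 - confidence,
                                   method=sm_method)
    return float(low), float(high)


def youden(sensitivity: float, specificity: float) -> float:
    """Youden index ``sensitivity + specificity - 1``.

    Equivalently the case positive-detection rate minus the control
    positive-detection rate.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must be proportions")
    return sensitivity + specificity - 1


@dataclass(frozen=True)
class RocCurve:
    """A ROC curve over all thresholds of a lower-is-disease score."""

    thresholds: np.ndarray  # ascending score thresholds (predict positive if score <= t)
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_cases: int
    n_controls: int

    def to_frame(self):  # pragma: no cover - thin convenience
        import pandas as pd

        return pd.DataFrame({
            "threshold": self.thresholds,
            "sensitivity": self.tpr,
            "one_minus_specificity": self.fpr,
        })


def roc_curve(
    scores: Sequence[float],
    is_case: Sequence[bool],
    lower_is_case: bool = True,
) -> RocCurve:
    """ROC curve and AUC for a censored continuous score.

    A sample is predicted positive when its score is at or below the
    threshold (for ``lower_is_case``).  The curve runs over every distinct
    observed score, including the censored mass at the maximal Ct, and is
    anchored at (0, 0) and (1, 1).  The trapezoidal AUC equals the
    two-sample rank statistic: ties between a case and a control count
    one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(is_case, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    if np.isnan(scores).any():
        raise ValueError("scores must not contain NaN")
    n_cases = int(labels.sum())
    n_controls = int((~labels).sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError("need at least one case and one control")
    if not lower_is_case:
        scores = -scores

    order = np.argsort(scores, kind="mergesort")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.diff(s) != 0, True]  # last index of each tie group
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(~y)[distinct]
    thresholds = s[distinct]
    tpr = np.r_[0.0, tp / n_cases]
    fpr = np.r_[0.0, fp / n_controls]
    auc = float(np.trapezoid(tpr, fpr))
    thresholds = np.r_[-np.inf, thresholds]
    if not lower_is_case:
        thresholds = -thresholds
    return RocCurve(thresholds, fpr, tpr, auc, n_cases, n_controls)


def _midrank_placements(cases: np.ndarray, controls: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong structural components V10 (cases) and V01 (controls)."""
    m, n = len(cases), len(controls)
    both = np.r_[cases, controls]
    r_all = sps.rankdata(both)
    r_cases = sps.rankdata(cases)
    r_controls = sps.rankdata(controls)
    # placement of each case among controls, and vice versa (lower = disease,
    # so "correctly ordered" means case score < control score)
    v10 = 1.0 - (r_all[:m] - r_cases) / n
    v01 = (r_all[m:] - r_controls) / m
    auc = float(v10.mean())
    return v10, v01, auc


def delong_auc_ci(
    scores: Sequence[float],
    is_case: Sequence[bool],
    confidence: float = 0.95,
    lower_is_case: bool = True,
) -> tuple[float, tuple[float, float]]:
    """AUC and DeLong confidence interval, clamped to ``[0, 1]``.

    Requires at least two cases and two controls (the variance estimate
    needs within-class variation).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(is_case, dtype=bool)
    cases = scores[labels]
    controls = scores[~labels]
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("DeLong CI needs at least 2 cases and 2 controls")
    if not lower_is_case:
        cases, controls = -cases, -controls
    v10, v01, auc = _midrank_placements(cases, controls)
    var = v10.var(ddof=1) / len(cases) + v01.var(ddof=1) / len(controls)
    z = sps.norm.ppf(1 - (1 - confidence) / 2)
    half = z * math.sqrt(var)
    return auc, (max(auc - half, 0.0), min(auc + half, 1.0))


def compare_positivity(
    calls_a: Sequence[bool],
    calls_b: Sequence[bool],
    method: Literal["welch", "student", "chi2"] = "welch",
) -> float:
    """Two-sided p-value comparing positivity between two arms.

    The default applies a Welch t-test to the 0/1 positivity indicators —
    the assay's reported analysis used a t-test on positivity, which for
    indicators is a two-proportion z-type test.  A pooled-variance Student
    t and a chi-square test (without continuity correction) are available
    because t-tests on proportions are unconventional.  Two arms with
    identical, degenerate rates give p = 1 by convention.
    """
    a = np.asarray(calls_a, dtype=float)
    b = np.asarray(calls_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each arm needs at least 2 samples")
    if method in ("welch", "student"):
        if a.var() == 0 and b.var() == 0:
            return 1.0 if a.mean() == b.mean() else 0.0
        res = sps.ttest_ind(a, b, equal_var=(method == "student"))
        return float(res.pvalue)
    if method == "chi2":
        table = np.array([[a.sum(), len(a) - a.sum()], [b.sum(), len(b) - b.sum()]])
        if (table.sum(axis=0) == 0).any():
            return 1.0
        return float(sps.chi2_contingency(table, correction=False)[1])
    raise ValueError(f"unknown method {method!r}")
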