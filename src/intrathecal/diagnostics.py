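"""Diagnostic-accuracy engine.

Confusion-table metrics with exact binomial confidence intervals, empirical
ROC curves and AUC, Youden-index cut-off optimisation, the DeLong test for
equality of paired (correlated) ROC areas, and marker concordance.

Conventions
-----------
* Markers are higher-is-positive unless stated otherwise; dichotomisation
  uses ``>=`` or ``>`` per marker (:func:`binary_marker`).
* Proportion confidence intervals are exact Clopper–Pearson.
* The AUC of a dichotomised (binary) marker equals
  (sensitivity + specificity) / 2; its CI uses the DeLong variance.
* Percent display: point estimates round half away from zero; CI bounds
  round via a one-decimal intermediate (the convention used in clinical
  tables, where interval bounds are transcribed from one-decimal output).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionTable",
    "MetricWithCI",
    "ConfusionMetrics",
    "ROCResult",
    "CutoffResult",
    "AUCComparison",
    "ConcordanceResult",
    "confusion_metrics",
    "roc_curve",
    "auc_delong",
    "youden_optimal_cutoff",
    "compare_auc",
    "concordance",
    "binary_marker",
    "round_percent",
    "round_ci_percent",
]


# --------------------------------------------------------------------------
# rounding helpers (percent display)

def round_percent(x: float) -> int:
    """Round a percentage to integer, half away from zero."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def round_ci_percent(x: float) -> int:
    """Round a CI bound to integer percent via a one-decimal intermediate."""
    one_decimal = math.copysign(math.floor(abs(x) * 10 + 0.5) / 10, x)
    return round_percent(one_decimal)


# --------------------------------------------------------------------------
# confusion-table metrics

@dataclass(frozen=True)
class ConfusionTable:
    """2x2 table of a binary marker against a binary outcome."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
        if self.total == 0:
            raise ValueError("confusion table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(
        cls, labels: Sequence[bool], predictions: Sequence[bool]
    ) -> "ConfusionTable":
        y = np.asarray(labels, dtype=bool)
        p = np.asarray(predictions, dtype=bool)
        if y.shape != p.shape:
            raise ValueError(f"length mismatch: {y.shape} labels vs {p.shape} predictions")
        return cls(
            tp=int(np.sum(p & y)),
            fp=int(np.sum(p & ~y)),
            fn=int(np.sum(~p & y)),
            tn=int(np.sum(~p & ~y)),
        )


class MetricWithCI(NamedTuple):
    """A proportion (or AUC) with its confidence interval; NaN if undefined."""

    estimate: float
    ci_low: float
    ci_high: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.estimate)

    def as_percent(self) -> Tuple[int, int, int]:
        """(point, ci_low, ci_high) rounded to integer percent."""
        return (
            round_percent(self.estimate * 100),
            round_ci_percent(self.ci_low * 100),
            round_ci_percent(self.ci_high * 100),
        )


@dataclass(frozen=True)
class ConfusionMetrics:
    """Sensitivity, specificity, PPV, NPV and binary-marker AUC with CIs."""

    sensitivity: MetricWithCI
    specificity: MetricWithCI
    ppv: MetricWithCI
    npv: MetricWithCI
    auc_binary: MetricWithCI
    table: ConfusionTable
    ci_level: float


def _proportion_ci(k: int, n: int, ci_level: float) -> MetricWithCI:
    if n == 0:
        return MetricWithCI(math.nan, math.nan, math.nan)
    lo, hi = proportion_confint(k, n, alpha=1 - ci_level, method="beta")
    return MetricWithCI(k / n, float(lo), float(hi))


def _binary_auc_ci(t: ConfusionTable, ci_level: float) -> MetricWithCI:
    """DeLong CI for the AUC of a dichotomised marker, from the 2x2 counts."""
    n_pos, n_neg = t.tp + t.fn, t.fp + t.tn
    if n_pos == 0 or n_neg == 0:
        return MetricWithCI(math.nan, math.nan, math.nan)
    sens, spec = t.tp / n_pos, t.tn / n_neg
    auc = (sens + spec) / 2.0
    # structural components take two values per class:
    # positives scoring 1 beat the tn negatives and tie the fp ones
    v10_hi, v10_lo = spec + 0.5 * (1 - spec), 0.5 * spec
    v01_hi, v01_lo = sens + 0.5 * (1 - sens), 0.5 * sens
    var10 = _two_point_var(v10_hi, t.tp, v10_lo, t.fn)
    var01 = _two_point_var(v01_hi, t.tn, v01_lo, t.fp)
    se = math.sqrt(var10 / n_pos + var01 / n_neg) if n_pos > 1 and n_neg > 1 else 0.0
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return MetricWithCI(auc, max(auc - z * se, 0.0), min(auc + z * se, 1.0))


def _two_point_var(a: float, na: int, b: float, nb: int) -> float:
    """Sample variance (ddof=1) of a vector with na copies of a, nb of b."""
    n = na + nb
    if n < 2:
        return 0.0
    mean = (na * a + nb * b) / n
    return (na * (a - mean) ** 2 + nb * (b - mean) ** 2) / (n - 1)


def confusion_metrics(t: ConfusionTable, ci_level: float = 0.95) -> ConfusionMetrics:
    """Compute sensitivity, specificity, PPV, NPV and binary AUC with CIs.

    Each metric whose denominator is zero is reported as NaN (with NaN CI)
    rather than silently zero.
    """
    if not 0 < ci_level < 1:
        raise ValueError(f"ci_level must be in (0, 1), got {ci_level}")
    return ConfusionMetrics(
        sensitivity=_proportion_ci(t.tp, t.tp + t.fn, ci_level),
        specificity=_proportion_ci(t.tn, t.tn + t.fp, ci_level),
        ppv=_proportion_ci(t.tp, t.tp + t.fp, ci_level),
        npv=_proportion_ci(t.tn, t.tn + t.fn, ci_level),
        auc_binary=_binary_auc_ci(t, ci_level),
        table=t,
        ci_level=ci_level,
    )


# --------------------------------------------------------------------------
# ROC / AUC

@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve with DeLong AUC confidence interval."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: Tuple[float, float]
    ci_level: float


def _validate_scores_labels(
    scores: Sequence[float], labels: Sequence[bool]
) -> Tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d sequences of equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    return s, y


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(
    scores: np.ndarray, labels: np.ndarray
) -> Tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components (V10 per positive, V01 per negative)."""
    pos, neg = scores[labels], scores[~labels]
    m, n = len(pos), len(neg)
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks, neg_ranks = _midranks(pos), _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return auc, v10, v01


def auc_delong(
    scores: Sequence[float], labels: Sequence[bool]
) -> Tuple[float, float]:
    """AUC (rank statistic, ties count 1/2) and its DeLong variance."""
    s, y = _validate_scores_labels(scores, labels)
    auc, v10, v01 = _delong_components(s, y)
    var = 0.0
    if len(v10) > 1:
        var += np.var(v10, ddof=1) / len(v10)
    if len(v01) > 1:
        var += np.var(v01, ddof=1) / len(v01)
    return float(auc), float(var)


def roc_curve(
    scores: Sequence[float],
    labels: Sequence[bool],
    ci_level: float = 0.95,
) -> ROCResult:
    """Empirical ROC curve over all distinct thresholds, with DeLong AUC CI.

    The marker is treated as higher-is-positive; the AUC is the
    concordance probability (ties between a positive and a negative
    contribute 1/2).
    """
    s, y = _validate_scores_labels(scores, labels)
    fpr, tpr, thresholds = _sk_roc_curve(y, s, drop_intermediate=False)
    auc, var = auc_delong(s, y)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    se = math.sqrt(var)
    return ROCResult(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        auc_ci=(max(auc - z * se, 0.0), min(auc + z * se, 1.0)),
        ci_level=ci_level,
    )


# --------------------------------------------------------------------------
# Youden cut-off optimisation

@dataclass(frozen=True)
class CutoffResult:
    """An optimal cut-off with its Youden index and operating point."""

    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float


def youden_optimal_cutoff(
    scores: Sequence[float],
    labels: Sequence[bool],
    op: str = "ge",
) -> CutoffResult:
    """Cut-off maximising the Youden index J = sensitivity + specificity − 1.

    Candidate cut-offs are the midpoints between adjacent distinct observed
    scores, plus one candidate below the minimum and one above the maximum.
    Ties on J are broken toward the highest specificity, then the largest
    cut-off (conservative toward false positives).  ``op`` selects whether
    positivity at the cut-off is ``value >= cutoff`` or ``value > cutoff``;
    with midpoint candidates the two give identical operating points.
    """
    if op not in ("ge", "gt"):
        raise ValueError(f"op must be 'ge' or 'gt', got {op!r}")
    s, y = _validate_scores_labels(scores, labels)
    distinct = np.unique(s)
    span = max(distinct[-1] - distinct[0], 1.0)
    candidates = np.concatenate(
        [
            [distinct[0] - 0.5 * span],
            (distinct[:-1] + distinct[1:]) / 2.0,
            [distinct[-1] + 0.5 * span],
        ]
    )
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    positive = (s[None, :] >= candidates[:, None]) if op == "ge" else (
        s[None, :] > candidates[:, None]
    )
    sens = (positive & y[None, :]).sum(axis=1) / n_pos
    spec = ((~positive) & ~y[None, :]).sum(axis=1) / n_neg
    j = sens + spec - 1.0
    best_j = j.max()
    mask = np.isclose(j, best_j, rtol=0, atol=1e-12)
    best_spec = spec[mask].max()
    mask &= np.isclose(spec, best_spec, rtol=0, atol=1e-12)
    idx = np.nonzero(mask)[0][-1]  # candidates ascending -> last = largest cutoff
    return CutoffResult(
        cutoff=float(candidates[idx]),
        youden_j=float(j[idx]),
        sensitivity=float(sens[idx]),
        specificity=float(spec[idx]),
    )


# --------------------------------------------------------------------------
# DeLong test of equality of paired ROC areas

@dataclass(frozen=True)
class AUCComparison:
    """Result of the DeLong test for two paired markers."""

    auc_a: float
    auc_b: float
    z: float
    p_value: float


def compare_auc(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
) -> AUCComparison:
    """Two-sided DeLong test of H0: AUC_a = AUC_b on the same subjects.

    Both markers must be measured on the same subjects (paired design);
    the covariance of the two empirical AUCs is estimated from the DeLong
    structural components.  If the estimated variance of the difference is
    zero the p-value is 1 when the AUCs are equal.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired markers must have equal length")
    _validate_scores_labels(a, np.asarray(labels, dtype=bool))
    y = np.asarray(labels, dtype=bool)
    auc_a, v10_a, v01_a = _delong_components(a, y)
    auc_b, v10_b, v01_b = _delong_components(b, y)
    m, n = len(v10_a), len(v01_a)
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else math.inf * math.copysign(1, diff)
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / math.sqrt(var)
        p = 2.0 * stats.norm.sf(abs(z))
    return AUCComparison(auc_a=float(auc_a), auc_b=float(auc_b), z=float(z), p_value=float(p))


# --------------------------------------------------------------------------
# concordance and dichotomisation

@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement between two binary markers on the same subjects."""

    agree: int
    total: int
    proportion: float
    a_pos_b_neg: int
    a_neg_b_pos: int


def concordance(
    marker_a: Sequence[bool], marker_b: Sequence[bool]
) -> ConcordanceResult:
    """Proportion of subjects on which two binary markers agree."""
    a = np.asarray(marker_a, dtype=bool)
    b = np.asarray(marker_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("markers must be 1-d sequences of equal length")
    if a.size == 0:
        raise ValueError("markers must be non-empty")
    agree = int(np.sum(a == b))
    return ConcordanceResult(
        agree=agree,
        total=int(a.size),
        proportion=agree / a.size,
        a_pos_b_neg=int(np.sum(a & ~b)),
        a_neg_b_pos=int(np.sum(~a & b)),
    )


def binary_marker(
    values: Sequence[float], cutoff: float, op: str = "ge"
) -> np.ndarray:
    """Dichotomise a higher-is-positive marker at a cut-off.

    ``op='ge'`` marks values >= cutoff positive (e.g. kappa index >= 5.8);
    ``op='gt'`` requires strict exceedance (e.g. KFLC IF > 0%).
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("marker values must be finite")
    if op == "ge":
        return v >= cutoff
    if op == "gt":
        return v > cutoff
    raise ValueError(f"op must be 'ge' or 'gt', got {op!r}")
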