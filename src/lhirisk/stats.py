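"""Evaluation statistics: ROC/AUC, Youden cutoffs, 2x2 tests, t tests.

The ROC machinery is written for ordinal risk scores: one operating point
per distinct score value, with the inclusive positive-prediction rule
"predict positive when score >= threshold" used consistently by
:func:`roc_curve`, :func:`sens_spec` and the cutoff selection, matching how
the clinical cutoffs (NIHSS >= 17, CHADS2 >= 4, score >= 2, ...) are stated.

AUC is trapezoidal, which for the step-function empirical ROC equals the
Mann-Whitney concordance probability (ties counted 1/2).  The "best"
cutoff maximizes Youden's J = sensitivity + specificity - 1, ties broken
toward higher sensitivity and then toward the lower threshold.

Tail probabilities come from scipy's chi2/t/hypergeometric distributions;
the statistics themselves are computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as _sps

__all__ = [
    "RocResult",
    "DegenerateInputError",
    "roc_curve",
    "auc_mann_whitney",
    "best_cutoff",
    "sens_spec",
    "pearson_chi2",
    "fisher_exact",
    "two_sample_t",
    "pct",
]


class DegenerateInputError(ValueError):
    """The input admits no informative answer (e.g. one-class labels)."""


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve for an ordinal score.

    ``points`` is an ordered tuple of ``(threshold, sensitivity,
    specificity)`` with thresholds strictly decreasing, starting from a
    sentinel above the maximum score (sensitivity 0, specificity 1) and
    ending at the minimum score (sensitivity 1, specificity 0).
    """

    points: tuple  # of (threshold, sensitivity, specificity)
    auc: float
    best_cutoff: float
    sens_at_best: float
    spec_at_best: float

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([t for t, _, _ in self.points])

    def point_at(self, threshold: float) -> tuple[float, float]:
        """(sensitivity, specificity) of the operating point at ``threshold``."""
        for t, se, sp in self.points:
            if t == threshold:
                return se, sp
        raise KeyError(f"no ROC point at threshold {threshold}")


def _check_labels(labels: np.ndarray) -> None:
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    if labels.min() == labels.max():
        raise DegenerateInputError("need at least one positive and one negative label")


def roc_curve(scores, labels) -> RocResult:
    """Empirical ROC of an ordinal score against a binary label.

    One operating point per distinct score value under the rule "positive
    iff score >= threshold", plus the (0, 1) sentinel.  AUC by trapezoidal
    integration over (1 - specificity, sensitivity); equals the
    Mann-Whitney concordance probability with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1 or len(scores) < 2:
        raise ValueError("scores and labels must be equal-length 1-d, length >= 2")
    _check_labels(labels)

    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    thresholds = np.unique(scores)[::-1]  # distinct scores, decreasing
    points = [(math.inf, 0.0, 1.0)]
    for t in thresholds:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        tn = int((~pred & (labels == 0)).sum())
        points.append((float(t), tp / n_pos, tn / n_neg))

    # trapezoid in ROC space; points are already ordered by increasing FPR
    fpr = np.array([1.0 - sp for _, _, sp in points])
    tpr = np.array([se for _, se, _ in points])
    auc = float(np.trapezoid(tpr, fpr))

    best, se_b, sp_b = _best_point(points)
    return RocResult(tuple(points), auc, best, se_b, sp_b)


def auc_mann_whitney(scores, labels) -> float:
    """AUC as pairwise concordance: P(score+ > score-) + 1/2 P(tie).

    Independent of the trapezoidal route; used as its cross-check.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def _best_point(points) -> tuple[float, float, float]:
    # maximize J; ties -> higher sensitivity, then lower threshold.
    # The +inf sentinel is a valid (degenerate) operating point and only
    # wins when nothing beats J = 0 with sensitivity 0.
    best = None
    for t, se, sp in points:
        j = se + sp - 1.0
        key = (j, se, -t)
        if best is None or key > best[0]:
            best = (key, t, se, sp)
    return best[1], best[2], best[3]


def best_cutoff(roc: RocResult) -> float:
    """Threshold maximizing Youden's J on an existing ROC."""
    t, _, _ = _best_point(roc.points)
    return t


def sens_spec(scores, labels, cutoff: float) -> tuple[float, float]:
    """Sensitivity and specificity at a cutoff (positive iff score >= cutoff)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    pred = scores >= cutoff
    tp = int((pred & (labels == 1)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    fp = int((pred & (labels == 0)).sum())
    return tp / (tp + fn), tn / (tn + fp)


def _as_table(table) -> tuple[int, int, int, int]:
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (arr < 0).any():
        raise ValueError("counts must be nonnegative")
    return int(arr[0, 0]), int(arr[0, 1]), int(arr[1, 0]), int(arr[1, 1])


def _check_margins(a, b, c, d) -> None:
    for m in (a + b, c + d, a + c, b + d):
        if m == 0:
            raise DegenerateInputError("2x2 test undefined with a zero margin")


def pearson_chi2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 table.

    Uncorrected by default: chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)),
    1 df.  ``correction=True`` applies the Yates continuity correction.
    """
    a, b, c, d = _as_table(table)
    _check_margins(a, b, c, d)
    n = a + b + c + d
    num = abs(a * d - b * c)
    if correction:
        num = max(num - n / 2.0, 0.0)
    stat = n * num ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return float(stat), float(_sps.chi2.sf(stat, df=1))


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities not exceeding that of the observed table (with a small
    relative tolerance so ties in probability are included).
    """
    a, b, c, d = _as_table(table)
    _check_margins(a, b, c, d)
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = _sps.hypergeom.pmf(support, n, c1, r1)
    p_obs = pmf[a - lo]
    included = pmf <= p_obs * (1 + 1e-9)
    if included.all():
        return 1.0
    return min(float(pmf[included].sum()), 1.0)


def two_sample_t(xs, ys, welch: bool = False) -> tuple[float, float]:
    """Two-sample t test, pooled-variance Student form by default.

    ``welch=True`` uses the unequal-variance form with Welch-Satterthwaite
    degrees of freedom.  Zero pooled variance: equal means give (0, 1);
    unequal means give a signed infinite statistic with p = 0.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    n1, n2 = len(xs), len(ys)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs at least 2 observations")
    m1, m2 = xs.mean(), ys.mean()
    v1, v2 = xs.var(ddof=1), ys.var(ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
        if se2 == 0:
            return _degenerate_t(m1, m2)
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        stat = (m1 - m2) / math.sqrt(se2)
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        if sp2 == 0:
            return _degenerate_t(m1, m2)
        df = n1 + n2 - 2
        stat = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(stat), float(2.0 * _sps.t.sf(abs(stat), df))


def _degenerate_t(m1: float, m2: float) -> tuple[float, float]:
    if m1 == m2:
        return 0.0, 1.0
    return math.copysign(math.inf, m1 - m2), 0.0


def pct(k: int, n: int, decimals: int = 1) -> float:
    """100*k/n rounded half-up, the reporting convention for percentages."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(100) * Decimal(k) / Decimal(n)).quantize(q, ROUND_HALF_UP))
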