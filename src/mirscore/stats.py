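"""Two-group comparison, rank correlation, ROC construction and Youden cut-points.

Everything here is computed from first principles (midranks, exact
Mann-Whitney enumeration, trapezoid AUC) because these primitives define the
scoring pipeline's behaviour; scipy is used only for reference distributions
(normal, t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, InputError

HIGH = "high_is_positive"
LOW = "low_is_positive"

_DIRECTIONS = (HIGH, LOW)


# ---------------------------------------------------------------------------
# ranking helpers
# ---------------------------------------------------------------------------

def midranks(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with tied values receiving the average of their ranks."""
    x = np.asarray(values, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


# ---------------------------------------------------------------------------
# Mann-Whitney / Wilcoxon rank-sum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoGroupTest:
    """Result of a two-sided Wilcoxon rank-sum comparison.

    ``direction`` is the sign of ``median2 - median1`` when the test is
    significant at the chosen alpha, else ``"none"``.
    """

    statistic_u: float
    p_value: float
    n1: int
    n2: int
    median1: float
    median2: float
    direction: str  # "up" | "down" | "none"


def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution counts of the rank sum of group 1 (no ties).

    Returns counts indexed by U = ranksum - n1(n1+1)/2, U in 0..n1*n2.
    """
    n = n1 + n2
    max_sum = n1 * n2  # after shifting by the minimal rank sum
    # f[k, s]: number of k-subsets of {1..r} with shifted sum s
    f = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    f[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(n1, r), 0, -1):
            # adding rank r to a (k-1)-subset shifts U by r - k
            shift = r - k
            if shift == 0:
                f[k, :] += f[k - 1, :]
            elif shift <= max_sum:
                f[k, shift:] += f[k - 1, : max_sum + 1 - shift]
    return f[n1]


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float], alpha: float = 0.05
) -> TwoGroupTest:
    """Two-sided Wilcoxon rank-sum test, U reported for ``group_a``.

    Exact p by enumeration of the null U distribution when both groups have
    at most 10 observations and there are no ties; otherwise a normal
    approximation with tie correction and continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("mann_whitney_u: both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = midranks(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    if n1 <= 10 and n2 <= 10 and not has_ties:
        counts = _exact_u_counts(n1, n2)
        total = counts.sum()
        u_vals = np.arange(counts.size, dtype=float)
        dev = abs(u1 - mu)
        p = float(counts[np.abs(u_vals - mu) >= dev - 1e-12].sum() / total)
    else:
        n = n1 + n2
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = max(0.0, abs(u1 - mu) - 0.5) / math.sqrt(var)
            p = min(1.0, 2.0 * float(sps.norm.sf(z)))

    med1 = float(np.median(a))
    med2 = float(np.median(b))
    if p < alpha and med2 > med1:
        direction = "up"
    elif p < alpha and med2 < med1:
        direction = "down"
    else:
        direction = "none"
    return TwoGroupTest(
        statistic_u=float(u1),
        p_value=p,
        n1=n1,
        n2=n2,
        median1=med1,
        median2=med2,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Midrank-based Spearman correlation with a t-approximation p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise InputError("spearman_rho: length mismatch")
    if xa.size < 3:
        raise InputError("spearman_rho: need at least 3 observations")
    rx = midranks(xa)
    ry = midranks(ya)
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise DegenerateInputError("spearman_rho: constant input")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    n = xa.size
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = min(1.0, 2.0 * float(sps.t.sf(abs(t), n - 2)))
    return SpearmanResult(rho=rho, p_value=p, n=n)


# ---------------------------------------------------------------------------
# ROC curves and Youden cut-points
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    positive_direction: str


@dataclass(frozen=True)
class CutpointResult:
    marker: str
    cutoff: float
    direction: str
    youden_j: float
    sensitivity: float
    specificity: float
    auc: float

    def to_dict(self) -> dict:
        return {
            "marker": self.marker,
            "cutoff": self.cutoff,
            "direction": self.direction,
            "youden_j": self.youden_j,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
        }


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise DegenerateInputError("both outcome classes must be represented")


def candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct values, plus one sentinel
    below the minimum and one above the maximum.

    With strict-inequality test positivity this guarantees a reported
    cut-off never coincides with an observed value.
    """
    uniq = np.unique(values)
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    return np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])


def roc_curve(
    values: Sequence[float],
    is_positive: Sequence[bool],
    direction: str = HIGH,
) -> RocCurve:
    """ROC over midpoint thresholds; positivity by strict inequality.

    ``high_is_positive``: test-positive iff value > threshold.
    ``low_is_positive``: test-positive iff value < threshold.
    AUC by the trapezoid rule over (1 - specificity, sensitivity).
    """
    if direction not in _DIRECTIONS:
        raise InputError(f"unknown direction {direction!r}")
    v = np.asarray(values, dtype=float)
    y = np.asarray(is_positive, dtype=bool)
    if v.size != y.size:
        raise InputError("roc_curve: length mismatch")
    _check_two_classes(y)

    thr = candidate_thresholds(v)
    pos = np.sort(v[y])
    neg = np.sort(v[~y])
    n_pos, n_neg = pos.size, neg.size
    if direction == HIGH:
        # value > t
        sens = (n_pos - np.searchsorted(pos, thr, side="right")) / n_pos
        spec = np.searchsorted(neg, thr, side="right") / n_neg
    else:
        # value < t
        sens = np.searchsorted(pos, thr, side="left") / n_pos
        spec = (n_neg - np.searchsorted(neg, thr, side="left")) / n_neg

    # integrate along the threshold path, where both coordinates are
    # monotone; |.| absorbs the orientation of the traversal
    fpr = 1.0 - spec
    auc = float(abs(np.trapezoid(sens, fpr)))
    return RocCurve(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        positive_direction=direction,
    )


def youden_cutpoint(
    values: Sequence[float],
    is_positive: Sequence[bool],
    direction: str = HIGH,
    marker: str = "",
) -> CutpointResult:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties on J are broken by higher sensitivity, remaining ties by the lower
    threshold; the ``low_is_positive`` case is solved canonically on the
    negated scale so that direction symmetry holds exactly.
    """
    if direction == LOW:
        flipped = youden_cutpoint(
            -np.asarray(values, dtype=float), is_positive, HIGH, marker
        )
        return CutpointResult(
            marker=marker,
            cutoff=-flipped.cutoff,
            direction=LOW,
            youden_j=flipped.youden_j,
            sensitivity=flipped.sensitivity,
            specificity=flipped.specificity,
            auc=flipped.auc,
        )

    roc = roc_curve(values, is_positive, HIGH)
    j = roc.sensitivity + roc.specificity - 1.0
    # lexsort: last key is primary
    order = np.lexsort((roc.thresholds, -roc.sensitivity, -j))
    best = int(order[0])
    return CutpointResult(
        marker=marker,
        cutoff=float(roc.thresholds[best]),
        direction=HIGH,
        youden_j=float(j[best]),
        sensitivity=float(roc.sensitivity[best]),
        specificity=float(roc.specificity[best]),
        auc=roc.auc,
    )
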