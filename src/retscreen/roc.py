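"""ROC analysis for single scores and for the dual-threshold OR-synergy
envelope of two raters' continuous scores.

The synergy envelope answers: if a patient is called positive whenever
rater A's score exceeds tau_a OR rater B's exceeds tau_b, what is the set of
(FPR, TPR) operating points achievable over all threshold pairs? The
returned frontier is the Pareto-dominant (upper-left) subset of that set,
not its convex hull: every returned point is an operating point a screening
program could actually run at.

Thresholds are the observed unique score values plus +inf, with >= call
semantics; on finite data this grid is lossless. A missing score (an
ungradable patient for that rater) never contributes a positive call;
patients missing both scores are excluded from the synergy curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = ["RocPoint", "RocFrontier", "roc_curve", "synergy_roc", "operating_point"]


class RocPoint(NamedTuple):
    fpr: float
    tpr: float
    threshold_a: float
    threshold_b: float | None = None

    @property
    def sensitivity(self) -> float:
        return self.tpr

    @property
    def specificity(self) -> float:
        return 1.0 - self.fpr


@dataclass(frozen=True)
class RocFrontier:
    """Ordered (FPR, TPR) operating points and the trapezoidal AUC."""

    points: tuple[RocPoint, ...]
    auc: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points, columns=RocPoint._fields)
        return df.astype({"threshold_b": float})

    @property
    def fpr(self) -> np.ndarray:
        return np.array([p.fpr for p in self.points])

    @property
    def tpr(self) -> np.ndarray:
        return np.array([p.tpr for p in self.points])


def _clean_xy(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must be paired")
    keep = ~np.isnan(s)
    s, y = s[keep], y[keep]
    if y.size == 0 or y.all() or not y.any():
        raise ValueError("both classes must be present among scored subjects")
    return s, y


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocFrontier:
    """Standard ROC with thresholds = unique score values plus +inf, call
    positive iff score >= threshold; AUC by the trapezoid rule.

    Missing (NaN) scores are excluded pairwise with their labels.
    """
    s, y = _clean_xy(scores, labels)
    order = np.argsort(-s, kind="mergesort")
    s, y = s[order], y[order]
    P = int(y.sum())
    N = y.size - P
    # indices of the last occurrence of each distinct score (descending)
    last = np.r_[np.nonzero(np.diff(s))[0], y.size - 1]
    tps = np.cumsum(y)[last]
    fps = (last + 1) - tps
    pts = [RocPoint(0.0, 0.0, np.inf)]
    pts += [
        RocPoint(fp / N, tp / P, float(s[i]))
        for i, tp, fp in zip(last, tps, fps)
    ]
    auc = float(np.trapezoid([p.tpr for p in pts], [p.fpr for p in pts]))
    return RocFrontier(points=tuple(pts), auc=auc)


def synergy_roc(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
) -> RocFrontier:
    """Pareto frontier of the OR-combination of two scores over every pair
    of thresholds, each frontier point annotated with one achieving
    (threshold_a, threshold_b) pair.

    The positive call is (score_a >= tau_a) OR (score_b >= tau_b); a missing
    score contributes ``False``. Setting one threshold to +inf recovers the
    other rater's single-score ROC, so the envelope dominates both
    component curves by construction.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("scores and labels must be paired")
    keep = ~(np.isnan(a) & np.isnan(b))
    a, b, y = a[keep], b[keep], y[keep]
    if y.size == 0 or y.all() or not y.any():
        raise ValueError("both classes must be present")
    P = int(y.sum())
    N = y.size - P

    ta = np.r_[np.unique(a[~np.isnan(a)]), np.inf]
    tb = np.r_[np.unique(b[~np.isnan(b)]), np.inf]
    # call matrices: rows = thresholds, cols = subjects (NaN >= t is False)
    with np.errstate(invalid="ignore"):
        A = a[None, :] >= ta[:, None]
        B = b[None, :] >= tb[:, None]

    def or_counts(mask: np.ndarray) -> np.ndarray:
        Am, Bm = A[:, mask], B[:, mask]
        # |A or B| = |A| + |B and not A|
        return Am.sum(axis=1)[:, None] + (~Am).astype(np.int64) @ Bm.T.astype(np.int64)

    tpr = or_counts(y) / P
    fpr = or_counts(~y) / N

    ii, jj = np.unravel_index(np.arange(tpr.size), tpr.shape)
    f, t = fpr.ravel(), tpr.ravel()
    order = np.lexsort((-t, f))  # fpr ascending, tpr descending
    pts: list[RocPoint] = []
    best = -1.0
    for k in order:
        if t[k] > best:
            best = t[k]
            pts.append(RocPoint(float(f[k]), float(t[k]), float(ta[ii[k]]), float(tb[jj[k]])))
    if pts[0].tpr > 0.0 or pts[0].fpr > 0.0:
        pts.insert(0, RocPoint(0.0, 0.0, np.inf, np.inf))
    if pts[-1].tpr < 1.0 or pts[-1].fpr < 1.0:
        pts.append(RocPoint(1.0, 1.0, -np.inf, -np.inf))
    auc = float(np.trapezoid([p.tpr for p in pts], [p.fpr for p in pts]))
    return RocFrontier(points=tuple(pts), auc=auc)


def operating_point(
    frontier: RocFrontier,
    mode: str,
    target: float | None = None,
    prevalence: float | None = None,
) -> RocPoint:
    """Pick a frontier operating point.

    ``match_specificity``: among points with specificity >= target, maximize
    sensitivity. ``match_sensitivity``: among points with sensitivity >=
    target, maximize specificity. ``max_f1``: maximize F1 at the given
    prevalence.
    """
    pts = frontier.points
    if mode == "match_specificity":
        if target is None:
            raise ValueError("target specificity required")
        ok = [p for p in pts if p.specificity >= target]
        if not ok:
            raise ValueError(f"specificity {target} unreachable")
        best = max(ok, key=lambda p: (p.tpr, p.specificity))
        if best.tpr == 0.0:
            warnings.warn(
                f"only the trivial all-negative point reaches specificity {target}",
                stacklevel=2,
            )
        return best
    if mode == "match_sensitivity":
        if target is None:
            raise ValueError("target sensitivity required")
        ok = [p for p in pts if p.tpr >= target]
        if not ok:
            raise ValueError(f"sensitivity {target} unreachable")
        return max(ok, key=lambda p: (p.specificity, p.tpr))
    if mode == "max_f1":
        if prevalence is None or not 0.0 < prevalence < 1.0:
            raise ValueError("prevalence in (0,1) required for max_f1")
        return max(pts, key=lambda p: (_f1_at(p, prevalence), p.specificity))
    raise ValueError(f"unknown mode {mode!r}")


def _f1_at(p: RocPoint, prev: float) -> float:
    pos_calls = prev * p.tpr + (1.0 - prev) * p.fpr
    if pos_calls == 0.0 or p.tpr == 0.0:
        return 0.0
    ppv = prev * p.tpr / pos_calls
    return 2.0 * ppv * p.tpr / (ppv + p.tpr)
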