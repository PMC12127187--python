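"""Independent brute-force oracles used by the tests.

These deliberately re-derive results by naive enumeration, staying
independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np


def pareto_points(points: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Upper-left Pareto subset of (fpr, tpr) points, sorted by fpr."""
    out: list[tuple[float, float]] = []
    best = -1.0
    for f, t in sorted(set(points), key=lambda p: (p[0], -p[1])):
        if t > best:
            out.append((f, t))
            best = t
    return out


def naive_synergy_points(scores_a, scores_b, labels) -> list[tuple[float, float]]:
    """All (fpr, tpr) points achievable by OR-combining two scores over
    every pair of thresholds (unique values plus +inf); plain loops."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    keep = ~(np.isnan(a) & np.isnan(b))
    a, b, y = a[keep], b[keep], y[keep]
    taus_a = sorted(set(a[~np.isnan(a)])) + [np.inf]
    taus_b = sorted(set(b[~np.isnan(b)])) + [np.inf]
    P = int(y.sum())
    N = int((~y).sum())
    pts = []
    for ta in taus_a:
        for tb in taus_b:
            pred = np.zeros(y.size, dtype=bool)
            for i in range(y.size):
                pa = (not np.isnan(a[i])) and a[i] >= ta
                pb = (not np.isnan(b[i])) and b[i] >= tb
                pred[i] = pa or pb
            tp = int((pred & y).sum())
            fp = int((pred & ~y).sum())
            pts.append((fp / N, tp / P))
    return pts


def naive_f1_threshold(scores, labels) -> float:
    """Best F1 threshold by full enumeration; ties toward the largest."""
    best_tau, best_f1 = None, -1.0
    ys = list(labels)
    for tau in sorted(set(scores)):
        tp = sum(1 for s, y in zip(scores, ys) if y and s >= tau)
        fp = sum(1 for s, y in zip(scores, ys) if not y and s >= tau)
        fn = sum(ys) - tp
        f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
        if f1 > best_f1 or (f1 == best_f1 and (best_tau is None or tau > best_tau)):
            best_tau, best_f1 = tau, f1
    return best_tau


def naive_auc_concordance(scores, labels) -> float:
    """AUC as the Mann-Whitney concordance fraction (ties count half)."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))
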