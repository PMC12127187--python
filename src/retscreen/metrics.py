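"""Confusion-matrix metrics, agreement coefficients and bootstrap inference.

The module also houses the integer reconstruction oracle
(:func:`reconstruct_counts`): given a panel of rounded percentage metrics
printed for several raters who share the same ground truth, it brute-forces
the unique 2x2 integer confusion matrices consistent with every printed
value. Published diagnostic-accuracy tables rarely ship their underlying
counts; when the printed precision pins the counts down uniquely, the
reconstruction turns a table of percentages into exact integer fixtures.

All percentage matching uses round-half-up to one decimal, implemented in
exact integer arithmetic so no floating-point edge case can flip a match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "BootstrapResult",
    "ReconstructionError",
    "confusion",
    "metric_set",
    "cohen_kappa",
    "percent_agreement",
    "bootstrap_metric",
    "paired_bootstrap_pvalue",
    "reconstruct_counts",
    "reconstruct_tier_counts",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 classification counts: tp, fp, fn, tn."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def positives(self) -> int:
        """Condition-positive count (tp + fn)."""
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn

    @property
    def prevalence(self) -> float:
        return self.positives / self.total


@dataclass(frozen=True)
class MetricSet:
    """Accuracy / sensitivity / specificity / PPV / F1; ``None`` when the
    denominator is zero (undefined, never silently 0)."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    f1: float | None

    def as_percent(self, ndigits: int = 1) -> dict[str, float | None]:
        return {
            k: (None if v is None else round_half_up(100.0 * v, ndigits))
            for k, v in self.__dict__.items()
        }


@dataclass(frozen=True)
class BootstrapResult:
    point: float
    ci_low: float
    ci_high: float
    p_value: float | None
    n_boot: int
    seed: int


def confusion(pred: Sequence[bool], truth: Sequence[bool]) -> ConfusionMatrix:
    p = np.asarray(pred)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.dtype == object or t.dtype == object:
        raise ValueError("undetermined entries are not allowed in confusion()")
    p = p.astype(bool)
    t = t.astype(bool)
    return ConfusionMatrix(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
        tn=int((~p & ~t).sum()),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metric_set(cm: ConfusionMatrix) -> MetricSet:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return MetricSet(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        f1=_ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn),
    )


def cohen_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement for a 2x2 table.

    kappa = (po - pe) / (1 - pe), where po is observed agreement and pe the
    expected agreement from the marginal products. The table is symmetric in
    the two raters, so either rater may sit on the "truth" axis.
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty table")
    po = (cm.tp + cm.tn) / n
    pe = ((cm.tp + cm.fp) * (cm.tp + cm.fn) + (cm.fn + cm.tn) * (cm.fp + cm.tn)) / (n * n)
    if pe == 1.0:
        raise ValueError("kappa undefined: expected agreement is 1")
    return (po - pe) / (1.0 - pe)


def percent_agreement(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty table")
    return (cm.tp + cm.tn) / cm.total


# ---------------------------------------------------------------------------
# bootstrap inference
# ---------------------------------------------------------------------------

def _vec_metric(name: str) -> Callable[..., np.ndarray]:
    def f(tp, fp, fn, tn):
        with np.errstate(invalid="ignore", divide="ignore"):
            if name == "accuracy":
                return (tp + tn) / (tp + fp + fn + tn)
            if name == "sensitivity":
                return np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), np.nan)
            if name == "specificity":
                return np.where(tn + fp > 0, tn / np.maximum(tn + fp, 1), np.nan)
            if name == "ppv":
                return np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.nan)
            if name == "f1":
                den = 2 * tp + fp + fn
                return np.where(den > 0, 2 * tp / np.maximum(den, 1), np.nan)
        raise KeyError(name)

    return f

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "ppv", "f1")


def _counts(pred: np.ndarray, truth: np.ndarray):
    tp = (pred & truth).sum(axis=-1)
    fp = (pred & ~truth).sum(axis=-1)
    fn = (~pred & truth).sum(axis=-1)
    tn = (~pred & ~truth).sum(axis=-1)
    return tp, fp, fn, tn


def bootstrap_metric(
    pred: Sequence[bool],
    truth: Sequence[bool],
    metric: str = "sensitivity",
    n_boot: int = 2000,
    seed: int = 0,
) -> BootstrapResult:
    """Percentile 95% CI for a confusion-matrix metric by resampling
    subjects with replacement. Deterministic under ``seed``."""
    if metric not in METRIC_NAMES:
        raise KeyError(f"unknown metric {metric!r}")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    p = np.asarray(pred, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if p.size == 0:
        raise ValueError("empty data")
    if p.shape != t.shape:
        raise ValueError("length mismatch")
    f = _vec_metric(metric)
    point = f(*(np.array([v]) for v in _counts(p, t)))[0]
    if np.isnan(point):
        raise ValueError(f"{metric} undefined on the full data")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, p.size, size=(n_boot, p.size))
    vals = f(*_counts(p[idx], t[idx]))
    bad = np.isnan(vals).mean()
    if bad > 0.5:
        raise ValueError(f"{metric} undefined in {bad:.0%} of resamples")
    lo, hi = np.nanpercentile(vals, [2.5, 97.5])
    return BootstrapResult(float(point), float(lo), float(hi), None, n_boot, seed)


def paired_bootstrap_pvalue(
    pred_a: Sequence[bool],
    pred_b: Sequence[bool],
    truth: Sequence[bool],
    metric: str = "sensitivity",
    n_boot: int = 2000,
    seed: int = 0,
) -> float:
    """Two-sided bootstrap p-value for the metric difference of two raters
    observed on the same subjects.

    Subjects are resampled jointly so the raters' sampling variation stays
    paired. p = 2 * min(frac(delta* <= 0), frac(delta* >= 0)); tie mass at
    zero counts on both sides, and the value is clipped below at 1/n_boot.
    """
    if metric not in METRIC_NAMES:
        raise KeyError(f"unknown metric {metric!r}")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    a = np.asarray(pred_a, dtype=bool)
    b = np.asarray(pred_b, dtype=bool)
    t = np.asarray(truth, dtype=bool)
    if not (a.shape == b.shape == t.shape) or a.size == 0:
        raise ValueError("raters must share non-empty paired data")
    f = _vec_metric(metric)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.size, size=(n_boot, a.size))
    ti = t[idx]
    da = f(*_counts(a[idx], ti)) - f(*_counts(b[idx], ti))
    da = da[~np.isnan(da)]
    if da.size < n_boot / 2:
        raise ValueError(f"{metric} difference undefined in most resamples")
    p = 2.0 * min((da <= 0).mean(), (da >= 0).mean())
    return float(min(max(p, 1.0 / n_boot), 1.0))


# ---------------------------------------------------------------------------
# integer reconstruction oracle
# ---------------------------------------------------------------------------

class ReconstructionError(ValueError):
    """No consistent integer table, or the solution is ambiguous."""


def _matches(num: int, den: int, d10: int) -> bool:
    # round-half-up of 1000*num/den (tenths of a percent) equals d10,
    # in exact integer arithmetic
    if den <= 0:
        return False
    return 2 * den * d10 <= 2000 * num + den < 2 * den * (d10 + 1)


def _candidates(den: int, d10: int) -> list[int]:
    """Integers k in [0, den] whose percentage k/den prints as d10/10."""
    lo = -((-den * (2 * d10 - 1)) // 2000)
    hi = (den * (2 * d10 + 1) - 1) // 2000
    return [k for k in range(max(lo, 0), min(hi, den) + 1) if _matches(k, den, d10)]


def _d10(value: float) -> int:
    d = int(round(value * 10))
    if not math.isclose(d, value * 10, abs_tol=1e-6):
        raise ValueError(f"printed value {value} is not given to one decimal")
    return d


def reconstruct_counts(
    printed: Mapping[str, Mapping[str, float]],
    n: int,
    unique: bool = True,
) -> tuple[int, dict[str, ConfusionMatrix]] | list[tuple[int, dict[str, list[ConfusionMatrix]]]]:
    """Brute-force the integer confusion matrices behind a printed panel.

    Parameters
    ----------
    printed
        ``{rater: {metric: percent}}`` with percents given to one decimal;
        metrics among accuracy/sensitivity/specificity/ppv/f1. All raters
        share one ground truth, hence one condition-positive count P.
    n
        Total number of subjects in the panel.
    unique
        When true (default), assert a single consistent solution and return
        ``(P, {rater: ConfusionMatrix})``; raise :class:`ReconstructionError`
        otherwise. When false, return the full solution set.

    The search enumerates P = 1..n-1 and, per rater, all (tp, tn) cells whose
    metrics round (half-up, one decimal) to every printed value.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    panels: list[tuple[int, dict[str, list[ConfusionMatrix]]]] = []
    digits = {
        r: {m: _d10(v) for m, v in mets.items()} for r, mets in printed.items()
    }
    for mets in digits.values():
        for m in mets:
            if m not in METRIC_NAMES:
                raise KeyError(f"unknown metric {m!r}")
    for P in range(1, n):
        N = n - P
        per: dict[str, list[ConfusionMatrix]] = {}
        ok = True
        for rater, d in digits.items():
            tps: Iterable[int] = (
                _candidates(P, d["sensitivity"]) if "sensitivity" in d else range(P + 1)
            )
            tns: Iterable[int] = (
                _candidates(N, d["specificity"]) if "specificity" in d else range(N + 1)
            )
            tns = list(tns)
            sols = []
            for tp in tps:
                fn = P - tp
                for tn in tns:
                    fp = N - tn
                    if "accuracy" in d and not _matches(tp + tn, n, d["accuracy"]):
                        continue
                    if "ppv" in d and not _matches(tp, tp + fp, d["ppv"]):
                        continue
                    if "f1" in d and not _matches(2 * tp, 2 * tp + fp + fn, d["f1"]):
                        continue
                    sols.append(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
            if not sols:
                ok = False
                break
            per[rater] = sols
        if ok:
            panels.append((P, per))
    if not unique:
        return panels
    if not panels:
        raise ReconstructionError("no integer table is consistent with the printed panel")
    if len(panels) > 1 or any(len(s) > 1 for s in panels[0][1].values()):
        raise ReconstructionError(
            f"ambiguous reconstruction: {len(panels)} positive-count candidates "
            f"{[p for p, _ in panels]}"
        )
    P, per = panels[0]
    return P, {r: s[0] for r, s in per.items()}


def reconstruct_tier_counts(
    n_positives: int,
    sens_medium_plus: Mapping[str, float],
    sens_high: Mapping[str, float],
    unique: bool = True,
) -> tuple[int, int, int] | list[tuple[int, int, int]]:
    """Recover (n_mild, n_medium, n_high) from printed tier-restricted
    sensitivities of raters sharing the truth.

    For each candidate split, every rater must admit tier-level true-positive
    counts that round to the printed sensitivities and are consistent with
    each other (true positives in the high tier cannot exceed those in the
    medium-or-higher tier).
    """
    out = []
    dm = {r: _d10(v) for r, v in sens_medium_plus.items()}
    dh = {r: _d10(v) for r, v in sens_high.items()}
    raters = set(dm) | set(dh)
    for m in range(1, n_positives):          # medium-or-higher count
        cm_ = {r: _candidates(m, d) for r, d in dm.items()}
        if any(not c for c in cm_.values()):
            continue
        for h in range(1, m + 1):            # high count
            ch = {r: _candidates(h, d) for r, d in dh.items()}
            if any(not c for c in ch.values()):
                continue
            feasible = all(
                any(
                    th <= tm
                    for th in ch.get(r, [0])
                    for tm in cm_.get(r, [m])
                )
                for r in raters
            )
            if feasible:
                out.append((n_positives - m, m - h, h))
    if not unique:
        return out
    if len(out) != 1:
        raise ReconstructionError(
            f"tier reconstruction not unique: {len(out)} candidates {out}"
        )
    return out[0]
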