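"""Continuous-measurement agreement between CDR raters.

Error statistics (MAE, relative error), Pearson correlation, and
Bland–Altman analysis (mean bias and 95% limits of agreement) of paired
CDR estimates against a reference, plus pairwise-complete correlation
matrices across any number of raters.

Differences are oriented estimate - reference, so a negative bias means
the rater underestimates relative to the reference. Relative error uses
the reference value as denominator. Limits of agreement use the
conventional fixed 1.96 multiplier on the SD of the differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AgreementSummary", "agreement", "correlation_matrix", "bland_altman_frame"]


@dataclass(frozen=True)
class AgreementSummary:
    """Paired agreement of one rater against a reference."""

    mae: float
    mae_sd: float
    relative_error_mean: float   # percent
    relative_error_sd: float     # percent
    pearson_r: float | None      # None when either input has zero variance
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n_pairs: int


def agreement(
    estimates: Sequence[float],
    reference: Sequence[float],
    relative_to: str = "reference",
) -> AgreementSummary:
    """Summarize agreement of paired estimates with a reference.

    ``relative_to`` selects the relative-error denominator: ``"reference"``
    (default) or ``"mean"`` of each pair.
    """
    e = np.asarray(estimates, dtype=float)
    g = np.asarray(reference, dtype=float)
    if e.shape != g.shape:
        raise ValueError("estimates and reference must be paired")
    if np.isnan(e).any() or np.isnan(g).any():
        raise ValueError("inputs must be complete (drop missing pairs first)")
    n = e.size
    if n < 2:
        raise ValueError("at least 2 pairs required")
    if relative_to == "reference":
        denom = g
    elif relative_to == "mean":
        denom = (e + g) / 2.0
    else:
        raise ValueError("relative_to must be 'reference' or 'mean'")
    if (denom <= 0).any():
        raise ValueError("relative-error denominator must be positive")
    d = e - g
    ad = np.abs(d)
    rel = ad / denom * 100.0
    sd_diff = float(np.std(d, ddof=1))
    bias = float(d.mean())
    if np.std(e) == 0.0 or np.std(g) == 0.0:
        r = None
    else:
        r = float(stats.pearsonr(e, g).statistic)
    return AgreementSummary(
        mae=float(ad.mean()),
        mae_sd=float(np.std(ad, ddof=1)),
        relative_error_mean=float(rel.mean()),
        relative_error_sd=float(np.std(rel, ddof=1)),
        pearson_r=r,
        bias=bias,
        sd_diff=sd_diff,
        loa_low=bias - 1.96 * sd_diff,
        loa_high=bias + 1.96 * sd_diff,
        n_pairs=int(n),
    )


def correlation_matrix(
    raters: Mapping[str, Sequence[float]] | pd.DataFrame,
    min_pairs: int = 2,
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between named CDR vectors.

    Cells with fewer than ``min_pairs`` complete pairs are NaN; the
    diagonal is 1 for any rater with at least one observation.
    """
    df = raters if isinstance(raters, pd.DataFrame) else pd.DataFrame(dict(raters))
    corr = df.corr(method="pearson", min_periods=max(min_pairs, 2))
    for name in corr.columns:
        if df[name].notna().any():
            corr.loc[name, name] = 1.0
    return corr


def bland_altman_frame(
    estimates: Sequence[float], reference: Sequence[float]
) -> pd.DataFrame:
    """Per-pair (mean, difference) table backing a Bland–Altman plot."""
    e = np.asarray(estimates, dtype=float)
    g = np.asarray(reference, dtype=float)
    if e.shape != g.shape:
        raise ValueError("estimates and reference must be paired")
    return pd.DataFrame({"mean": (e + g) / 2.0, "difference": e - g})
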