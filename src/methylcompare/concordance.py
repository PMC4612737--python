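"""Binned concordance curves, rank correlation and chance-corrected agreement.

The concordance curve bins one platform's quantitative values (array
beta-values) into equidistant bins over [0, 1] and averages the other
platform's response (binary capture call, or a continuous methylation
degree) per bin, optionally stratified by assay chemistry.  An almost
linear rise of capture fraction with beta indicates concordance; the curves
differ by chemistry because capture efficiency tracks local CpG density.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

__all__ = ["bin_concordance", "spearman_rho", "cohens_kappa"]


def bin_concordance(
    x: Sequence[float],
    y: Sequence[float],
    n_bins: int,
    strata: Sequence | None = None,
) -> pd.DataFrame:
    """Mean of ``y`` per equidistant bin of ``x`` over [0, 1].

    Bins are half-open ``[lo, hi)`` with the final bin closed so x = 1.0 is
    countable.  Pairs with a missing value in either vector are dropped.
    Returns one row per (stratum, bin) with columns ``stratum``, ``bin``,
    ``lo``, ``hi``, ``count``, ``mean`` (NaN for empty bins).
    """
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    strata_arr = (
        np.zeros(len(x), dtype=int) if strata is None else np.asarray(strata)
    )
    keep = ~(np.isnan(x) | np.isnan(y))
    if ((x[keep] < 0) | (x[keep] > 1)).any():
        raise ValidationError("x values outside [0, 1]")
    x, y, strata_arr = x[keep], y[keep], strata_arr[keep]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.minimum((x * n_bins).astype(int), n_bins - 1)  # closed last bin
    rows = []
    for stratum in np.unique(strata_arr):
        mask = strata_arr == stratum
        counts = np.bincount(idx[mask], minlength=n_bins)
        sums = np.bincount(idx[mask], weights=y[mask], minlength=n_bins)
        with np.errstate(invalid="ignore"):
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        for b in range(n_bins):
            rows.append((stratum, b, edges[b], edges[b + 1], int(counts[b]), means[b]))
    return pd.DataFrame(rows, columns=["stratum", "bin", "lo", "hi", "count", "mean"])


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided P."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) == 0:
        raise ValidationError("x and y must be nonempty and equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def cohens_kappa(calls_a: Sequence[int], calls_b: Sequence[int]) -> float:
    """Cohen's kappa for two binary raters: (p_o - p_e) / (1 - p_e)."""
    a = np.asarray(calls_a, dtype=float)
    b = np.asarray(calls_b, dtype=float)
    if a.shape != b.shape or len(a) == 0:
        raise ValidationError("call vectors must be nonempty and equal length")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValidationError("missing values not allowed; drop them first")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValidationError("calls must be binary")
    n = len(a)
    p_o = float((a == b).mean())
    p1a, p1b = a.mean(), b.mean()
    p_e = p1a * p1b + (1 - p1a) * (1 - p1b)
    if p_e >= 1.0:
        raise ValidationError("kappa undefined: both raters constant")
    return float((p_o - p_e) / (1.0 - p_e))
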