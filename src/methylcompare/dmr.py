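"""Differential-methylation testing on dichotomized calls.

Per-locus 2x2 tables (group x call) are tested with the two-sided Fisher
exact test; multiplicity is handled by a permutation-derived false discovery
rate tailored to the discreteness of Fisher P-values: one label permutation
per locus yields a null P-value multiset with the same per-locus methylation
frequencies, and for the i-th smallest observed P-value

    FDR_i = #{null P <= P_(i)} / i.

This assumes every locus is null (conservative) and ignores dependence
between loci.  Constant loci (all-methylated or all-unmethylated across
samples) carry no contrast and are removed first.

The module also provides the binomial detection criterion (how many of n
samples must show capture signal to beat a background detection rate) and
candidate-DMR (cDMR) coverage/detection summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import IntervalSet, ProbeManifest, ValidationError

__all__ = [
    "DMRTable",
    "filter_constant_loci",
    "fisher_p",
    "fisher_tests",
    "permutation_null",
    "permutation_fdr",
    "min_detection_count",
    "cdmr_detection",
    "cdmr_probe_coverage",
]

# relative tolerance when comparing table probabilities to the observed
# table's probability (two-sided point-probability method); guards against
# float noise excluding tables of identical probability
_REL_TOL = 1.0 + 1e-7


@lru_cache(maxsize=200_000)
def fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact P for the 2x2 table [[a, b], [c, d]].

    Point-probability method: sum of hypergeometric probabilities of all
    tables with the observed margins whose probability does not exceed the
    observed table's.
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("negative cell count")
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c
    kmin = max(0, r1 + c1 - n)
    kmax = min(r1, c1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - kmin]
    return float(min(1.0, pmf[pmf <= p_obs * _REL_TOL].sum()))


def filter_constant_loci(calls: pd.DataFrame) -> pd.Index:
    """Indices of loci with at least one 0 and one 1 among non-missing calls."""
    vals = calls.to_numpy(dtype=float)
    has_one = np.nansum(vals == 1, axis=1) > 0
    has_zero = np.nansum(vals == 0, axis=1) > 0
    return calls.index[has_one & has_zero]


def _group_tables(vals: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Per-locus 2x2 tables (a, b, c, d) = (g1+, g1-, g0+, g0-); NaN dropped."""
    g1 = groups == 1
    g0 = ~g1
    pos = vals == 1
    neg = vals == 0
    a = (pos[:, g1]).sum(axis=1)
    b = (neg[:, g1]).sum(axis=1)
    c = (pos[:, g0]).sum(axis=1)
    d = (neg[:, g0]).sum(axis=1)
    return np.stack([a, b, c, d], axis=1)


def fisher_tests(calls: pd.DataFrame, groups: Sequence[int]) -> pd.Series:
    """Two-sided Fisher exact P per locus for group x call association.

    ``groups`` is a binary label per sample (column).  Missing calls are
    dropped per locus; a locus whose non-missing calls are confined to one
    group gets a missing P.
    """
    groups = np.asarray(groups)
    if len(groups) != calls.shape[1]:
        raise ValidationError("one group label per sample required")
    if len(np.unique(groups)) != 2:
        raise ValidationError("exactly two groups required")
    groups = (groups == np.max(groups)).astype(int)
    vals = calls.to_numpy(dtype=float)
    tables = _group_tables(vals, groups)
    out = np.empty(len(tables))
    for i, (a, b, c, d) in enumerate(tables):
        if (a + b == 0) or (c + d == 0):
            out[i] = np.nan
        else:
            out[i] = fisher_p(int(a), int(b), int(c), int(d))
    return pd.Series(out, index=calls.index, name="fisher_p")


def permutation_null(
    calls: pd.DataFrame, groups: Sequence[int], seed: int, n_rounds: int = 1
) -> pd.Series:
    """Null Fisher P-values from per-locus label permutations.

    Permuting group labels locus-by-locus preserves each locus's average
    methylation frequency exactly while destroying any group association.
    The default is one permutation per locus, the literal procedure; with a
    single null per locus the FDR at the very smallest observed P is
    unstable (the global minimum lands on the observed side with
    probability ~1/2), so ``n_rounds`` > 1 pools that many independent
    permutation rounds — ``permutation_fdr`` renormalizes by the
    null/observed cardinality ratio.
    """
    if n_rounds < 1:
        raise ValidationError("n_rounds must be >= 1")
    groups = np.asarray(groups)
    groups = (groups == np.max(groups)).astype(int)
    rng = np.random.default_rng(seed)
    vals = calls.to_numpy(dtype=float)
    n_samples = vals.shape[1]
    out = np.empty(len(vals) * n_rounds)
    for r in range(n_rounds):
        for i in range(len(vals)):
            perm = groups[rng.permutation(n_samples)]
            row = vals[i : i + 1]
            a, b, c, d = _group_tables(row, perm)[0]
            if (a + b == 0) or (c + d == 0):
                out[r * len(vals) + i] = np.nan
            else:
                out[r * len(vals) + i] = fisher_p(int(a), int(b), int(c), int(d))
    return pd.Series(
        out, index=list(calls.index) * n_rounds, name="null_p"
    )


@dataclass(frozen=True)
class DMRTable:
    """Observed P-values with permutation-FDR, sorted ascending by P.

    ``table`` columns: ``locus``, ``p``, ``rank`` (1-based), ``fdr``,
    ``significant``.  ``n_significant`` is the size of the flagged set at
    level q (ties at the cut P-value are all flagged).
    """

    table: pd.DataFrame
    q: float
    n_significant: int

    @property
    def significant_loci(self) -> pd.Index:
        return pd.Index(self.table.loc[self.table["significant"], "locus"])


def permutation_fdr(observed: pd.Series, null: pd.Series, q: float = 0.05) -> DMRTable:
    """FDR_i = #{null <= P_(i)} / i on the ascending observed P-values.

    The significance cut is the largest rank i with FDR_i <= q; every locus
    with P at or below that rank's P-value is flagged.  When the null
    multiset holds R values per observed locus (pooled permutation rounds)
    the count is divided by R.
    """
    obs = observed.dropna()
    nul = np.sort(null.dropna().to_numpy())
    if len(obs) == 0 or len(nul) == 0:
        raise ValidationError("observed and null P-values must be nonempty")
    scale = len(nul) / len(obs)
    order = np.argsort(obs.to_numpy(), kind="mergesort")
    p_sorted = obs.to_numpy()[order]
    loci = obs.index.to_numpy()[order]
    ranks = np.arange(1, len(p_sorted) + 1)
    n_null_le = np.searchsorted(nul, p_sorted, side="right")
    fdr = n_null_le / (scale * ranks)
    ok = np.nonzero(fdr <= q)[0]
    if len(ok):
        cut_p = p_sorted[ok[-1]]
        significant = p_sorted <= cut_p
    else:
        significant = np.zeros(len(p_sorted), dtype=bool)
    df = pd.DataFrame(
        {
            "locus": loci,
            "p": p_sorted,
            "rank": ranks,
            "fdr": fdr,
            "significant": significant,
        }
    )
    return DMRTable(table=df, q=q, n_significant=int(significant.sum()))


def min_detection_count(n: int, p0: float, alpha: float = 0.05) -> int:
    """Smallest k with P(X >= k) < alpha for X ~ Binomial(n, p0).

    A locus detected in at least this many of n samples has a detection
    rate significantly above the background (non-specific) rate p0.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not 0 < p0 < 1 or not 0 < alpha < 1:
        raise ValidationError("p0 and alpha must be in (0, 1)")
    for k in range(n + 1):
        if stats.binom.sf(k - 1, n, p0) < alpha:
            return k
    raise ValidationError(f"no k <= n={n} reaches significance at alpha={alpha}")


def _contained_counts(
    intervals: pd.DataFrame, positions: np.ndarray, values: np.ndarray
) -> list[np.ndarray]:
    """Per interval, the values at positions it contains (half-open)."""
    order = np.argsort(positions, kind="mergesort")
    pos, val = positions[order], values[order]
    out = []
    for _, row in intervals.iterrows():
        lo = np.searchsorted(pos, row["start"], side="left")
        hi = np.searchsorted(pos, row["end"] - 1, side="right")
        out.append(val[lo:hi])
    return out


def cdmr_detection(
    cdmrs: IntervalSet,
    cpg_table: pd.DataFrame,
    k: int,
    mode: str = "any",
) -> tuple[int, float, int]:
    """Fraction of candidate DMRs with significant methylation signal.

    ``cpg_table`` columns: ``seq``, ``pos``, ``count`` (number of samples in
    which that CpG was captured).  A CpG is significantly methylated when
    its count >= k (see ``min_detection_count``).  A cDMR is detected when
    at least one contained CpG qualifies (``mode="any"``) or at least half
    of them do, ceil(n/2) (``mode="half"``).  Returns (n_detected, fraction
    of cDMRs with >= 1 contained CpG, n_without_cpgs).
    """
    if mode not in ("any", "half"):
        raise ValidationError("mode must be 'any' or 'half'")
    detected = 0
    with_cpg = 0
    empty = 0
    for seq, ivs in cdmrs.table.groupby("seq", sort=False):
        sub = cpg_table[cpg_table["seq"] == seq]
        per_iv = _contained_counts(
            ivs, sub["pos"].to_numpy(), sub["count"].to_numpy()
        )
        for counts in per_iv:
            if len(counts) == 0:
                empty += 1
                continue
            with_cpg += 1
            n_sig = int((counts >= k).sum())
            need = 1 if mode == "any" else -(-len(counts) // 2)
            if n_sig >= need:
                detected += 1
    if with_cpg == 0:
        raise ValidationError("no cDMR contains a CpG")
    return detected, detected / with_cpg, empty


def cdmr_probe_coverage(cdmrs: IntervalSet, probes: ProbeManifest) -> float:
    """Fraction of cDMR intervals containing at least one probe position."""
    if len(cdmrs) == 0:
        raise ValidationError("empty cDMR set")
    covered = 0
    for seq, ivs in cdmrs.table.groupby("seq", sort=False):
        pos = np.sort(probes.table.loc[probes.table["seq"] == seq, "pos"].to_numpy())
        for _, row in ivs.iterrows():
            lo = np.searchsorted(pos, row["start"], side="left")
            hi = np.searchsorted(pos, row["end"] - 1, side="right")
            if hi > lo:
                covered += 1
    return covered / len(cdmrs)
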