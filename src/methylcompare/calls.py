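"""Dichotomization: turn each platform's quantitative signal into binary
presence/absence-of-methylation calls.

Array side: a locus is called methylated when its beta-value is at or above
the chosen threshold (0.2 / 0.3 / 0.4 are the standard grid), and masked as
missing when the detection P-value exceeds the significance level (default
0.05).  Capture side: a locus is called methylated when at least one
deduplicated fragment covers its position.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .io import BetaMatrix, FragmentSet, ProbeManifest, ValidationError

__all__ = [
    "call_from_beta",
    "coverage_at_loci",
    "call_from_coverage",
    "m_value",
    "exclude_low_depth",
]


def call_from_beta(
    beta: BetaMatrix, threshold: float, detection_alpha: float = 0.05
) -> pd.DataFrame:
    """Binary calls from beta-values: 1 iff beta >= threshold.

    Cells whose detection P-value exceeds ``detection_alpha`` (unreliable
    measurements) become missing, as do cells missing in the source.  The
    boundary is inclusive: beta exactly at the threshold is called
    methylated.
    """
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"threshold {threshold} outside (0, 1)")
    if not 0.0 < detection_alpha < 1.0:
        raise ValidationError(f"detection_alpha {detection_alpha} outside (0, 1)")
    b = beta.beta.to_numpy(dtype=float)
    p = beta.detp.to_numpy(dtype=float)
    calls = (b >= threshold).astype(float)
    calls[np.isnan(b) | np.isnan(p) | (p > detection_alpha)] = np.nan
    return pd.DataFrame(calls, index=beta.beta.index, columns=beta.beta.columns)


def coverage_at_loci(
    frags: FragmentSet, loci: ProbeManifest, window: int = 0
) -> np.ndarray:
    """Fragment coverage at each probe's CpG position, in manifest order.

    A fragment ``[start, end)`` covers position ``p`` iff
    ``start <= p < end`` (half-open containment).  ``window`` widens the
    query to ``[p - window, p + window]`` for users who prefer a probe
    window over the single CpG coordinate.
    """
    counts = np.zeros(len(loci), dtype=np.int64)
    frag_by_seq = dict(tuple(frags.fragments.groupby("seq", sort=False)))
    for seq, probes in loci.table.groupby("seq", sort=False):
        sub = frag_by_seq.get(seq)
        if sub is None or not len(sub):
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        pos = probes["pos"].to_numpy()
        # fragments with start <= p+window, minus fragments with end <= p-window
        n_started = np.searchsorted(starts, pos + window, side="right")
        n_ended = np.searchsorted(ends, pos - window, side="right")
        counts[probes.index.to_numpy()] = n_started - n_ended
    return counts


def call_from_coverage(cov: np.ndarray) -> np.ndarray:
    """One sample's capture calls: methylated iff >= 1 covering fragment."""
    cov = np.asarray(cov)
    if (cov < 0).any():
        raise ValidationError("negative fragment count")
    return (cov >= 1).astype(float)


def m_value(beta, epsilon: float = 0.0):
    """logit2 transform of beta: log2((beta+eps) / (1-beta+eps)).

    M-values are the scale of choice for differential tests on array
    methylation.  With ``epsilon=0`` betas are clamped to
    [1e-6, 1 - 1e-6] to avoid infinities at the boundaries.
    """
    b = np.asarray(beta, dtype=float)
    if np.nanmin(b, initial=0.0) < 0 or np.nanmax(b, initial=1.0) > 1:
        raise ValidationError("beta values outside [0, 1]")
    if epsilon == 0.0:
        b = np.clip(b, 1e-6, 1.0 - 1e-6)
    out = np.log2((b + epsilon) / (1.0 - b + epsilon))
    return float(out) if np.isscalar(beta) else out


def exclude_low_depth(
    sample_totals: Mapping[str, int], min_fragments: int = 2_000_000
) -> tuple[list[str], list[str]]:
    """Split samples into (retained, excluded) by total mapped fragments.

    Samples below ``min_fragments`` (default 2 million, the usual floor for
    a usable capture-sequencing library) are excluded from estimation.
    """
    retained = [s for s, t in sample_totals.items() if t >= min_fragments]
    excluded = [s for s, t in sample_totals.items() if t < min_fragments]
    return retained, excluded
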