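"""Global group-difference testing by ordination of binary call profiles.

Samples are compared by the Jaccard distance between their sets of
methylated loci, embedded with principal coordinate analysis (classical
MDS), and the tumour/control contrast is tested by a Monte-Carlo
permutation test on the between-group inertia of the ordination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = ["PCOResult", "jaccard_distances", "pco", "between_group_test"]


def jaccard_distances(calls: pd.DataFrame, sqrt: bool = True) -> pd.DataFrame:
    """Pairwise Jaccard distances between sample columns.

    Similarity s = a / (a + b + c) with a the both-methylated count and
    b, c the discordant counts; loci missing in either member of a pair are
    dropped pairwise.  Distance is sqrt(1 - s) by default (the Euclidean-
    embeddable form, so the ordination has no negative eigenvalues);
    ``sqrt=False`` gives the plain 1 - s.
    """
    vals = calls.to_numpy(dtype=float)
    n = vals.shape[1]
    if n < 2:
        raise ValidationError("need at least two samples")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x, y = vals[:, i], vals[:, j]
            keep = ~(np.isnan(x) | np.isnan(y))
            xk, yk = x[keep], y[keep]
            a = float(((xk == 1) & (yk == 1)).sum())
            bc = float((xk != yk).sum())
            if a + bc == 0:
                raise ValidationError(
                    f"samples {calls.columns[i]!r}/{calls.columns[j]!r}: "
                    "no methylated locus in either; Jaccard undefined"
                )
            s = a / (a + bc)
            d[i, j] = d[j, i] = np.sqrt(1.0 - s) if sqrt else 1.0 - s
    return pd.DataFrame(d, index=calls.columns, columns=calls.columns)


@dataclass(frozen=True)
class PCOResult:
    """Principal-coordinate embedding: centered coordinates on positive axes."""

    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # descending, > 0
    total_inertia: float
    n_negative: int  # negative eigenvalues dropped (diagnostic)


def pco(d: pd.DataFrame, tol: float = 1e-10) -> PCOResult:
    """Classical MDS: Gower-center -0.5 d^2, eigendecompose, keep lambda > 0.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue); their centroid
    is the origin by construction.  Negative eigenvalues (non-Euclidean
    input) are dropped and counted.
    """
    dm = d.to_numpy(dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T):
        raise ValidationError("distance matrix must be square and symmetric")
    if np.diag(dm).any():
        raise ValidationError("distance matrix diagonal must be zero")
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(abs(eigval[0]), 1.0)
    pos = eigval > tol * scale
    n_negative = int((eigval < -tol * scale).sum())
    lam = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(lam)
    cols = [f"PCo{k + 1}" for k in range(coords.shape[1])]
    return PCOResult(
        coordinates=pd.DataFrame(coords, index=d.index, columns=cols),
        eigenvalues=lam,
        total_inertia=float(lam.sum()),
        n_negative=n_negative,
    )


def _between_ratio(coords: np.ndarray, groups: np.ndarray) -> float:
    """Between-group inertia / total inertia, group-size weighted."""
    center = coords.mean(axis=0)
    total = ((coords - center) ** 2).sum()
    if total == 0:
        raise ValidationError("degenerate configuration: zero total inertia")
    between = 0.0
    for g in np.unique(groups):
        sub = coords[groups == g]
        between += len(sub) * ((sub.mean(axis=0) - center) ** 2).sum()
    return float(between / total)


def between_group_test(
    result: PCOResult,
    groups: Sequence[int],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo test of group separation on the ordination.

    Statistic: between-group inertia over total inertia of the PCO
    coordinates (all positive axes), with group-size-weighted centroids.
    P = (1 + #{permuted >= observed}) / (1 + n_perm) under uniform label
    permutations (add-one convention; never exactly zero).
    """
    groups = np.asarray(groups)
    if len(np.unique(groups)) != 2:
        raise ValidationError("exactly two nonempty groups required")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    coords = result.coordinates.to_numpy(dtype=float)
    if len(groups) != coords.shape[0]:
        raise ValidationError("one group label per sample required")
    observed = _between_ratio(coords, groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = groups[rng.permutation(len(groups))]
        if _between_ratio(coords, perm) >= observed:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return observed, float(p)
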