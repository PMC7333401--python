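"""Beta diversity: Bray-Curtis distances, principal coordinates, PERMANOVA.

Distance matrices are carried as :class:`skbio.DistanceMatrix` (which
enforces symmetry, zero diagonal and labelled axes).  PCoA and PERMANOVA
are computed here directly: the ordination reports the negative
eigenvalue mass instead of silently correcting it, and the PERMANOVA
permutation engine supports exhaustive enumeration of label
rearrangements on small designs, where the permutation p-value is exact.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .otu import OtuTable

__all__ = [
    "bray_curtis",
    "pcoa",
    "permanova",
    "collapse_to_groups",
    "read_distance_matrix",
    "write_distance_matrix",
    "OrdinationResult",
    "PermanovaResult",
]


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity d(u,v) = sum|u-v| / sum(u+v)."""
    sums = table.sample_sums()
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"zero-sum sample(s): {list(zero.index)}")
    condensed = pdist(table.counts.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(table.sample_ids))


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=list(df.index.astype(str)))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="id"
    )


@dataclass
class OrdinationResult:
    """PCoA embedding with eigenvalue bookkeeping.

    ``coordinates`` holds one row per sample over the retained
    (positive-eigenvalue) axes, ordered by decreasing eigenvalue.
    ``proportion_explained`` is computed over the positive eigenvalues;
    ``negative_eigenvalue_mass`` is sum|lambda_neg| / sum|lambda|, a
    diagnostic of how non-Euclidean the input distances are.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinate analysis via Gower double-centering.

    B = -0.5 * J D^2 J is eigendecomposed; coordinates are eigenvectors
    scaled by sqrt(eigenvalue) on the positive axes.  Negative
    eigenvalues are reported, not corrected.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # clip eigenvalues that are zero up to round-off
    tol = np.abs(eigval).max() * 1e-12 if n > 1 else 0.0
    eigval = np.where(np.abs(eigval) < tol, 0.0, eigval)
    pos = eigval > 0
    n_pos = int(pos.sum())
    k = n_pos if n_axes is None else min(n_axes, n_pos)
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    total_abs = np.abs(eigval).sum()
    neg_mass = float(np.abs(eigval[eigval < 0]).sum() / total_abs) if total_abs else 0.0
    prop = eigval[:k] / eigval[pos].sum() if n_pos else np.zeros(0)
    coordinates = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"PC{i+1}" for i in range(k)]
    )
    return OrdinationResult(coordinates, eigval, prop, neg_mass)


@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p: float
    n_perm: int


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA (ADONIS) on a distance matrix.

    SS_total = sum of squared distances over all pairs divided by n;
    SS_within sums the analogous within-group terms; the pseudo-F uses
    k-1 and n-k degrees of freedom and R^2 = SS_among / SS_total.
    Significance permutes the group labels: ``exact=True`` enumerates
    every label permutation (p = fraction of permuted F >= observed,
    identity included); otherwise ``n_perm`` seeded random permutations
    with the standard (hits+1)/(n_perm+1) estimator.
    """
    labels = pd.Series(list(grouping))
    codes, uniques = pd.factorize(labels)
    k = len(uniques)
    n = len(codes)
    if n != dm.shape[0]:
        raise ValueError("grouping length does not match distance matrix")
    if k < 2:
        raise ValueError("need at least 2 groups")
    if (np.bincount(codes) == n).any():
        raise ValueError("a group contains every sample")
    d2 = np.asarray(dm.data, dtype=float) ** 2

    def pseudo_f(c: np.ndarray) -> float:
        ss_w = _ss_within(d2, c, k)
        ss_t = d2.sum() / (2.0 * n)
        ss_a = ss_t - ss_w
        return (ss_a / (k - 1)) / (ss_w / (n - k))

    f_obs = pseudo_f(codes)
    ss_t = d2.sum() / (2.0 * n)
    r2 = 1.0 - _ss_within(d2, codes, k) / ss_t

    if exact:
        if n > 9:
            raise ValueError("exact enumeration limited to n <= 9 samples")
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            f_p = pseudo_f(codes[list(perm)])
            hits += f_p >= f_obs - 1e-12
            total += 1
        return PermanovaResult(f_obs, float(r2), hits / total, total)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_p = pseudo_f(rng.permutation(codes))
        hits += f_p >= f_obs
    p = (hits + 1) / (n_perm + 1)
    return PermanovaResult(f_obs, float(r2), p, n_perm)


def collapse_to_groups(dm: DistanceMatrix, grouping) -> DistanceMatrix:
    """Mean between-group distance matrix (e.g. samples -> populations)."""
    labels = pd.Series(list(grouping))
    codes, uniques = pd.factorize(labels)
    k = len(uniques)
    d = np.asarray(dm.data, dtype=float)
    out = np.zeros((k, k))
    for a in range(k):
        ia = np.flatnonzero(codes == a)
        for b in range(a + 1, k):
            ib = np.flatnonzero(codes == b)
            out[a, b] = out[b, a] = d[np.ix_(ia, ib)].mean()
    return DistanceMatrix(out, ids=[str(u) for u in uniques])
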