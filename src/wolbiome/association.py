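"""Relating community distances to genetic, geographic and climatic
predictors: Spearman correlation, Mantel tests and a distance-based
recursive path model.

All pairwise analyses operate on the strict lower triangles of matched
square matrices over the same labels (|delta latitude|, |delta Bio1|,
Fst, Bray-Curtis, KL ...), so the Mantel tests and the path model
consume identical objects.  Pairwise vectorization violates the
independence assumed by normal-theory p-values; those are reported as
nominal, and a matrix-permutation mode is provided for distance
responses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from skbio import DistanceMatrix

__all__ = [
    "spearman",
    "mantel",
    "covariate_distance",
    "path_model",
    "MantelResult",
    "PathModelResult",
]


def spearman(x, y) -> float:
    """Tie-aware Spearman rank correlation (Pearson on average ranks)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str = "spearman"


def _tri(m: np.ndarray) -> np.ndarray:
    return m[np.tril_indices(m.shape[0], k=-1)]


def _rank_matrix(m: np.ndarray) -> np.ndarray:
    """Ranks of the strict-lower-triangle values, mirrored back into a
    symmetric matrix so a joint row/column permutation permutes ranks."""
    n = m.shape[0]
    ranks = stats.rankdata(_tri(m))
    out = np.zeros((n, n))
    out[np.tril_indices(n, k=-1)] = ranks
    return out + out.T


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 1000,
    seed: int | None = None,
    alternative: str = "greater",
    exact: bool = False,
) -> MantelResult:
    """Mantel test: Spearman correlation of two distance matrices.

    r is the rank correlation over strict lower triangles; significance
    permutes the rows and columns of ``d2`` jointly.  One-tailed
    positive by default (``alternative`` in {"greater", "less",
    "two-sided"}).  ``exact=True`` enumerates all n! permutations
    (identity included; n <= 8) so the p-value is the exact permutation
    fraction; otherwise ``n_perm`` seeded draws with (hits+1)/(n_perm+1).
    """
    if list(d1.ids) != list(d2.ids):
        raise ValueError("distance matrices must share labels and order")
    n = d1.shape[0]
    v1 = _tri(np.asarray(d1.data, dtype=float))
    m2 = np.asarray(d2.data, dtype=float)
    if np.ptp(v1) == 0 or np.ptp(_tri(m2)) == 0:
        raise ValueError("constant lower triangle: Mantel r undefined")
    r1 = stats.rankdata(v1)
    rank2 = _rank_matrix(m2)
    r_obs = _pearson(r1, _tri(rank2))

    def score(r_perm: float) -> bool:
        if alternative == "greater":
            return r_perm >= r_obs - 1e-12
        if alternative == "less":
            return r_perm <= r_obs + 1e-12
        return abs(r_perm) >= abs(r_obs) - 1e-12

    if exact:
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            perm = list(perm)
            hits += score(_pearson(r1, _tri(rank2[np.ix_(perm, perm)])))
            total += 1
        return MantelResult(r_obs, hits / total, total)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        hits += score(_pearson(r1, _tri(rank2[np.ix_(perm, perm)])))
    return MantelResult(r_obs, (hits + 1) / (n_perm + 1), n_perm)


def covariate_distance(metadata: pd.DataFrame, column: str) -> DistanceMatrix:
    """Pairwise |delta covariate| matrix over the metadata index."""
    if column not in metadata.columns:
        raise KeyError(column)
    v = metadata[column].astype(float)
    if v.isna().any():
        raise ValueError(f"missing values in {column!r}")
    arr = v.to_numpy()
    return DistanceMatrix(
        np.abs(arr[:, None] - arr[None, :]), ids=[str(i) for i in metadata.index]
    )


@dataclass
class PathEdge:
    source: str
    target: str
    slope: float
    p: float


@dataclass
class PathModelResult:
    """Per-equation OLS fit of a recursive path diagram.

    ``edges`` carries the unstandardized slope and p-value per arrow;
    ``r2`` the coefficient of determination per endogenous variable.
    p-values are normal-theory (nominal under pairwise vectorization)
    unless a permutation mode was requested.
    """

    edges: list[PathEdge]
    r2: dict[str, float]
    fit_notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.source, e.target, e.slope, e.p) for e in self.edges],
            columns=["source", "target", "slope", "p"],
        )


def _toposort(nodes: set[str], edges: list[tuple[str, str]]) -> list[str]:
    order, seen, active = [], set(), set()

    def visit(v: str) -> None:
        if v in seen:
            return
        if v in active:
            raise ValueError("edge specification contains a cycle")
        active.add(v)
        for s, t in edges:
            if t == v:
                visit(s)
        active.discard(v)
        seen.add(v)
        order.append(v)

    for v in sorted(nodes):
        visit(v)
    return order


def _as_vector(value) -> np.ndarray:
    if isinstance(value, DistanceMatrix):
        return _tri(np.asarray(value.data, dtype=float))
    return np.asarray(value, dtype=float)


def path_model(
    variables: dict,
    edges: list[tuple[str, str]],
    permutations: int = 0,
    seed: int | None = None,
) -> PathModelResult:
    """Recursive path analysis by per-equation least squares.

    ``variables`` maps names to equal-length vectors or to
    DistanceMatrix objects (vectorized as strict lower triangles).  Each
    endogenous variable is regressed on its parents with an intercept;
    the reported slopes are unstandardized.  With ``permutations`` > 0
    and a DistanceMatrix response, per-edge p-values come from jointly
    permuting that response matrix's rows and columns instead of normal
    theory.
    """
    matrices = {
        k: v for k, v in variables.items() if isinstance(v, DistanceMatrix)
    }
    vectors = {k: _as_vector(v) for k, v in variables.items()}
    lengths = {len(v) for v in vectors.values()}
    if len(lengths) != 1:
        raise ValueError("all variables must vectorize to the same length")
    for s, t in edges:
        if s not in vectors or t not in vectors:
            raise KeyError(f"edge references unknown variable: {s} -> {t}")
    _toposort(set(vectors), edges)  # raises on cycles

    notes: list[str] = []
    out_edges: list[PathEdge] = []
    r2: dict[str, float] = {}
    rng = np.random.default_rng(seed)
    targets = sorted({t for _, t in edges})
    for target in targets:
        parents = [s for s, t in edges if t == target]
        y = vectors[target]
        X = np.column_stack([vectors[p] for p in parents])
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) < len(parents) + 1:
            notes.append(f"collinear parents for {target}: {parents}")
        fit = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
        r2[target] = float(fit.rsquared)
        slopes = fit.params[1:]
        pvals = fit.pvalues[1:]
        if permutations > 0 and target in matrices:
            pvals = _permutation_pvalues(
                matrices[target], X, slopes, permutations, rng
            )
        for parent, b, p in zip(parents, slopes, pvals):
            out_edges.append(PathEdge(parent, target, float(b), float(p)))
    return PathModelResult(out_edges, r2, notes)


def _permutation_pvalues(
    response: DistanceMatrix,
    X: np.ndarray,
    slopes_obs: np.ndarray,
    permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    m = np.asarray(response.data, dtype=float)
    n = m.shape[0]
    Xc = sm.add_constant(X, has_constant="add")
    pinv = np.linalg.pinv(Xc)
    hits = np.zeros(len(slopes_obs))
    for _ in range(permutations):
        perm = rng.permutation(n)
        y_p = _tri(m[np.ix_(perm, perm)])
        b_p = (pinv @ y_p)[1:]
        hits += np.abs(b_p) >= np.abs(slopes_obs) - 1e-12
    return (hits + 1) / (permutations + 1)
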