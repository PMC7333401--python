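"""Heavy-tail characterization of OTU abundance distributions.

Species-abundance data in symbiont-swept insect microbiomes are strongly
aggregated: a handful of taxa carry most reads, the rest form a heavy
tail.  This module characterizes that tail with a power law

    p(x) = a * x^(-epsilon),   x > x'

fitted by continuous maximum likelihood on the observations above the
threshold x', with x' chosen by minimizing the Kolmogorov-Smirnov
distance between the empirical and fitted tail CCDFs (the standard
heavy-tail recipe), and classifies the exponent by its moment
implications: epsilon <= 2 (mean and variance infinite), 2 < epsilon < 3
(mean finite, variance infinite), epsilon >= 3 (both finite).

The exceedance probability P(X >= x) = (x/x')^(1-epsilon) summarizes the
fit; per-group histogram densities feed a (symmetrized) Kullback-Leibler
divergence used as a surrogate pairwise index of community structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .otu import OtuTable

__all__ = [
    "PowerLawFit",
    "ExceedanceCurve",
    "fit_powerlaw",
    "exceedance_curve",
    "histogram_density",
    "kl_divergence",
    "jeffreys_divergence",
    "kl_matrix",
]

MOMENT_CLASSES = {
    "mean&var-infinite": "epsilon <= 2",
    "mean-finite-var-infinite": "2 < epsilon < 3",
    "mean&var-finite": "epsilon >= 3",
}

MIN_TAIL = 10  # fits on fewer tail points are flagged, not refused

KL_SMOOTHING = 1e-10  # additive mass per empty bin before renormalization


def moment_class(epsilon: float) -> str:
    """Moment trichotomy of a power-law exponent."""
    if epsilon <= 2:
        return "mean&var-infinite"
    if epsilon < 3:
        return "mean-finite-var-infinite"
    return "mean&var-finite"


@dataclass
class PowerLawFit:
    x_prime: float
    epsilon: float
    a: float
    n_tail: int
    ks_stat: float
    moment_class: str
    small_tail: bool = False


def _tail_mle(tail: np.ndarray, x_prime: float) -> float:
    # continuous Hill estimator: eps = 1 + n / sum ln(x_i / x')
    return 1.0 + len(tail) / np.log(tail / x_prime).sum()


def _ks_distance(tail: np.ndarray, x_prime: float, epsilon: float) -> float:
    x = np.sort(tail)
    n = len(x)
    fitted = (x / x_prime) ** (1.0 - epsilon)  # model CCDF at the data points
    # empirical CCDF P(X >= x) just before and at each order statistic
    emp_hi = 1.0 - np.arange(n) / n
    emp_lo = 1.0 - np.arange(1, n + 1) / n
    return float(
        max(np.abs(fitted - emp_hi).max(), np.abs(fitted - emp_lo).max())
    )


def fit_powerlaw(
    abundances,
    x_prime: float | None = None,
    max_candidates: int = 100,
) -> PowerLawFit:
    """Fit the tail power law to positive abundances.

    With ``x_prime`` given, the exponent is the continuous MLE on the
    observations >= x_prime.  Otherwise candidate thresholds are the
    distinct abundance values (thinned to ``max_candidates``) and the
    threshold minimizing the KS distance between empirical and fitted
    tail CCDFs is selected, requiring at least 10 tail points.
    """
    x = np.asarray(abundances, dtype=float)
    x = x[x > 0]
    if len(x) == 0:
        raise ValueError("no positive abundances")
    if np.all(x == x[0]):
        raise ValueError("degenerate fit: all abundances equal")

    def fit_at(xp: float) -> tuple[float, np.ndarray]:
        tail = x[x >= xp]
        return _tail_mle(tail, xp), tail

    if x_prime is not None:
        eps, tail = fit_at(x_prime)
        if len(tail) < 2 or np.all(tail == tail[0]):
            raise ValueError("degenerate fit: tail has no spread")
        ks = _ks_distance(tail, x_prime, eps)
        return PowerLawFit(
            float(x_prime), float(eps), float((eps - 1) * x_prime ** (eps - 1)),
            len(tail), ks, moment_class(eps), small_tail=len(tail) < MIN_TAIL,
        )

    candidates = np.unique(x)
    candidates = candidates[candidates < candidates[-1]]  # tail needs spread
    # drop thresholds leaving fewer than MIN_TAIL points
    n_ge = (x[:, None] >= candidates[None, :]).sum(axis=0)
    candidates = candidates[n_ge >= MIN_TAIL]
    if len(candidates) == 0:
        raise ValueError("need at least 10 observations above some threshold")
    if len(candidates) > max_candidates:
        idx = np.unique(
            np.linspace(0, len(candidates) - 1, max_candidates).astype(int)
        )
        candidates = candidates[idx]

    best = None
    for xp in candidates:
        eps, tail = fit_at(xp)
        if not np.isfinite(eps):
            continue
        ks = _ks_distance(tail, xp, eps)
        if best is None or ks < best[0]:
            best = (ks, xp, eps, len(tail))
    ks, xp, eps, n_tail = best
    return PowerLawFit(
        float(xp), float(eps), float((eps - 1) * xp ** (eps - 1)),
        int(n_tail), float(ks), moment_class(eps), small_tail=n_tail < MIN_TAIL,
    )


@dataclass
class ExceedanceCurve:
    x: np.ndarray
    p_exceed: np.ndarray
    fitted_p_exceed: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"abundance": self.x, "p_exceed": self.p_exceed,
             "fitted_p_exceed": self.fitted_p_exceed}
        )


def exceedance_curve(abundances, fit: PowerLawFit) -> ExceedanceCurve:
    """Empirical CCDF P(X >= x) by rank, with the fitted tail curve
    (x/x')^(1-epsilon) evaluated for x >= x' (NaN below the threshold)."""
    x = np.sort(np.asarray(abundances, dtype=float))
    x = x[x > 0]
    n = len(x)
    p_exceed = 1.0 - np.arange(n) / n  # P(X >= x_(i)) = (n - i) / n
    fitted = np.where(
        x >= fit.x_prime, (x / fit.x_prime) ** (1.0 - fit.epsilon), np.nan
    )
    return ExceedanceCurve(x, p_exceed, fitted)


def histogram_density(
    abundances,
    bins: int = 32,
    edges: np.ndarray | None = None,
    log_spaced: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete probability masses over (by default log-spaced) bins.

    Returns ``(masses, edges)`` with masses summing to 1.  Passing
    ``edges`` pins the support, which is how two groups are made
    comparable for a KL divergence.
    """
    x = np.asarray(abundances, dtype=float)
    x = x[x > 0]
    if len(x) == 0:
        raise ValueError("no positive abundances")
    if edges is None:
        lo, hi = x.min(), x.max()
        if lo == hi:
            lo, hi = lo * 0.5, hi * 1.5
        if log_spaced:
            edges = np.geomspace(lo, hi, bins + 1)
        else:
            edges = np.linspace(lo, hi, bins + 1)
    edges = np.asarray(edges, dtype=float)
    # clip so observations outside the shared support land in the end bins
    clipped = np.clip(x, edges[0], np.nextafter(edges[-1], edges[0]))
    counts, _ = np.histogram(clipped, bins=edges)
    return counts / counts.sum(), edges


def _smooth(p: np.ndarray) -> np.ndarray:
    q = np.asarray(p, dtype=float) + KL_SMOOTHING
    return q / q.sum()


def kl_divergence(p, q) -> float:
    """Directed Kullback-Leibler divergence D(p||q) = sum p ln(p/q).

    Both densities must live on the same bins; empty bins receive a
    1e-10 mass before renormalization so the divergence is finite.
    """
    p, q = np.asarray(p, dtype=float), np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("densities are on mismatched bins")
    ps, qs = _smooth(p), _smooth(q)
    return float((ps * np.log(ps / qs)).sum())


def jeffreys_divergence(p, q) -> float:
    """Symmetrized KL, J = (D(p||q) + D(q||p)) / 2 — the form used for
    distance matrices."""
    return 0.5 * (kl_divergence(p, q) + kl_divergence(q, p))


def kl_matrix(table: OtuTable, grouping, bins: int = 32) -> DistanceMatrix:
    """Pairwise symmetrized KL divergence between group-pooled OTU
    abundance densities.

    Per group, sample reads are pooled per OTU; positive pooled
    abundances are binned on log-spaced edges shared across all groups,
    and each pair of group densities is compared with the Jeffreys
    divergence.
    """
    labels = pd.Series(list(grouping), index=table.sample_ids)
    pooled = table.counts.groupby(labels).sum()
    totals = pooled.sum(axis=1)
    empty = totals[totals == 0]
    if len(empty):
        raise ValueError(f"group(s) with no reads: {list(empty.index)}")
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 groups")
    all_pos = pooled.to_numpy(dtype=float).ravel()
    all_pos = all_pos[all_pos > 0]
    lo, hi = all_pos.min(), all_pos.max()
    if lo == hi:
        lo, hi = lo * 0.5, hi * 1.5
    edges = np.geomspace(lo, hi, bins + 1)
    densities = [
        histogram_density(pooled.loc[g].to_numpy(), edges=edges)[0]
        for g in pooled.index
    ]
    k = len(densities)
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            out[a, b] = out[b, a] = jeffreys_divergence(densities[a], densities[b])
    return DistanceMatrix(out, ids=[str(g) for g in pooled.index])
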