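"""Alpha-diversity indexes in the mothur/QIIME conventions.

Shannon uses the natural log.  Simpson is the finite-sample *dominance*
form sum n_i(n_i-1) / (N(N-1)): it is LARGE when one taxon (e.g. an
endosymbiont at >80% of reads) dominates, which is the convention under
which symbiont load correlates positively with Simpson and negatively
with Shannon.  Chao1 is the bias-corrected variant; ACE uses the
standard rare/abundant split at 10 reads.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .otu import OtuTable

__all__ = [
    "sobs",
    "shannon",
    "simpson",
    "chao1",
    "ace",
    "goods_coverage",
    "alpha_diversity_table",
]

# column order of the conventional per-sample diversity report
ALPHA_COLUMNS = ["sobs", "shannon", "simpson", "ace", "chao", "coverage"]


def _as_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be one-dimensional")
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    return c


def sobs(counts) -> int:
    """Observed richness: number of taxa with at least one read."""
    return int((_as_counts(counts) > 0).sum())


def shannon(counts) -> float:
    """Shannon entropy -sum p ln p (nats) over nonzero proportions."""
    c = _as_counts(counts)
    total = c.sum()
    if total <= 0:
        raise ValueError("zero total count")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Simpson dominance sum n_i(n_i-1) / (N(N-1)); larger = less even."""
    c = _as_counts(counts)
    total = c.sum()
    if total < 2:
        raise ValueError("Simpson dominance needs a total count of at least 2")
    return float((c * (c - 1)).sum() / (total * (total - 1)))


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: Sobs + F1(F1-1) / (2(F2+1))."""
    c = _as_counts(counts)
    if c.sum() <= 0:
        raise ValueError("zero total count")
    s_obs = sobs(c)
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based Coverage Estimator of richness.

    Taxa with <= ``rare_cutoff`` reads form the rare class; the estimator
    corrects the rare-class richness by its sample coverage and a squared
    coefficient of variation.  With no rare taxa ACE reduces to Sobs;
    when the rare class consists solely of singletons (coverage 0) the
    estimator is undefined and bias-corrected Chao1 is returned with a
    warning.
    """
    c = _as_counts(counts)
    if c.sum() <= 0:
        raise ValueError("zero total count")
    c = c[c > 0]
    rare = c[c <= rare_cutoff]
    s_abund = int((c > rare_cutoff).sum())
    s_rare = len(rare)
    if s_rare == 0:
        return float(s_abund)
    n_rare = rare.sum()
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace == 0.0:
        warnings.warn(
            "ACE undefined (rare class is all singletons); falling back to Chao1",
            RuntimeWarning,
            stacklevel=2,
        )
        return chao1(counts)
    freqs = np.array([(rare == i).sum() for i in range(1, rare_cutoff + 1)])
    i = np.arange(1, rare_cutoff + 1)
    gamma2 = max(
        s_rare / c_ace * (i * (i - 1) * freqs).sum() / (n_rare * (n_rare - 1)) - 1.0,
        0.0,
    ) if n_rare > 1 else 0.0
    return float(s_abund + s_rare / c_ace + f1 / c_ace * gamma2)


def goods_coverage(counts) -> float:
    """Good's coverage 1 - F1/N: chance the next read is a seen taxon."""
    c = _as_counts(counts)
    total = c.sum()
    if total <= 0:
        raise ValueError("zero total count")
    return float(1.0 - (c == 1).sum() / total)


def alpha_diversity_table(table: OtuTable, rare_cutoff: int = 10) -> pd.DataFrame:
    """One row of alpha indexes per sample (Sobs, Shannon, Simpson, Ace,
    Chao, Coverage)."""
    rows = {}
    for sample_id, row in table.counts.iterrows():
        c = row.to_numpy()
        rows[sample_id] = [
            sobs(c),
            shannon(c),
            simpson(c),
            ace(c, rare_cutoff=rare_cutoff),
            chao1(c),
            goods_coverage(c),
        ]
    out = pd.DataFrame.from_dict(rows, orient="index", columns=ALPHA_COLUMNS)
    out.index.name = "sample_id"
    return out
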