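"""Infected-vs-uninfected comparison battery.

Welch t-tests on alpha-diversity indexes, Mann-Whitney U tests on
per-genus relative abundances (exact by full enumeration on small
tie-free samples, tie- and continuity-corrected normal approximation
otherwise), and Spearman correlations of diversity against the symbiont
read proportion.  Significance stars follow the usual convention
*P < 0.05, **P < 0.01, ***P < 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .otu import OtuTable
from .association import spearman

__all__ = [
    "GroupTestResult",
    "significance_stars",
    "welch_t",
    "mann_whitney_u",
    "per_genus_comparison",
    "diversity_vs_proportion",
]

EXACT_MW_MAX_N = 12  # exact enumeration when total n is at most this and no ties


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class GroupTestResult:
    unit: str
    statistic: float
    p: float
    effect_direction: str
    n_group1: int
    n_group2: int
    stars: str = ""

    def __post_init__(self) -> None:
        if not self.stars:
            self.stars = significance_stars(self.p)


def welch_t(x, y, unit: str = "") -> GroupTestResult:
    """Welch two-sample t-test (Satterthwaite df), two-sided."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Welch t needs at least 2 observations per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] == y[0]:
            return GroupTestResult(unit, 0.0, 1.0, "equal", len(x), len(y))
        raise ValueError("both groups constant with different values")
    res = stats.ttest_ind(x, y, equal_var=False)
    direction = (
        "higher in group 1" if x.mean() > y.mean()
        else "higher in group 2" if x.mean() < y.mean() else "equal"
    )
    return GroupTestResult(
        unit, float(res.statistic), float(res.pvalue), direction, len(x), len(y)
    )


def mann_whitney_u(x, y, unit: str = "", mode: str = "auto") -> GroupTestResult:
    """Two-sided Mann-Whitney U test.

    ``mode='auto'`` enumerates the exact null distribution when the
    pooled sample has no ties and at most 12 observations, and otherwise
    uses the normal approximation with tie and continuity corrections;
    ``'exact'`` / ``'asymptotic'`` force a method.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        method = "exact" if (len(pooled) <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    mx, my = np.median(x), np.median(y)
    direction = (
        "higher in group 1" if mx > my
        else "higher in group 2" if mx < my else "equal"
    )
    return GroupTestResult(
        unit, float(res.statistic), float(res.pvalue), direction, len(x), len(y)
    )


def per_genus_comparison(
    table: OtuTable,
    groups: pd.Series,
    adjust: bool = True,
) -> pd.DataFrame:
    """Mann-Whitney U per genus on relative abundances between two groups.

    Expects a genus-level table; relative abundances are computed per
    sample.  Genera absent from both groups are skipped with a note in
    the ``note`` column.  Emits the unadjusted p (the reproduction-mode
    default), a Benjamini-Hochberg adjusted column, the direction by
    median comparison, stars, and log10 mean read percentages per group
    for plotting.
    """
    groups = groups.reindex(table.sample_ids)
    levels = pd.unique(groups.dropna())
    if len(levels) != 2:
        raise ValueError("per-genus comparison needs exactly 2 groups")
    props = table.counts.div(table.sample_sums(), axis=0)
    g1 = props.loc[groups == levels[0]]
    g2 = props.loc[groups == levels[1]]
    rows = []
    for genus in props.columns:
        a, b = g1[genus].to_numpy(), g2[genus].to_numpy()
        if a.sum() == 0 and b.sum() == 0:
            rows.append(
                {"unit": genus, "statistic": np.nan, "p": np.nan,
                 "direction": "", "log10_pct_group1": np.nan,
                 "log10_pct_group2": np.nan, "note": "absent from both groups"}
            )
            continue
        res = mann_whitney_u(a, b, unit=str(genus))
        direction = {
            "higher in group 1": f"decreased in {levels[1]}",
            "higher in group 2": f"increased in {levels[1]}",
            "equal": "no median shift",
        }[res.effect_direction]
        with np.errstate(divide="ignore"):
            l1 = np.log10(100 * a.mean()) if a.mean() > 0 else -np.inf
            l2 = np.log10(100 * b.mean()) if b.mean() > 0 else -np.inf
        rows.append(
            {"unit": genus, "statistic": res.statistic, "p": res.p,
             "direction": direction, "log10_pct_group1": l1,
             "log10_pct_group2": l2, "note": ""}
        )
    out = pd.DataFrame(rows).set_index("unit")
    tested = out["p"].notna()
    out["stars"] = [significance_stars(p) if np.isfinite(p) else "" for p in out["p"]]
    if adjust:
        out["p_adj"] = np.nan
        if tested.any():
            out.loc[tested, "p_adj"] = multipletests(
                out.loc[tested, "p"], method="fdr_bh"
            )[1]
    return out


def diversity_vs_proportion(alpha: pd.DataFrame, proportion: pd.Series) -> pd.DataFrame:
    """Spearman r and p of each alpha index against the symbiont read
    proportion, over matched samples."""
    prop = proportion.reindex(alpha.index)
    if prop.isna().any():
        raise ValueError("proportion missing for some samples")
    if len(alpha) < 5:
        raise ValueError("need at least 5 matched samples")
    if np.ptp(prop.to_numpy(dtype=float)) == 0:
        raise ValueError("symbiont proportions are constant")
    rows = {}
    for col in alpha.columns:
        res = stats.spearmanr(prop.to_numpy(), alpha[col].to_numpy())
        rows[col] = {"r": float(res.statistic), "p": float(res.pvalue)}
    return pd.DataFrame.from_dict(rows, orient="index")
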