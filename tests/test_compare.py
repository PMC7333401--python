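"""Welch t, Mann-Whitney U, per-genus battery and diversity-vs-load."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from wolbiome import (
    OtuTable,
    alpha_diversity_table,
    diversity_vs_proportion,
    mann_whitney_u,
    per_genus_comparison,
    significance_stars,
    simulate_dominance_gradient,
    welch_t,
)
from wolbiome.datasets import sap_alpha_diversity


def _welch_oracle(x, y):
    """Textbook Welch statistic with Satterthwaite df, coded independently."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    from scipy import stats

    p = 2 * stats.t.sf(abs(t), df)
    return t, p


class TestWelch:
    def test_identical_groups_t_zero_p_one(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_independent_oracle(self, rng):
        for _ in range(10):
            x = rng.normal(0, 1, int(rng.integers(3, 12)))
            y = rng.normal(0.5, 2, int(rng.integers(3, 12)))
            res = welch_t(x, y)
            t_ref, p_ref = _welch_oracle(x, y)
            assert res.statistic == pytest.approx(t_ref, abs=1e-10)
            assert res.p == pytest.approx(p_ref, abs=1e-10)

    def test_group_swap_flips_sign_only(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 6)
        a, b = welch_t(x, y), welch_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p == pytest.approx(b.p)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])

    def test_published_alpha_table_shannon_and_simpson(self):
        """The printed 10 infected vs 9 uninfected individuals: diversity
        collapse significant well below the 0.001 level."""
        df = sap_alpha_diversity()
        inf, uninf = df[df["infected"]], df[~df["infected"]]
        assert welch_t(inf["shannon"], uninf["shannon"]).p < 0.001
        assert welch_t(inf["simpson"], uninf["simpson"]).p < 0.001


def _mw_enumeration_oracle(x, y):
    """Exact two-sided p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    u_obs = sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
        1 for xi in x for yi in y if xi == yi
    )
    mean_u = nx * len(y) / 2
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(1 for xi in xs for yi in ys if xi > yi)
        hits += abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12
        total += 1
    return hits / total


class TestMannWhitney:
    def test_complete_separation_three_vs_three(self):
        res = mann_whitney_u([7.0, 8.0, 9.0], [1.0, 2.0, 3.0])
        assert res.statistic == 9.0
        assert res.p == pytest.approx(0.1)  # 2/20 arrangements as extreme

    def test_identical_value_sets_centered_u(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(4.5)  # n_x n_y / 2
        assert res.p > 0.9

    @pytest.mark.parametrize("nx,ny", [(2, 3), (3, 3), (4, 4), (3, 6), (5, 5)])
    def test_exact_mode_matches_enumeration_oracle(self, nx, ny, rng):
        x, y = rng.normal(0, 1, nx), rng.normal(1, 1, ny)
        res = mann_whitney_u(x, y)
        assert res.p == pytest.approx(_mw_enumeration_oracle(x, y), abs=1e-12)

    def test_normal_approximation_close_to_exact_at_six_per_group(self, rng):
        x, y = rng.normal(0, 1, 6), rng.normal(0.8, 1, 6)
        exact = mann_whitney_u(x, y, mode="exact")
        approx = mann_whitney_u(x, y, mode="asymptotic")
        assert approx.p == pytest.approx(exact.p, abs=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney_u([], [1.0])


class TestStars:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.049, "*"), (0.051, ""), (0.0099, "**"), (0.011, "*"),
         (0.00099, "***"), (0.002, "**"), (1.0, "")],
    )
    def test_threshold_boundaries(self, p, expected):
        assert significance_stars(p) == expected


def _genus_table(rows, genera, ids=None):
    rows = np.atleast_2d(rows)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    counts = pd.DataFrame(rows, index=ids, columns=genera)
    return OtuTable(counts, pd.Series(genera, index=genera))


class TestPerGenus:
    def test_identical_groups_nothing_significant(self):
        rows = [[10, 20, 5]] * 8
        t = _genus_table(rows, ["GenA", "GenB", "GenC"])
        groups = pd.Series(["g1"] * 4 + ["g2"] * 4, index=t.sample_ids)
        out = per_genus_comparison(t, groups)
        assert (out["p"].dropna() > 0.9).all()

    def test_group_specific_genus_direction_and_p(self):
        rows = [[50, 50], [60, 40], [55, 45], [40, 100], [30, 100], [20, 100]]
        t = _genus_table(rows, ["GenA", "GenB"])
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=t.sample_ids)
        out = per_genus_comparison(t, groups)
        assert out.loc["GenA", "direction"] == "decreased in g2"
        assert out.loc["GenA", "p"] == pytest.approx(0.1)

    def test_absent_genus_skipped_with_note(self):
        rows = [[10, 0], [12, 0], [9, 0], [11, 0]]
        t = _genus_table(rows, ["GenA", "GenB"])
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=t.sample_ids)
        out = per_genus_comparison(t, groups)
        assert out.loc["GenB", "note"] == "absent from both groups"
        assert np.isnan(out.loc["GenB", "p"])

    def test_spiked_effects_recovered(self, rng):
        """Mass-balanced spike design (8 genera up, 8 down, total reads
        conserved so null genera stay null compositionally): significant
        calls track the spiked genera within binomial tolerance."""
        n_genera, n_per_group = 40, 10
        up, down, null = np.arange(8), np.arange(8, 16), np.arange(16, 40)
        mean_g1 = np.full(n_genera, 100.0)
        mean_g1[down] = 160.0
        mean_g2 = mean_g1.copy()
        mean_g2[up] = 180.0   # +640 reads expected
        mean_g2[down] = 80.0  # -640 reads expected
        rows, labels = [], []
        for g, mean in (("g1", mean_g1), ("g2", mean_g2)):
            for _ in range(n_per_group):
                rows.append(rng.poisson(mean))
                labels.append(g)
        t = _genus_table(rows, [f"Gen{i}" for i in range(n_genera)])
        out = per_genus_comparison(t, pd.Series(labels, index=t.sample_ids))
        sig = out[out["p"] < 0.05]
        up_names = {f"Gen{i}" for i in up}
        down_names = {f"Gen{i}" for i in down}
        n_up = sum(out.loc[g, "p"] < 0.05 and out.loc[g, "direction"] ==
                   "increased in g2" for g in up_names)
        n_down = sum(out.loc[g, "p"] < 0.05 and out.loc[g, "direction"] ==
                     "decreased in g2" for g in down_names)
        assert n_up >= 6 and n_down >= 6  # most spiked genera detected
        false_calls = sig.index.intersection([f"Gen{i}" for i in null])
        assert len(false_calls) <= 5  # 24 null genera at alpha = 0.05


class TestDiversityVsProportion:
    def test_constant_proportions_rejected(self):
        alpha = pd.DataFrame({"shannon": np.arange(6.0)}, index=list("abcdef"))
        prop = pd.Series(0.5, index=list("abcdef"))
        with pytest.raises(ValueError, match="constant"):
            diversity_vs_proportion(alpha, prop)

    def test_dominance_gradient_sign_pattern(self):
        """Symbiont load suppresses Shannon and inflates Simpson dominance."""
        table, meta = simulate_dominance_gradient(
            n_samples=30, depth=4000, n_taxa=150, seed=5
        )
        alpha = alpha_diversity_table(table)
        out = diversity_vs_proportion(
            alpha[["shannon", "simpson"]], meta["symbiont_prop_true"]
        )
        assert out.loc["shannon", "r"] < 0
        assert out.loc["simpson", "r"] > 0

    def test_null_shuffles_rarely_significant(self, rng):
        table, meta = simulate_dominance_gradient(
            n_samples=30, depth=2000, n_taxa=100, seed=6
        )
        alpha = alpha_diversity_table(table)[["shannon"]]
        prop = meta["symbiont_prop_true"].to_numpy()
        n_sig = 0
        for _ in range(100):
            shuffled = pd.Series(rng.permutation(prop), index=alpha.index)
            out = diversity_vs_proportion(alpha, shuffled)
            n_sig += out.loc["shannon", "p"] < 0.05
        assert n_sig <= 10
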