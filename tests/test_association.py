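"""Spearman, Mantel tests and the distance-based path model."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from wolbiome import covariate_distance, mantel, path_model, spearman


def _euclid_dm(points, prefix="x"):
    return DistanceMatrix(
        squareform(pdist(np.atleast_2d(points))),
        ids=[f"{prefix}{i}" for i in range(len(points))],
    )


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        assert spearman([1, 2, 3, 4], [10, 20, 25, 100]) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        assert spearman([1, 2, 3, 4], [8, 6, 4, 2]) == pytest.approx(-1.0)

    def test_tied_data_matches_average_rank_oracle(self, rng):
        """Pearson correlation of hand-computed average ranks."""
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0])
        y = rng.random(7)

        def avg_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v), float)
            ranks[order] = np.arange(1, len(v) + 1)
            for val in np.unique(v):
                mask = v == val
                ranks[mask] = ranks[mask].mean()
            return ranks

        expected = np.corrcoef(avg_ranks(x), avg_ranks(y))[0, 1]
        assert spearman(x, y) == pytest.approx(expected)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([1, 1, 1], [1, 2, 3])


def _brute_force_mantel(d1, d2, alternative="greater"):
    """Independent full-enumeration oracle via scipy.spearmanr."""
    n = d1.shape[0]
    tri = np.tril_indices(n, k=-1)
    v1 = d1[tri]
    r_obs = stats.spearmanr(v1, d2[tri]).statistic
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        perm = list(perm)
        r_p = stats.spearmanr(v1, d2[np.ix_(perm, perm)][tri]).statistic
        if alternative == "greater":
            hits += r_p >= r_obs - 1e-12
        else:
            hits += abs(r_p) >= abs(r_obs) - 1e-12
        total += 1
    return r_obs, hits / total


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        dm = _euclid_dm(rng.random((6, 2)))
        res = mantel(dm, dm, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_exact_p_matches_full_enumeration(self, rng):
        d1 = _euclid_dm(rng.random((5, 2)))
        d2 = _euclid_dm(rng.random((5, 2)))
        res = mantel(d1, d2, exact=True)
        r_ref, p_ref = _brute_force_mantel(d1.data, d2.data)
        assert res.r == pytest.approx(r_ref)
        assert res.p == pytest.approx(p_ref)
        assert res.n_perm == 120

    def test_statistic_symmetric_in_arguments(self, rng):
        d1 = _euclid_dm(rng.random((7, 2)))
        d2 = _euclid_dm(rng.random((7, 2)))
        assert mantel(d1, d2, n_perm=9, seed=0).r == pytest.approx(
            mantel(d2, d1, n_perm=9, seed=0).r
        )

    def test_reproducible_under_fixed_seed(self, rng):
        d1 = _euclid_dm(rng.random((8, 2)))
        d2 = _euclid_dm(rng.random((8, 2)))
        assert (
            mantel(d1, d2, n_perm=999, seed=4).p
            == mantel(d1, d2, n_perm=999, seed=4).p
        )

    def test_mismatched_labels_rejected(self, rng):
        d1 = _euclid_dm(rng.random((4, 2)), prefix="a")
        d2 = _euclid_dm(rng.random((4, 2)), prefix="b")
        with pytest.raises(ValueError, match="labels"):
            mantel(d1, d2)


class TestCovariateDistance:
    def test_absolute_differences(self):
        meta = pd.DataFrame({"bio1": [10.0, 14.0, 7.0]}, index=["a", "b", "c"])
        dm = covariate_distance(meta, "bio1")
        assert dm["a", "b"] == 4.0
        assert dm["b", "c"] == 7.0

    def test_equal_values_zero_matrix(self):
        meta = pd.DataFrame({"lat": [3.0, 3.0]}, index=["a", "b"])
        assert covariate_distance(meta, "lat").data.sum() == 0.0

    def test_triangle_inequality(self, rng):
        meta = pd.DataFrame({"v": rng.random(6)}, index=list("abcdef"))
        d = covariate_distance(meta, "v").data
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12

    def test_missing_values_rejected(self):
        meta = pd.DataFrame({"v": [1.0, np.nan]}, index=["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            covariate_distance(meta, "v")


class TestPathModel:
    def test_single_edge_reduces_to_simple_regression(self, rng):
        x = rng.random(40)
        y = 2.0 * x + rng.normal(0, 0.1, 40)
        res = path_model({"x": x, "y": y}, [("x", "y")])
        lr = stats.linregress(x, y)
        assert res.edges[0].slope == pytest.approx(lr.slope)
        assert res.r2["y"] == pytest.approx(lr.rvalue**2)

    def test_zero_noise_recursive_system_recovered(self, rng):
        """x -> m (slope 0.7), {x, m} -> y (slopes 0.7, -0.3), no noise:
        slopes within 1e-6 and R^2 = 1."""
        n = 1000
        x = rng.random(n)
        m = 0.7 * x
        y = 0.7 * x - 0.3 * m
        res = path_model({"x": x, "m": m, "y": y}, [("x", "m"), ("x", "y"), ("m", "y")])
        slopes = {(e.source, e.target): e.slope for e in res.edges}
        assert slopes[("x", "m")] == pytest.approx(0.7, abs=1e-6)
        assert res.r2["m"] == pytest.approx(1.0, abs=1e-9)
        assert res.r2["y"] == pytest.approx(1.0, abs=1e-9)
        # x and m are perfectly collinear parents of y: flagged, not fatal
        assert any("collinear" in note for note in res.fit_notes)

    def test_noisy_recovery_calibrated(self):
        """True slopes fall within +-2 SE in at least 90% of simulations."""
        hits = trials = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.random(200)
            m = 0.7 * x + rng.normal(0, 0.2, 200)
            y = -0.3 * m + rng.normal(0, 0.2, 200)
            import statsmodels.api as sm

            for parent, child, true in ((x, m, 0.7), (m, y, -0.3)):
                fit = sm.OLS(child, sm.add_constant(parent)).fit()
                hits += abs(fit.params[1] - true) <= 2 * fit.bse[1]
                trials += 1
        assert hits / trials >= 0.90

    def test_distance_matrix_variables_vectorized(self, rng):
        lat = pd.DataFrame({"lat": np.sort(rng.random(6))}, index=list("abcdef"))
        d_lat = covariate_distance(lat, "lat")
        fst = DistanceMatrix(0.5 * d_lat.data, ids=list("abcdef"))
        res = path_model({"lat": d_lat, "fst": fst}, [("lat", "fst")])
        assert res.edges[0].slope == pytest.approx(0.5, abs=1e-9)

    def test_permutation_p_mode(self, rng):
        lat = pd.DataFrame({"lat": np.sort(rng.random(8))}, index=list("abcdefgh"))
        d_lat = covariate_distance(lat, "lat")
        fst = DistanceMatrix(
            np.clip(0.5 * d_lat.data + 0.01 * (lambda m: m + m.T)(
                rng.normal(0, 1, (8, 8)) * (1 - np.eye(8))
            ), 0, None),
            ids=list("abcdefgh"),
        )
        res = path_model(
            {"lat": d_lat, "fst": fst}, [("lat", "fst")],
            permutations=199, seed=1,
        )
        assert res.edges[0].p <= 0.05  # strong true effect detected

    def test_generator_path_structure_recovered(self):
        """On the default synthetic survey, the chain latitude -> Fst ->
        community distance comes out with positive slopes: latitude decay
        drives Fst, and the latitude-tilted communities make Fst a positive
        predictor of Bray-Curtis distance."""
        import wolbiome as w

        cspec, mspec = w.study_conditions(seed=77)
        cspec.samples_per_population = 2
        cspec.depth = 3000
        table, meta = w.simulate_otu_table(cspec)
        pops = list(meta["population"].unique())
        pop_meta, fst = w.simulate_metadata(mspec, pops)
        bc_pop = w.collapse_to_groups(w.bray_curtis(table), meta["population"])
        res = path_model(
            {"lat": covariate_distance(pop_meta, "latitude"),
             "fst": fst, "community": bc_pop},
            [("lat", "fst"), ("fst", "community")],
        )
        slopes = {(e.source, e.target): e.slope for e in res.edges}
        assert slopes[("lat", "fst")] > 0
        assert slopes[("fst", "community")] > 0

    def test_cyclic_edges_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            path_model(
                {"a": np.arange(4.0), "b": np.arange(4.0)},
                [("a", "b"), ("b", "a")],
            )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same length"):
            path_model({"a": np.arange(4.0), "b": np.arange(5.0)}, [("a", "b")])
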