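import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baoflow.iokit.rasters import EnvRaster
from baoflow.niche import (
    area_curve,
    ecological_valence,
    equivalency_test,
    extract_env,
    land_area,
    niche_density,
    overlap_tests,
    pca_niche_space,
    schoener_d,
    select_variables,
    similarity_test,
    superimpose_habitat,
)
from baoflow.synthgen import IslandConfig, sample_occurrences, simulate_island_rasters


class TestSelectVariables:
    def test_perfectly_correlated_pair_reduced(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        df = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": rng.standard_normal(100)})
        keep, _ = select_variables(df)
        assert "c" in keep and len(keep) == 2

    def test_independent_variables_all_kept(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((500, 6)), columns=list("abcdef"))
        keep, _ = select_variables(df)
        assert sorted(keep) == list("abcdef")

    def test_block_structure_decorrelated(self):
        rng = np.random.default_rng(2)
        base1 = rng.standard_normal(300)
        base2 = rng.standard_normal(300)
        df = pd.DataFrame(
            {
                "a1": base1,
                "a2": base1 + 0.1 * rng.standard_normal(300),
                "a3": base1 + 0.1 * rng.standard_normal(300),
                "b1": base2,
                "b2": base2 + 0.1 * rng.standard_normal(300),
            }
        )
        keep, _ = select_variables(df)
        sub = df[keep].corr().abs().to_numpy()
        np.fill_diagonal(sub, 0.0)
        assert sub.max() < 0.8

    def test_constant_variable_dropped_first(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"k": np.ones(50), "x": rng.standard_normal(50),
                           "y": rng.standard_normal(50)})
        keep, _ = select_variables(df)
        assert "k" not in keep


class TestExtractAndValence:
    def test_cell_centre_value(self):
        r = EnvRaster(np.array([[1.0, 2.0], [3.0, 4.0]]), 0.0, 0.0, 1.0)
        occ = pd.DataFrame({"species": ["s"], "lon": [0.5], "lat": [1.5]})
        out = extract_env({"v": r}, occ)
        assert out.loc[0, "v"] == 1.0

    def test_nodata_point_excluded(self):
        r = EnvRaster(np.array([[np.nan, 2.0]]), 0.0, 0.0, 1.0)
        occ = pd.DataFrame({"species": ["s", "s"], "lon": [0.5, 1.5], "lat": [0.5, 0.5]})
        out = extract_env({"v": r}, occ)
        assert len(out) == 1 and out.loc[0, "v"] == 2.0

    def test_all_points_off_raster_raise(self):
        r = EnvRaster(np.ones((2, 2)), 0.0, 0.0, 1.0)
        occ = pd.DataFrame({"species": ["s"], "lon": [10.0], "lat": [10.0]})
        with pytest.raises(ValueError):
            extract_env({"v": r}, occ)

    def test_valence_min_max(self):
        df = pd.DataFrame({"species": ["s"] * 3, "v": [3.0, 7.0, 5.0]})
        val = ecological_valence(df)
        assert (val.loc[0, "min"], val.loc[0, "max"]) == (3.0, 7.0)

    def test_single_occurrence_degenerate(self):
        df = pd.DataFrame({"species": ["s"], "v": [4.2]})
        val = ecological_valence(df)
        assert val.loc[0, "min"] == val.loc[0, "max"] == 4.2

    def test_sampled_valence_within_truth(self, island):
        cfg, _, env = island
        ranges = cfg.species_ranges["sp1"]
        occ = sample_occurrences(env, ranges, 500, seed=2)
        table = extract_env(env, occ)
        val = ecological_valence(table).set_index("variable")
        for var, (lo, hi) in ranges.items():
            assert lo <= val.loc[var, "min"] <= val.loc[var, "max"] <= hi


class TestHabitat:
    def make_rasters(self):
        vals1 = np.array([[1.0, 2.0], [3.0, 4.0]])
        vals2 = np.array([[10.0, 20.0], [30.0, 40.0]])
        return {
            "v1": EnvRaster(vals1, 0, 0, 1.0),
            "v2": EnvRaster(vals2, 0, 0, 1.0),
        }

    def valence(self, r1, r2):
        return pd.DataFrame(
            {"species": ["s", "s"], "variable": ["v1", "v2"],
             "min": [r1[0], r2[0]], "max": [r1[1], r2[1]]}
        )

    def test_everything_in_range(self):
        hm = superimpose_habitat(self.make_rasters(), self.valence((0, 5), (0, 50)), "s")
        assert (hm.counts.values == 2).all()
        assert (hm.habitat.values == 1).all()

    def test_one_failing_layer_excludes_cell(self):
        hm = superimpose_habitat(self.make_rasters(), self.valence((0, 5), (15, 50)), "s")
        assert hm.counts.values[0, 0] == 1  # v2=10 out of range
        assert hm.habitat.values[0, 0] == 0
        assert hm.habitat.values[0, 1] == 1

    def test_endpoints_inclusive(self):
        hm = superimpose_habitat(self.make_rasters(), self.valence((1, 4), (10, 40)), "s")
        assert (hm.habitat.values == 1).all()

    def test_widening_never_shrinks_habitat(self):
        rng = np.random.default_rng(4)
        rasters = {
            "v1": EnvRaster(rng.random((20, 20)), 0, 0, 1.0),
            "v2": EnvRaster(rng.random((20, 20)), 0, 0, 1.0),
        }
        narrow = superimpose_habitat(rasters, self.valence((0.3, 0.6), (0.2, 0.7)), "s")
        wide = superimpose_habitat(rasters, self.valence((0.2, 0.8), (0.2, 0.7)), "s")
        assert (wide.habitat.values >= narrow.habitat.values).all()

    def test_missing_variable_raises(self):
        with pytest.raises(ValueError, match="missing"):
            superimpose_habitat(
                self.make_rasters(),
                pd.DataFrame({"species": ["s"], "variable": ["v1"], "min": [0], "max": [9]}),
                "s",
            )

    def test_synthetic_species_habitat_jaccard(self, island):
        cfg, _, env = island
        ranges = cfg.species_ranges["sp1"]
        occ = sample_occurrences(env, ranges, 500, seed=5)
        val = ecological_valence(extract_env(env, occ))
        hm = superimpose_habitat(env, val, "sp1")
        truth = np.ones(next(iter(env.values())).values.shape, dtype=bool)
        for var, (lo, hi) in ranges.items():
            v = env[var].values
            truth &= ~np.isnan(v) & (v >= lo) & (v <= hi)
        pred = hm.habitat.values == 1
        jacc = (pred & truth).sum() / (pred | truth).sum()
        assert jacc >= 0.9


class TestNicheSpace:
    def test_isotropic_variance_split(self):
        rng = np.random.default_rng(5)
        r = {
            "a": EnvRaster(rng.standard_normal((50, 50)), 0, 0, 1.0),
            "b": EnvRaster(rng.standard_normal((50, 50)), 0, 0, 1.0),
        }
        space = pca_niche_space(r, ["a", "b"])
        assert space.pca.explained_variance_ratio_[0] == pytest.approx(0.5, abs=0.05)

    def test_duplicated_variable_collapses_to_pc1(self):
        rng = np.random.default_rng(6)
        vals = rng.standard_normal((40, 40))
        r = {"a": EnvRaster(vals, 0, 0, 1.0), "b": EnvRaster(vals.copy(), 0, 0, 1.0)}
        space = pca_niche_space(r, ["a", "b"])
        assert space.pca.explained_variance_ratio_[0] == pytest.approx(1.0, abs=1e-9)

    def test_background_mean_projects_to_origin(self):
        rng = np.random.default_rng(7)
        r = {
            "a": EnvRaster(rng.random((30, 30)), 0, 0, 1.0),
            "b": EnvRaster(rng.random((30, 30)), 0, 0, 1.0),
        }
        space = pca_niche_space(r, ["a", "b"])
        mean_table = pd.DataFrame(
            {"a": [np.nanmean(r["a"].values)], "b": [np.nanmean(r["b"].values)]}
        )
        np.testing.assert_allclose(space.project(mean_table), 0.0, atol=1e-9)


class TestNicheDensity:
    def test_normalization(self):
        rng = np.random.default_rng(8)
        z = niche_density(rng.standard_normal((100, 2)), (-3, 3, -3, 3), R=50)
        assert z.z.sum() == pytest.approx(1.0, abs=1e-9)
        assert (z.z >= 0).all()

    def test_tight_cluster_peaks_at_centroid(self):
        pts = np.array([[1.0, 1.0]] * 30) + 1e-3 * np.random.default_rng(9).standard_normal((30, 2))
        z = niche_density(pts, (0, 2, 0, 2), R=21)
        r, c = np.unravel_index(np.argmax(z.z), z.z.shape)
        # centre of the grid is (1, 1)
        assert abs(c - 10) <= 1 and abs(r - 10) <= 1

    def test_zero_variance_single_cell_mass(self):
        pts = np.array([[0.5, 0.5]] * 10)
        z = niche_density(pts, (0, 1, 0, 1), R=10)
        assert z.z.max() == pytest.approx(1.0)

    def test_two_equal_clusters_two_modes(self):
        rng = np.random.default_rng(10)
        a = rng.standard_normal((200, 2)) * 0.1 + [-2, 0]
        b = rng.standard_normal((200, 2)) * 0.1 + [2, 0]
        z = niche_density(np.vstack([a, b]), (-4, 4, -2, 2), R=80, bandwidth=0.3)
        left = z.z[:, :40].sum()
        right = z.z[:, 40:].sum()
        assert left == pytest.approx(right, rel=0.1)


class TestSchoenerD:
    def test_self_overlap_is_one(self):
        rng = np.random.default_rng(11)
        z = rng.random((20, 20))
        z /= z.sum()
        assert schoener_d(z, z) == 1.0

    def test_disjoint_supports_zero(self):
        z1 = np.zeros((4, 4))
        z2 = np.zeros((4, 4))
        z1[:, :2] = 1 / 8
        z2[:, 2:] = 1 / 8
        assert schoener_d(z1, z2) == 0.0

    def test_half_overlap_example(self):
        z1 = np.array([0.5, 0.5, 0.0, 0.0])
        z2 = np.array([0.5, 0.0, 0.5, 0.0])
        assert schoener_d(z1, z2) == pytest.approx(0.5)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            schoener_d(np.ones((2, 2)) / 4, np.ones((3, 3)) / 9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_bounded(self, seed):
        rng = np.random.default_rng(seed)
        z1 = rng.random(16)
        z2 = rng.random(16)
        z1 /= z1.sum()
        z2 /= z2.sum()
        d12 = schoener_d(z1, z2)
        assert d12 == schoener_d(z2, z1)
        assert 0.0 <= d12 <= 1.0


@pytest.fixture(scope="module")
def toy_space(request):
    rng = np.random.default_rng(12)
    rasters = {
        "a": EnvRaster(rng.random((40, 40)), 0, 0, 1.0),
        "b": EnvRaster(rng.random((40, 40)), 0, 0, 1.0),
    }
    return pca_niche_space(rasters, ["a", "b"])


class TestOverlapTests:
    def test_identical_distribution_rarely_significant(self, toy_space):
        rng = np.random.default_rng(13)
        ok = 0
        for i in range(20):
            s1 = rng.standard_normal((40, 2)) * 0.5
            s2 = rng.standard_normal((40, 2)) * 0.5
            _, p = equivalency_test(s1, s2, toy_space, n_reps=99, seed=i, R=40)
            ok += p > 0.05
        assert ok >= 18

    def test_separated_clusters_minimal_p(self, toy_space):
        rng = np.random.default_rng(14)
        s1 = rng.standard_normal((30, 2)) * 0.05 + [-1.5, 0]
        s2 = rng.standard_normal((30, 2)) * 0.05 + [1.5, 0]
        d, p = equivalency_test(s1, s2, toy_space, n_reps=199, seed=0, R=40)
        assert d == pytest.approx(0.0, abs=0.01)
        assert p == pytest.approx(1 / 200)

    def test_equivalency_null_p_uniform(self, toy_space):
        rng = np.random.default_rng(15)
        ps = []
        for i in range(100):
            s1 = rng.standard_normal((25, 2)) * 0.5
            s2 = rng.standard_normal((25, 2)) * 0.5
            _, p = equivalency_test(s1, s2, toy_space, n_reps=49, seed=i, R=30)
            ps.append(p)
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_similarity_tight_cluster_significant_both_directions(self, toy_space):
        rng = np.random.default_rng(16)
        pts = rng.standard_normal((30, 2)) * 0.05
        res = overlap_tests(pts, pts.copy(), toy_space, n_reps=99, seed=3, R=40)
        assert res.schoener_d == pytest.approx(1.0, abs=1e-9)
        assert res.p_similarity_12 < 0.05
        assert res.p_similarity_21 < 0.05

    def test_background_occurrences_not_significant(self, toy_space):
        rng = np.random.default_rng(17)
        bg = toy_space.background_scores
        s1 = bg[rng.choice(len(bg), 40, replace=False)]
        s2 = bg[rng.choice(len(bg), 40, replace=False)]
        _, p = similarity_test(s1, s2, toy_space, n_reps=99, seed=5, direction=2, R=40)
        assert p > 0.05

    def test_direction_validated(self, toy_space):
        with pytest.raises(ValueError, match="direction"):
            similarity_test(np.zeros((3, 2)), np.zeros((3, 2)), toy_space, direction=3)


class TestLandArea:
    def cone(self):
        cfg = IslandConfig(nrows=120, ncols=120, noise_amp=0.0, seed=0)
        elevation, _ = simulate_island_rasters(cfg)
        return cfg, elevation

    def test_below_minimum_all_land(self):
        _, elev = self.cone()
        row = land_area(elev, -1000.0)
        assert row["n_cells"] == int(np.sum(~np.isnan(elev.values)))

    def test_above_peak_no_land(self):
        cfg, elev = self.cone()
        assert land_area(elev, cfg.peak_elev + 1)["n_cells"] == 0

    def test_baseline_percent_change_zero(self):
        _, elev = self.cone()
        assert land_area(elev, 0.0)["pct_change"] == 0.0

    def test_half_peak_matches_disc_and_brute_force(self):
        cfg, elev = self.cone()
        s = cfg.peak_elev / 2
        row = land_area(elev, s)
        # brute-force cell count oracle
        count = sum(
            1
            for r in range(elev.nrows)
            for c in range(elev.ncols)
            if not np.isnan(elev.values[r, c]) and elev.values[r, c] > s
        )
        assert row["n_cells"] == count
        assert row["n_cells"] == pytest.approx(np.pi * (cfg.radius_cells / 2) ** 2, rel=0.02)

    def test_monotone_over_sweep(self):
        _, elev = self.cone()
        curve = area_curve(elev, np.linspace(-200, 1600, 50))
        assert (np.diff(curve["n_cells"]) <= 0).all()
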