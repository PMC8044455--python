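import dataclasses
import math

import numpy as np
import pytest
import shapely
from shapely.ops import unary_union

from habqual.env import validate_ranges
from habqual.grids import GridSpec
from habqual.synth import (
    ConfigError,
    GradientSpec,
    ScenarioConfig,
    gen_concessions,
    gen_dataset,
    gen_env_stack,
    gen_fitness,
    gen_tree_locations,
    _union_area_ha,
)


class TestEnvGeneration:
    def test_values_inside_configured_ranges(self, default_dataset):
        env = default_dataset.env
        from habqual.env import ENV_RANGES

        for name, arr in env.layers.items():
            lo, hi = ENV_RANGES[name]
            assert arr.min() >= lo - 1e-9 and arr.max() <= hi + 1e-9

    def test_same_seed_identical(self):
        cfg = ScenarioConfig(seed=5)
        a = gen_env_stack(cfg)
        b = gen_env_stack(cfg)
        for name in a.names:
            np.testing.assert_array_equal(a.layers[name], b.layers[name])

    def test_correlation_target(self):
        grads = {
            "bio12": GradientSpec(kind="field", smoothness=3.0),
            "bio13": GradientSpec(kind="field", smoothness=3.0,
                                  correlate_with="bio12", rho=0.9),
        }
        cfg = ScenarioConfig(seed=9, gradients=grads)
        env = gen_env_stack(cfg)
        a = env.layers["bio12"].ravel()
        b = env.layers["bio13"].ravel()
        assert len(a) >= 10_000
        r = np.corrcoef(a, b)[0, 1]
        assert r == pytest.approx(0.9, abs=0.05)


class TestConcessions:
    def test_count_valid_disjoint(self):
        cfg = ScenarioConfig(seed=2)
        polys = gen_concessions(cfg)
        assert len(polys) == cfg.n_concessions
        geoms = list(polys.values())
        assert all(g.is_valid for g in geoms)
        for i in range(len(geoms)):
            for j in range(i + 1, len(geoms)):
                assert not geoms[i].intersection(geoms[j]).area > 0

    def test_mean_area_within_ten_percent(self):
        cfg = ScenarioConfig(seed=2)
        polys = gen_concessions(cfg)
        lat_c = (cfg.extent[1] + cfg.extent[3]) / 2
        areas = [_union_area_ha(g, lat_c) for g in polys.values()]
        assert np.mean(areas) == pytest.approx(cfg.concession_mean_area_ha, rel=0.10)

    def test_same_seed_identical(self):
        cfg = ScenarioConfig(seed=4)
        a, b = gen_concessions(cfg), gen_concessions(cfg)
        assert all(a[k].equals(b[k]) for k in a)


class TestTreeLocations:
    def test_count_oracle_homogeneous(self):
        """Realized count matches lambda_parent * area * offspring_mean within
        3 sd of the compound-Poisson count law (var = N * (1 + mu_kids))."""
        cfg = ScenarioConfig(seed=6, density_beta={}, thinning_strength=0.0)
        env = gen_env_stack(cfg)
        polys = gen_concessions(cfg)
        pts = gen_tree_locations(cfg, env, polys)
        union = unary_union(list(polys.values()))
        area_km2 = _union_area_ha(union, union.centroid.y) / 100
        expected = cfg.parent_intensity_km2 * area_km2 * cfg.offspring_mean
        sd = math.sqrt(expected * (1 + cfg.offspring_mean))
        assert abs(len(pts) - expected) < 3 * sd

    def test_every_tree_inside_a_concession(self, default_dataset):
        polys = default_dataset.concessions
        union = unary_union(list(polys.values()))
        rec = default_dataset.records
        inside = shapely.contains_xy(union, rec["lon"].to_numpy(),
                                     rec["lat"].to_numpy())
        assert inside.all()
        assert rec["concession_id"].notna().all()

    def test_thinning_reduces_clustering(self):
        """CNDDD thinning removes close conspecifics, raising the mean
        per-cell aggregation index (same location seed stream)."""
        from habqual.aggregation import aggregation_map
        from habqual.grids import rasterize

        def mean_R(strength):
            cfg = ScenarioConfig(seed=21, thinning_strength=strength,
                                 dispersal_sigma_m=25.0)
            ds = gen_dataset(cfg)
            cells, _ = rasterize(ds.records, GridSpec(), ds.concessions)
            out = aggregation_map(ds.records, cells, GridSpec())
            return np.nanmean(out["aggregation"])

        assert mean_R(0.8) > mean_R(0.0)

    def test_degenerate_dispersal_collapses_to_parents(self):
        cfg = ScenarioConfig(seed=13, dispersal_sigma_m=1e-9, offspring_mean=1.0)
        env = gen_env_stack(cfg)
        polys = gen_concessions(cfg)
        pts = gen_tree_locations(cfg, env, polys)
        # offspring sharing a parent are coincident at this dispersal scale
        for _, grp in pts.groupby("parent"):
            assert grp["lon"].std(ddof=0) < 1e-7
            assert grp["lat"].std(ddof=0) < 1e-7

    def test_refuses_absurd_expected_count(self):
        cfg = ScenarioConfig(seed=1, parent_intensity_km2=1e5,
                             offspring_mean=1000.0)
        env = gen_env_stack(cfg)
        polys = gen_concessions(cfg)
        with pytest.raises(ConfigError, match="1e6|exceeds"):
            gen_tree_locations(cfg, env, polys)


class TestFitness:
    def test_structural_zero_fraction(self):
        """Realized structural non-producer share within +-0.01 of the
        configured 13% at n = 10^4 (binomial MC bound)."""
        import pandas as pd

        cfg = ScenarioConfig(seed=8)
        env = gen_env_stack(cfg)
        rng = np.random.default_rng(88)
        n = 10_000
        pts = pd.DataFrame({
            "lon": rng.uniform(cfg.extent[0], cfg.extent[2], n),
            "lat": rng.uniform(cfg.extent[1], cfg.extent[3], n),
        })
        rec = gen_fitness(pts, env, cfg, rng)
        frac = rec["structural_zero"].mean()
        assert frac == pytest.approx(0.13, abs=0.01)
        # observed zeros include sampling zeros on top of the structural mass
        assert (rec["latas"] == 0).mean() >= frac

    def test_pi_zero_no_structural_zeros(self):
        import pandas as pd

        cfg = dataclasses.replace(ScenarioConfig(seed=8), zero_inflation=0.0)
        env = gen_env_stack(cfg)
        rng = np.random.default_rng(5)
        pts = pd.DataFrame({"lon": np.full(500, -69.7), "lat": np.full(500, -12.7)})
        rec = gen_fitness(pts, env, cfg, rng)
        assert not rec["structural_zero"].any()

    def test_marks_are_wellformed(self, default_dataset):
        rec = default_dataset.records
        assert (rec["dbh"] >= 10.0).all()
        assert (rec["latas"] >= 0).all()
        assert np.allclose(rec["latas"], np.round(rec["latas"]))


class TestDatasetContract:
    def test_same_seed_identical_dataset(self):
        a = gen_dataset(ScenarioConfig(seed=17))
        b = gen_dataset(ScenarioConfig(seed=17))
        assert a.records.equals(b.records)

    def test_fitness_config_does_not_perturb_locations(self):
        base = ScenarioConfig(seed=17)
        alt = dataclasses.replace(base, zero_inflation=0.5, sp_mean_latas=9.0)
        a, b = gen_dataset(base), gen_dataset(alt)
        np.testing.assert_array_equal(a.records["lon"], b.records["lon"])
        np.testing.assert_array_equal(a.records["lat"], b.records["lat"])

    def test_passes_inventory_and_range_validation(self, default_dataset, tmp_path):
        from habqual.inventory import read_inventory, write_inventory

        rec = default_dataset.records
        cols = ["tree_id", "concession_id", "lon", "lat", "dbh", "height",
                "latas", "phyto_flags"]
        path = tmp_path / "inv.csv"
        write_inventory(rec[cols], path)
        back = read_inventory(path)  # raises on any invariant violation
        assert len(back) == len(rec)

        env = default_dataset.env
        tab = env.sample_at(rec["lon"], rec["lat"])
        assert len(validate_ranges(tab)) == 0

    def test_ground_truth_echoes_config(self, default_dataset):
        gt = default_dataset.ground_truth
        assert gt["zero_inflation"] == 0.13
        assert gt["realized"]["n_trees"] == len(default_dataset.records)

    def test_writer_roundtrip(self, tmp_path, small_scenario):
        from habqual.inventory import read_concessions, read_inventory
        from habqual.synth import write_dataset

        ds = gen_dataset(small_scenario)
        write_dataset(ds, tmp_path / "world")
        inv = read_inventory(tmp_path / "world" / "inventory.csv")
        polys = read_concessions(tmp_path / "world" / "concessions.geojson")
        assert len(inv) == len(ds.records)
        assert set(polys) == set(ds.concessions)
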