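import math

import numpy as np
import pytest

from habqual.aggregation import (
    aggregation_index,
    aggregation_map,
    edge_filter,
    nn_distances,
    project_to_cell,
)
from habqual.grids import GridSpec

GRID = GridSpec()


def brute_force_nn(xy):
    xy = np.asarray(xy, float)
    out = np.empty(len(xy))
    for i in range(len(xy)):
        d = np.sqrt(((xy - xy[i]) ** 2).sum(axis=1))
        d[i] = np.inf
        out[i] = d.min()
    return out


def haversine_m(lon1, lat1, lon2, lat2, R=6_371_000.0):
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    dp = p2 - p1
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * R * math.asin(math.sqrt(a))


class TestNNDistances:
    def test_two_points_symmetric_distance(self):
        xy = np.array([[0.0, 0.0], [100.0, 0.0]])
        np.testing.assert_allclose(nn_distances(xy), [100.0, 100.0])

    def test_single_point_undefined(self):
        assert nn_distances(np.array([[5.0, 5.0]])) is None

    def test_matches_brute_force(self, rng):
        xy = rng.random((30, 2)) * 200
        np.testing.assert_allclose(nn_distances(xy), brute_force_nn(xy))

    def test_projected_distance_matches_haversine(self):
        # two points ~100 m apart in geographic coordinates at 12.5 S
        cell = GRID.cell_of(-69.5, -12.5)
        w, s, _, _ = GRID.cell_bounds(*cell)
        lon = np.array([w + 0.0002, w + 0.0002 + 0.001 / 1.09])
        lat = np.array([s + 0.0005, s + 0.0005])
        xy, _ = project_to_cell(lon, lat, cell, GRID)
        d_proj = nn_distances(xy)[0]
        d_hav = haversine_m(lon[0], lat[0], lon[1], lat[1])
        assert d_proj == pytest.approx(d_hav, rel=1e-3)


class TestEdgeFilter:
    def test_point_near_edge_excluded(self):
        # point 1 m from edge whose NN is 5 m away
        xy = np.array([[1.0, 50.0], [6.0, 50.0], [50.0, 50.0]])
        keep = edge_filter(xy, (0, 0, 100, 100))
        assert not keep[0]

    def test_interior_pair_retained(self):
        xy = np.array([[495.0, 500.0], [505.0, 500.0]])
        keep = edge_filter(xy, (0, 0, 1000, 1000))
        assert keep.all()

    def test_matches_brute_force_rule(self, rng):
        for _ in range(20):
            xy = rng.random((20, 2)) * 232
            keep = edge_filter(xy, (0, 0, 232, 232))
            nn = brute_force_nn(xy)
            edge = np.minimum(
                np.minimum(xy[:, 0], 232 - xy[:, 0]),
                np.minimum(xy[:, 1], 232 - xy[:, 1]),
            )
            np.testing.assert_array_equal(keep, edge >= nn)


class TestAggregationIndex:
    def test_coincident_points_zero(self):
        xy = np.tile([[50.0, 50.0]], (5, 1))
        res = aggregation_index(xy, (0, 0, 100, 100))
        assert res.R == 0.0

    def test_lattice_index_two(self):
        # 10x10 lattice, spacing s, centred in a cell of area n*s^2:
        # observed mean NN = s, expected = s/2 -> R = 2
        s = 10.0
        gx, gy = np.meshgrid(np.arange(10), np.arange(10))
        xy = np.column_stack([gx.ravel() * s, gy.ravel() * s]) + 5.0
        res = aggregation_index(xy, (0, 0, 100.0, 100.0))
        assert res.R == pytest.approx(2.0, abs=1e-9)
        assert res.mean_nn_m == pytest.approx(s)

    def test_too_few_retained_is_absent(self):
        xy = np.array([[1.0, 1.0], [230.0, 230.0]])  # both closer to edges than NN
        assert aggregation_index(xy, (0, 0, 232, 232)) is None

    def test_zero_area_rejected(self):
        xy = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError):
            aggregation_index(xy, (0, 0, 10, 10), cell_area_m2=0.0)

    def test_scale_invariance(self, rng):
        xy = rng.random((40, 2)) * 232
        r1 = aggregation_index(xy, (0, 0, 232, 232))
        r2 = aggregation_index(xy * 3.0, (0, 0, 696, 696))
        assert r1.R == pytest.approx(r2.R)
        assert r1.n_retained == r2.n_retained

    def test_ordering_clustered_csr_lattice(self, rng):
        """Thomas clusters < CSR < lattice in mean index, matched n/area."""
        side = 232.0

        def mean_R(gen, reps=150):
            vals = []
            for _ in range(reps):
                xy = gen()
                res = aggregation_index(xy, (0, 0, side, side))
                if res is not None:
                    vals.append(res.R)
            return float(np.mean(vals))

        def csr():
            return rng.random((49, 2)) * side

        def thomas():
            parents = rng.random((7, 2)) * side
            xy = parents[rng.integers(0, 7, 49)] + rng.normal(0, 8, (49, 2))
            return np.clip(xy, 0, side)

        def lattice():
            g = np.arange(7) * side / 7 + side / 14
            gx, gy = np.meshgrid(g, g)
            return np.column_stack([gx.ravel(), gy.ravel()])

        m_th, m_csr, m_lat = mean_R(thomas), mean_R(csr), mean_R(lattice)
        assert m_th < m_csr < m_lat

    def test_lambda_from_retained_flag(self, rng):
        xy = rng.random((50, 2)) * 232
        r_all = aggregation_index(xy, (0, 0, 232, 232), lambda_from="all")
        r_ret = aggregation_index(xy, (0, 0, 232, 232), lambda_from="retained")
        if r_all.n_retained < r_all.n_points:
            assert r_ret.R < r_all.R  # fewer points -> larger expected distance

    def test_plain_weighting_lower_than_hanisch_under_csr(self, rng):
        vals = []
        for _ in range(200):
            xy = rng.random((50, 2)) * 232
            h = aggregation_index(xy, (0, 0, 232, 232), weighting="hanisch")
            p = aggregation_index(xy, (0, 0, 232, 232), weighting="plain")
            if h and p:
                vals.append(h.R - p.R)
        assert np.mean(vals) > 0  # plain retained mean is biased low


class TestAggregationMap:
    def test_single_tree_cell_absent(self, default_dataset):
        from habqual.grids import rasterize

        rec = default_dataset.records
        cells, _ = rasterize(rec, GRID, default_dataset.concessions)
        out = aggregation_map(rec, cells, GRID)
        singles = out[out["n_trees"] == 1]
        assert singles["aggregation"].isna().all()

    def test_map_equals_percell_calls(self, default_dataset):
        from habqual.aggregation import aggregation_index, project_to_cell
        from habqual.grids import cell_area_ha, rasterize

        rec = default_dataset.records
        cells, _ = rasterize(rec, GRID, default_dataset.concessions)
        out = aggregation_map(rec, cells, GRID)
        ix, iy = GRID.cell_of(rec["lon"].to_numpy(), rec["lat"].to_numpy())
        checked = 0
        for row in out[out["aggregation"].notna()].head(10).itertuples():
            mask = (ix == row.ix) & (iy == row.iy)
            xy, bounds = project_to_cell(
                rec["lon"].to_numpy()[mask], rec["lat"].to_numpy()[mask],
                (row.ix, row.iy), GRID,
            )
            res = aggregation_index(
                xy, bounds, cell_area_m2=cell_area_ha(row.iy, GRID) * 1e4
            )
            assert res.R == pytest.approx(row.aggregation)
            checked += 1
        assert checked > 0

    def test_translation_equivariance(self, default_dataset):
        from habqual.grids import rasterize

        rec = default_dataset.records.copy()
        cells, _ = rasterize(rec, GRID, default_dataset.concessions)
        out1 = aggregation_map(rec, cells, GRID)

        shifted = rec.copy()
        shifted["lon"] = shifted["lon"] + GRID.step  # one full cell east
        cells_s = cells.copy()
        cells_s["ix"] = cells_s["ix"] + 1
        out2 = aggregation_map(shifted, cells_s, GRID)
        a, b = out1["aggregation"].to_numpy(), out2["aggregation"].to_numpy()
        ok = ~np.isnan(a)
        np.testing.assert_array_equal(ok, ~np.isnan(b))
        np.testing.assert_allclose(a[ok], b[ok], rtol=1e-9)
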