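"""Landmask, overland distances (vs networkx oracle), correlation surface."""

import numpy as np
import pandas as pd
import pytest

from hubseek.errors import HubseekError
from hubseek.focal import (
    Raster,
    build_landmask,
    focal_correlation_surface,
    haversine_km,
    identify_focal_area,
    overland_distance,
    read_ascii_grid,
    snap_to_land,
    write_ascii_grid,
)


def raster(values, cellsize=1.0, xll=10.0, yll=40.0):
    return Raster(values=np.asarray(values, dtype=float), xllcorner=xll,
                  yllcorner=yll, cellsize=cellsize)


def all_land(nrows, ncols, **kw):
    return raster(np.ones((nrows, ncols)), **kw)


class TestLandmask:
    def test_sign_map_at_zero_offset(self):
        elev = raster([[10.0, -5.0], [-1.0, 3.0]])
        mask = build_landmask(elev, 0.0)
        assert mask.values.tolist() == [[1.0, 0.0], [0.0, 1.0]]

    def test_glacial_lowstand_exposes_shelf(self):
        elev = raster([[-50.0, -130.0], [-119.0, 5.0]])
        mask = build_landmask(elev, -120.0)
        assert mask.values.sum() == 3  # the -130 m cell stays sea

    def test_all_ocean_warns(self):
        elev = raster([[-10.0, -20.0]])
        with pytest.warns(UserWarning, match="empty"):
            mask = build_landmask(elev, 0.0)
        assert mask.values.sum() == 0


class TestAsciiGrid:
    def test_roundtrip(self, tmp_path):
        r = raster([[1.0, 2.5], [np.nan, 4.0]])
        write_ascii_grid(r, tmp_path / "g.asc")
        back = read_ascii_grid(tmp_path / "g.asc")
        assert back.cellsize == 1.0 and back.xllcorner == 10.0
        assert back.values[0, 1] == 2.5
        assert back.values[1, 0] == back.nodata


class TestOverlandDistance:
    def test_origin_equals_target_is_zero(self):
        mask = all_land(5, 5)
        assert overland_distance(mask, (2, 2), [(2, 2)])[0] == 0.0

    def test_straight_corridor_close_to_great_circle(self):
        mask = all_land(1, 8)
        d = overland_distance(mask, (0, 0), [(0, 7)])[0]
        lon0, lat0 = mask.cell_center(0, 0)
        lon1, lat1 = mask.cell_center(0, 7)
        gc = haversine_km(lon0, lat0, lon1, lat1)
        # grid path follows the parallel, not the true great circle: agree
        # within one cell diagonal
        diag = haversine_km(lon0, lat0, lon0 + 1, lat0 + 1)
        assert gc <= d <= gc + diag

    def test_sea_origin_rejected(self):
        mask = raster([[0.0, 1.0]])
        with pytest.raises(HubseekError, match="origin"):
            overland_distance(mask, (0, 0), [(0, 1)], snap_targets=False)

    def test_unreachable_target_is_infinite(self):
        mask = raster([[1.0, 0.0, 1.0]])
        d = overland_distance(mask, (0, 0), [(0, 2)], snap_targets=False)
        assert np.isinf(d[0])

    def test_u_shaped_barrier_matches_networkx_oracle(self):
        mask = np.ones((20, 20))
        mask[3:17, 10] = 0  # vertical wall with a gap at top and bottom
        m = raster(mask)
        got = overland_distance(m, (10, 5), [(10, 15)], snap_targets=False)[0]
        assert got == pytest.approx(_networkx_distance(m, (10, 5), (10, 15)))
        # the wall forces a detour well beyond the straight-line distance
        lon0, lat0 = m.cell_center(10, 5)
        lon1, lat1 = m.cell_center(10, 15)
        assert got > 1.5 * haversine_km(lon0, lat0, lon1, lat1)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_masks_match_networkx_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = (rng.random((12, 12)) > 0.35).astype(float)
        mask[0, 0] = 1
        m = raster(mask)
        land_cells = [tuple(ij) for ij in np.argwhere(mask > 0)][:8]
        got = overland_distance(m, (0, 0), land_cells, snap_targets=False)
        for cell, d in zip(land_cells, got):
            assert d == pytest.approx(_networkx_distance(m, (0, 0), cell))

    @pytest.mark.parametrize("seed", range(5))
    def test_metric_properties_on_random_masks(self, seed):
        rng = np.random.default_rng(100 + seed)
        mask = (rng.random((10, 10)) > 0.3).astype(float)
        m = raster(mask)
        land = [tuple(ij) for ij in np.argwhere(mask > 0)]
        pts = [land[i] for i in rng.choice(len(land), size=3, replace=False)]
        a, b, c = pts
        d_ab = overland_distance(m, a, [b], snap_targets=False)[0]
        d_ba = overland_distance(m, b, [a], snap_targets=False)[0]
        d_ac = overland_distance(m, a, [c], snap_targets=False)[0]
        d_cb = overland_distance(m, c, [b], snap_targets=False)[0]
        assert d_ab == pytest.approx(d_ba)  # symmetry
        if np.isfinite(d_ac) and np.isfinite(d_cb):
            assert d_ab <= d_ac + d_cb + 1e-9  # triangle inequality


def _networkx_distance(mask: Raster, a, b):
    import networkx as nx

    from hubseek.focal import _NEIGHBOURS

    land = mask.values > 0
    G = nx.Graph()
    nrows, ncols = land.shape
    for r in range(nrows):
        for c in range(ncols):
            if not land[r, c]:
                continue
            for dr, dc in _NEIGHBOURS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols and land[rr, cc]:
                    lon0, lat0 = mask.cell_center(r, c)
                    lon1, lat1 = mask.cell_center(rr, cc)
                    G.add_edge((r, c), (rr, cc),
                               weight=float(haversine_km(lon0, lat0, lon1, lat1)))
    try:
        return nx.dijkstra_path_length(G, a, b)
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return np.inf


class TestSnap:
    def test_within_tolerance(self):
        mask = raster([[0.0, 0.0, 1.0]])
        assert snap_to_land(mask, 0, 0, tolerance=3) == (0, 2)

    def test_beyond_tolerance_errors(self):
        mask = raster([[0.0, 0.0, 0.0, 0.0, 1.0]])
        with pytest.raises(HubseekError, match="snapped"):
            snap_to_land(mask, 0, 0, tolerance=3)


class TestCorrelationSurface:
    def _chain_locations(self, mask, source, n=8):
        """Locations along a row, value strictly decreasing with distance."""
        cells = [(source[0], c) for c in range(0, mask.shape[1], 2)][:n]
        d = overland_distance(mask, source, cells)
        rows = []
        for k, ((r, c), dist) in enumerate(zip(cells, d)):
            lon, lat = mask.cell_center(r, c)
            rows.append({"population": f"p{k}", "lon": lon, "lat": lat,
                         "value": 1.0 - 1e-4 * dist})
        return pd.DataFrame(rows)

    def test_perfect_anticorrelation_at_source(self):
        mask = all_land(3, 12)
        source = (1, 0)
        locs = self._chain_locations(mask, source)
        surf = focal_correlation_surface(locs, mask, radius_km=1e6)
        assert surf.r.values[source] == pytest.approx(-1.0, abs=1e-9)

    def test_constant_values_raise(self):
        mask = all_land(3, 6)
        locs = self._chain_locations(mask, (1, 0))
        locs["value"] = 0.5
        with pytest.raises(HubseekError, match="zero variance"):
            focal_correlation_surface(locs, mask)

    def test_fewer_than_three_locations_rejected(self):
        mask = all_land(3, 6)
        locs = self._chain_locations(mask, (1, 0)).iloc[:2]
        with pytest.raises(HubseekError, match="at least 3"):
            focal_correlation_surface(locs, mask)

    def test_matches_bruteforce_pearson(self):
        rng = np.random.default_rng(3)
        mask = all_land(6, 9)
        cells = [(int(r), int(c)) for r, c in
                 zip(rng.integers(0, 6, 5), rng.integers(0, 9, 5))]
        rows = []
        for k, (r, c) in enumerate(cells):
            lon, lat = mask.cell_center(r, c)
            rows.append({"population": f"p{k}", "lon": lon, "lat": lat,
                         "value": float(rng.random())})
        locs = pd.DataFrame(rows)
        surf = focal_correlation_surface(locs, mask, radius_km=1e6)
        for cell in [(0, 0), (3, 4), (5, 8)]:
            d = [overland_distance(mask, (r, c), [cell])[0] for r, c in cells]
            expected = np.corrcoef(d, locs["value"])[0, 1]
            assert surf.r.values[cell] == pytest.approx(expected, abs=1e-9)

    def test_radius_gate_masks_remote_cells(self):
        mask = all_land(1, 30)
        locs = self._chain_locations(mask, (0, 0), n=3)  # cols 0, 2, 4
        surf = focal_correlation_surface(locs, mask, radius_km=300.0)
        assert np.isnan(surf.r.values[0, 29])  # far cell has nobody in range
        assert np.isfinite(surf.r.values[0, 1])

    def test_negating_values_negates_r(self):
        mask = all_land(4, 7)
        locs = self._chain_locations(mask, (2, 0), n=4)
        surf = focal_correlation_surface(locs, mask, radius_km=1e6)
        neg = locs.copy()
        neg["value"] = -neg["value"]
        surf2 = focal_correlation_surface(neg, mask, radius_km=1e6)
        land = mask.values > 0
        assert np.allclose(surf.r.values[land], -surf2.r.values[land])

    def test_affine_invariance(self):
        mask = all_land(4, 7)
        locs = self._chain_locations(mask, (2, 0), n=4)
        surf = focal_correlation_surface(locs, mask, radius_km=1e6)
        scaled = locs.copy()
        scaled["value"] = 3.0 * scaled["value"] + 0.7
        surf2 = focal_correlation_surface(scaled, mask, radius_km=1e6)
        land = mask.values > 0
        assert np.allclose(surf.r.values[land], surf2.r.values[land])


class TestIdentifyFocalArea:
    def test_chain_argmin_at_source(self):
        mask = all_land(3, 12)
        source = (1, 0)
        cells = [(1, c) for c in range(0, 12, 2)]
        d = overland_distance(mask, source, cells)
        rows = []
        for k, ((r, c), dist) in enumerate(zip(cells, d)):
            lon, lat = mask.cell_center(r, c)
            rows.append({"population": f"p{k}", "lon": lon, "lat": lat,
                         "value": np.exp(-1e-4 * dist)})
        surf = focal_correlation_surface(pd.DataFrame(rows), mask, radius_km=1e6)
        _, argmin = identify_focal_area(surf, 0.05)
        assert argmin == source

    def test_quantile_one_returns_all_defined(self):
        mask = all_land(3, 8)
        cells = [(1, c) for c in (0, 3, 6)]
        rows = []
        for k, (r, c) in enumerate(cells):
            lon, lat = mask.cell_center(r, c)
            rows.append({"population": f"p{k}", "lon": lon, "lat": lat,
                         "value": float(k)})
        surf = focal_correlation_surface(pd.DataFrame(rows), mask, radius_km=1e6)
        cells_out, _ = identify_focal_area(surf, 1.0)
        assert len(cells_out) == int(np.isfinite(surf.r.values).sum())


def test_planted_radial_decay_recovers_source():
    """Parameter recovery: gradient cohorts point back at the planted cell."""
    from hubseek.synthetic import generate_fixture

    for seed in (0, 1, 2):
        import tempfile

        with tempfile.TemporaryDirectory() as tmp:
            truth = generate_fixture("gradient_cohort", tmp, seed=seed)
            locs = pd.read_csv(f"{tmp}/locations.tsv", sep="\t")
            mask = read_ascii_grid(f"{tmp}/landmask.asc")
            surf = focal_correlation_surface(locs, mask, radius_km=1e9)
            _, argmin = identify_focal_area(surf, 0.05)
            src = tuple(truth["source_cell"])
            assert max(abs(argmin[0] - src[0]), abs(argmin[1] - src[1])) <= 1
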