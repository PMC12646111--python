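"""D8 routing, catchment tracing, basins, flooding, zonal statistics."""

import numpy as np
import pytest

from conftest import brute_accumulation, random_dem
from resghg import delineation as dl
from resghg.errors import EmptyMask, NoRiver, NoWaterAtDam

# ---------------------------------------------------------------------------
# flow routing
# ---------------------------------------------------------------------------


class TestFlowRouting:
    def test_west_sloping_ramp(self):
        z = np.tile(np.arange(10, dtype=float), (6, 1))  # rises eastward
        d8 = dl.flow_directions(dl.ElevationGrid(z))
        # interior drains west (index 6 in N,NE,E,SE,S,SW,W,NW)
        assert (d8[:, 1:] == 6).all()
        assert (d8[:, 0] == dl.OUTLET).all()
        acc = dl.flow_accumulation(d8)
        assert (acc == np.tile(np.arange(10, 0, -1), (6, 1))).all()

    def test_single_cell(self):
        d8 = dl.flow_directions(dl.ElevationGrid(np.array([[5.0]])))
        assert d8[0, 0] == dl.OUTLET
        assert dl.flow_accumulation(d8)[0, 0] == 1

    def test_accumulation_matches_bfs_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            dem = random_dem(rng)
            d8 = dl.flow_directions(dem)
            acc = dl.flow_accumulation(d8)
            assert (acc == brute_accumulation(d8)).all()

    def test_conditioned_dem_single_outlet(self):
        rng = np.random.default_rng(5)
        dem = random_dem(rng, 20, 20)
        d8 = dl.flow_directions(dem)
        assert (d8 == dl.OUTLET).sum() == 1


class TestSnapDam:
    def test_on_river_stays(self):
        z = np.tile(np.arange(8, dtype=float), (8, 1))
        d8 = dl.flow_directions(dl.ElevationGrid(z))
        acc = dl.flow_accumulation(d8)
        site = dl.DamSite(row=3, col=0, dam_height=10.0)
        # (3, 0) is itself a maximal-accumulation river cell: snap is identity
        assert dl.snap_dam(site, acc, threshold=int(acc.max())) == (3, 0)

    def test_tie_broken_by_accumulation(self):
        acc = np.zeros((3, 5), dtype=int)
        acc[0, 1] = 5
        acc[2, 1] = 9  # equidistant from (1, 1)
        site = dl.DamSite(row=1, col=1, dam_height=10.0)
        assert dl.snap_dam(site, acc, threshold=5) == (2, 1)

    def test_exhaustive_nearest_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            acc = rng.integers(0, 20, size=(12, 14))
            thr = 10
            if not (acc >= thr).any():
                continue
            site = dl.DamSite(row=int(rng.integers(0, 12)),
                              col=int(rng.integers(0, 14)), dam_height=5.0)
            r, c = dl.snap_dam(site, acc, thr)
            d2 = (r - site.row) ** 2 + (c - site.col) ** 2
            rivers = np.argwhere(acc >= thr)
            best = ((rivers[:, 0] - site.row) ** 2
                    + (rivers[:, 1] - site.col) ** 2).min()
            assert d2 == best

    def test_no_river(self):
        with pytest.raises(NoRiver):
            dl.snap_dam(dl.DamSite(row=0, col=0, dam_height=1.0),
                        np.ones((4, 4), dtype=int), threshold=100)


class TestLocalCatchment:
    def test_ramp_outlet_catches_all(self):
        z = np.tile(np.arange(6, dtype=float), (4, 1))
        d8 = dl.flow_directions(dl.ElevationGrid(z))
        # the ramp has one outlet per row; each row is its own catchment
        mask = dl.local_catchment((2, 0), d8)
        assert mask[2].all() and mask.sum() == 6

    def test_headwater_singleton(self):
        z = np.tile(np.arange(6, dtype=float), (4, 1))
        d8 = dl.flow_directions(dl.ElevationGrid(z))
        assert dl.local_catchment((1, 5), d8).sum() == 1

    def test_matches_reverse_bfs_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            dem = random_dem(rng)
            d8 = dl.flow_directions(dem)
            point = (int(rng.integers(0, d8.shape[0])),
                     int(rng.integers(0, d8.shape[1])))
            mask = dl.local_catchment(point, d8)
            # oracle: a cell is in the catchment iff its downstream walk
            # passes through the point
            for r in range(d8.shape[0]):
                for c in range(d8.shape[1]):
                    cur, hit = (r, c), False
                    while cur is not None:
                        if cur == point:
                            hit = True
                            break
                        cur = dl.downstream_cell(cur[0], cur[1], d8)
                    assert mask[r, c] == hit


class TestBasins:
    def _chain(self):
        # linear chain: basin 0 (outlet, code 1) ... basin 3 (source, code 7)
        codes = {0: "1", 1: "3", 2: "5", 3: "7"}
        downstream = {0: None, 1: 0, 2: 1, 3: 2}
        return dl.BasinSet(codes=codes, downstream=downstream)

    def test_most_upstream_empty(self):
        assert dl.upstream_subbasins(3, self._chain()) == set()

    def test_chain_from_middle(self):
        assert dl.upstream_subbasins(1, self._chain()) == {2, 3}

    def test_random_trees_match_ancestor_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(3, 12))
            # random rooted tree; codes increase upstream along every path
            parent = {0: None}
            codes = {0: "1"}
            child_count = {0: 0}
            for i in range(1, n):
                p = int(rng.integers(0, i))
                parent[i] = p
                child_count[i] = 0
                child_count[p] += 1
                codes[i] = codes[p] + str(2 * child_count[p])
            basins = dl.BasinSet(codes=codes, downstream=parent)
            s0 = int(rng.integers(0, n))
            got = dl.upstream_subbasins(s0, basins)
            # oracle: exhaustive ancestor search on the drainage graph
            oracle = {i for i in range(n) if _drains_to(i, s0, parent) and i != s0}
            assert got == oracle

    def test_grid_basins_consistent_with_d8(self):
        rng = np.random.default_rng(4)
        dem = random_dem(rng, 20, 22)
        d8 = dl.flow_directions(dem)
        acc = dl.flow_accumulation(d8)
        basins = dl.pfafstetter_basins(d8, acc, levels=2)
        # codes unique, topology closed
        assert len(set(basins.codes.values())) == len(basins.codes)
        for b, ds in basins.downstream.items():
            assert ds is None or ds in basins.codes
        # upstream compilation equals exhaustive ancestor search
        for s0 in list(basins.codes)[:5]:
            got = dl.upstream_subbasins(s0, basins)
            oracle = {
                b for b in basins.codes
                if b != s0 and _drains_to(b, s0, basins.downstream)
            }
            assert got == oracle


def _drains_to(b, s0, downstream):
    cur = b
    while cur is not None:
        if cur == s0:
            return True
        cur = downstream[cur]
    return False


class TestFlooding:
    def test_fsl_below_base_empty(self):
        z = np.tile(np.arange(8, dtype=float), (8, 1)) * 10
        dem = dl.ElevationGrid(z)
        d8 = dl.flow_directions(dem)
        site = dl.DamSite(row=4, col=4, fsl=z[4, 4] - 5.0, dam_height=1.0,
                          buffer_height=0.0)
        with pytest.warns(UserWarning, match="below dam-base"):
            mask, _ = dl.flood_reservoir(dem, d8, site)
        assert not mask.any()

    def test_valley_floods_upstream(self):
        # valley floor at 100 sloping gently, ridges at 200
        z = np.full((7, 9), 200.0)
        z[3, :] = 100.0 + 0.1 * np.arange(9)
        dem = dl.ElevationGrid(z)
        d8 = dl.flow_directions(dem)
        site = dl.DamSite(row=3, col=0, fsl=101.0, dam_height=5.0)
        mask, _ = dl.flood_reservoir(dem, d8, site)
        assert mask[3].all()
        assert mask.sum() == 9

    def test_monotone_in_fsl(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            dem = random_dem(rng)
            d8 = dl.flow_directions(dem)
            r = int(rng.integers(0, dem.shape[0]))
            c = int(rng.integers(0, dem.shape[1]))
            base = dem.data[r, c]
            m1, _ = dl.flood_reservoir(
                dem, d8, dl.DamSite(row=r, col=c, fsl=base + 5, dam_height=1))
            m2, _ = dl.flood_reservoir(
                dem, d8, dl.DamSite(row=r, col=c, fsl=base + 15, dam_height=1))
            assert (m2 | m1 == m2).all()  # m1 subset of m2

    def test_reservoir_inside_catchment(self, small_fleet):
        for dam_id, res_mask in small_fleet.reservoir_masks.items():
            cat = small_fleet.catchment_masks[dam_id]
            assert not (res_mask & ~cat).any()


class TestExistingReservoir:
    def _setup(self):
        z = np.tile(np.arange(10, dtype=float), (6, 1))
        dem = dl.ElevationGrid(z)
        d8 = dl.flow_directions(dem)
        lc = np.full((6, 10), 1, dtype=int)
        return dem, d8, lc

    def test_blob_at_dam(self):
        dem, d8, lc = self._setup()
        lc[2, 3:7] = 0  # water along row 2
        site = dl.DamSite(row=2, col=3, dam_height=5.0)
        mask = dl.existing_reservoir(lc, site, d8)
        assert mask.sum() == 4 and mask[2, 3:7].all()

    def test_downstream_blob_excluded(self):
        dem, d8, lc = self._setup()
        lc[2, 4:6] = 0
        lc[2, 0:2] = 0  # downstream of the dam at col 4 (flow is westward)
        site = dl.DamSite(row=2, col=4, dam_height=5.0)
        mask = dl.existing_reservoir(lc, site, d8)
        assert mask[2, 4:6].all() and not mask[2, 0:2].any()

    def test_no_water(self):
        dem, d8, lc = self._setup()
        site = dl.DamSite(row=2, col=3, dam_height=5.0)
        with pytest.raises(NoWaterAtDam):
            dl.existing_reservoir(lc, site, d8)


class TestZonalParameters:
    def test_uniform_raster_mean(self):
        dem = dl.ElevationGrid(np.zeros((5, 5)), cellsize=100.0)
        mask = np.zeros((5, 5), dtype=bool)
        mask[1:3, 1:4] = True
        out = dl.zonal_parameters(mask, np.ones((5, 5), dtype=bool), dem,
                                  fsl=2.0, rasters={"t": np.full((5, 5), 7.0)})
        assert out["catchment_mean_t"] == 7.0
        assert out["mean_depth_m"] == 2.0

    def test_area_from_cellcount(self):
        dem = dl.ElevationGrid(np.zeros((5, 5)), cellsize=100.0)
        mask = np.zeros((5, 5), dtype=bool)
        mask.flat[:10] = True
        out = dl.zonal_parameters(mask, np.ones((5, 5), dtype=bool), dem,
                                  fsl=1.0, rasters={})
        assert out["reservoir_area_km2"] == pytest.approx(0.1)

    def test_matches_naive_loops(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            nr, nc = 8, 9
            dem = dl.ElevationGrid(rng.uniform(0, 50, (nr, nc)), cellsize=50.0)
            res = rng.random((nr, nc)) < 0.3
            cat = res | (rng.random((nr, nc)) < 0.5)
            if not res.any():
                res[2, 2] = cat[2, 2] = True
            raster = rng.normal(size=(nr, nc))
            fsl = float(dem.data.max() + 1)
            out = dl.zonal_parameters(res, cat, dem, fsl, {"x": raster},
                                      exclude_reservoir_from_catchment=False)
            # naive loops
            depths, vals = [], []
            for r in range(nr):
                for c in range(nc):
                    if res[r, c]:
                        depths.append(fsl - dem.data[r, c])
                    if cat[r, c]:
                        vals.append(raster[r, c])
            assert out["mean_depth_m"] == pytest.approx(np.mean(depths))
            assert out["volume_mm3"] == pytest.approx(sum(depths) * 2500 / 1e6)
            assert out["catchment_mean_x"] == pytest.approx(np.mean(vals))

    def test_empty_mask(self):
        dem = dl.ElevationGrid(np.zeros((3, 3)))
        with pytest.raises(EmptyMask):
            dl.zonal_parameters(np.zeros((3, 3), bool), np.zeros((3, 3), bool),
                                dem, 0.0, {})
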