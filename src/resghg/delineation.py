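"""Raster-scale catchment and reservoir delineation.

Steepest-descent D8 routing on an elevation grid, local-catchment tracing,
Pfafstetter-coded sub-basin compilation, full-supply-level (FSL) flooding of
planned reservoirs, extraction of existing reservoirs from land-cover water
pixels, and zonal parameter computation.

Conventions: grids are row/col indexed, 0-based, cell-centre registered.
D8 neighbours are ordered N, NE, E, SE, S, SW, W, NW and ties are broken in
that order, which makes every operation deterministic.  Flooding and water-
body extraction use 4-connectivity; flow routing uses 8-connectivity.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np

from .errors import AllMasked, BrokenTopology, EmptyMask, NoRiver, NoWaterAtDam

__all__ = [
    "ElevationGrid",
    "DamSite",
    "BasinSet",
    "D8_OFFSETS",
    "OUTLET",
    "NODATA",
    "flow_directions",
    "flow_accumulation",
    "snap_dam",
    "local_catchment",
    "upstream_subbasins",
    "pfafstetter_basins",
    "flood_reservoir",
    "existing_reservoir",
    "zonal_parameters",
    "condition_dem",
]

# neighbour order N, NE, E, SE, S, SW, W, NW
D8_OFFSETS = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
_D8_DIST = tuple(np.hypot(dr, dc) for dr, dc in D8_OFFSETS)

OUTLET = -1
NODATA = -2


@dataclass
class ElevationGrid:
    """Elevations (m) on a regular grid with cell size in metres.

    ``mask`` marks nodata cells (True = masked).  ``xll``/``yll`` georeference
    the lower-left corner for ESRI ASCII round-trips.
    """

    data: np.ndarray
    cellsize: float = 100.0
    mask: Optional[np.ndarray] = None
    xll: float = 0.0
    yll: float = 0.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("elevation grid must be 2-D")
        if self.mask is None:
            self.mask = ~np.isfinite(self.data)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if not np.all(np.isfinite(self.data[~self.mask])):
            raise ValueError("unmasked elevations must be finite")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape


@dataclass
class DamSite:
    """A dam location on the grid plus the heights defining its FSL.

    When ``fsl`` is absent it is derived as base elevation + dam_height -
    buffer_height (freeboard between FSL and crest)."""

    row: int
    col: int
    dam_height: float = 0.0
    buffer_height: float = 0.0
    fsl: Optional[float] = None
    res_type: str = "hydroelectric"
    id: str = ""

    def __post_init__(self):
        if self.fsl is None and not (self.dam_height > self.buffer_height >= 0):
            raise ValueError(
                "need dam_height > buffer_height >= 0 when fsl is not given"
            )


def _neighbors(r, c, shape):
    nr_, nc_ = shape
    for k, (dr, dc) in enumerate(D8_OFFSETS):
        rr, cc = r + dr, c + dc
        if 0 <= rr < nr_ and 0 <= cc < nc_:
            yield k, rr, cc


def flow_directions(dem: ElevationGrid) -> np.ndarray:
    """Steepest-descent D8 directions (index into ``D8_OFFSETS``).

    Cells with no strictly lower unmasked neighbour become outlets/pits
    (code ``OUTLET``); masked cells get ``NODATA``.  Equal gradients are
    broken by neighbour order.
    """
    z = dem.data
    masked = dem.mask
    if masked.all():
        raise AllMasked("elevation grid has no unmasked cells")
    nr, nc = z.shape
    d8 = np.full((nr, nc), NODATA, dtype=np.int8)
    for r in range(nr):
        for c in range(nc):
            if masked[r, c]:
                continue
            best_k, best_g = OUTLET, 0.0
            for k, rr, cc in _neighbors(r, c, (nr, nc)):
                if masked[rr, cc]:
                    continue
                g = (z[r, c] - z[rr, cc]) / _D8_DIST[k]
                if g > best_g + 0.0 and g > 0:
                    best_k, best_g = k, g
                elif g == best_g and g > 0 and best_k != OUTLET and k < best_k:
                    best_k = k
            d8[r, c] = best_k
    return d8


def downstream_cell(r: int, c: int, d8: np.ndarray):
    """The cell (row, col) that ``(r, c)`` drains to, or None for outlets."""
    code = d8[r, c]
    if code < 0:
        return None
    dr, dc = D8_OFFSETS[code]
    return r + dr, c + dc


def flow_accumulation(d8: np.ndarray) -> np.ndarray:
    """Upstream cell counts, including the cell itself (Kahn ordering)."""
    nr, nc = d8.shape
    acc = np.where(d8 >= NODATA + 1, 1, 0).astype(np.int64)
    acc[d8 == NODATA] = 0
    indeg = np.zeros((nr, nc), dtype=np.int32)
    for r in range(nr):
        for c in range(nc):
            ds = downstream_cell(r, c, d8)
            if ds is not None:
                indeg[ds] += 1
    queue = deque(
        (r, c) for r in range(nr) for c in range(nc)
        if d8[r, c] != NODATA and indeg[r, c] == 0
    )
    while queue:
        r, c = queue.popleft()
        ds = downstream_cell(r, c, d8)
        if ds is None:
            continue
        acc[ds] += acc[r, c]
        indeg[ds] -= 1
        if indeg[ds] == 0:
            queue.append(ds)
    return acc


def snap_dam(site: DamSite, acc: np.ndarray, threshold: int) -> Tuple[int, int]:
    """Snap a dam to the nearest river cell (accumulation >= threshold).

    Ties by Euclidean distance are broken by higher accumulation, then
    row-major order.
    """
    rivers = np.argwhere(acc >= threshold)
    if len(rivers) == 0:
        raise NoRiver(f"no cell reaches accumulation threshold {threshold}")
    d2 = (rivers[:, 0] - site.row) ** 2 + (rivers[:, 1] - site.col) ** 2
    a = acc[rivers[:, 0], rivers[:, 1]]
    # lexicographic: min distance, then max accumulation, then row-major
    order = np.lexsort((rivers[:, 1], rivers[:, 0], -a, d2))
    r, c = rivers[order[0]]
    return int(r), int(c)


def _upstream_adjacency(d8: np.ndarray):
    nr, nc = d8.shape
    ups: Dict[Tuple[int, int], list] = {}
    for r in range(nr):
        for c in range(nc):
            ds = downstream_cell(r, c, d8)
            if ds is not None:
                ups.setdefault(ds, []).append((r, c))
    return ups


def local_catchment(point: Tuple[int, int], d8: np.ndarray) -> np.ndarray:
    """Boolean mask of all cells whose D8 path reaches ``point`` (inclusive)."""
    nr, nc = d8.shape
    ups = _upstream_adjacency(d8)
    mask = np.zeros((nr, nc), dtype=bool)
    stack = [tuple(point)]
    mask[point[0], point[1]] = True
    while stack:
        cell = stack.pop()
        for up in ups.get(cell, ()):
            if not mask[up]:
                mask[up] = True
                stack.append(up)
    return mask


# ---------------------------------------------------------------------------
# Pfafstetter sub-basins
# ---------------------------------------------------------------------------

@dataclass
class BasinSet:
    """Sub-basins with Pfafstetter codes and downstream topology.

    ``codes`` maps basin id -> digit string; ``downstream`` maps basin id ->
    downstream basin id (None at the root).  ``grid`` optionally assigns a
    basin id to every cell (-1 outside).
    """

    codes: Dict[int, str]
    downstream: Dict[int, Optional[int]]
    grid: Optional[np.ndarray] = None
    level: int = field(default=0)

    def __post_init__(self):
        if not self.level and self.codes:
            self.level = max(len(c) for c in self.codes.values())
        by_len: Dict[int, set] = {}
        for code in self.codes.values():
            by_len.setdefault(len(code), set())
            if code in by_len[len(code)]:
                raise ValueError(f"duplicate Pfafstetter code {code!r}")
            by_len[len(code)].add(code)

    def basin_of(self, r: int, c: int) -> int:
        if self.grid is None:
            raise ValueError("basin set has no grid")
        return int(self.grid[r, c])


def _pfaf_compare(a: str, b: str) -> int:
    """Pfafstetter order: -1 if a is downstream of b, +1 upstream, 0 equal.

    Equal-length codes compare as integers (lower number = downstream).
    Unequal lengths compare hierarchically digit by digit; a code that is a
    prefix of the other is treated as containing it (returned equal).
    """
    for da, db in zip(a, b):
        if da != db:
            return -1 if da < db else 1
    return 0


def upstream_subbasins(s0: int, basins: BasinSet):
    """Ids of sub-basins upstream of ``s0`` (excluded), per the code rules.

    The region of interest is the coarsest enclosing unit that still contains
    everything draining to ``s0`` — here the longest code prefix of ``s0``
    shared by all its topological ancestors.  Within the ROI, basins with a
    Pfafstetter code number lower than ``s0``'s (i.e. downstream) are
    discarded, and the survivors are confirmed by an upstream traversal of
    the downstream-neighbour topology; anything not reached is dropped.
    """
    if s0 not in basins.codes:
        raise KeyError(f"unknown basin id {s0}")
    code0 = basins.codes[s0]

    # upstream adjacency from the downstream links
    ups: Dict[int, list] = {}
    for b, ds in basins.downstream.items():
        if ds is not None:
            if ds not in basins.codes:
                raise BrokenTopology(f"basin {b} drains to unknown basin {ds}")
            ups.setdefault(ds, []).append(b)

    # exhaustive ancestors (used to pick the ROI prefix)
    ancestors = set()
    stack = [s0]
    while stack:
        b = stack.pop()
        for up in ups.get(b, ()):
            if up not in ancestors:
                ancestors.add(up)
                stack.append(up)

    roi_prefix = ""
    for plen in range(len(code0), 0, -1):
        p = code0[:plen]
        if all(basins.codes[a].startswith(p) for a in ancestors):
            roi_prefix = p
            break

    roi = {b for b, code in basins.codes.items() if code.startswith(roi_prefix)}
    kept = {
        b for b in roi
        if b == s0 or _pfaf_compare(basins.codes[b], code0) >= 0
    }

    # upstream traversal restricted to the kept set
    reached = set()
    stack = [s0]
    while stack:
        b = stack.pop()
        for up in ups.get(b, ()):
            if up in kept and up not in reached:
                reached.add(up)
                stack.append(up)
    return reached


def _main_stem(outlet, cells, d8, acc):
    """Trace the main stem upstream from the outlet by max accumulation."""
    ups = {}
    for cell in cells:
        ds = downstream_cell(cell[0], cell[1], d8)
        if ds is not None and ds in cells:
            ups.setdefault(ds, []).append(cell)
    stem = [outlet]
    cur = outlet
    while True:
        cands = ups.get(cur, [])
        if not cands:
            break
        cur = max(cands, key=lambda cc: (acc[cc], -cc[0], -cc[1]))
        stem.append(cur)
    return stem, ups


def pfafstetter_basins(d8: np.ndarray, acc: np.ndarray, levels: int = 2,
                       min_cells: int = 1) -> BasinSet:
    """Generate Pfafstetter-coded sub-basins for the largest drainage system.

    Standard digit scheme per level: the four largest tributaries of the
    main stem take even digits 2/4/6/8 (downstream to upstream) and the five
    interbasins between them odd digits 1/3/5/7/9.  Units recurse until
    ``levels`` or until they have no internal junction.
    """
    outlets = [tuple(x) for x in np.argwhere(d8 == OUTLET)]
    if not outlets:
        raise AllMasked("no outlet cell in the D8 grid")
    outlet = max(outlets, key=lambda cc: (acc[cc], -cc[0], -cc[1]))
    catch = local_catchment(outlet, d8)
    cells = {tuple(x) for x in np.argwhere(catch)}

    grid = np.full(d8.shape, -1, dtype=np.int64)
    codes: Dict[int, str] = {}
    downstream: Dict[int, Optional[int]] = {}
    next_id = [0]

    def assign(unit_cells, code):
        bid = next_id[0]
        next_id[0] += 1
        codes[bid] = code
        for r, c in unit_cells:
            grid[r, c] = bid
        return bid

    def subdivide(unit_cells, unit_outlet, code, depth):
        if depth >= levels or len(unit_cells) <= min_cells:
            assign(unit_cells, code)
            return
        stem, ups = _main_stem(unit_outlet, unit_cells, d8, acc)
        stem_set = set(stem)
        # tributary entry cells: upstream neighbours of stem cells not on stem
        juncs = []  # (stem index, entry cell)
        for i, sc in enumerate(stem):
            for up in ups.get(sc, ()):
                if up not in stem_set:
                    juncs.append((i, up))
        if not juncs:
            assign(unit_cells, code)
            return
        juncs.sort(key=lambda t: (-acc[t[1]], t[0]))
        tribs = sorted(juncs[:4], key=lambda t: t[0])  # downstream -> upstream

        # tributary catchments (within the unit)
        trib_cells = []
        for _, entry in tribs:
            tc = {cell for cell in _trace_up(entry, ups)}
            trib_cells.append(tc)
        claimed = set().union(*trib_cells) if trib_cells else set()

        # interbasins split along the stem just *above* each junction cell:
        # the confluence cell itself drains the tributary, so it belongs to
        # the downstream interbasin (keeps "lower code = downstream" exact)
        cuts = [i + 1 for i, _ in tribs]
        segments = []
        bounds = [0] + cuts + [len(stem)]
        for si in range(len(bounds) - 1):
            lo, hi = bounds[si], bounds[si + 1]
            segments.append(set(stem[lo:hi]))
        # assign every unclaimed cell to the interbasin whose stem segment
        # its flow path first meets
        seg_of_stem = {}
        for si, seg in enumerate(segments):
            for cell in seg:
                seg_of_stem[cell] = si
        inter = [set(seg) for seg in segments]
        for cell in unit_cells:
            if cell in claimed or cell in stem_set:
                continue
            cur = cell
            while cur not in seg_of_stem and cur in unit_cells:
                nxt = downstream_cell(cur[0], cur[1], d8)
                if nxt is None or nxt not in unit_cells:
                    break
                cur = nxt
                if cur in claimed:
                    break
            si = seg_of_stem.get(cur)
            if si is not None:
                inter[si].add(cell)
            elif cur in claimed:
                # drains through a tributary: attach to that tributary
                for tc in trib_cells:
                    if cur in tc:
                        tc.add(cell)
                        break

        units = []  # (digit, cells, outlet)
        for si, ib in enumerate(inter):
            if ib:
                units.append((str(2 * si + 1), ib, stem[bounds[si]]))
        for ti, ((idx, entry), tc) in enumerate(zip(tribs, trib_cells)):
            units.append((str(2 * (ti + 1)), tc, entry))
        for digit, ucells, uoutlet in units:
            subdivide(ucells, uoutlet, code + digit, depth + 1)

    def _trace_up(entry, ups):
        out = {entry}
        stack = [entry]
        while stack:
            cur = stack.pop()
            for up in ups.get(cur, ()):
                if up not in out:
                    out.add(up)
                    stack.append(up)
        return out

    subdivide(cells, outlet, "", 0)

    # downstream links: follow the basin-outlet cell's flow path out of the basin
    cells_by_basin: Dict[int, list] = {}
    for r, c in cells:
        cells_by_basin.setdefault(int(grid[r, c]), []).append((r, c))
    for bid, bcells in cells_by_basin.items():
        bset = set(bcells)
        ds_id = None
        # the basin outlet is its cell with maximal accumulation
        start = max(bcells, key=lambda cc: (acc[cc], -cc[0], -cc[1]))
        cur = start
        while True:
            nxt = downstream_cell(cur[0], cur[1], d8)
            if nxt is None:
                break
            if nxt not in bset:
                ds_id = int(grid[nxt]) if grid[nxt] >= 0 else None
                break
            cur = nxt
        downstream[bid] = ds_id

    return BasinSet(codes=codes, downstream=downstream, grid=grid)


# ---------------------------------------------------------------------------
# flooding / existing reservoirs / zonal statistics
# ---------------------------------------------------------------------------

def _flood_fill_4(seed, allowed: np.ndarray) -> np.ndarray:
    """4-connected flood fill from ``seed`` within the ``allowed`` mask."""
    nr, nc = allowed.shape
    out = np.zeros_like(allowed, dtype=bool)
    if not allowed[seed]:
        return out
    stack = [seed]
    out[seed] = True
    while stack:
        r, c = stack.pop()
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < nr and 0 <= cc < nc and allowed[rr, cc] and not out[rr, cc]:
                out[rr, cc] = True
                stack.append((rr, cc))
    return out


def flood_reservoir(
    dem: ElevationGrid, d8: np.ndarray, site: DamSite,
    catchment: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, float]:
    """Flood a planned reservoir behind a snapped dam; returns (mask, FSL).

    The mask contains cells 4-connected to the dam cell with elevation <=
    FSL, restricted to the dam's upstream catchment so nothing downstream of
    the dam floods.  An FSL below the base elevation yields an empty mask
    with a warning.
    """
    base = dem.data[site.row, site.col]
    fsl = site.fsl if site.fsl is not None else base + site.dam_height - site.buffer_height
    if fsl < base:
        warnings.warn(
            f"FSL {fsl} below dam-base elevation {base}; empty reservoir",
            stacklevel=2,
        )
        return np.zeros(dem.shape, dtype=bool), float(fsl)
    if catchment is None:
        catchment = local_catchment((site.row, site.col), d8)
    allowed = (dem.data <= fsl) & catchment & ~dem.mask
    mask = _flood_fill_4((site.row, site.col), allowed)
    return mask, float(fsl)


def existing_reservoir(
    landcover: np.ndarray, site: DamSite, d8: np.ndarray,
    water_class: int = 0, catchment: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Contiguous water-class region at/adjacent to the dam, upstream side."""
    if catchment is None:
        catchment = local_catchment((site.row, site.col), d8)
    water = np.asarray(landcover) == water_class
    seeds = [(site.row, site.col)]
    nr, nc = water.shape
    for rr, cc in (
        (site.row - 1, site.col), (site.row + 1, site.col),
        (site.row, site.col - 1), (site.row, site.col + 1),
    ):
        if 0 <= rr < nr and 0 <= cc < nc:
            seeds.append((rr, cc))
    for seed in seeds:
        if water[seed] and catchment[seed]:
            return _flood_fill_4(seed, water & catchment)
    raise NoWaterAtDam(
        f"no water pixel (class {water_class}) at or adjacent to dam "
        f"({site.row}, {site.col}) on the upstream side"
    )


def zonal_parameters(
    reservoir_mask: np.ndarray,
    catchment_mask: np.ndarray,
    dem: ElevationGrid,
    fsl: float,
    rasters: Mapping[str, np.ndarray],
    landcover: Optional[np.ndarray] = None,
    landcover_classes: Optional[Mapping[int, str]] = None,
    exclude_reservoir_from_catchment: bool = True,
) -> dict:
    """Zonal statistics over the reservoir and catchment masks.

    Returns a flat dict: reservoir area (km2), mean depth (m, mean of FSL
    minus elevation), volume (Mm3), land-cover fractions inside the
    reservoir; catchment area, means of every raster in ``rasters`` over the
    catchment (minus the reservoir by default), and catchment land-cover
    fractions.
    """
    res_n = int(reservoir_mask.sum())
    cat_n = int(catchment_mask.sum())
    if cat_n == 0:
        raise EmptyMask("catchment mask is empty")
    cell_area_m2 = dem.cellsize ** 2

    out = {
        "reservoir_area_km2": res_n * cell_area_m2 / 1e6,
        "catchment_area_km2": cat_n * cell_area_m2 / 1e6,
    }
    if res_n:
        depth = fsl - dem.data[reservoir_mask]
        out["mean_depth_m"] = float(depth.mean())
        out["volume_mm3"] = float(depth.sum() * cell_area_m2 / 1e6)
    else:
        out["mean_depth_m"] = 0.0
        out["volume_mm3"] = 0.0

    stat_mask = catchment_mask
    if exclude_reservoir_from_catchment:
        stat_mask = catchment_mask & ~reservoir_mask
        if not stat_mask.any():
            stat_mask = catchment_mask
    for name, raster in rasters.items():
        out[f"catchment_mean_{name}"] = float(np.asarray(raster)[stat_mask].mean())

    if landcover is not None and landcover_classes:
        lc = np.asarray(landcover)
        for mask, prefix, n in (
            (reservoir_mask, "reservoir", res_n),
            (stat_mask, "catchment", int(stat_mask.sum())),
        ):
            for value, cls in landcover_classes.items():
                frac = float((lc[mask] == value).sum() / n) if n else 0.0
                out[f"{prefix}_{cls}_fraction"] = frac
    return out


def condition_dem(dem: ElevationGrid, outlet: Optional[Tuple[int, int]] = None,
                  epsilon: float = 1e-4) -> ElevationGrid:
    """Hydrologically condition a DEM by priority-flood from a single outlet.

    Raises every cell to at least its pour-path elevation plus a tiny
    increment so that each cell has a strictly descending D8 path to the
    outlet (the grid's minimum boundary cell by default).  Used by the
    synthetic landscape generator; real conditioned DEMs can be supplied
    directly.
    """
    import heapq

    z = dem.data.copy()
    masked = dem.mask
    nr, nc = z.shape
    if masked.all():
        raise AllMasked("elevation grid has no unmasked cells")
    if outlet is None:
        boundary = [
            (r, c)
            for r in range(nr) for c in range(nc)
            if not masked[r, c] and (r in (0, nr - 1) or c in (0, nc - 1))
        ]
        outlet = min(boundary, key=lambda cc: (z[cc], cc))
    out = np.full((nr, nc), np.inf)
    out[outlet] = z[outlet]
    heap = [(z[outlet], outlet)]
    visited = np.zeros((nr, nc), dtype=bool)
    while heap:
        elev, (r, c) = heapq.heappop(heap)
        if visited[r, c]:
            continue
        visited[r, c] = True
        for _, rr, cc in _neighbors(r, c, (nr, nc)):
            if masked[rr, cc] or visited[rr, cc]:
                continue
            cand = max(z[rr, cc], elev + epsilon)
            if cand < out[rr, cc]:
                out[rr, cc] = cand
                heapq.heappush(heap, (cand, (rr, cc)))
    out[masked] = z[masked]
    return ElevationGrid(out, cellsize=dem.cellsize, mask=masked.copy(),
                         xll=dem.xll, yll=dem.yll)
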