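"""File formats: CSV tables, ESRI ASCII grids, network JSON, run configs.

Tables round-trip losslessly; integer mask grids round-trip bit-exact.
Schema violations raise :class:`SchemaError` with the file, row and field.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .delineation import ElevationGrid
from .emissions import (
    CatchmentRecord,
    ClimateZone,
    ReservoirRecord,
)
from .errors import SchemaError, UnknownZone
from .planner import AssetMetrics, TreeNetwork

__all__ = [
    "read_reservoir_table",
    "write_reservoir_table",
    "read_catchment_table",
    "write_catchment_table",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_network",
    "write_network",
    "RunConfig",
    "load_run_config",
    "emit_report",
]

_LC = ("forest", "cropland", "shrub", "other")

_RES_COLUMNS = [
    "id", "res_type", "zone", "area", "mean_depth", "volume", "residence_time",
    "forest_fraction", "cropland_fraction", "shrub_fraction", "other_fraction",
    "generation", "catchment_id",
]
_CAT_COLUMNS = [
    "id", "area", "runoff", "evapotranspiration", "air_temperature",
    "mean_slope", "population_density",
    "forest_fraction", "cropland_fraction", "shrub_fraction", "other_fraction",
]


def write_reservoir_table(reservoirs: List[ReservoirRecord], path) -> None:
    rows = []
    for r in reservoirs:
        rows.append(
            {
                "id": r.id, "res_type": r.res_type, "zone": r.zone.value,
                "area": r.area, "mean_depth": r.mean_depth, "volume": r.volume,
                "residence_time": r.residence_time,
                **{f"{c}_fraction": r.landcover.get(c, 0.0) for c in _LC},
                "generation": "" if r.generation is None else r.generation,
                "catchment_id": r.catchment_id,
            }
        )
    pd.DataFrame(rows, columns=_RES_COLUMNS).to_csv(path, index=False)


def read_reservoir_table(path) -> List[ReservoirRecord]:
    df = pd.read_csv(path)
    missing = set(_RES_COLUMNS) - {"generation"} - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns {sorted(missing)}", source=str(path))
    out = []
    for i, row in df.iterrows():
        line = int(i) + 2  # header is line 1
        try:
            zone = ClimateZone.parse(row["zone"])
        except UnknownZone as e:
            raise SchemaError(str(e), source=str(path), row=line, field="zone") from None
        gen = row.get("generation")
        gen = None if pd.isna(gen) or gen == "" else float(gen)
        try:
            out.append(
                ReservoirRecord(
                    id=str(row["id"]), res_type=str(row["res_type"]), zone=zone,
                    area=float(row["area"]), mean_depth=float(row["mean_depth"]),
                    volume=float(row["volume"]),
                    residence_time=float(row["residence_time"]),
                    landcover={c: float(row[f"{c}_fraction"]) for c in _LC},
                    generation=gen, catchment_id=str(row["catchment_id"]),
                )
            )
        except (SchemaError, ValueError) as e:
            raise SchemaError(str(e), source=str(path), row=line) from None
    return out


def write_catchment_table(catchments: List[CatchmentRecord], path) -> None:
    rows = []
    for c in catchments:
        rows.append(
            {
                "id": c.id, "area": c.area, "runoff": c.runoff,
                "evapotranspiration": c.evapotranspiration,
                "air_temperature": c.air_temperature, "mean_slope": c.mean_slope,
                "population_density": c.population_density,
                **{f"{k}_fraction": c.landcover.get(k, 0.0) for k in _LC},
            }
        )
    pd.DataFrame(rows, columns=_CAT_COLUMNS).to_csv(path, index=False)


def read_catchment_table(path) -> List[CatchmentRecord]:
    df = pd.read_csv(path)
    missing = set(_CAT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns {sorted(missing)}", source=str(path))
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                CatchmentRecord(
                    id=str(row["id"]), area=float(row["area"]),
                    runoff=float(row["runoff"]),
                    evapotranspiration=float(row["evapotranspiration"]),
                    air_temperature=float(row["air_temperature"]),
                    mean_slope=float(row["mean_slope"]),
                    population_density=float(row["population_density"]),
                    landcover={c: float(row[f"{c}_fraction"]) for c in _LC},
                )
            )
        except (SchemaError, ValueError) as e:
            raise SchemaError(str(e), source=str(path), row=int(i) + 2) from None
    return out


# ---------------------------------------------------------------------------
# ESRI ASCII grids
# ---------------------------------------------------------------------------

def write_ascii_grid(grid, path, cellsize: Optional[float] = None,
                     nodata: float = -9999, fmt: str = "%.6f") -> None:
    """Write a 2-D array or :class:`ElevationGrid` as an ESRI ASCII grid."""
    if isinstance(grid, ElevationGrid):
        data, cs, xll, yll, mask = grid.data, grid.cellsize, grid.xll, grid.yll, grid.mask
    else:
        data = np.asarray(grid)
        cs = cellsize if cellsize is not None else 1.0
        xll = yll = 0.0
        mask = ~np.isfinite(data.astype(float))
    arr = data.astype(float).copy()
    arr[mask] = nodata
    if np.issubdtype(np.asarray(grid.data if isinstance(grid, ElevationGrid)
                                else grid).dtype, np.integer):
        fmt = "%d"
    nr, nc = arr.shape
    header = (
        f"ncols {nc}\nnrows {nr}\nxllcorner {xll}\nyllcorner {yll}\n"
        f"cellsize {cs}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt=fmt)


def read_ascii_grid(path, as_int: bool = False):
    """Read an ESRI ASCII grid -> (:class:`ElevationGrid` or int array)."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise SchemaError(f"ASCII grid missing header field {key}",
                              source=str(path))
    data = np.loadtxt(lines[n_header:])
    data = data.reshape(int(header["nrows"]), int(header["ncols"]))
    nodata = header.get("nodata_value", -9999)
    if as_int:
        return data.astype(np.int64)
    mask = data == nodata
    data = data.copy()
    data[mask] = np.nan
    return ElevationGrid(
        data, cellsize=header["cellsize"], mask=mask,
        xll=header.get("xllcorner", 0.0), yll=header.get("yllcorner", 0.0),
    )


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(tree: TreeNetwork, path) -> None:
    edges = []
    for (down, up), a in sorted(tree.assets.items()):
        edges.append(
            {
                "from": down, "to": up,
                "asset": {
                    "id": a.id, "type": a.asset_type, "energy": a.energy,
                    "firm_power": a.firm_power, "emissions": a.emissions,
                    "cropland_loss": a.cropland_loss, "forest_loss": a.forest_loss,
                    "existing": a.existing,
                },
            }
        )
    payload = {"root": tree.root, "nodes": sorted(tree.children), "edges": edges}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_network(path) -> TreeNetwork:
    with open(path) as fh:
        payload = json.load(fh)
    for key in ("root", "edges"):
        if key not in payload:
            raise SchemaError(f"network JSON missing key {key!r}", source=str(path))
    children: Dict[str, List[str]] = {payload["root"]: []}
    assets: Dict[Tuple[str, str], AssetMetrics] = {}
    for i, e in enumerate(payload["edges"]):
        try:
            a = e["asset"]
            asset = AssetMetrics(
                id=a["id"], asset_type=a["type"], energy=float(a["energy"]),
                firm_power=float(a["firm_power"]),
                emissions={k: float(v) for k, v in a["emissions"].items()},
                cropland_loss=float(a.get("cropland_loss", 0.0)),
                forest_loss=float(a.get("forest_loss", 0.0)),
                existing=bool(a.get("existing", False)),
            )
        except (KeyError, TypeError, ValueError) as err:
            raise SchemaError(f"bad edge record: {err}", source=str(path),
                              row=i) from None
        children.setdefault(e["from"], []).append(e["to"])
        children.setdefault(e["to"], [])
        assets[(e["from"], e["to"])] = asset
    return TreeNetwork(root=payload["root"], children=children, assets=assets)


# ---------------------------------------------------------------------------
# run configuration and reports
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "run"
    ef_provenance: str = "global"
    include_irrigation_degassing: bool = True
    lifecycle_ei: bool = False
    epsilon: float = 0.05
    scenario: str = "not-built"
    emission_method: str = "model"
    net_co2: float = 1.0
    net_ch4: float = 1.0
    r_downstream: float = 0.0
    n_boot: int = 1000
    grid_size: Tuple[int, int] = (64, 64)
    n_dams: int = 60

    def echo(self, out_dir) -> None:
        path = Path(out_dir) / "run_config.yaml"
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    bad = set(raw) - known
    if bad:
        raise SchemaError(f"unknown config keys {sorted(bad)}", source=str(path))
    if "grid_size" in raw:
        raw["grid_size"] = tuple(raw["grid_size"])
    return RunConfig(**raw)


def emit_report(path, *, per_reservoir: pd.DataFrame,
                ef_comparison: Optional[pd.DataFrame] = None,
                frontier: Optional[pd.DataFrame] = None,
                config: Optional[RunConfig] = None) -> dict:
    """Assemble and write the run's JSON report; returns the payload."""
    payload = {
        "totals": {
            "n_reservoirs": int(len(per_reservoir)),
            "total_mass_model_t": float(per_reservoir["model_mass_t"].sum())
            if "model_mass_t" in per_reservoir else None,
            "total_mass_ef_t": float(per_reservoir["ef_mass_t"].sum())
            if "ef_mass_t" in per_reservoir else None,
        },
        "per_reservoir": per_reservoir.to_dict(orient="records"),
    }
    if ef_comparison is not None:
        payload["ef_comparison"] = ef_comparison.to_dict(orient="records")
    if frontier is not None:
        payload["frontier"] = frontier.to_dict(orient="records")
    if config is not None:
        payload["config"] = asdict(config)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return payload
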