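"""Synthetic landscapes, reservoir fleets, emission ground truth and
generation series.

The generator emulates the statistical structure the framework assumes so
that delineation, calibration, explanation and planning are all testable
offline against a known ground truth:

* a smoothed random-field DEM, hydrologically conditioned so every cell
  drains to a single boundary outlet; temperature falls with elevation at a
  fixed lapse rate, runoff rises with elevation, and forest probability
  rises away from the warm lowland band;
* climatic-zone labels assigned by elevation band, drawn from the six-zone
  stratification (warm/tropical zones in the lowlands, cool/polar at
  altitude);
* a fleet of dams nested along flow paths — irrigation reservoirs in the
  warm lowlands, hydroelectric and multipurpose upstream, a share of
  run-of-river — whose network is a tree by construction;
* a linear-in-features emission law per pathway with known coefficients and
  Gaussian noise: CH4 pathways decrease in mean depth and increase in
  temperature and catchment area; diffusive CO2 increases in impounded
  forest fraction and temperature; zone-level mean structure makes the
  zone-EF calibration target recoverable;
* weekly generation series over 38 years from the hydropower relation
  P = rho g eta Q H with a power-law volume-depth bathymetry and a seasonal
  sinusoid plus noise on flows.

Everything is deterministic under the config seed, and every distribution
parameter is recorded in the run manifest.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import delineation as dl
from .emissions import (
    CatchmentRecord,
    ClimateZone,
    EmissionPathway,
    EmpiricalModelConfig,
    PathwayRegression,
    PreImpoundmentTable,
    ReservoirRecord,
    net_anthropogenic,
    tier1_gross_profile,
)
from .errors import TooManyDams
from .planner import AssetMetrics, TreeNetwork, firm_power

__all__ = [
    "SyntheticConfig",
    "Landscape",
    "Fleet",
    "synth_landscape",
    "synth_fleet",
    "sample_fleet_records",
    "sample_zone_fluxes",
    "truth_model_config",
    "synth_emission_truth",
    "synth_generation",
    "build_asset_metrics",
    "DEFAULT_PRE_IMPOUNDMENT",
    "LANDCOVER_CLASSES",
    "WEEKS_PER_YEAR",
]

WEEKS_PER_YEAR = 365.25 / 7.0

#: Land-cover raster encoding.
LANDCOVER_CLASSES = {0: "water", 1: "forest", 2: "cropland", 3: "shrub", 4: "other"}

#: Pre-impoundment landscape fluxes, gCO2e/m2/yr: forest a sink, cropland a
#: modest source, shrub near-neutral.
DEFAULT_PRE_IMPOUNDMENT = PreImpoundmentTable(
    {"forest": -150.0, "cropland": 80.0, "shrub": -20.0, "other": 0.0}
)

# elevation-band -> climate zone, lowest to highest band
_ZONE_BANDS = (
    ClimateZone.TROPICAL_WET_MOIST,
    ClimateZone.WARM_TEMPERATE_DRY,
    ClimateZone.TROPICAL_DRY_MONTANE,
    ClimateZone.WARM_TEMPERATE_MOIST,
    ClimateZone.COOL_TEMPERATE_MOIST_DRY,
    ClimateZone.POLAR_MOIST_BOREAL_DRY_MOIST,
)


@dataclass
class SyntheticConfig:
    """All knobs of the generator; the defaults are the study conditions.

    Fleet size 60 mirrors a national planned-hydropower inventory; weekly
    generation series span 38 years.  The emission law is identity-link so
    closed-form checks exist (``truth_link='log10'`` gives a stress
    variant); noise_sd is in gCO2e/m2/yr.
    """

    seed: int = 0
    grid_size: Tuple[int, int] = (64, 64)
    cellsize: float = 200.0  # m
    relief: float = 900.0  # m of total elevation range
    smoothness: float = 6.0  # gaussian-filter sigma, cells
    n_dams: int = 60
    ror_fraction: float = 0.25
    river_threshold: int = 25  # accumulation cells
    # climate
    sea_level_temp: float = 28.0  # degC in the lowland band
    lapse_rate: float = 6.5e-3  # degC per m
    runoff_base: float = 400.0  # mm/yr at the lowest band
    runoff_per_m: float = 1.2  # mm/yr per metre of elevation
    # emission law
    truth_link: str = "identity"
    noise_sd: float = 30.0
    gwp_ch4: float = 1.0  # truth coefficients already express gCO2e
    uas_fraction: float = 0.05
    # hydrology
    years: int = 38
    seasonal_amplitude: float = 0.5
    flow_noise_sd: float = 0.15
    efficiency: float = 0.9


@dataclass
class Landscape:
    dem: dl.ElevationGrid  # hydrologically conditioned
    raw_dem: dl.ElevationGrid
    d8: np.ndarray
    accumulation: np.ndarray
    landcover: np.ndarray
    temperature: np.ndarray
    runoff: np.ndarray
    zone_index: np.ndarray  # index into _ZONE_BANDS
    manifest: dict = field(default_factory=dict)

    def zone_at(self, r: int, c: int) -> ClimateZone:
        return _ZONE_BANDS[int(self.zone_index[r, c])]


def _zone_bands_from_elevation(z: np.ndarray) -> np.ndarray:
    """Six elevation bands by quantile, weighted toward the warm lowlands."""
    qs = np.quantile(z, [0.35, 0.55, 0.75, 0.88, 0.96])
    return np.digitize(z, qs)


def synth_landscape(cfg: SyntheticConfig) -> Landscape:
    """Generate the DEM, climate and land-cover rasters (seed-deterministic)."""
    rng = np.random.default_rng(cfg.seed)
    nr, nc = cfg.grid_size
    if nr < 16 or nc < 16:
        raise ValueError("grid must be at least 16x16")

    noise = rng.normal(size=(nr, nc))
    rough = gaussian_filter(noise, sigma=cfg.smoothness, mode="nearest")
    rough = (rough - rough.min()) / (rough.max() - rough.min())
    # tilt toward one corner so drainage has a preferred direction
    rows = np.linspace(0.0, 1.0, nr)[:, None]
    cols = np.linspace(0.0, 1.0, nc)[None, :]
    tilt = 0.35 * (rows + cols) / 2.0
    z = (0.65 * rough + tilt) * cfg.relief
    raw = dl.ElevationGrid(z, cellsize=cfg.cellsize)
    dem = dl.condition_dem(raw)
    d8 = dl.flow_directions(dem)
    acc = dl.flow_accumulation(d8)

    zone_index = _zone_bands_from_elevation(dem.data)
    temperature = (
        cfg.sea_level_temp
        - cfg.lapse_rate * (dem.data - dem.data.min())
        + rng.normal(0.0, 0.3, size=(nr, nc))
    )
    runoff = np.maximum(
        cfg.runoff_base
        + cfg.runoff_per_m * (dem.data - dem.data.min())
        + rng.normal(0.0, 25.0, size=(nr, nc)),
        10.0,
    )

    # forest probability rises away from the warm lowland band
    p_forest = np.clip(0.10 + 0.16 * zone_index, 0.0, 0.9)
    p_crop = np.clip(0.45 - 0.08 * zone_index, 0.05, 1.0)
    u = rng.random((nr, nc))
    landcover = np.full((nr, nc), 4, dtype=np.int8)  # other
    landcover[u < p_forest + p_crop + 0.2] = 3  # shrub
    landcover[u < p_forest + p_crop] = 2  # cropland
    landcover[u < p_forest] = 1  # forest
    # water along the largest rivers
    landcover[acc >= 4 * cfg.river_threshold] = 0

    manifest = {
        "config": asdict(cfg),
        "zone_bands": [zz.value for zz in _ZONE_BANDS],
        "landcover_classes": LANDCOVER_CLASSES,
        "forest_probability": "0.10 + 0.16 * zone_band",
        "cropland_probability": "0.45 - 0.08 * zone_band",
    }
    return Landscape(
        dem=dem, raw_dem=raw, d8=d8, accumulation=acc, landcover=landcover,
        temperature=temperature, runoff=runoff, zone_index=zone_index,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# fleets
# ---------------------------------------------------------------------------

@dataclass
class Fleet:
    sites: List[dl.DamSite]
    reservoirs: List[ReservoirRecord]
    catchments: List[CatchmentRecord]
    tree: TreeNetwork
    reservoir_masks: Dict[str, np.ndarray]
    catchment_masks: Dict[str, np.ndarray]
    manifest: dict = field(default_factory=dict)

    def records_frame(self) -> pd.DataFrame:
        rows = []
        for res, cat in zip(self.reservoirs, self.catchments):
            rows.append(
                {
                    "id": res.id,
                    "res_type": res.res_type,
                    "zone": res.zone.value,
                    "area": res.area,
                    "mean_depth": res.mean_depth,
                    "volume": res.volume,
                    "residence_time": res.residence_time,
                    **{f"{k}_fraction": v for k, v in res.landcover.items()},
                    "catchment_area": cat.area,
                    "runoff": cat.runoff,
                    "air_temperature": cat.air_temperature,
                }
            )
        return pd.DataFrame(rows)


def _dam_parent(cell, d8, dam_cells):
    """First dam cell met on the downstream flow path, or None."""
    cur = cell
    while True:
        nxt = dl.downstream_cell(cur[0], cur[1], d8)
        if nxt is None:
            return None
        if nxt in dam_cells:
            return nxt
        cur = nxt


def synth_fleet(cfg: SyntheticConfig, landscape: Landscape) -> Fleet:
    """Place dams on the river network and delineate their reservoirs.

    Dams sit on river cells (accumulation above the threshold), spaced apart
    and nested along flow paths, so the dam network is a tree rooted at the
    outlet.  Reservoir types follow the elevation gradient: irrigation in
    the warm lowland bands, hydroelectric/multipurpose upstream, and a
    configured fraction of run-of-river assets.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    acc = landscape.accumulation
    d8 = landscape.d8
    dem = landscape.dem

    rivers = np.argwhere(acc >= cfg.river_threshold)
    if len(rivers) < cfg.n_dams:
        raise TooManyDams(
            f"{cfg.n_dams} dams requested but only {len(rivers)} river cells"
        )
    order = rng.permutation(len(rivers))
    chosen: List[Tuple[int, int]] = []
    min_sep2 = 9.0
    for idx in order:
        r, c = map(int, rivers[idx])
        if all((r - rr) ** 2 + (c - cc) ** 2 >= min_sep2 for rr, cc in chosen):
            chosen.append((r, c))
        if len(chosen) == cfg.n_dams:
            break
    if len(chosen) < cfg.n_dams:
        raise TooManyDams(
            f"could not place {cfg.n_dams} separated dams on this network"
        )

    dam_cells = set(chosen)
    sites, reservoirs, catchments = [], [], []
    res_masks, cat_masks = {}, {}
    n_ror = int(round(cfg.ror_fraction * cfg.n_dams))
    ror_ids = set(rng.choice(cfg.n_dams, size=n_ror, replace=False).tolist())

    for i, (r, c) in enumerate(chosen):
        dam_id = f"dam{i:03d}"
        zone = landscape.zone_at(r, c)
        band = int(landscape.zone_index[r, c])
        is_ror = i in ror_ids
        if is_ror:
            res_type = "ror"
        elif band <= 1:
            res_type = rng.choice(["irrigation", "irrigation", "multipurpose"])
        else:
            res_type = rng.choice(["hydroelectric", "hydroelectric", "multipurpose"])
        dam_height = float(rng.uniform(12.0, 45.0))
        site = dl.DamSite(row=r, col=c, dam_height=dam_height, buffer_height=2.0,
                          res_type=res_type, id=dam_id)
        cat_mask = dl.local_catchment((r, c), d8)
        if is_ror:
            res_mask = np.zeros(dem.shape, dtype=bool)
            fsl = dem.data[r, c]
        else:
            res_mask, fsl = dl.flood_reservoir(dem, d8, site, catchment=cat_mask)
            if not res_mask.any():
                res_mask[r, c] = True
        params = dl.zonal_parameters(
            res_mask, cat_mask, dem, fsl,
            rasters={
                "temperature": landscape.temperature,
                "runoff": landscape.runoff,
            },
            landcover=landscape.landcover,
            landcover_classes=LANDCOVER_CLASSES,
        )
        lc = _normalized_fractions(params, "reservoir")
        cat_lc = _normalized_fractions(params, "catchment")
        runoff = params["catchment_mean_runoff"]
        volume = params["volume_mm3"]
        inflow_m3yr = runoff * 1e-3 * params["catchment_area_km2"] * 1e6
        residence = volume * 1e6 / inflow_m3yr if inflow_m3yr > 0 else 0.0
        reservoirs.append(
            ReservoirRecord(
                id=dam_id,
                res_type=res_type,
                zone=zone,
                area=0.0 if is_ror else params["reservoir_area_km2"],
                mean_depth=0.0 if is_ror else max(params["mean_depth_m"], 0.5),
                volume=0.0 if is_ror else volume,
                residence_time=0.0 if is_ror else residence,
                landcover=lc,
                catchment_id=f"cat{i:03d}",
            )
        )
        catchments.append(
            CatchmentRecord(
                id=f"cat{i:03d}",
                area=params["catchment_area_km2"],
                runoff=runoff,
                evapotranspiration=max(1200.0 - 0.8 * runoff, 100.0),
                air_temperature=params["catchment_mean_temperature"],
                mean_slope=float(
                    np.mean(np.abs(np.gradient(dem.data)[0][cat_mask])) / dem.cellsize
                    * 100.0
                ),
                population_density=float(rng.uniform(5.0, 150.0)),
                landcover=cat_lc,
            )
        )
        sites.append(site)
        res_masks[dam_id] = res_mask
        cat_masks[dam_id] = cat_mask

    # dam tree: each dam's parent is the first dam downstream on its flow path
    cell_to_id = {cell: f"dam{i:03d}" for i, cell in enumerate(chosen)}
    children: Dict[str, List[str]] = {"outlet": []}
    edges: Dict[Tuple[str, str], str] = {}
    for i, cell in enumerate(chosen):
        parent_cell = _dam_parent(cell, d8, dam_cells)
        parent_region = (
            f"up:{cell_to_id[parent_cell]}" if parent_cell is not None else "outlet"
        )
        dam_id = cell_to_id[cell]
        region = f"up:{dam_id}"
        children.setdefault(parent_region, []).append(region)
        children.setdefault(region, [])
        edges[(parent_region, region)] = dam_id

    fleet = Fleet(
        sites=sites, reservoirs=reservoirs, catchments=catchments,
        tree=TreeNetwork(root="outlet", children=children, assets={}),
        reservoir_masks=res_masks, catchment_masks=cat_masks,
        manifest={**landscape.manifest, "n_dams": cfg.n_dams,
                  "dam_edges": {str(k): v for k, v in edges.items()}},
    )
    fleet.manifest["edge_assets"] = edges
    return fleet


def _normalized_fractions(params: dict, prefix: str) -> Dict[str, float]:
    lc = {}
    for cls in ("forest", "cropland", "shrub", "other"):
        lc[cls] = params.get(f"{prefix}_{cls}_fraction", 0.0)
    # fold any water share into "other" so fractions sum to one
    water = params.get(f"{prefix}_water_fraction", 0.0)
    lc["other"] += water
    total = sum(lc.values())
    if total <= 0:
        return {"forest": 0.0, "cropland": 0.0, "shrub": 0.0, "other": 1.0}
    return {k: v / total for k, v in lc.items()}


def sample_fleet_records(
    cfg: SyntheticConfig, n: Optional[int] = None, seed: Optional[int] = None
) -> Tuple[List[ReservoirRecord], List[CatchmentRecord]]:
    """Tabular fleet generator (no rasters) with the same zone structure.

    Used where only the records matter (calibration, xAI, planning at
    scale); the raster route via :func:`synth_fleet` exercises delineation.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = n or cfg.n_dams
    reservoirs, catchments = [], []
    # zone mix echoing a three-zone tropical country plus rare others
    zone_probs = {
        ClimateZone.TROPICAL_WET_MOIST: 0.35,
        ClimateZone.WARM_TEMPERATE_DRY: 0.35,
        ClimateZone.TROPICAL_DRY_MONTANE: 0.24,
        ClimateZone.WARM_TEMPERATE_MOIST: 0.06,
    }
    zones = list(zone_probs)
    probs = np.array(list(zone_probs.values()))
    band_of = {
        ClimateZone.TROPICAL_WET_MOIST: 0,
        ClimateZone.WARM_TEMPERATE_DRY: 1,
        ClimateZone.TROPICAL_DRY_MONTANE: 2,
        ClimateZone.WARM_TEMPERATE_MOIST: 3,
    }
    for i in range(n):
        zone = zones[rng.choice(len(zones), p=probs)]
        band = band_of[zone]
        lowland = band <= 1
        res_type = rng.choice(
            ["irrigation", "multipurpose", "hydroelectric"],
            p=[0.6, 0.2, 0.2] if lowland else [0.05, 0.25, 0.7],
        )
        depth = float(rng.lognormal(math.log(6.0 if lowland else 18.0), 0.5))
        area = float(rng.lognormal(math.log(4.0 if lowland else 15.0), 0.8))
        forest = float(np.clip(rng.beta(2, 6) + 0.12 * band, 0, 0.9))
        crop = float(np.clip(rng.beta(2, 5) * (1.4 if lowland else 0.5), 0,
                             0.95 - forest))
        shrub = float(np.clip(rng.beta(2, 8), 0, max(0.99 - forest - crop, 0)))
        other = max(1.0 - forest - crop - shrub, 0.0)
        temp = 28.0 - 4.5 * band + float(rng.normal(0, 1.0))
        runoff = 400.0 + 250.0 * band + float(rng.normal(0, 60.0))
        cat_area = float(rng.lognormal(math.log(250.0), 1.0))
        volume = area * depth  # km2 x m = Mm3
        inflow = max(runoff, 10.0) * 1e-3 * cat_area * 1e6
        reservoirs.append(
            ReservoirRecord(
                id=f"res{i:03d}",
                res_type=res_type,
                zone=zone,
                area=area,
                mean_depth=depth,
                volume=volume,
                residence_time=volume * 1e6 / inflow,
                landcover={"forest": forest, "cropland": crop, "shrub": shrub,
                           "other": other},
                catchment_id=f"cat{i:03d}",
            )
        )
        catchments.append(
            CatchmentRecord(
                id=f"cat{i:03d}",
                area=cat_area,
                runoff=max(runoff, 10.0),
                evapotranspiration=max(1300.0 - 0.7 * max(runoff, 10.0), 100.0),
                air_temperature=temp,
                mean_slope=float(rng.uniform(2.0, 25.0)),
                population_density=float(rng.lognormal(math.log(40.0), 0.8)),
                landcover={"forest": forest, "cropland": crop, "shrub": shrub,
                           "other": other},
            )
        )
    return reservoirs, catchments


def sample_zone_fluxes(
    zone_means: Mapping[ClimateZone, float],
    sigma: float,
    n: int,
    seed: int = 0,
    pathway: str = "co2_diffusive",
    hp_fraction: float = 0.5,
) -> pd.DataFrame:
    """Calibration samples with a pure zone-mean flux law plus Gaussian noise.

    The injected per-zone means are the ground truth the zone-EF calibration
    should recover.
    """
    rng = np.random.default_rng(seed)
    zones = list(zone_means)
    zdraw = rng.integers(0, len(zones), size=n)
    flux = np.array([zone_means[zones[i]] for i in zdraw]) + rng.normal(0, sigma, n)
    types = np.where(
        rng.random(n) < hp_fraction,
        rng.choice(["hydroelectric", "multipurpose"], size=n),
        "irrigation",
    )
    return pd.DataFrame(
        {
            "id": [f"res{i:03d}" for i in range(n)],
            "zone": [ClimateZone.parse(zones[i]).value for i in zdraw],
            "res_type": types,
            pathway: flux,
        }
    )


# ---------------------------------------------------------------------------
# emission ground truth
# ---------------------------------------------------------------------------

def truth_model_config(cfg: SyntheticConfig) -> EmpiricalModelConfig:
    """The emitted empirical-model config that *is* the ground-truth law.

    Effect signs by construction: CH4 pathways decrease in mean depth and
    increase in temperature and catchment area; diffusive CO2 increases in
    impounded forest fraction and temperature.  Coefficients already
    express gCO2e, so the config's CH4 equivalence factor is explicitly 1.
    """
    link = cfg.truth_link
    if link == "identity":
        pathways = {
            EmissionPathway.CO2_DIFFUSIVE: PathwayRegression(
                features=["res_forest_fraction", "cat_air_temperature",
                          "cat_evapotranspiration"],
                coefficients=[700.0, 18.0, 0.15],
                intercept=60.0,
            ),
            EmissionPathway.CH4_DIFFUSIVE: PathwayRegression(
                features=["res_mean_depth", "cat_air_temperature", "cat_area"],
                coefficients=[-9.0, 14.0, 0.05],
                intercept=180.0,
            ),
            EmissionPathway.CH4_EBULLITION: PathwayRegression(
                features=["res_mean_depth", "cat_air_temperature"],
                coefficients=[-11.0, 16.0],
                intercept=160.0,
            ),
            EmissionPathway.CH4_DEGASSING: PathwayRegression(
                features=["res_mean_depth", "res_residence_time", "cat_area"],
                coefficients=[-4.0, 30.0, 0.08],
                intercept=120.0,
            ),
        }
    elif link == "log10":
        pathways = {
            EmissionPathway.CO2_DIFFUSIVE: PathwayRegression(
                features=["res_forest_fraction", "cat_air_temperature"],
                coefficients=[0.45, 0.012], intercept=2.2, link="log10",
            ),
            EmissionPathway.CH4_DIFFUSIVE: PathwayRegression(
                features=["res_mean_depth", "cat_air_temperature"],
                coefficients=[-0.02, 0.015], intercept=2.0, link="log10",
            ),
            EmissionPathway.CH4_EBULLITION: PathwayRegression(
                features=["res_mean_depth", "cat_air_temperature"],
                coefficients=[-0.025, 0.018], intercept=1.9, link="log10",
            ),
            EmissionPathway.CH4_DEGASSING: PathwayRegression(
                features=["res_mean_depth", "res_residence_time"],
                coefficients=[-0.01, 0.003], intercept=1.8, link="log10",
            ),
        }
    else:
        raise ValueError(f"truth_link must be 'identity' or 'log10', got {link!r}")
    return EmpiricalModelConfig(
        pathways=pathways, gwp_ch4=cfg.gwp_ch4, uas_fraction=cfg.uas_fraction
    )


def synth_emission_truth(
    cfg: SyntheticConfig,
    reservoirs: Sequence[ReservoirRecord],
    catchments: Sequence[CatchmentRecord],
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, EmpiricalModelConfig, dict]:
    """Per-reservoir pathway fluxes from the truth law plus Gaussian noise.

    Returns (fluxes, the matching EmpiricalModelConfig, truth manifest).
    With ``cfg.noise_sd == 0`` the fluxes equal the config's predictions
    exactly.  Noisy fluxes are clamped at zero like the model's own
    identity-link predictions.
    """
    model_cfg = truth_model_config(cfg)
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    cat_by_id = {c.id: c for c in catchments}
    rows = []
    for res in reservoirs:
        cat = cat_by_id[res.catchment_id]
        row = {"id": res.id, "zone": res.zone.value, "res_type": res.res_type}
        if res.res_type == "ror":
            for p in EmissionPathway:
                row[p.value] = 0.0
        else:
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                from .emissions import predict_empirical_profile

                profile = predict_empirical_profile(res, cat, model_cfg)
            for p in EmissionPathway:
                noisy = profile.fluxes[p] + (
                    rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0
                )
                row[p.value] = max(noisy, 0.0)
        rows.append(row)
    fluxes = pd.DataFrame(rows)
    manifest = {
        "truth_link": cfg.truth_link,
        "noise_sd": cfg.noise_sd,
        "gwp_ch4": cfg.gwp_ch4,
        "uas_fraction": cfg.uas_fraction,
        "pathway_regressions": {
            p.value: {
                "features": list(r.features),
                "coefficients": list(r.coefficients),
                "intercept": r.intercept,
                "link": r.link,
            }
            for p, r in model_cfg.pathways.items()
        },
    }
    return fluxes, model_cfg, manifest


# ---------------------------------------------------------------------------
# generation series
# ---------------------------------------------------------------------------

_RHO_G = 1000.0 * 9.81  # kg/m3 x m/s2


def synth_generation(
    cfg: SyntheticConfig,
    reservoirs: Sequence[ReservoirRecord],
    catchments: Sequence[CatchmentRecord],
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Weekly generation series (GWh/week), one column per asset.

    P = rho g eta Q H with head from a cube-root volume-depth bathymetry
    (head proportional to mean depth), flow from catchment runoff with a
    seasonal sinusoid and multiplicative Gaussian noise.  Run-of-river
    assets scale with runoff directly at a nominal 20 m head.
    """
    rng = np.random.default_rng(cfg.seed + 3 if seed is None else seed)
    n_weeks = int(round(cfg.years * WEEKS_PER_YEAR))
    t = np.arange(n_weeks)
    season = 1.0 + cfg.seasonal_amplitude * np.sin(2 * np.pi * t / WEEKS_PER_YEAR)
    cat_by_id = {c.id: c for c in catchments}
    out = {}
    for res in reservoirs:
        cat = cat_by_id[res.catchment_id]
        q_mean = cat.runoff * 1e-3 * cat.area * 1e6 / (365.25 * 86400.0)  # m3/s
        if res.res_type == "ror":
            head = 20.0
        else:
            # power-law bathymetry: head tracks (volume / area)^(1) = mean depth,
            # modulated by storage state via the cube root of relative volume
            head = 1.5 * res.mean_depth
        noise = (
            rng.normal(1.0, cfg.flow_noise_sd, size=n_weeks)
            if cfg.flow_noise_sd > 0 else np.ones(n_weeks)
        )
        q = np.maximum(q_mean * season * noise, 0.0)
        p_watts = _RHO_G * cfg.efficiency * q * head
        gwh_per_week = p_watts * (7 * 24 * 3600.0) / 3.6e12
        out[res.id] = gwh_per_week
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# planner inputs
# ---------------------------------------------------------------------------

def build_asset_metrics(
    fleet: Fleet,
    fluxes: pd.DataFrame,
    model_cfg: EmpiricalModelConfig,
    generation: pd.DataFrame,
    pre_table: PreImpoundmentTable = DEFAULT_PRE_IMPOUNDMENT,
    ef_table=None,
    existing_fraction: float = 0.3,
    seed: int = 0,
) -> TreeNetwork:
    """Attach AssetMetrics to the fleet's dam tree.

    Emissions carry both routes: ``model`` (net anthropogenic from the
    empirical law) and ``ef`` (Tier 1 gross from the zone table).  RoR
    assets get the constant biogenic intensity times their generation.
    Land losses are the impounded cropland/forest areas (zero for RoR).
    A seeded random share of assets is flagged ``existing`` for the built
    scenario.
    """
    from .emissions import ROR_BIOGENIC_EI, global_ef_table

    rng = np.random.default_rng(seed)
    if ef_table is None:
        ef_table = global_ef_table()
    cat_by_id = {c.id: c for c in fleet.catchments}
    flux_by_id = fluxes.set_index("id")
    assets = {}
    existing_flags = rng.random(len(fleet.reservoirs)) < existing_fraction
    metrics_by_id = {}
    for flag, res in zip(existing_flags, fleet.reservoirs):
        cat = cat_by_id[res.catchment_id]
        series = generation[res.id].to_numpy()
        energy = float(series.mean() * WEEKS_PER_YEAR)
        firm = firm_power(series, periods_per_year=WEEKS_PER_YEAR)
        if res.res_type == "ror":
            emissions = {"model": ROR_BIOGENIC_EI * energy,
                         "ef": ROR_BIOGENIC_EI * energy}
            crop = forest = 0.0
        else:
            net = net_anthropogenic(res, cat, model_cfg, pre_table)
            row = flux_by_id.loc[res.id]
            model_mass = max(
                float(sum(row[p.value] for p in EmissionPathway)) * res.area, 0.0
            )
            # prefer the noisy "observed" fluxes for the model route total
            model_mass = model_mass if np.isfinite(model_mass) else net.gross.total_mass
            ef_mass = tier1_gross_profile(res, ef_table).total_mass
            emissions = {"model": model_mass, "ef": float(ef_mass)}
            crop = res.cropland_fraction * res.area
            forest = res.forest_fraction * res.area
        metrics_by_id[res.id] = AssetMetrics(
            id=res.id,
            asset_type="ror" if res.res_type == "ror" else "reservoir",
            energy=energy,
            firm_power=firm,
            emissions=emissions,
            cropland_loss=crop,
            forest_loss=forest,
            existing=bool(flag),
        )
    edges = fleet.manifest["edge_assets"]
    assets = {edge: metrics_by_id[dam_id] for edge, dam_id in edges.items()}
    return TreeNetwork(root=fleet.tree.root, children=fleet.tree.children,
                       assets=assets)
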