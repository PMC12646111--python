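"""Gross and net reservoir greenhouse-gas emissions.

Two estimation routes are supported:

* **Tier 1 emission factors** — a constant areal flux per (climate zone,
  emission pathway) stratum, applied to every reservoir in the stratum.  The
  shipped global table stratifies by six climatic zones and four pathways
  (CO2 diffusion; CH4 diffusion, ebullition and downstream degassing).
* **Pathway-structured empirical model** — per-pathway regressions on
  reservoir and catchment descriptors (surface area, mean depth, land-cover
  fractions, temperature, runoff, ...), configurable coefficients and link
  functions.  The regression coefficients are user configuration, not
  package constants.

Gross surface fluxes are converted to *net anthropogenic* emissions either
by subtracting the pre-impoundment landscape footprint and the share of the
flux attributable to unrelated anthropogenic nutrient/organic-matter inputs,
or — for the Tier 1 route — with the bilinear net-conversion law

    F_net = (net_co2 * F_CO2 + net_ch4 * F_CH4) * (1 + R_downstream)

where ``net_co2``/``net_ch4`` are the net-anthropogenic proportions of each
gas and ``R_downstream`` the ratio of downstream to surface emissions.  The
law is linear, so it is applied in the package's canonical flux unit
(gCO2e/m2/yr) even though it is often quoted per day; converters are
provided for reporting parity.

All fluxes are areal, in gCO2e per square metre per year, CH4 already
weighted to CO2-equivalents.  Mass totals use the exact unit identity
1 gCO2e/m2/yr x 1 km2 = 1 tCO2e/yr.
"""

from __future__ import annotations

import enum
import math
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    MissingClassFlux,
    MissingEF,
    MissingFeature,
    NonFiniteFlux,
    SchemaError,
    UnknownZone,
    ZeroArea,
    ZeroGeneration,
)

__all__ = [
    "ClimateZone",
    "EmissionPathway",
    "EFTable",
    "ReservoirRecord",
    "CatchmentRecord",
    "GrossEmissionProfile",
    "NetConversionParams",
    "PreImpoundmentTable",
    "PathwayRegression",
    "EmpiricalModelConfig",
    "NetEmissionResult",
    "load_ef_table",
    "global_ef_table",
    "myanmar_ef_table",
    "lookup_ef",
    "tier1_gross_profile",
    "predict_empirical_profile",
    "pre_impoundment_flux",
    "net_from_gross",
    "net_anthropogenic",
    "emission_intensity",
    "per_day",
    "per_year",
    "ROR_BIOGENIC_EI",
    "LIFECYCLE_EI_INCREMENT",
    "DAYS_PER_YEAR",
]

#: Constant biogenic emission intensity assumed for run-of-river hydropower,
#: gCO2e/kWh.
ROR_BIOGENIC_EI = 3.0

#: Increment added to biogenic emission intensity to obtain a life-cycle
#: intensity (infrastructure and supply-chain emissions), gCO2e/kWh.
LIFECYCLE_EI_INCREMENT = 19.0

DAYS_PER_YEAR = 365.25

CH4_PATHWAYS = ("ch4_diffusive", "ch4_ebullition", "ch4_degassing")


class ClimateZone(str, enum.Enum):
    """The closed six-element set of climatic-zone strata."""

    COOL_TEMPERATE_MOIST_DRY = "Cool temperate moist dry"
    POLAR_MOIST_BOREAL_DRY_MOIST = "Polar moist boreal dry moist"
    TROPICAL_DRY_MONTANE = "Tropical dry montane"
    TROPICAL_WET_MOIST = "Tropical wet moist"
    WARM_TEMPERATE_DRY = "Warm temperate dry"
    WARM_TEMPERATE_MOIST = "Warm temperate moist"

    @classmethod
    def parse(cls, label: str) -> "ClimateZone":
        """Parse a zone label after canonical whitespace normalization."""
        if isinstance(label, cls):
            return label
        canon = re.sub(r"\s+", " ", str(label)).strip()
        for z in cls:
            if z.value == canon:
                return z
        raise UnknownZone(
            f"unknown climate zone {label!r}; expected one of "
            + ", ".join(repr(z.value) for z in cls)
        )


class EmissionPathway(str, enum.Enum):
    """The closed four-element set of emission pathways."""

    CO2_DIFFUSIVE = "co2_diffusive"
    CH4_DIFFUSIVE = "ch4_diffusive"
    CH4_EBULLITION = "ch4_ebullition"
    CH4_DEGASSING = "ch4_degassing"

    @classmethod
    def parse(cls, name: str) -> "EmissionPathway":
        if isinstance(name, cls):
            return name
        try:
            return cls(str(name).strip().lower())
        except ValueError:
            raise SchemaError(f"unknown emission pathway {name!r}") from None


def _zone_key(z) -> ClimateZone:
    return ClimateZone.parse(z)


def _pathway_key(p) -> EmissionPathway:
    return EmissionPathway.parse(p)


@dataclass
class EFTable:
    """(zone, pathway) -> areal emission factor, gCO2e/m2/yr.

    Cells may be absent (no data for the stratum).  Fitted tables carry a
    ``margin`` (half-width of the bootstrap 95% CI) and a per-cell sample
    count ``n``.
    """

    entries: dict
    margin: dict = field(default_factory=dict)
    n: dict = field(default_factory=dict)
    provenance: str = "global"

    def __post_init__(self):
        clean = {}
        for (z, p), v in self.entries.items():
            v = float(v)
            if v < 0:
                raise SchemaError(f"negative emission factor {v} for ({z}, {p})")
            clean[(_zone_key(z), _pathway_key(p))] = v
        self.entries = clean
        self.margin = {
            (_zone_key(z), _pathway_key(p)): float(m)
            for (z, p), m in self.margin.items()
            if m is not None and not (isinstance(m, float) and math.isnan(m))
        }
        if any(m < 0 for m in self.margin.values()):
            raise SchemaError("negative margin in emission-factor table")
        self.n = {(_zone_key(z), _pathway_key(p)): int(c) for (z, p), c in self.n.items()}

    def get(self, zone, pathway) -> float:
        return lookup_ef(self, zone, pathway)

    def has(self, zone, pathway) -> bool:
        return (_zone_key(zone), _pathway_key(pathway)) in self.entries

    def zones(self):
        return sorted({z for z, _ in self.entries}, key=lambda z: z.value)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (z, p), v in sorted(
            self.entries.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
        ):
            rows.append(
                {
                    "zone": z.value,
                    "pathway": p.value,
                    "flux": v,
                    "margin": self.margin.get((z, p), np.nan),
                    "n": self.n.get((z, p), np.nan),
                    "provenance": self.provenance,
                }
            )
        return pd.DataFrame(rows)


def lookup_ef(table: EFTable, zone, pathway) -> float:
    """Return the stored areal emission factor for a (zone, pathway) cell.

    Raises :class:`MissingEF` for absent cells and :class:`UnknownZone` for
    labels outside the six-zone set.
    """
    z = _zone_key(zone)
    p = _pathway_key(pathway)
    try:
        return table.entries[(z, p)]
    except KeyError:
        raise MissingEF(
            f"no emission factor for zone {z.value!r}, pathway {p.value!r} "
            f"in {table.provenance} table"
        ) from None


def load_ef_table(path_or_buffer, provenance: str = "global") -> EFTable:
    """Load an EF table from CSV (columns zone,pathway,flux,margin,provenance).

    Rows are filtered to the requested ``provenance``; absent cells are simply
    absent rows.
    """
    df = pd.read_csv(path_or_buffer)
    required = {"zone", "pathway", "flux"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"EF table must have columns {sorted(required)}", source=str(path_or_buffer)
        )
    if "provenance" in df.columns:
        df = df[df["provenance"] == provenance]
    entries, margin = {}, {}
    for i, row in df.iterrows():
        try:
            key = (ClimateZone.parse(row["zone"]), EmissionPathway.parse(row["pathway"]))
        except UnknownZone as e:
            raise SchemaError(str(e), source=str(path_or_buffer), row=int(i) + 2) from None
        entries[key] = float(row["flux"])
        if "margin" in df.columns and pd.notna(row.get("margin")):
            margin[key] = float(row["margin"])
    return EFTable(entries=entries, margin=margin, provenance=provenance)


def _packaged_table(provenance: str) -> EFTable:
    ref = resources.files("resghg.data").joinpath("emission_factors_global.csv")
    with ref.open("r") as fh:
        return load_ef_table(fh, provenance=provenance)


def global_ef_table() -> EFTable:
    """The shipped global (zone x pathway) Tier 1 emission-factor table."""
    return _packaged_table("global")


def myanmar_ef_table(subset: str = "all") -> EFTable:
    """The shipped Myanmar-recalibrated table (``all`` or ``hp`` reservoirs)."""
    if subset not in ("all", "hp"):
        raise ValueError("subset must be 'all' or 'hp'")
    return _packaged_table(f"myanmar_{subset}")


# ---------------------------------------------------------------------------
# per-site records
# ---------------------------------------------------------------------------

_RES_TYPES = ("hydroelectric", "multipurpose", "irrigation", "ror")
_LANDCOVER_CLASSES = ("forest", "cropland", "shrub", "other")


def _check_fractions(fractions: Mapping[str, float], what: str):
    total = 0.0
    for cls, f in fractions.items():
        if not (0.0 <= f <= 1.0):
            raise SchemaError(f"{what} fraction {cls}={f} outside [0, 1]")
        total += f
    if abs(total - 1.0) > 1e-9:
        raise SchemaError(f"{what} fractions sum to {total}, expected 1")


@dataclass
class ReservoirRecord:
    """Per-reservoir descriptors driving every emission prediction.

    Areas in km2, depth in m, volume in Mm3, residence time in years,
    generation in GWh/yr.  ``landcover`` holds the impounded-area class
    fractions (forest/cropland/shrub/other), summing to one.
    """

    id: str
    res_type: str
    zone: ClimateZone
    area: float
    mean_depth: float
    volume: float
    residence_time: float
    landcover: Mapping[str, float]
    generation: Optional[float] = None
    catchment_id: str = ""

    def __post_init__(self):
        if self.res_type not in _RES_TYPES:
            raise SchemaError(
                f"reservoir {self.id}: res_type {self.res_type!r} not in {_RES_TYPES}"
            )
        self.zone = ClimateZone.parse(self.zone)
        self.landcover = dict(self.landcover)
        _check_fractions(self.landcover, f"reservoir {self.id} land-cover")
        if self.res_type == "ror":
            if self.area != 0:
                raise SchemaError(f"run-of-river asset {self.id} must have area 0")
        else:
            if self.area <= 0:
                raise ZeroArea(f"reservoir {self.id}: area {self.area} <= 0")
            if self.mean_depth <= 0:
                raise SchemaError(f"reservoir {self.id}: mean_depth must be > 0")

    @property
    def forest_fraction(self) -> float:
        return self.landcover.get("forest", 0.0)

    @property
    def cropland_fraction(self) -> float:
        return self.landcover.get("cropland", 0.0)

    @property
    def shrub_fraction(self) -> float:
        return self.landcover.get("shrub", 0.0)

    @property
    def other_fraction(self) -> float:
        return self.landcover.get("other", 0.0)

    @property
    def littoral_fraction(self) -> float:
        """Rough littoral-area proxy: share of the surface over depth < 3 m,
        assuming a linear depth distribution up to twice the mean depth."""
        if self.mean_depth <= 0:
            return 1.0
        return min(1.0, 3.0 / (2.0 * self.mean_depth))


@dataclass
class CatchmentRecord:
    """Per-catchment descriptors (area km2, runoff and ET mm/yr, air
    temperature degC, mean slope %, population density persons/km2)."""

    id: str
    area: float
    runoff: float
    evapotranspiration: float
    air_temperature: float
    mean_slope: float
    population_density: float
    landcover: Mapping[str, float]

    def __post_init__(self):
        if self.area <= 0:
            raise SchemaError(f"catchment {self.id}: area must be > 0")
        if self.runoff < 0 or self.evapotranspiration < 0:
            raise SchemaError(f"catchment {self.id}: runoff/ET must be >= 0")
        self.landcover = dict(self.landcover)
        _check_fractions(self.landcover, f"catchment {self.id} land-cover")

    @property
    def forest_fraction(self) -> float:
        return self.landcover.get("forest", 0.0)

    @property
    def cropland_fraction(self) -> float:
        return self.landcover.get("cropland", 0.0)


@dataclass
class GrossEmissionProfile:
    """Per-pathway gross areal fluxes plus totals for one reservoir.

    ``total_areal`` (gCO2e/m2/yr) is the sum over pathways; ``total_mass``
    (tCO2e/yr) is total_areal x area in km2 (exact unit identity).
    """

    fluxes: Mapping[EmissionPathway, float]
    area: float
    ch4_split: Optional[Mapping[str, float]] = None

    def __post_init__(self):
        self.fluxes = {_pathway_key(p): float(v) for p, v in self.fluxes.items()}
        for p, v in self.fluxes.items():
            if v < 0:
                raise SchemaError(f"negative gross flux {v} for pathway {p.value}")

    @property
    def total_areal(self) -> float:
        return float(sum(self.fluxes.values()))

    @property
    def total_mass(self) -> float:
        # g/m2/yr x 1e6 m2/km2 = 1e6 g/km2/yr = 1 t/km2/yr
        return self.total_areal * self.area

    @property
    def f_co2(self) -> float:
        return self.fluxes.get(EmissionPathway.CO2_DIFFUSIVE, 0.0)

    def f_ch4(self, include_degassing: bool = True) -> float:
        """CH4 aggregate for the net-conversion law.  Defaults to all three
        CH4 pathways; ``include_degassing=False`` restricts to surface
        pathways."""
        if self.ch4_split is not None:
            return float(sum(self.ch4_split.values()))
        total = 0.0
        for name in CH4_PATHWAYS:
            if name == "ch4_degassing" and not include_degassing:
                continue
            total += self.fluxes.get(EmissionPathway(name), 0.0)
        return total


@dataclass
class NetConversionParams:
    """Parameters of the bilinear gross-to-net conversion law.

    ``net_co2``/``net_ch4`` are the net-anthropogenic proportions of each
    gas's gross flux; ``r_downstream`` the downstream-to-surface emission
    ratio.  The shipped default (1, 1, 0) is deliberately neutral and
    labelled *uncalibrated*: calibrated values must come from
    :class:`resghg.calibration.NetParameterModel` or user input.
    """

    net_co2: float = 1.0
    net_ch4: float = 1.0
    r_downstream: float = 0.0
    calibrated: bool = False

    def __post_init__(self):
        if not (-1.0 <= self.net_co2 <= 1.0 and -1.0 <= self.net_ch4 <= 1.0):
            raise SchemaError("net_co2 and net_ch4 must lie in [-1, 1]")
        if self.r_downstream < 0:
            raise SchemaError("r_downstream must be >= 0")


@dataclass
class PreImpoundmentTable:
    """Areal GHG flux of each pre-impoundment land-cover class, gCO2e/m2/yr.

    Entries may be negative: intact landscapes (notably tropical forest on
    mineral soil) can be net carbon sinks, and flooding them converts the
    lost sink into a positive net emission term.
    """

    fluxes: Mapping[str, float]

    def __post_init__(self):
        self.fluxes = {str(k): float(v) for k, v in self.fluxes.items()}


@dataclass
class PathwayRegression:
    """One pathway's regression: flux = link_inv(intercept + coef . x)."""

    features: Sequence[str]
    coefficients: Sequence[float]
    intercept: float
    link: str = "identity"

    def __post_init__(self):
        if self.link not in ("identity", "log10"):
            raise SchemaError(f"link must be 'identity' or 'log10', got {self.link!r}")
        if len(self.features) != len(self.coefficients):
            raise SchemaError("features and coefficients differ in length")
        self.coefficients = [float(c) for c in self.coefficients]


@dataclass
class EmpiricalModelConfig:
    """Pathway-structured empirical emission model configuration.

    ``gwp_ch4`` is the CO2-equivalence factor applied to CH4-pathway
    predictions (required; no silent default because it depends on the GWP
    horizon the user adopts).  ``uas_fraction`` is the share of the gross
    flux attributed to unrelated anthropogenic nutrient/organic-matter
    sources in the catchment, removed when converting to net emissions.
    ``lifetime_factor`` and ``displaced_areal`` are the neutral-by-default
    multiplier/offset standing in for lifetime-integration and displaced-
    emission accounting.
    """

    pathways: Mapping[EmissionPathway, PathwayRegression]
    gwp_ch4: float
    uas_fraction: float = 0.0
    lifetime_factor: float = 1.0
    displaced_areal: float = 0.0

    def __post_init__(self):
        self.pathways = {_pathway_key(p): r for p, r in self.pathways.items()}
        if self.gwp_ch4 <= 0:
            raise SchemaError("gwp_ch4 must be > 0")
        if not (0.0 <= self.uas_fraction <= 1.0):
            raise SchemaError("uas_fraction must lie in [0, 1]")


@dataclass
class NetEmissionResult:
    """Gross profile plus the net-anthropogenic accounting for one site."""

    gross: GrossEmissionProfile
    pre_impoundment_areal: float
    net_areal: float

    @property
    def net_mass(self) -> float:
        return self.net_areal * self.gross.area


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def per_day(flux_per_year: float) -> float:
    """Convert gCO2e/m2/yr to gCO2e/m2/d."""
    return flux_per_year / DAYS_PER_YEAR


def per_year(flux_per_day: float) -> float:
    """Convert gCO2e/m2/d to gCO2e/m2/yr."""
    return flux_per_day * DAYS_PER_YEAR


def tier1_gross_profile(
    res: ReservoirRecord,
    table: EFTable,
    include_degassing_for_irrigation: bool = True,
) -> GrossEmissionProfile:
    """Tier 1 gross profile: four (zone, pathway) lookups for the reservoir.

    With ``include_degassing_for_irrigation=False`` the CH4 degassing flux of
    irrigation reservoirs is zeroed — degassing requires a pressurized deep
    outlet, which irrigation systems typically lack.  Other reservoir types
    are unaffected by the flag.
    """
    if res.res_type != "ror" and res.area <= 0:
        raise ZeroArea(f"reservoir {res.id}: area {res.area} <= 0")
    fluxes = {}
    for p in EmissionPathway:
        if (
            p is EmissionPathway.CH4_DEGASSING
            and res.res_type == "irrigation"
            and not include_degassing_for_irrigation
        ):
            fluxes[p] = 0.0
            continue
        fluxes[p] = lookup_ef(table, res.zone, p)
    return GrossEmissionProfile(fluxes=fluxes, area=res.area)


def _resolve_feature(name: str, res: ReservoirRecord, cat: CatchmentRecord) -> float:
    """Resolve a feature name against the reservoir record, then the
    catchment record.  ``res_``/``cat_`` prefixes force the namespace."""
    if name.startswith("res_") and name != "res_type":
        return _lookup_attr(res, name[4:], name)
    if name.startswith("cat_"):
        return _lookup_attr(cat, name[4:], name)
    for obj in (res, cat):
        try:
            return _lookup_attr(obj, name, name)
        except MissingFeature:
            continue
    raise MissingFeature(f"feature {name!r} resolves to no reservoir or catchment field")


def _lookup_attr(obj, attr: str, original: str) -> float:
    if hasattr(obj, attr):
        value = getattr(obj, attr)
        if isinstance(value, (int, float, np.floating)) and value is not None:
            return float(value)
    raise MissingFeature(f"feature {original!r} resolves to no numeric field")


def predict_empirical_profile(
    res: ReservoirRecord,
    cat: CatchmentRecord,
    cfg: EmpiricalModelConfig,
) -> GrossEmissionProfile:
    """Evaluate the configured per-pathway regressions for one site.

    CH4-pathway outputs are multiplied by ``cfg.gwp_ch4`` to express them in
    gCO2e.  Negative identity-link predictions are clamped to zero with a
    warning (gross fluxes are non-negative by definition); log10-link
    predictions are positive by construction.
    """
    fluxes = {}
    for pathway, reg in cfg.pathways.items():
        eta = reg.intercept
        for name, coef in zip(reg.features, reg.coefficients):
            eta += coef * _resolve_feature(name, res, cat)
        if reg.link == "log10":
            flux = 10.0 ** eta
        else:
            flux = eta
            if flux < 0:
                warnings.warn(
                    f"clamped negative {pathway.value} prediction "
                    f"({flux:.3g}) to 0 for reservoir {res.id}",
                    stacklevel=2,
                )
                flux = 0.0
        if pathway.value in CH4_PATHWAYS:
            flux *= cfg.gwp_ch4
        if not math.isfinite(flux):
            raise NonFiniteFlux(
                f"non-finite {pathway.value} flux for reservoir {res.id} "
                f"(linear predictor {eta:.6g}, link {reg.link})"
            )
        fluxes[pathway] = flux
    return GrossEmissionProfile(fluxes=fluxes, area=res.area)


def pre_impoundment_flux(res: ReservoirRecord, table: PreImpoundmentTable) -> float:
    """Area-weighted pre-impoundment landscape flux over the impounded area.

    May be negative when the flooded landscape was a net carbon sink.
    """
    total = 0.0
    for cls, fraction in res.landcover.items():
        if fraction <= 0.0:
            continue
        if cls not in table.fluxes:
            raise MissingClassFlux(
                f"reservoir {res.id}: land-cover class {cls!r} (fraction "
                f"{fraction}) has no pre-impoundment flux entry"
            )
        total += fraction * table.fluxes[cls]
    return total


def net_from_gross(f_co2: float, f_ch4: float, p: NetConversionParams) -> float:
    """Bilinear gross-to-net conversion (same unit in as out)."""
    return (p.net_co2 * f_co2 + p.net_ch4 * f_ch4) * (1.0 + p.r_downstream)


def net_anthropogenic(
    res: ReservoirRecord,
    cat: CatchmentRecord,
    cfg: EmpiricalModelConfig,
    pre_table: PreImpoundmentTable,
) -> NetEmissionResult:
    """Model-route net anthropogenic emissions for one site.

    net_areal = [gross_total x (1 - uas_fraction) - pre_impoundment]
                x lifetime_factor - displaced_areal

    with the lifetime factor and displaced offset neutral (1, 0) by default.
    The result may be negative (flooding a strong source landscape, or high
    unrelated-anthropogenic share).
    """
    gross = predict_empirical_profile(res, cat, cfg)
    pre = pre_impoundment_flux(res, pre_table)
    net_areal = (
        gross.total_areal * (1.0 - cfg.uas_fraction) - pre
    ) * cfg.lifetime_factor - cfg.displaced_areal
    return NetEmissionResult(gross=gross, pre_impoundment_areal=pre, net_areal=net_areal)


def emission_intensity(
    total_mass: float,
    generation: float,
    res_type: str = "hydroelectric",
    lifecycle: bool = False,
    ror_constant: float = ROR_BIOGENIC_EI,
    lifecycle_increment: float = LIFECYCLE_EI_INCREMENT,
) -> float:
    """Emission intensity in gCO2e/kWh.

    tCO2e/yr over GWh/yr reduces to g/kWh exactly (1e6 g/t over 1e6 kWh/GWh).
    Run-of-river assets use the configured constant biogenic intensity
    regardless of mass; the life-cycle variant adds the configured increment.
    """
    if res_type == "ror":
        ei = ror_constant
    else:
        if generation is None or generation <= 0:
            raise ZeroGeneration(f"generation must be > 0, got {generation}")
        ei = total_mass / generation
    if lifecycle:
        ei += lifecycle_increment
    return ei
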