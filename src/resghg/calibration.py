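"""Country-specific emission-factor and net-parameter calibration.

Two fittable models, both presented in the Model -> ``fit()`` -> Results
idiom:

* :class:`ZoneEmissionFactorModel` regresses per-reservoir pathway fluxes
  (typically empirical-model outputs) on climate-zone indicator variables
  without a global intercept.  Because the indicators are disjoint, the OLS
  solution is exactly the per-zone mean flux — the refined, country-specific
  Tier 1 emission factor.  Uncertainty comes from a percentile bootstrap
  over reservoirs (resampled datasets, refit per resample, 95% interval;
  the reported *margin* is half the interval width).
* :class:`NetParameterModel` calibrates the bilinear gross-to-net law
  F_net = (a * F_CO2 + b * F_CH4) * (1 + r): for each candidate r on a
  user grid it solves the two-coefficient least squares for (a, b) and
  returns the triple with the smallest residual sum of squares (ties to the
  smallest r).  Profiling r on a grid sidesteps the bilinearity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .emissions import (
    ClimateZone,
    EFTable,
    EmissionPathway,
    NetConversionParams,
)
from .errors import DegenerateCell, EmptySubset, RankDeficient, SchemaError

__all__ = [
    "ZoneEmissionFactorModel",
    "ZoneEFResults",
    "NetParameterModel",
    "NetParameterResults",
    "PATHWAY_COLUMNS",
]

PATHWAY_COLUMNS = tuple(p.value for p in EmissionPathway)
_HP_TYPES = ("hydroelectric", "multipurpose")


def _validate_samples(samples: pd.DataFrame) -> pd.DataFrame:
    required = {"id", "zone", "res_type"}
    missing = required - set(samples.columns)
    if missing:
        raise SchemaError(f"calibration samples missing columns {sorted(missing)}")
    flux_cols = [c for c in PATHWAY_COLUMNS if c in samples.columns]
    if not flux_cols:
        raise SchemaError(
            f"calibration samples need at least one pathway flux column "
            f"among {list(PATHWAY_COLUMNS)}"
        )
    if samples["id"].duplicated().any():
        dup = samples.loc[samples["id"].duplicated(), "id"].iloc[0]
        raise SchemaError(f"duplicate reservoir id {dup!r} in calibration samples")
    out = samples.copy()
    out["zone"] = out["zone"].map(lambda z: ClimateZone.parse(z).value)
    return out


def _zone_ols(zones: np.ndarray, flux: np.ndarray, zone_labels: Sequence[str]):
    """OLS of flux on disjoint zone indicators (no intercept).

    Solved with lstsq on the indicator design rather than a groupby so the
    estimator genuinely is the stated regression; tests check the group-mean
    identity independently.
    """
    X = np.column_stack([(zones == z).astype(float) for z in zone_labels])
    present = X.sum(axis=0) > 0
    beta = np.full(len(zone_labels), np.nan)
    if present.any():
        ok = np.isfinite(flux)
        sol, *_ = np.linalg.lstsq(X[ok][:, present], flux[ok], rcond=None)
        beta[present] = sol
    return beta, X.sum(axis=0).astype(int)


@dataclass
class ZoneEFResults:
    """Fitted zone emission factors, one per (zone, pathway) cell.

    ``table`` carries the fluxes as an :class:`EFTable` with provenance
    ``fitted``; ``margins`` (half-width of the bootstrap percentile 95% CI)
    are present when the model was fitted with ``n_boot >= 2``.
    """

    model: "ZoneEmissionFactorModel"
    subset: str
    ef: pd.DataFrame  # columns zone, pathway, ef, n
    margins: Optional[pd.DataFrame] = None  # + margin, unreliable
    n_boot: int = 0
    seed: Optional[int] = None
    unreliable_cells: list = field(default_factory=list)

    @property
    def table(self) -> EFTable:
        entries, margin, counts = {}, {}, {}
        mg = None
        if self.margins is not None:
            mg = {
                (r.zone, r.pathway): r.margin
                for r in self.margins.itertuples()
                if np.isfinite(r.margin)
            }
        for r in self.ef.itertuples():
            if not np.isfinite(r.ef):
                continue
            key = (r.zone, r.pathway)
            entries[key] = max(r.ef, 0.0)
            counts[key] = r.n
            if mg and key in mg:
                margin[key] = mg[key]
        return EFTable(entries=entries, margin=margin, n=counts, provenance="fitted")

    def summary(self) -> str:
        lines = [
            "Zone emission-factor calibration",
            f"  subset: {self.subset}   reservoirs: {self.model.n_samples(self.subset)}",
            f"  bootstrap: n_boot={self.n_boot}, seed={self.seed}",
            "",
            f"{'zone':<30}{'pathway':<16}{'EF':>10}{'margin':>10}{'n':>5}",
        ]
        mg = {}
        if self.margins is not None:
            mg = {(r.zone, r.pathway): r.margin for r in self.margins.itertuples()}
        for r in self.ef.itertuples():
            if not np.isfinite(r.ef):
                continue
            m = mg.get((r.zone, r.pathway), np.nan)
            m_str = f"{m:>10.1f}" if np.isfinite(m) else f"{'--':>10}"
            lines.append(f"{r.zone:<30}{r.pathway:<16}{r.ef:>10.2f}{m_str}{r.n:>5d}")
        if self.unreliable_cells:
            lines.append("")
            lines.append(f"  unreliable cells (zone lost in >50% of resamples): "
                         f"{self.unreliable_cells}")
        return "\n".join(lines)


class ZoneEmissionFactorModel:
    """OLS of per-reservoir pathway fluxes on climate-zone indicators.

    Parameters
    ----------
    samples : DataFrame
        One row per reservoir with columns ``id``, ``zone``, ``res_type``
        and one or more pathway flux columns (gCO2e/m2/yr) among
        ``co2_diffusive, ch4_diffusive, ch4_ebullition, ch4_degassing``.
    """

    def __init__(self, samples: pd.DataFrame):
        self.samples = _validate_samples(samples)
        self.flux_columns = [c for c in PATHWAY_COLUMNS if c in self.samples.columns]

    @classmethod
    def from_dataframe(cls, samples: pd.DataFrame) -> "ZoneEmissionFactorModel":
        return cls(samples)

    def _subset(self, subset: str) -> pd.DataFrame:
        if subset == "all":
            df = self.samples
        elif subset in ("hp", "hp_only"):
            df = self.samples[self.samples["res_type"].isin(_HP_TYPES)]
        else:
            raise ValueError(f"subset must be 'all' or 'hp_only', got {subset!r}")
        if len(df) == 0:
            raise EmptySubset(f"no calibration samples in subset {subset!r}")
        return df

    def n_samples(self, subset: str = "all") -> int:
        return len(self._subset(subset))

    def fit(
        self,
        subset: str = "all",
        n_boot: int = 1000,
        seed: Optional[int] = None,
        degenerate_threshold: float = 0.5,
    ) -> ZoneEFResults:
        """Fit zone EFs; with ``n_boot >= 2`` also bootstrap the margins.

        The bootstrap resamples reservoirs (rows) with replacement, refits
        the zone regression per resample, and takes the percentile 2.5/97.5
        interval per cell.  Cells whose zone vanishes from more than
        ``degenerate_threshold`` of the resamples are flagged unreliable
        (margin reported as NaN) and a :class:`DegenerateCell` warning is
        issued.
        """
        df = self._subset(subset)
        zone_labels = sorted(df["zone"].unique())
        zones = df["zone"].to_numpy()

        rows = []
        for col in self.flux_columns:
            beta, counts = _zone_ols(zones, df[col].to_numpy(float), zone_labels)
            for z, b, n in zip(zone_labels, beta, counts):
                rows.append({"zone": z, "pathway": col, "ef": b, "n": int(n)})
        ef = pd.DataFrame(rows)

        margins = None
        unreliable = []
        if n_boot >= 2:
            rng = np.random.default_rng(seed)
            n = len(df)
            flux_mat = df[self.flux_columns].to_numpy(float)
            boot = np.full((n_boot, len(zone_labels), len(self.flux_columns)), np.nan)
            idx_all = rng.integers(0, n, size=(n_boot, n))
            for b in range(n_boot):
                idx = idx_all[b]
                zb = zones[idx]
                for j in range(len(self.flux_columns)):
                    beta, _ = _zone_ols(zb, flux_mat[idx, j], zone_labels)
                    boot[b, :, j] = beta
            mrows = []
            for i, z in enumerate(zone_labels):
                present = np.isfinite(boot[:, i, 0])
                lost_fraction = 1.0 - present.mean()
                for j, col in enumerate(self.flux_columns):
                    vals = boot[present, i, j]
                    if lost_fraction > degenerate_threshold or len(vals) < 2:
                        unreliable.append((z, col))
                        mrows.append(
                            {"zone": z, "pathway": col, "margin": np.nan,
                             "lo": np.nan, "hi": np.nan, "unreliable": True}
                        )
                        continue
                    lo, hi = np.percentile(vals, [2.5, 97.5])
                    mrows.append(
                        {"zone": z, "pathway": col, "margin": (hi - lo) / 2.0,
                         "lo": lo, "hi": hi, "unreliable": False}
                    )
            margins = pd.DataFrame(mrows)
            for z, col in unreliable:
                warnings.warn(
                    DegenerateCell(
                        f"zone {z!r} vanished from >{degenerate_threshold:.0%} of "
                        f"bootstrap resamples; margin for ({z}, {col}) unreliable"
                    ).args[0],
                    stacklevel=2,
                )

        return ZoneEFResults(
            model=self,
            subset="all" if subset == "all" else "hp_only",
            ef=ef,
            margins=margins,
            n_boot=n_boot if n_boot >= 2 else 0,
            seed=seed,
            unreliable_cells=unreliable,
        )


# ---------------------------------------------------------------------------
# net-parameter calibration
# ---------------------------------------------------------------------------

@dataclass
class NetParameterResults:
    """Calibrated net-conversion parameters with the profiled-r diagnostics."""

    params: NetConversionParams
    rss: float
    r_grid: np.ndarray
    rss_by_r: np.ndarray
    n: int

    def summary(self) -> str:
        p = self.params
        return (
            "Net-conversion parameter calibration\n"
            f"  n = {self.n} reservoirs, r profiled over {len(self.r_grid)} values\n"
            f"  net_co2 = {p.net_co2:.4f}\n"
            f"  net_ch4 = {p.net_ch4:.4f}\n"
            f"  r_downstream = {p.r_downstream:.4f}\n"
            f"  residual sum of squares = {self.rss:.6g}"
        )


class NetParameterModel:
    """Calibrate (net_co2, net_ch4, r_downstream) against target net fluxes.

    Parameters
    ----------
    f_co2, f_ch4 : array-like
        Per-reservoir gross areal CO2 and CH4 fluxes (any consistent unit).
    target_net : array-like
        Per-reservoir net anthropogenic flux to be matched (same unit),
        typically the empirical-model output.
    """

    def __init__(self, f_co2, f_ch4, target_net):
        self.f_co2 = np.asarray(f_co2, dtype=float)
        self.f_ch4 = np.asarray(f_ch4, dtype=float)
        self.target = np.asarray(target_net, dtype=float)
        if not (len(self.f_co2) == len(self.f_ch4) == len(self.target)):
            raise SchemaError("f_co2, f_ch4 and target_net must have equal length")
        if len(self.f_co2) < 2:
            raise SchemaError("need at least two reservoirs to calibrate")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, co2="f_co2", ch4="f_ch4", target="net"
    ) -> "NetParameterModel":
        return cls(df[co2], df[ch4], df[target])

    def fit(self, r_grid: Sequence[float]) -> NetParameterResults:
        r_grid = np.asarray(sorted(set(float(r) for r in r_grid)))
        if len(r_grid) == 0:
            raise SchemaError("r_grid must be non-empty")
        if np.any(r_grid < 0):
            raise SchemaError("r_downstream candidates must be >= 0")
        X0 = np.column_stack([self.f_co2, self.f_ch4])
        if np.linalg.matrix_rank(X0) < 2:
            raise RankDeficient(
                "f_co2 and f_ch4 columns are collinear; net_co2/net_ch4 not identifiable"
            )
        from scipy.optimize import lsq_linear

        best = None
        rss_by_r = np.empty(len(r_grid))
        for i, r in enumerate(r_grid):
            X = X0 * (1.0 + r)
            sol = lsq_linear(X, self.target, bounds=(-1.0, 1.0))
            resid = self.target - X @ sol.x
            rss = float(resid @ resid)
            rss_by_r[i] = rss
            # near-ties resolve to the smallest r (grid is sorted ascending)
            if best is None or rss < best[0] * (1.0 - 1e-9) - 1e-12:
                best = (rss, r, sol.x)
        rss, r, coef = best
        params = NetConversionParams(net_co2=float(coef[0]), net_ch4=float(coef[1]),
                                     r_downstream=float(r), calibrated=True)
        return NetParameterResults(
            params=params, rss=rss, r_grid=r_grid, rss_by_r=rss_by_r, n=len(self.target)
        )
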