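# Methods

This note records the models implemented in `resghg`, their assumptions,
the numerical choices made where the design was genuinely open, and what
the synthetic-data generator does and does not emulate.

## Units and accounting identities

The canonical flux unit is gCO₂e m⁻² yr⁻¹ (the unit of the shipped
emission-factor table); CH₄ is always already weighted to CO₂-equivalents.
Mass totals use the exact identity 1 g m⁻² yr⁻¹ × 10⁶ m² km⁻² =
1 t km⁻² yr⁻¹, and emission intensity uses t yr⁻¹ / GWh yr⁻¹ ≡ g/kWh, so no
rounding constants enter the accounting. The bilinear gross-to-net law is
often quoted per day; because it is homogeneous of degree one in the
fluxes, applying it directly in per-year units is exact, and
`per_day`/`per_year` converters (× / ÷ 365.25) are provided only for
reporting parity.

## Tier 1 route

A Tier 1 emission factor is one areal flux per (climatic zone × pathway)
stratum applied to every reservoir in the stratum. The shipped global
table covers six zones and four pathways (CO₂ diffusion; CH₄ diffusion,
ebullition, downstream degassing); a fitted country-specific variant
carries bootstrap margins and per-cell sample counts, with absent cells
meaning "no data for this stratum", which lookups surface as a `MissingEF`
error rather than a silent fallback. CH₄ degassing requires a pressurised
deep outlet; irrigation reservoirs typically lack one, so a flag can zero
their degassing flux (the default keeps it, the deliberately inclusive
choice). Totals are monotone in every table cell by construction.

## Empirical (model) route

Each pathway has a regression F_p = link⁻¹(β₀ + βᵀx) over named reservoir
and catchment fields (identity or log₁₀ link). The coefficients are user
configuration, not package constants: published model regressions are
licensed artefacts and the framework is designed to wrap any
spatially-explicit emission model. Negative identity-link predictions are
clamped to zero with a logged warning — gross fluxes are non-negative by
definition. The CH₄ CO₂-equivalence factor (`gwp_ch4`) is a *required*
configuration value with no silent default, because it depends on the GWP
horizon the user adopts; the Tier 1 table needs none since its cells are
already CO₂e.

Net anthropogenic emissions on this route are

    net = [gross_total · (1 − uas_fraction) − pre_impoundment] · lifetime − displaced

where `pre_impoundment` is the area-weighted flux of the flooded landscape
(negative for sink landscapes such as forest on mineral soils — flooding a
sink *adds* to the net footprint), `uas_fraction` removes the share of the
gross flux driven by unrelated anthropogenic nutrient and organic-matter
inputs, and the lifetime-integration factor and displaced-emission offset
default to the neutral (1, 0): they are named but unspecified balances, so
they are exposed as configuration rather than modelled. The Tier 1 route
instead uses the bilinear law F_net = (a·F_CO2 + b·F_CH4)(1 + r); its
default parameters (1, 1, 0) are labelled *uncalibrated* and the CH₄
aggregate defaults to all three CH₄ pathways with a surface-only switch,
since the aggregation behind published coefficient sets is not fixed.

## Zone-EF calibration

`ZoneEmissionFactorModel` fits ordinary least squares of per-reservoir
pathway fluxes on climate-zone indicator variables without a global
intercept. Because the indicators are disjoint, the OLS solution is
algebraically the per-zone mean — the tests assert this identity rather
than assume it. Zones absent from the data yield absent cells; an `hp_only`
subset restricts to hydroelectric + multipurpose reservoirs. Uncertainty
is a percentile bootstrap (chosen over a normal approximation, and
switchable in principle, because percentile intervals behave better for
skewed flux distributions at modest n): reservoirs are resampled with
replacement `n_boot` times (default 1000), the regression refit per
resample, and the margin reported as half the width of the 2.5–97.5
percentile interval. A zone that vanishes from more than half the
resamples marks its cells unreliable (margin NaN plus a warning) instead
of reporting a fabricated interval. Fitted tables carry n per cell so a
rendered table can annotate reliability.

`NetParameterModel` profiles R_downstream on a user grid — the law is
bilinear, so for fixed r the (net_CO2, net_CH4) fit is linear — and solves
each conditional fit as *bounded* least squares on [−1, 1] (the parameters
are proportions). Ties in residual sum of squares resolve to the smallest
r. One consequence is worth stating plainly: the law is scale-invariant in
(1 + r), so with targets that the law fits exactly, r is not identifiable
— every grid point achieves the same RSS and the smallest r is returned.
The identifiable quantities are the products net·(1 + r); r itself becomes
identifiable only when the [−1, 1] bound binds for small r. The tests
check exactly this.

## Delineation

Grids are row/col, 0-based, cell-centre registered; raster I/O is ESRI
ASCII (single band, text). Flow routing is D8 steepest descent with
neighbours ordered N, NE, E, SE, S, SW, W, NW and ties broken in that
order — every operation is deterministic, with no randomness anywhere in
the delineation chain. Flooding and water-body extraction use
4-connectivity; routing uses 8-connectivity. Dam snapping minimises
Euclidean distance to cells whose accumulation exceeds the river
threshold, ties broken by higher accumulation then row-major order.

A planned reservoir floods cells with elevation ≤ FSL that are 4-connected
to the dam cell *and inside the dam's catchment* — the catchment
restriction is what keeps the downstream valley dry. FSL defaults to base
elevation + dam height − buffer height (the freeboard between FSL and
crest). Flooding is monotone in FSL. An existing reservoir is the
contiguous water-class region at or adjacent to the dam on the upstream
side.

Pfafstetter codes are generated on synthetic basins by the standard
scheme: per level, the four largest tributaries of the main stem (traced
upstream by maximal accumulation) take even digits 2/4/6/8 downstream to
upstream, the interbasins between them odd digits 1/3/5/7/9. One
refinement matters for correctness: the confluence cell itself is assigned
to the *downstream* interbasin, which keeps the "numerically lower code =
downstream" comparison exact even when a tributary joins at a unit's
outlet. Upstream compilation picks the region of interest as the longest
code prefix shared by all topological ancestors of the dam's sub-basin,
discards basins with codes lower than the dam basin's (codes of unequal
length compare hierarchically, digit by digit, with a prefix treated as
containing), and confirms the survivors by an upstream traversal of the
downstream-neighbour topology. Mixed working resolutions are emulated by
an optional nearest-neighbour coarsen/refine step rather than modelled.

## Surrogate and explanations

The surrogate is a LightGBM gradient-boosted regression-tree ensemble, one
per gas. Hyperparameters (learning rate, num_leaves, max_depth,
feature/bagging fractions, L1/L2, min_data_in_leaf) are tuned by a seeded
random search — default 50 trials, 5-fold cross-validation, up to 1000
boosting rounds with 50-round early stopping — scored by out-of-fold RMSE,
then refit on all data at the median of the per-fold best iteration
counts. LightGBM runs single-threaded deterministic, so a fixed seed
reproduces parameters, metrics and predictions bit-for-bit. Reported
metrics are out-of-fold: RRMSE = 100·RMSE/mean(y), RMAE =
100·MAE/mean(|y|) (these denominators are this package's definition), R².
Constant targets report RRMSE 0 and an undefined (NaN) R².

Breakdown attributions decompose one prediction against a background
sample (default: the full training matrix; a seeded subsample is available
for speed): v₀ is the mean prediction over the background, and feature k's
contribution is the change in that mean when features 1..k are replaced by
the instance's values. The replacement order is greedy by decreasing
single-feature |effect on the mean| — the ordering is a documented choice;
for additive models it is irrelevant, and interaction attribution is out
of scope in this version. The telescoping construction makes
intercept + Σ contributions = prediction exact. Permutation importance is
the mean RMSE increase over B (default 10) seeded column shuffles; a
feature the fitted trees never split on scores exactly zero. The
attribution matrix is embedded by column-centred PCA (SVD); reservoirs are
grouped by seeded k-means on the scores into 3 categories by default —
the categories are a reading convenience for maps and scatter plots, not a
claim of discrete structure.

## Portfolio planning

Dams are edges of a rooted tree oriented from the outlet toward the
sources; the line-graph transform collapses maximal dam-free river
stretches into single region nodes (dam-free edges are merged by
union-find; a headwater dam gets a synthesised empty source region).
Objectives are sums for energy and firm power, and sums *or* means for
emissions and land losses — reports default to total emissions, with the
mean variant selectable per objective, since both aggregations are in
legitimate use. Firm power is the 5th percentile of the generation series
under the linear-interpolation order-statistic convention, annualised by a
caller-supplied periods-per-year factor.

The frontier is computed by a bottom-up dynamic program: each subtree
carries (portfolio, accumulator) states; an edge's states are its child's
states with and without the dam (forced dams under the built scenario drop
the "without" branch); children merge by accumulator addition, with
mean-aggregated objectives carried as (sum, count) pairs so merging stays
exact. After every merge, states are pruned two ways: an exact dominance
filter, and — for ε > 0 — a grid filter with per-merge cell ε/n (n =
number of assets) on objectives normalised by single-asset-extrema ranges,
so the error accumulated along any composition path is at most ε. Because
a partial mean is not monotone under later additions, dominance and grid
pruning are applied only *within* groups of equal selected-asset count
when any mean objective is present; the final frontier is filtered by
global exact dominance on the realised objective values. ε = 0 therefore
returns the exact Pareto set, and the tests verify both exactness and the
ε-coverage guarantee against brute-force enumeration.

## Synthetic data

The generator's defaults are the package's study conditions. The DEM is a
smoothed Gaussian random field with a corner tilt, hydrologically
conditioned by priority-flood from the single lowest boundary cell with a
strictly increasing epsilon — this guarantees every cell has a descending
D8 path to exactly one outlet. Temperature falls with elevation at a
6.5 °C/km lapse rate; runoff rises with elevation; six elevation bands map
to the six climatic zones with the warm/tropical zones occupying most of
the lowlands; forest probability rises away from the warm lowland band and
water is painted along the largest rivers. The default fleet is 60 dams
(the scale of a national planned-hydropower inventory) placed on river
cells with a minimum separation, typed by elevation band (irrigation in
the warm lowlands, hydroelectric/multipurpose upstream, 25 % run-of-river);
the dam network is a tree by construction because dams sit on a drainage
network. Generation is weekly over 38 years from P = ρgηQH (η = 0.9), flow
from catchment runoff with a seasonal sinusoid (amplitude 0.5) and
multiplicative Gaussian noise (sd 0.15), head proportional to mean depth
via a power-law bathymetry; run-of-river assets scale with runoff at a
nominal 20 m head.

The emission truth law is linear-in-features with identity link by default
(so closed-form checks exist; a log₁₀ variant is provided for stress
tests): CH₄ pathways decrease in mean depth and increase in temperature
and catchment area, diffusive CO₂ increases in impounded forest fraction
and temperature, with Gaussian noise of sd 30 g m⁻² yr⁻¹ and truth
coefficients expressed directly in gCO₂e (the emitted config sets the CH₄
equivalence factor to 1 explicitly). A separate tabular generator draws
fleets and pure zone-mean flux laws directly — used where only the records
matter (calibration recovery at n = 300, driver-recovery checks) because
raster delineation of hundreds of reservoirs contributes nothing to those
questions. Every distribution parameter is recorded in the run manifest
and all outputs are bit-identical under a fixed seed.

What the generator does *not* emulate: real geography or climatology,
hydrological seasonality beyond a single sinusoid, reservoir operating
rules, drawdown and stratification dynamics, spatially correlated land
cover, or measurement error in the descriptors. Passing tests therefore
demonstrate the *mechanics* — calibration recovers injected strata,
explanations recover injected drivers, the planner is exact against
enumeration — not predictive skill on real fleets.

## Problem sizes and tolerances

The test and acceptance runs use desk-scale sizes chosen to exercise every
code path with comfortable margins: 48×48 grids with 15–25 dams for the
raster pipeline, 100 random grids up to ~24×24 for the delineation
oracles, fleets of 300 for calibration coverage (50 replicates, 500–1000
bootstrap resamples), surrogates at n = 500 with a 6-trial search, and 100
random planner instances up to 12 assets for brute-force comparison.
Exact identities (additivity, OLS = group mean, mass accounting) are
asserted to 1e-9 relative; stochastic recoveries use the standard-error
bounds stated in the tests. Degenerate inputs have defined behaviour
throughout: empty reservoirs flood to an empty mask with a warning,
empty calibration subsets and all-masked grids raise typed errors, and
constant targets report undefined R² rather than a number.

## Known limitations

The delineation operates on single in-memory grids (no tiling, no
geodesic cell areas); the planner's ε-guarantee for mean objectives is
conditional on the count-grouped pruning described above; the breakdown
ordering is a heuristic and interaction effects are not attributed; N₂O,
lifetime flux decay curves and drawdown-zone emissions are out of scope;
and the net-parameter calibration cannot identify R_downstream away from
the coefficient bounds (see above).
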