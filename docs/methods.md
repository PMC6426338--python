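# Methods

This note describes the models the package implements, the conventions and
numerical choices behind them, and what the synthetic generators do and do
not emulate.

## Grids and change layers

All rasters live on a regular lat/lon grid, 0.05° by default (~5 km at the
equator), stored row-major from the northwest corner; cell (i, j) has center
`lon = origin_lon + (j + 0.5)·res`, `lat = origin_lat − (i + 0.5)·res`.
Masked cells never contribute to any computation and masking only grows
through the pipeline.

Fine-resolution forest cover is aggregated by block averaging over valid
fine cells (a coarse cell with no valid fine cell is masked). Continuous
fields at other resolutions are brought to the analysis grid by bilinear
interpolation at cell centers; a target cell giving nonzero weight to any
masked source cell is masked rather than filled (conservative propagation —
the alternative, renormalizing over valid neighbors, invents values at mask
edges).

Quality control follows the conventions of the satellite products the
pipeline is designed around: LST cells require emissivity error ≤ 0.02 and
LST error ≤ 2 K; albedo cells require quality flags in {0, 1, 2}; a coarse
ET cell requires all 36 fine subpixels present. Temporal aggregation is
hierarchical — day/night pairs average within month before months average to
a year; 8-day composites average within month first — because with unequal
member counts a pooled mean would weight months unequally. Day and night
enter as an unweighted two-term mean. Annual ET is the mean of monthly
mm/month values, not the annual sum. A cell contributes to an intermediate
mean whenever at least one member is valid (`require_all` switches to the
strict policy); how months with partially missing day or night retrievals
should be treated is genuinely ambiguous, so it is a configuration option
rather than a fixed rule.

Changes are decadal differences, later minus earlier epoch, per cell. The
climate epochs sit one year after the forest epochs by default so the
presumed cause precedes the response; same-epoch differencing is a
robustness mode. Latitude bands are tropical (|lat| ≤ 20°), temperate
(20° < |lat| ≤ 50°) and boreal (|lat| > 50°); the boundary values are
assigned to the equatorward class.

## Window pairing

Windows of 5 (lon) × 3 (lat) cells advance with stride 2 × 2, so neighbors
overlap by 3 columns and 1 row. Within a window the focal cell maximizes
|ΔF| among cells exceeding the focal threshold (15 percentage points) and
the reference cell minimizes |ΔF| among cells below the reference threshold
(5 points); either candidate set being empty yields no pair. Ties break to
the first cell in row-major order; windows that do not fit inside the grid
are dropped (no padding, no longitude wraparound); identical (focal,
reference) index pairs arising in overlapping windows keep only the first
occurrence in scan order. The standardized change of each variable is the
focal cell's change minus the reference cell's, taken from the exact same
two cells for every variable; a variable whose value is masked at either
cell is simply absent for that pair, so different analyses see different
pair counts. The pair's region and change category (forestation vs
deforestation, by the sign of the standardized ΔF) are assigned from the
focal cell.

Because both members sit within ~25 km of each other, any climate signal
smooth at scales much larger than a window cancels in the difference: a
field g(lon, lat) added to a change layer moves a standardized change by at
most max|∇g| times the window diagonal. This is the property that lets the
pair statistics isolate local forest-change effects from the regional trend,
and it is tested directly.

## Spatially correlated regression

Residual correlation is modelled as a function of the Euclidean distance
between observations in raw (lon, lat) degrees — matching the convention of
correlation forms written as `~ longitude + latitude` — with one of five
families (r = range):

| family              | ρ(d)                                      |
|---------------------|-------------------------------------------|
| exponential         | exp(−d/r)                                  |
| gaussian            | exp(−(d/r)²)                               |
| rational quadratic  | 1 / (1 + (d/r)²)                           |
| spherical           | 1 − 1.5(d/r) + 0.5(d/r)³ for d < r, else 0 |
| linear              | 1 − d/r for d < r, else 0                  |

No nugget term is included. The paired design adds a per-window random
intercept, entering the marginal covariance as `V = ratio·Z Zᵀ + C` with
`ratio` the window-to-residual variance ratio, so V has diagonal 1 + ratio.

Fixed effects and the residual variance are profiled out analytically
(Cholesky solves), leaving a 1- or 2-parameter likelihood in log(range) and
log(ratio) maximized numerically: bounded Brent for one parameter,
Nelder-Mead from three deterministic starts (distance quantiles 0.1/0.5/0.9)
for two, objective tolerance ~1e-10. Covariance matrices that fail
factorization get an escalating diagonal jitter (recorded on the fit);
parameter regions where even that fails are treated as −∞ likelihood.
REML is the default for reported coefficients and standard errors; ML
log-likelihoods are always computed at the fitted covariance parameters
because AICc comparisons across correlation structures require a common
likelihood (whether rankings should use ML or REML is not settled practice,
so the search likelihood is switchable). The parameter count k for AICc is
fixed effects + range (if any) + variance ratio (if any) + residual
variance. Confidence intervals are the normal approximation ±1.96·SE;
p-values use a t reference with n − p residual degrees of freedom, except
the paired model's within-window contrast, which uses (number of windows −
1) — the containment convention for nested designs, and the choice that
makes the independence-structure paired model reproduce the paired t-test
estimate, t and p exactly (verified to 1e−6 in the tests).

Dense solves are exact up to a few thousand observations, the scale this
package targets; larger paired fits should subsample windows (as the
acceptance script does) rather than silently approximate.

Distance-based structures admit no duplicate observation locations: two
unequal observations at zero distance contradict a no-nugget correlation of
1, and the ML fit then degenerates toward compound symmetry at unbounded
range with a wildly unstable intercept. Pair tables from raster landscapes
do contain duplicates — one strong-change cell is the focal of several
overlapping windows with different references — so path-model fits with a
spatial structure keep the first pair per focal location (with a warning);
independence fits keep all pairs.

## Piecewise SEM and effect decomposition

The causal DAG: forest change is exogenous; albedo change depends on forest
change; ET change on forest and albedo change; LST change on all three.
Each endogenous variable gets its own GLS regression on the complete-case
pair subset (pairs with all four standardized changes), with the spatial
structure anchored at focal-cell coordinates; rational quadratic is the
default family. Standardized coefficients are raw × SD(predictor) /
SD(response) with sample SDs from the same subset, making them invariant to
unit changes. Links with p > 0.05 are flagged in reports but retained in all
arithmetic — a pathway product with one noisy link is still the model's
estimate of that pathway.

The total standardized effect of ΔF on ΔLST is the direct coefficient plus
the three pathway products (ΔF→Δalbedo→ΔLST, ΔF→ΔET→ΔLST,
ΔF→Δalbedo→ΔET→ΔLST); the identity total = direct + Σ indirect is exact by
construction. For a linear Gaussian DAG this total equals the population
standardized simple-regression slope of ΔLST on ΔF (path tracing), which the
tests verify at n = 5000. Multiplying the total by SD(ΔLST) converts it to
°C per SD of forest change.

Pruned models are tested through the d-separation basis: for each
non-adjacent ordered pair (x before y in the causal order), the claim
y ⟂ x | parents(x) ∪ parents(y), tested by regressing y on the conditioning
set plus x with the same GLS structure and reading x's p-value. Claims are
ordered deterministically (topological generations, alphabetical within).
Fisher's C = −2 Σ ln pᵢ is compared to χ² with 2k degrees of freedom; the
saturated model has an empty basis and admits no global test. A claim
p-value of exactly zero yields C = ∞ with a warning rather than an error.

Two R² definitions are computed for every component model because no single
definition is canonical for GLS: 1 − RSS/TSS on raw residuals (primary) and
the squared fitted-observed correlation.

## Scenario projection

A scenario raster of forest change over some horizon maps linearly to
predicted LST change per cell: `ΔLST_pred = total_std × (ΔF / SD_ΔF) ×
SD_ΔLST`, masked where the scenario is masked, zero where ΔF is zero. Using
the total effect is equivalent to propagating ΔF through the full linear
path system. Coarser scenario rasters are brought to the analysis grid by
bilinear resampling first. No clipping is applied outside the observed ΔF
range. The projection freezes the fitted relationships over the horizon;
that stationarity assumption is recorded in the result metadata rather than
silently embedded.

## Synthetic generators

`generate_pairs` draws pair-level data directly from the structural
equations: standardized forest change is a mixture (focal |ΔF| uniform on
15–100% with a configurable forestation fraction, reference ΔF uniform on
±5%), and the three responses follow the DAG with structural coefficients
specified on the standardized scale. With the default noise convention every
standardized variable has unit population variance, so the supplied
coefficients are exactly the population standardized path coefficients and
each equation's explained variance is its population R² (`implied_moments`
reports both). Noise is an i.i.d. component plus a spatially correlated
component (default exponential, range 1°, 15% of noise variance) drawn by
Cholesky factorization at the focal coordinates, which are uniform over a
configurable lon/lat box (default a Brazil-like extent, 74–35°W, 33°S–5°N).
The default coefficients (−0.5, +0.5, −0.04 into albedo/ET; −0.23, +0.3,
−0.5 into LST) put the total standardized effect at −0.64 with a direct
effect of −0.23 — the regime reported for tropical South America — as a
convention anchoring the synthetic world to realistic magnitudes.

`generate_landscape` builds two-epoch rasters: baseline forest cover from a
smoothed random field scaled to 0–100% (adjusted so both epochs stay in
bounds); forest change near zero (±5%) except on clustered square patches of
1–3 cells (Poisson-seeded centers grown until the target changed-cell
fraction, default 5%, is reached) with per-patch magnitudes uniform on
15–100%; climate changes from the structural equations applied to the
standardized forest change. Cell-level noise is drawn at SD/√2 so that pair
differencing (focal minus reference) restores exactly the pair-level noise
budget; the spatially correlated noise field and the smooth background trend
sit outside that budget as regional structure the pairing is designed to
cancel (the trend's surviving share of pair-level variance is under 2% when
its scale exceeds ~10 window widths, which is tested). Second epochs are
first epoch plus change exactly. QC layers fail independently per cell at a
configurable rate (default 2%). The landscape's spatially correlated noise
uses a Gaussian-kernel-smoothed field regardless of the configured family
(the exact-Cholesky family applies to pair-level generation); identical
parameters and seed give bit-identical output.

What the generators do not emulate: sensor noise and cloud-gap patterns,
realistic biome geography, seasonal dynamics, interannual forest dynamics
within the decade, and non-linear or threshold responses. Passing tests
therefore demonstrate that the estimators recover a known linear causal
structure under spatially correlated noise and realistic masking — not that
the linear model is adequate for any particular real landscape.

## Problem sizes and numerical conventions

The test suite and the acceptance script run at desk scale: landscapes of
200×200 cells (≈1,600–1,900 complete pairs), path models on 850–2,000 pairs,
coverage and selection simulations at n = 300–500 with 100–1,000 replicates.
The paired mixed model in the acceptance script fits a 500-window subsample,
keeping the dense spatial solve exact. Ties, degenerate inputs and
convergence failures raise or warn explicitly rather than returning silent
defaults; every stochastic component takes an explicit seed.

## Known limitations

- Great-circle distances are not used; degrees of longitude shrink with
  latitude, so the distance metric is anisotropic away from the equator.
  This mirrors the `~ longitude + latitude` convention but is a real
  approximation at boreal latitudes.
- The no-nugget correlation families cannot represent measurement error at
  zero distance; see the duplicate-location rule above.
- AICc model selection among correlation families is performed conditional
  on fitted ranges, ignoring range-estimation uncertainty.
- Raster I/O is NetCDF/CSV; GeoTIFF and CRS reprojection are out of scope.
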