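# Methods

`landepi` implements an ecological analysis linking urban landscape
patterns to the prevalence of diarrhoea among children under five, at the
level of survey-cluster buffer zones, together with a fully synthetic data
generator that reproduces the structure of the real inputs with known
ground truth.  This note records the model, the generator, the numerical
choices, and what the tests do and do not demonstrate.

## The analysis chain

**Spatial units.**  The analysis row is a circular buffer around a survey
cluster's published point: radius 2 km for urban clusters and 5 km for
rural ones, matching the anonymisation blur applied to cluster coordinates
(published points are displaced up to those distances, so the buffer is the
smallest area guaranteed to contain the true location).  Buffers are
128-segment polygons (area error ≈ 0.04 %).  A raster pixel belongs to a
buffer iff its centre falls inside the polygon; the centre rule is
unambiguous and stable across grid resolutions.  Units are retained when
their coordinates are valid and the buffer contains at least one urban
land-cover pixel; retained units whose urbanised fraction strictly exceeds
the mean over retained units form the *urban subset*, analysed separately.

**Urban precarity classification.**  Night-light intensity is used as a
proxy for the presence of urban infrastructure.  Population density and
lights are resampled to the 300 m land-cover grid by exact area-weighted
means (both are intensive quantities), then ranked into deciles over the
urban pixels of the whole study area — one shared series, so labels are
comparable across units.  An urban pixel is *precarious* when its density
decile strictly exceeds its light decile; it is *dense precarious* when its
density sits in the top decile while its illumination is above the median
but below the top decile.  Quantile ranking uses the empirical CDF with
ties sharing the lower index — deterministic, and conservative in the sense
that a tie never creates precarity.  Labels are rank-based and therefore
invariant under any positive rescaling of either layer.

**Landscape metrics.**  Patches are 8-connected components of same-class
cells within a unit (4-connectivity available).  Per class and unit the
battery holds: class proportion (cells of the class over unit cells), total
edge (exposed cell faces × cell size; faces cut by the unit boundary count
by default), and a patch-shape summary.  The shape index of a patch is its
perimeter over the minimum perimeter of an equal-area raster patch
(`4n`, `4n+2`, or `4n+4` for area relative to `n = floor(sqrt(a))`).  The
unit-level summary is `sum(area_i * shape_i) / N_patches` — dividing by patch
count rather than total area — with the standard area-weighted mean
(`/ sum(area_i)`) stored alongside under a separate name.  The retained
exposure is the dense-precarious patch area over buffer area.  Road
indicators: clipped road length (km) per hectare of built-up area, and mean
edge linearity (polyline length over chord; closed loops are excluded with
a warning; a length-weighted mean is available).

**Aggregation.**  All survey aggregates are proportions with population
denominators: prevalence is cases over under-fives in the cluster; service
access is person-weighted (members of flagged households over all members;
a household-weighted variant exists); education is the share of women aged
15–49 without schooling.  Units with no under-fives have undefined
prevalence and are dropped with a log entry.  Controls and landscape
metrics are min/max scaled to [0, 1] so coefficients are comparable;
constant columns are dropped with a warning.  The outcome is left on its
natural prevalence scale (it is already a proportion).

**Models.**  Four models are fitted on {constant + controls + selected
exposures}: unweighted OLS; weighted OLS with cluster weights rescaled to
sum to N (so weighted and unweighted intercepts are comparable, and equal
weights reproduce OLS exactly); and maximum-likelihood spatial lag
(`y = α + ρWy + Xβ + ε`) and spatial error (`y = α + Xβ + u`,
`u = λWu + ε`) models.  W defaults to row-standardised 8-nearest-neighbour
weights on buffer centroids (a distance band is available); the scheme is
reported in the output header because the choice is not dictated by the
method.  The spatial parameter is found by bounded scalar maximisation
(tolerance 1e-8) of the likelihood concentrated in ρ (or λ), with
`ln|I − ρW|` evaluated from the cached eigenvalues of W and the search
interval `(1/λ_min, 1/λ_max)` from the extreme real eigenvalues.  Standard
errors come from the asymptotic information matrix (for the error model the
β block is orthogonal to (λ, σ²)).  Pseudo-R² is the squared correlation of
fitted with observed outcome; AIC is `2k − 2 lnL` with k counting the
constant, slopes and the spatial parameter, comparable within model
families only.

**Feature selection.**  Two filters.  (1) Combined forward/backward
stepwise OLS over the landscape metrics with the controls always in the
design: at each step the candidate with the largest residual-sum-of-squares
reduction enters if its entry t-test p ≤ 0.1; after every entry, any
selected variable whose p has drifted above 0.1 is removed; ties break by
column order, so the procedure is deterministic.  (2) A Spearman screen:
selected features are kept only when the rank correlation with the outcome
has p < 0.1 (t approximation for N > 20, seeded Monte-Carlo permutation p —
9999 draws — for N ≤ 20).  The magnitude of ρ, not its sign, decides.

**Diagnostics.**  Global Moran's I with analytic randomisation inference
(or seeded permutations), the Lagrange-multiplier test for spatial error on
OLS residuals (`[e'We/(e'e/N)]² / tr(W'W + WW)`, χ²(1)), Jarque–Bera,
Breusch–Pagan, and per-variable VIFs.

## The synthetic world

The generator emulates the analysis inputs on a flat 60 × 60 km plane
(reprojection is a reader concern, outside the math core):

- **Land cover (300 m).**  Quantile slices of one Gaussian-smoothed noise
  field (kernel 4 cells), so classes form contiguous blobs; the urban class
  takes the top slice.  Default fractions: water 5 %, forest 35 %,
  cropland 45 %, urban 15 %.
- **Population (100 m).**  Mean 120 persons/cell on urban land, 4
  elsewhere, times smoothed log-normal noise (σ_log = 0.5, mean-corrected).
  A *primacy* gradient scales urban density by local agglomeration size
  (smoothed urban indicator, renormalised to preserve the stratum mean), so
  the largest city is the densest — the concentration of demographic growth
  in a few cities that motivates the precarity construct.
- **Infrastructure deficit.**  A square region grown around the densest
  urban cell until it holds 40 % of urban pixels (large deficit shares are
  the realistic condition: around half of the urban population of the
  study setting lives in informal settlements), with deficit 0.6 inside.
- **Night lights (500 m).**  `gain × density × (1 − deficit)` plus 2 %
  Gaussian sensor noise, clipped at zero.  With deficit 0.6, top-decile
  density pixels inside the region fall to mid-range light deciles —
  exactly the dense-precarious signature — while outside the region lights
  track density.
- **Roads.**  Edges join nearby urban pixel centres; a perpendicular
  mid-point offset sets each edge's length/chord ratio exactly to the
  target (default 1.2).
- **Clusters.**  351 by default, half urban (placed on urban pixels), with
  uniform-disc displacement (radius `R·sqrt(u)`, angle uniform; R = 2/5 km)
  — the published blur radii are known but the displacement law is not, so
  the uniform disc is a stand-in, not an assertion about the real protocol.
  Ten of 351 are marked as lacking valid coordinates.
- **Survey.**  Households per cluster ~ Poisson(27) (a typical DHS cluster size),
  members ~ 1 + Poisson(4), under-fives ~ Binomial(members, 0.18).
  Cluster-level control probabilities rise (water, sanitation) or fall
  (no-education) with the unit's urbanised fraction plus noise; a
  `control_coupling` knob scales those slopes.  The latent cluster
  prevalence follows the planted linear model on the min/max-scaled
  *realised* covariates — identity link by default, clipped to
  [0.01, 0.99]; logistic available — with optional spatial-lag structure
  (reduced form `(I − ρW)^{-1}(α + Xβ + ε)`) or spatial-error structure.
  Household case counts are Binomial(under-fives, p_cluster).  The default
  truth uses effect sizes realistic for this design
  (α 0.43; sanitation −0.19; education −0.14; dense-precarious +0.26 on the
  scaled design; latent noise sd 0.15) and carries ρ = 0.45, so the
  emulated outcome exhibits the significant positive spatial
  autocorrelation the analysis is designed to handle.

**What the generator does not emulate:** real geography and land-cover
legends, survey nonresponse and weighting design beyond a log-normal
cluster weight, within-cluster covariate heterogeneity, seasonality, and
measurement error in the rasters beyond simple sensor noise.  Passing tests
therefore show that the chain recovers structure *of the kind planted*, at
this scale; they are not evidence about effect sizes in real data.

## Recovery experiments and their conditions

- **Spatial-parameter recovery** simulates directly from the lag and error
  equations (N = 400, KNN-8 W, β = (1, −0.5), 50 replicates) and checks the
  mean estimates; with ρ = λ = 0 both models collapse to OLS.
- **Deficit recovery** regenerates the full raster stack over 10 seeds and
  requires ≥ 80 % of dense-precarious pixels to fall inside the planted
  region.
- **Sign recovery** runs the whole pipeline — generation through the four
  models — and requires the dense-precarious metric to survive both filters
  with the planted signs significant in every model, in ≥ 90 % of seeds.
  This experiment uses 100 households per cluster, latent noise sd 0.03,
  effects +0.45 (exposure) and −0.25 (sanitation), and control coupling
  0.3.  The larger survey is deliberate: at the default 27 households per
  cluster the binomial noise in measured prevalence (sd ≈ 0.075) is larger
  than the typical per-unit effect of the zero-inflated exposure, and the
  *marginal* Spearman screen then fails in a material fraction of
  replicates regardless of the coefficient's size.  The recovery experiment tests that the chain finds what
  is findable; the default conditions document what is marginal.
- **Null calibration** re-runs the same pipeline with all effects zero and
  requires the exposure to survive the filter chain rarely (≈ the nominal
  level of the 0.1/0.1 screens).

## Numerical choices and degenerate inputs

- Resampling uses exact 1-D interval-overlap products (axis-aligned grids);
  `sum` conserves totals to well under 0.1 %, `mean` is bounded by the
  input range, nodata cells carry zero weight.
- Eigenvalues of asymmetric row-standardised W may be complex; the
  log-determinant uses complex moduli, and the parameter interval uses the
  extreme real parts.  An estimate within 1e-4 of the interval boundary
  raises rather than returning a spurious optimum.
- Stepwise selection refuses rank-deficient candidate designs; OLS raises
  on collinear columns, listing them.
- Constant outcome (Moran), constant features (Spearman), zero under-fives
  (prevalence), closed road loops (linearity), zero built-up area (road
  density) are all rejected or flagged rather than silently coerced.
- All randomness flows through `numpy` Generators seeded from explicit
  integers; stage seeds derive from the run seed via `SeedSequence`.  Reports
  serialise with sorted keys and no timestamps, so a rerun with the same
  configuration and seed is byte-identical.

## Known limitations

- The spatial models use eigenvalue-based log-determinants and dense
  algebra: fine for hundreds of units, not for tens of thousands.
- Moran's I analytic inference uses the normal approximation under
  randomisation; for small N or heavy-tailed outcomes the permutation mode
  is preferable.
- The stepwise/Spearman screen inherits the usual multiple-testing and
  overfitting caveats of stepwise procedures; the null-calibration test
  quantifies, but does not remove, them.
- Raster IO is plain-text ASCII grid with a JSON sidecar — portable and
  diff-able, but not compressed; very large rasters would be better served
  by a binary format.
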