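# Methods

## Occurrence handling

Occurrence records are presence-only points (species, lon, lat, source
tag) in WGS84 decimal degrees; coordinates outside bounds are rejected
with a count rather than silently fixed. Spatial thinning keeps at most
one record per 10 × 10 km cell. Two readings of "one record per 10-km
neighbourhood" exist in practice — a buffer of radius 10 km around each
kept point, or a fixed 10 × 10 km grid; we implement the grid form because
it is deterministic, order-independent in its cell structure, and matches
the ~10-km pixel size of 5-arc-minute climate layers. The grid origin is
fixed at (lon 0, lat 0) and north/east distances use a per-point
equirectangular approximation (111.32 km per degree latitude, scaled by
cos lat for longitude). Ties within a cell keep the first record in file
order, so thinning is reproducible without a seed and idempotent.

## Environmental layers

Layers are single-band rasters on a shared square-cell geographic grid;
supported formats are ESRI ASCII grid and single-band GeoTIFF (the GeoTIFF
reader/writer handles the pixel-scale, tie-point and nodata tags
directly). A stack's validity mask is the intersection of its layers'
masks, and geometry equality is exact — silent misregistration is treated
as worse than a hard error. Regridding to a reference geometry is
nearest-neighbour (mask-safe; the analysis resolution is coarse enough
that kernel choice is immaterial). Slope and aspect come from Horn's 3 × 3
finite differences on elevation, with metre spacing derived from latitude;
aspect uses the compass convention (degrees clockwise from north of the
downslope direction), flat cells get slope 0 and undefined aspect, and
border cells are masked. Point extraction takes the containing cell's
value with a floor rule on edges — no interpolation, again matching the
analysis resolution.

## Variable screening

Candidate variables are screened on pairwise Pearson correlation at the
presence + background points with an |r| > 0.9 cut-off. Because the
criterion "keep the higher-contribution member" does not by itself fix an
order of resolution, screening is greedy on descending |r|: repeatedly
find the worst remaining pair, drop its lower-contribution member (ties:
drop the later variable in Bio-number order), and re-check. Contributions
come from a preliminary model fitted on all candidates with default
settings. The no-violations post-condition is asserted on every run.

## The maximum-entropy model

The model is the presence/background Gibbs formulation: covariates are
affinely rescaled to [0, 1] on training data, expanded into linear,
quadratic, optional pairwise-product, and hinge features (10 evenly spaced
interior knots per variable by default, forward and reverse), and the
density `exp(β·f(x))/Z` is fitted by maximizing the presence
log-likelihood with a per-feature L1 penalty

    λⱼ = reg_multiplier · base(class) · sⱼ/√m,

where `sⱼ` is the feature's presence-sample standard deviation (floored at
0.05), `m` the presence count, and base = 0.05 (linear, quadratic),
0.1 (product), 0.5 (hinge). The optimizer is coordinate-wise proximal
Newton: each feature takes a soft-thresholded Newton step (curvature =
background variance of the feature) with backtracking that only accepts
non-decreasing regularized gain — monotonicity of the gain trace is
therefore structural, not incidental. One iteration is a full sweep;
fitting stops when a sweep improves the gain by less than 10⁻⁵ (the
convergence domain used throughout) or at 500 sweeps, in which case a
warning is attached and the model still returned.

Outputs: `raw` is the normalized density over the training background
(sums to 1 there by construction, checked to 1e−6); `cloglog`
`1 − exp(−e^H·raw)` maps it into (0, 1) using the entropy H of the fitted
distribution. Projection onto another period's stack keeps Z fixed at its
training value and, with clamping on (the default), truncates covariates
to their training bounds before feature expansion so hinge/quadratic terms
are never extrapolated.

Replicates: "n bootstrap runs" is implemented as n independent 75/25
splits (|train| = round(0.75·n)), with the training presences resampled
with replacement within each replicate; reported surfaces are per-cell
means across replicates. Background is a uniform without-replacement
sample of valid cells, 10,000 by default or all cells when the grid is
smaller.

## Evaluation

AUC uses the Mann–Whitney pair formulation (ties ½), with background
points as pseudo-absences — the standard presence-background ROC, since no
true absences exist. Verbal bands are half-open with boundaries assigned
upward ([0.9, 1.0] → "excellent"), resolving the overlap in the customary
prose ranges. Percent contribution is path-credit-based: every accepted
coordinate step's gain increase is credited to the updated feature's
underlying variable(s) (products split evenly), then normalized to 100;
a permutation-importance alternative is provided and labelled as such.
Jackknife importance refits with each variable alone and (optionally)
excluded, under one shared FitConfig. Response curves sweep one variable
across its training range with the others at their training means.

## Classification, areas, change, centroids

Suitability is classified into four levels by Fisher–Jenks natural breaks
— exact dynamic programming minimizing within-class sum of squares on the
sorted sample, cross-checked in tests against exhaustive enumeration.
Samples above 50,000 cells are subsampled uniformly with a fixed seed
before the DP. Breaks are computed once on the near-current map and reused
for future periods: recomputing per period would make the area series
incommensurable. Binary conversion uses the lowest break (any suitability
counts), matching the way four-level maps are totalled into "potential
suitability area". Cell areas are (111.32 · cellsize)² · cos(lat); change
maps label gain/loss/stable transitions, and gain − loss equals the net
area change exactly. The habitat centroid is the area-weighted mean of
suitable-cell centres; shifts report haversine distance on the IUGG mean
sphere (R = 6371.0088 km), initial great-circle bearing, and the nearest
of the 16 compass winds (the granularity used to describe shifts like
"west-southwest").

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:
each layer is white noise convolved with a Gaussian kernel (correlation
length 6 cells by default) rescaled to a plausible range for its name; a
wavy nodata margin emulates a map border; a manufactured collinear pair
(Bio11 = Bio1 + 5% noise, r ≈ 0.999) exercises screening. The truth is a
Gibbs density on standardized layers — dominated by temperature
seasonality (Bio4, β = +2) with a secondary negative precipitation-
seasonality effect (Bio15, β = −1) — chosen so the truth family matches
the fitted family and parameter recovery is a well-posed oracle test.
Presences (200 by default) sample cells proportionally to the truth
density, placed uniformly within the cell. Future stacks add per-variable
drift in SD units, by default a progressive warm-west longitudinal
gradient on Bio4 (offset 0.15·i, west gradient 0.6·i for period i = 1…4),
which moves the favourable window — and hence the recovered centroid —
westward. The default grid is 120 × 160 cells at 5 arc-minutes (≈1.9·10⁴
cells), sized so a full study runs in about a minute on one CPU.

What the generator does **not** emulate: realistic CMIP6 spatial
covariance, cross-variable physical constraints, elevation-climate
coupling, observation bias in occurrence records, or any real geography.
Passing tests therefore demonstrate that the implementation recovers known
structure under its own assumptions, not that any particular real-world
range forecast is correct.

## Pipeline and reproducibility

One run handles one species (a wrapper can loop species). All randomness
flows from a single root seed expanded deterministically per stage and
replicate; the manifest records config, per-stage summaries, and a sha256
for every output, and a rerun from the same inputs and seed is
bit-identical. Any stage failure aborts the run with the stage named.

## Known limitations

- The optimizer is a straightforward coordinate method, not the original
  sequential-update algorithm; coefficients match it only in the small-λ
  limit where both converge to the same maximum-entropy solution.
- Percent contributions are path-dependent (as in the original software)
  and should be read comparatively, not as variance decompositions.
- Presence-background AUC has the usual ceiling below 1 that depends on
  species prevalence; bands are conventions, not hypothesis tests.
- Equirectangular thinning cells and cos-latitude areas are approximations
  appropriate to mid-latitudes and ~10-km resolution, not polar work.
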