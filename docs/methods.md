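# Methods

`pantherscape` implements a landscape-scale, presence–absence habitat model
for the Florida panther (*Puma concolor coryi*) as a tested, reusable
pipeline, together with a synthetic-landscape generator whose planted
preference structure makes every stage testable for parameter recovery.
This note records the model, the design choices made where the design was
genuinely open, the generator's assumptions, and known limitations.

## The analysis

The study region is partitioned into 1-km² square cells. Each cell carries
15 covariates:

* **10 land-cover fractions** — open freshwater wetland, wetland forest,
  agriculture, saltwater wetland, grassland, wet shrub, urban, upland
  forest, open water, upland shrub — computed by exact polygon overlay
  (`area(cell ∩ category) / area(cell)`).
* **Forest edge** (km/cell): total length of shared boundary between a
  forest polygon (upland or wetland forest) and an edge-forming cover type
  (grassland, freshwater open water, shrubs, open freshwater wetland),
  plus upland-forest/wetland-forest boundaries. Urban, agriculture and
  saltwater wetland do not form edge. Edge is a proxy for white-tailed
  deer (prey) availability.
* **Wet- and dry-season water depth** (m): inverse-distance-weighted
  (power 2) interpolation of daily gauge stages, minus ground elevation,
  sampled on a 3×3 subgrid per cell and averaged over all in-season days
  of the averaging period (wet = June–October, dry = November–May).
  Positive = standing water; negative = water table below ground.
* **Human population density** (people/km²): area-weighted average of
  census-block densities.
* **Road density** (km/cell): clipped road length, excluding four-wheel
  drive, bike and pedestrian trails.

Presence labels come from radio-telemetry: fixes are filtered to a study
window, to the study area, to animals at least 3 years old at the fix
(continuous age, 365.25-day years), and then to animals with ≥ 50
remaining fixes; a cell with ≥ 1 filtered fix is *present*, every other
cell *absent*. The dense, decade-long monitoring of this population is
what justifies reading unvisited cells as true absences. Each animal also
gets a 100% minimum convex polygon (convex hull) home range.

The classifier is a 500-tree random-forest with 3 candidate variables per
split. Reported probabilities of presence `P` are out-of-bag (OOB) by
default. The habitat cutoff `t*` is the probability at which sensitivity
equals specificity (candidates = sorted unique probabilities, ties broken
toward the smaller threshold); this rule tends to classify a
prevalence-sized fraction of cells as present. Accuracy is reported as
PCC, sensitivity, specificity (percent), Cohen's kappa and midrank AUC,
under resubstitution, OOB, and 10-fold cross-validation. Variable
importance is reported two ways — mean OOB accuracy decrease under
permutation, and Gini impurity decrease — each standardized so the top
variable scores 1, with a combined rank by summed standardized scores.

The sensitivity analysis is stratified one-at-a-time: cells are grouped
into excellent (P ∈ [0.85, 0.95]), medium ([0.45, 0.55]) and poor
([0.05, 0.15]) habitat; the non-swept covariates are fixed at
*stratum-specific* means (no real cell has every covariate at its global
median, so global-median anchoring would be unrealistic); the target
covariate sweeps 50 equally spaced points over its observed range.

Habitat area in km² is the count of cells with `P ≥ t*` (`>` is available
as a config switch; the two differ only at the exact cutoff). Zone
summaries assign cells to comparison polygons by cell center and conserve
totals; carrying capacity is `area × density / 100` with a default
density of 2.80 adults per 100 km², the maximum adult puma density
reported in the field literature — an upper bound.

## Conventions and numerical choices

* **Planar metric coordinates** throughout; projection handling is outside
  scope.
* **Boundary tie-break ("lower-left rule")**: a point or line segment
  lying exactly on a shared cell boundary belongs to the neighbouring cell
  with the smaller `(col, row)` index; the grid's own lower/left edge
  belongs to the first cell. Line features are split by the grid and each
  piece is assigned by its midpoint. This makes per-cell edge and road
  totals sum exactly to the un-gridded totals (tested to 1e-6 km).
* **Cell membership in polygons** (study area, home ranges, zones) is by
  cell center, so cell counts approximate areas.
* **Wilcoxon rank-sum** (sex comparison of home-range mean P): exact
  enumeration on midranks for combined n ≤ 20, tie-corrected normal
  approximation otherwise — stated so p-values are exactly reproducible.
* **CV thresholding**: the equal-sens/spec cutoff is re-derived inside
  each training fold (from that fold model's OOB probabilities) to avoid
  leakage; a pooled threshold is also reported.
* **Permutation importance** uses OOB rows only, per tree, with seeded
  permutations (default 10 replicates).
* **Collinear depth covariates**: both seasonal depths stay in the model
  even at R² ≈ 0.98+ (dropping one costs a little accuracy, and the
  ensemble tolerates collinearity).
* **Determinism**: one seed drives fold assignment, tree randomness,
  permutations and all generators; a re-run reproduces the manifest's
  result hash bit-for-bit.

## The synthetic landscape

The generator emulates the south-Florida study system so the pipeline can
be validated against known ground truth without any data download:

* **Cover** — a Voronoi tessellation (~1 polygon/km²; the real cover
  database is several polygons per km²) assigned to the 10 categories by
  seeded region-growing on the adjacency graph: urban grows from one
  corner, saltwater wetland along the south edge, other categories from
  ~120 scattered patch seeds. Realized composition tracks the configured
  mix (default = the real study area's proportions, e.g. 34.3% open
  freshwater wetland) to well within ±5 points.
* **Hydrology** — elevation is a smooth analytic gradient rising toward
  the urban corner plus low-frequency ripple, calibrated with the stage
  regime so seasonal depths span roughly −5.2 to +2.6 m. Twelve gauges
  (¾ inside, ¼ just outside the extent) record two years of daily stages;
  the wet-season rise averages 0.30 m but varies spatially (±0.35 m), so
  the two seasonal depth surfaces are highly but not perfectly correlated,
  as in real hydrology.
* **Anthropogenic layers** — a main city at the urban corner
  (~8000 people/km², Gaussian decay, σ = 7 km) with four seeded satellite
  towns; a dense urban street grid, three highways crossing the whole
  extent, eight secondary interior roads, and trails carrying excluded
  class codes. A cover mix with zero urban produces an uninhabited,
  road-free wilderness.
* **Telemetry** — per-cell utilization weight
  `w = logistic(b0 + Σ βj·zj − γ (dry_depth − d*)²)` with covariates
  z-scored across cells; defaults: forest edge +1.5, wetland forest +1.3,
  human density −2.0, road density −1.0, agriculture −1.3, depth optimum
  d* = −0.6 m with curvature γ = 2.5 m⁻² (field observation: presence
  drops sharply on either side of the optimum). Grassland and upland
  shrub are deliberate β = 0 nulls for importance-recovery tests. Each of
  20 animals gets a home-range center drawn ∝ w and ~330 fixes
  (≈ 28,720/87, the real data's mean) drawn ∝ w from cells within a 6-km
  movement disc, uniformly within the chosen cell, at a 2–4-day cadence
  inside 2004–2013, all breeding-age adults. Movement is weighted
  independent sampling, not a correlated walk: the analysis consumes
  fixes, not paths.

With these defaults the pipeline recovers the planted structure: OOB AUC
0.93–0.97 across seeds, OOB ≈ CV PCC ≈ 88–92% with resubstitution near
100% (the expected validation pattern), prevalence ≈ 0.3, both null
covariates below every planted covariate in combined importance in ≥ 9/10
seeds, planted effect signs recovered from the response curves, and the
depth-curve peak in excellent habitat within ±0.4 m of −0.6 m.

### What the generator does not emulate

No demography, territoriality, dispersal or sex-specific habitat use; no
telemetry error (the 1-km cell absorbs it); no seasonal movement; cover
patches have Voronoi geometry rather than realistic shapes; stage
dynamics are sinusoidal rather than rainfall-driven. Passing tests
therefore demonstrate that the *pipeline* recovers a known preference
structure from realistically structured inputs — not that the ecological
conclusions transfer to any particular real landscape.

### A caveat the synthetic world makes visible

Even with all preference coefficients at zero, simulated animals still
live *somewhere*: presence cells cluster inside movement discs, and
covariates with spatial structure (population gradient, depth gradient)
act as location proxies that the forest legitimately learns. Response
curves on such "null" data can show swings up to ≈ 0.5 in P. After
permuting labels (a true no-signal null), the sweep machinery itself has
a noise floor of median ΔP ≈ 0.1 (95th percentile ≈ 0.2–0.3) for a fully
grown 500-tree forest — effects below that scale should not be
interpreted. This is a general caution for one-at-a-time sensitivity
analyses of observational presence data, not an artifact of the
generator.

## Problem sizes

Defaults were chosen so a full run (synthesis → features → hydrology →
telemetry → fit → 10-fold CV → importance → sensitivity → map) completes
in about a minute on one core: 3600 cells, ~3600 cover polygons, 12
gauges × 730 days, 900 census blocks, 20 animals × 330 fixes, 500 trees.
All sizes are configuration.
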