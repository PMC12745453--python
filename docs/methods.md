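# Methods

## Intensity indices

Observed activities are coded with 3-digit subcategory codes whose
leading digit fixes the category (1xx exercise, 2xx leisure, 3xx
social); the packaged taxonomy has 34 codes (16 EB, 11 LB, 7 SB). For
a plot's record set, each category index is the MET-weighted
participant sum Σ MET(code)·count over that category's records, in
MET·persons. OBI is computed *as* EBI + LBI + SBI (not as an
independent sum over all records), so the category partition holds to
machine precision; per-category sums use `math.fsum`, making scores
invariant under record reordering. Records with zero count are legal
and contribute nothing. A plot's score pools all sessions; filter
records first for per-session scores.

MET values are dimensionless multiples of resting metabolic rate and
must be strictly positive. The packaged default table is a stand-in
assembled from 2011 Adult Compendium conventions because the original
study's per-code values were never published; every value-sensitive
computation accepts a user table (CSV `code,met` or JSON).

Reported percentage shares (activity and demographic summaries) round
half-up to two decimals, matching how such observation tables are
conventionally printed; fractions are stored in [0, 1] internally and
only rendered as percentages at report time.

## Landscape profiles

Label maps are H×W integer grids of segmentation class ids. A remap
table sends each id to one of the 11 features or to "other"; per-image
fractions are pixel counts over total pixels, so the 11 features plus
"other" sum to exactly 1. Unknown ids go to "other" with a warning
(strict mode raises instead). The packaged ADE20K(150)→11 mapping is a
plausible reconstruction — e.g. tree+palm→tree, road/sidewalk/path/
step→pavement, earth/mountain/rock/sand/hill/dirt-track/land→rough
ground, chair/seat/bench/stool→resting facility, awning/canopy→shading
facility, person and all vehicles→other — and should be overridden
when the upstream network's vocabulary differs. "Rough or uneven
ground" means non-paved, minimally modified ground (bare soil, sparse
vegetation, gentle slopes).

Plot profiles are unweighted arithmetic means of per-image vectors.
Descriptive statistics default to the sample SD across plots (ddof=1);
a single-profile group reports SD 0 with an `sd_undefined` flag.

## Regression chain

Correlation screening uses Spearman rank correlation with average-rank
ties by default (Pearson available; the method is always recorded in
the output because published correlation tables are sometimes labelled
inconsistently). Constant features yield missing coefficients with a
warning rather than an error.

VIF filtering regresses each candidate on the others (with intercept):
VIF_j = 1/(1−R²ⱼ). Filtering is iterative worst-first: the highest
VIF at or above the threshold (default 10) is dropped and VIFs are
recomputed until all pass. Exact collinearity (R²ⱼ = 1) appears as
infinite VIF and is dropped immediately. A single surviving feature
has VIF 1 by convention.

Fits are ordinary least squares with intercept via statsmodels,
reporting per-term SE/t/p, R², adjusted R² and the overall-F p-value.
Rank-deficient designs raise rather than silently pseudo-inverting.
p-values are two-sided t with no multiple-testing correction — a
deliberate match to common practice in this literature and a
documented limitation. A zero-variance outcome yields NaN R² (legal).

`reference_models()` returns the published reduced prediction
equations (significant terms only):

| index | equation |
|---|---|
| OBI | 281.63 + 857.13·sky + 1040.91·pavement − 1736.40·rough_ground |
| EBI | −167.14 + 762.37·tree + 1462.50·pavement − 1553.52·rough_ground − 27547.01·resting_facility |
| LBI | 119.00 + 585.04·shrub |
| SBI | −106.58 + 1261.75·sky |

`full_reference_models()` carries the complete published term sets
(including non-significant terms) with their printed standard errors;
R²/adjusted R² for the reference models are the published fit
diagnostics, not recomputed. Predictions are linear and may be
negative (two reference intercepts are negative); an optional
floor-at-zero is off by default because clamping would silently bias
any downstream averaging.

## Spatial mapping

Image filtering keeps points with short-side resolution ≥ 1080 px
(crowdsourcing platforms describe this as "1080p"), landscape-related
content, and a first-seen content hash (exact duplicates only; near-
duplicate detection is out of scope). The fishnet origin sits at the
boundary bounding-box minimum with 30 m cells by default (matching the
field plot size); cells intersecting the boundary are kept. Point
assignment is half-open — [xmin, xmin+s) × [ymin, ymin+s), shared
edges belong to the higher-index cell — with the grid's outermost
top/right edges closed so boundary points are not dropped; the tiling
therefore partitions the grid extent and every point lands in at most
one cell. Coordinates must be projected in meters; inputs that look
geographic (|x| ≤ 180, |y| ≤ 90) are rejected with a message rather
than silently reprojected.

Cells average their points' feature vectors; empty cells carry no-data
and are excluded from prediction and classification (no interpolation
— exported maps show them as null). Jenks natural-breaks
classification is the exact Fisher optimal 1-D partition minimizing
within-class squared deviation, computed by O(k·n²) dynamic
programming with prefix sums; among equally good partitions the one
with the smaller upper classes is returned, runs of equal values are
never split across classes, and goodness of variance fit
(1 − SSD_within/SSD_total) is reported. k defaults to 5 classes (a
conventional choice for intensity maps; configurable via `--classes`)
and is reduced automatically when a score series has fewer distinct
values. Exports are GeoJSON (cell polygon + four scores + four
classes) and flat CSV; a matplotlib raster render is optional.

## Observer reliability

ICC forms ICC(1,1), ICC(2,1) and ICC(3,1) are computed from the
two-way ANOVA mean squares of a complete targets × raters matrix;
ICC(2,1) (two-way random, absolute agreement, single measures) is the
default, the standard choice for observer reliability in structured
park observation. Zero-variance matrices yield NaN with a warning.
Percent agreement is matched pairs over total pairs, rounded half-up
to one decimal; a stratified variant reports per-stratum agreement.

## Synthetic-data generator

The generator reproduces the published study conditions so the
pipeline is testable without the unreleased field data.

* **Profiles.** Defaults: 68 plots; per-feature means and SDs equal
  the published overall landscape moments (tree 0.3626 ± 0.11, etc.).
  Features are drawn from independent truncated normals whose
  underlying location is calibrated (Brent root-find) so the
  *truncated* mean equals the target — naive truncation at 0 would
  inflate small-mean features like water and grass. The composition is
  completed with an "other" component (mean 1 − Σmeans ≈ 0.105, SD
  defaulting to the mean feature SD) and renormalized to sum to 1,
  which keeps compositions feasible with only a second-order effect on
  the marginal means (measured bias ≈ 0.001 on tree at n = 500) and a
  modest shrinkage of marginal SDs (≈ 0.09 realized vs 0.11 nominal
  for tree) — the price of respecting the sum constraint that real
  compositions obey. With all SDs zero every profile equals the mean
  vector exactly. A Dirichlet alternative (`use_dirichlet`) provides a
  fully joint compositional model. True joint covariances are
  unknowable from published marginals; independence before
  normalization is assumed and documented.
* **Behavior records.** Per plot and category, the target intensity is
  max(0, model(features) + N(0, σ)) using the reference equations as
  generating truth; default residual SDs are those implied by the
  published fits, σ_outcome·√(1−R²) (EBI ≈ 137, LBI ≈ 78, SBI ≈ 128
  MET·persons). Targets are decomposed greedily into integer
  (code, count) records drawn from the category's codes, leaving a
  residual below the category's smallest MET — so realized scores land
  within one MET unit of the target. Demographics follow the published
  marginal shares (age 69/22/8/1, gender 52/48, weekend/weekday
  56/44 across three daily observation windows). OBI emerges as the
  category sum.
* **Geo-images.** Default 467 points (the retained crowdsourced sample
  size) uniform over a ~7.7 ha rectangular park (320 × 240 m);
  per-feature values follow a low-frequency sinusoidal spatial field
  centred on the feature mean with amplitude equal to its SD, plus
  white noise (SD 0.05), clipped and capped. Five percent of points
  are flagged low-resolution, 2% duplicate, 3% non-landscape to
  exercise filtering.
* **Rating matrices.** Target effects with variance ρ and residuals
  with variance 1−ρ give population ICC ρ; ρ = 1 yields noiseless
  ratings.

All generators draw from independent seeded sub-streams
(SeedSequence(seed, tag)), so outputs are bit-reproducible and
mutually independent: changing the number of images never perturbs the
profiles.

What the generator does *not* emulate: spatial autocorrelation between
neighbouring plots, within-day temporal structure beyond session
labels, joint feature covariance (beyond the sum constraint), weather,
and observer error in counts. Passing tests therefore demonstrate the
correctness of the computational chain and its statistical calibration
under the stated conditions, not the field validity of the reference
equations.

## Pipeline and determinism

`run_study` executes profiles → scores → correlation screen → VIF →
four fits, selecting each model's features as the VIF-passing features
significantly correlated with that outcome (α = 0.05), unless an
explicit feature set is configured. `run_mapping` executes filter →
fishnet → join → average → predict → classify → export with per-stage
counts logged. An `exact_intensity` mode scores plots directly from
the continuous generator targets instead of decomposed integer
records; with zero noise this makes scores exactly linear in the
features, which is the parameter-recovery harness (the record route's
one-MET-unit granularity would otherwise bound achievable precision).
In that mode each index follows its own equation, so OBI additivity is
intentionally not enforced there.

No output file embeds wall-clock time and all randomness flows from
the config seed, so identical configs produce byte-identical bundles.
Default problem sizes (68 plots, a few hundred image points, 500-
replicate coverage checks) keep a full run in seconds; they are the
published design sizes, scaled where a property needs replication.

## Known limitations

* The published intensity summary for one park (UP-7) is internally
  inconsistent (category means sum to 432.30 against a printed overall
  mean of 419.79, where all other parks sum exactly); the package
  stores the values as printed and documents, rather than reproduces,
  the discrepancy.
* Reference-model diagnostics are published values; per-term t/p for
  the full published term sets are not recomputable without raw data
  and some printed t-signs are inconsistent with their estimates, so
  fitted-model diagnostics are always recomputed for user fits.
* No spatial autocorrelation modelling, regularized or mixed-effects
  extensions; empty grid cells are omitted, not interpolated.
* The ICC stratification behind the published 0.979 is unstated; the
  package defaults to ICC(2,1) on total counts.
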