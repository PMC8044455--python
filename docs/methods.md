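# Methods

This note documents the models, numerical choices and limitations of
`habqual`. Everything quantitative stated here is computed by the test
suite or the example scripts; nothing is asserted beyond what the code
reproduces.

## Geodesy and the analysis grid

The grid is anchored at (−180°, −90°) with half-open cells
[west, east) × [south, north), so every point maps to exactly one cell and
a point on a shared edge belongs to the cell whose west/south edge it lies
on. The anchor is configurable but fixed by default for reproducibility,
since gridded climate products differ in alignment by fractions of a cell.

Cell ground areas use the spherical model
`area = R²·Δλ·(sin φ_n − sin φ_s)` with R = 6,371 km, giving 5.37 ha for a
7.5″ cell at the equator (5.4 ha to one decimal). Polygon–cell overlap is
computed on a local cylindrical equal-area projection of the cell;
within-cell distances use a local equirectangular projection scaled by
cos(centre latitude). At the ~232 m cell scale the spheroidal correction is
below 0.4% and the projection distortion far smaller — both negligible
against every decision boundary in the pipeline (the 90% overlap threshold,
significance bands, index calibration). The overlap threshold comparison is
inclusive (a cell at exactly 0.90 is kept). Zero-tree included cells are
retained in the cell table; whether they enter the density model is a
modelling option (they do by default).

## Aggregation index and edge correction

Per cell, the index is R = m̄ / (1/(2√λ)) where m̄ is the mean
nearest-neighbour (NN) distance and λ = n/A the cell intensity. λ uses the
*pre-exclusion* count by default (`lambda_from="retained"` for
sensitivity): the edge filter corrects the biased distance sample, not the
true intensity. Cells with fewer than 2 retained points get no index —
absent, never imputed.

Edge effects are handled by exclusion: point i is dropped from the distance
average when its distance to the nearest cell boundary is smaller than its
NN distance (its true NN could then lie outside the cell). NN distances are
always computed over *all* points, before exclusion.

The plain average over retained points is negatively biased: retention
(d_edge ≥ d_NN) conditions on small NN distances wherever d_edge is small,
so near-edge points enter the average only when their NN happens to be
close. Monte Carlo under CSR at n = 50 puts the plain-mean index near 0.92
rather than 1. The default therefore weights each retained point by the
inverse of its retention probability for a uniformly placed point with that
NN distance, `w_i = 1/|W ⊖ d_i|` (the minus-sampling / Hanisch weighting
associated with border exclusion — |W ⊖ r| is the cell eroded by r). This
uses exactly the same retained set and restores E[R] = 1 under CSR
(measured 1.002 ± 0.003 over 1,000 cells of 50 points); the plain mean
remains available as `weighting="plain"`. No Donnelly or buffer-zone
corrections are implemented — only the exclusion rule in these two forms.

Degenerate cases: all-coincident points give R = 0 (zero numerator); zero
cell area is a domain error; the index is invariant to uniform rescaling of
coordinates and cell.

## Allometry

The default AGB model is the pantropical moist-forest DBH-only form
`AGB = ρ·exp(−1.499 + 2.148 ln D + 0.207 (ln D)² − 0.0281 (ln D)³)` (kg, D
in cm) with wood density ρ = 0.59 g/cm³; it yields 39.40 kg at D = 10 cm
and is strictly increasing over (0, 300] cm. A height-inclusive variant
`AGB = 0.0509·ρ·D²·H` is registered for inventories with measured heights
(18.0 kg at D = 10 cm, H = 6 m). Models live in a registry keyed by name so
a different published equation can be pinned via configuration; output is
linear in ρ. Which of the two forms underlies any particular published AGB
summary cannot generally be determined from summary statistics alone, so
neither is asserted to reproduce external minima/maxima.

## Environmental covariates

Soil properties are depth-weighted means over the intervals
0–5/5–15/15–30/30–60/60–100 cm with weights (0.05, 0.10, 0.15, 0.30, 0.40)
— interval thickness over 100 cm. A missing interval yields a missing mean
by default; optional renormalization over the present layers is available
but off, because silent renormalization can move values across validation
bounds. The terrain ruggedness index is the Riley root-sum-of-squares of
the eight neighbour differences in a 3×3 DEM window (border cells:
missing). Raster sampling at trees and cell centres is nearest-cell, the
convention for attributing coarse climate/soil products to point records;
no bilinear smoothing. Covariate tables are validated against the
documented study-area ranges (bounds inclusive); `ENV_RANGES` mirrors the
published gradient table (e.g. annual precipitation 1,794–3,093 mm,
pH 4.29–5.48).

## Response models

Counts (per-tree seed production in latas, per-cell tree counts, per-cell
seed production expressed as lata multiples — cell kg sums divided by 11.66
and rounded half-up, logged) are fitted as quasi-Poisson log-linear models:
Poisson-log-linear mean, dispersion φ estimated as Pearson χ²/df, reported
SE = raw SE·√φ. Continuous responses (AGB in tons, the aggregation index)
use Gaussian identity-link fits, where φ is the residual variance.

Fits are univariate — one model per environmental variable — because the
trade-off classification consumes per-variable slopes, and collinear
variables are deliberately all retained. Within-concession correlation is
handled by concession-clustered sandwich standard errors (statsmodels GLM);
a penalized-quasi-likelihood random-intercept backend is not available in
the Python stack, and the contract here is backend-agnostic: signs and
significance bands of generating coefficients must be recovered, which the
test suite verifies on synthetic worlds (≥ 95% of 50 replicates at
n ≈ 3,000 trees / ~1,500 cells). The quasi-SE identity se_quasi =
se_raw·√φ holds exactly by construction and is tested.

Arrow discretization uses conventional p-value bands — p < 0.001 → three
arrows, < 0.01 → two, < 0.05 → one, < 0.10 → marginal (–↑/–↓), else flat —
with direction from the coefficient sign. The bands are configurable; the
marginal band exists because the published matrices distinguish marginal
from flat responses.

Permutation importance is an explicit loop around a bagged tree ensemble
(random-forest regressor, 200 trees, leaf size 5): fit on a 75% split,
importance of covariate j = mean over repeats of the held-out loss increase
after permuting column j (MSE; mean Poisson deviance for counts).
Deterministic given the seed. Collinearity spreads importance across
duplicates rather than zeroing either — tested.

Residual correlograms report Moran's I per distance bin with binary
neighbour weights, the null expectation −1/(n−1), and a one-sided
permutation p-value (≥ 199 permutations) for positive autocorrelation;
empty bins are missing, not zero.

## Trade-off classification

Each variable × service triple (fitness arrow, density arrow, area arrow)
is classified by sign logic only — arrow *strength* records evidence but
does not enter the rules, while marginal codes count as signal-bearing:

- both components signal-bearing, same sign → **congruent**;
- both signal-bearing, opposite signs → **divergent**, labelled **N** if
  the area response is flat (neutralization), **D**/**F** if the area sign
  matches density/fitness;
- exactly one signal-bearing → **partial**, labelled by the side the area
  response matches: the live side's label when the area carries its sign,
  the *flat* side's label when the area is also flat (flat mirrors flat);
  a signal-bearing area opposing the only live component matches neither
  side and yields `none` with a diagnostic;
- neither → **null**.

Marginal-as-signal and the flat-mirrors-flat fallback are both required to
reproduce every printed letter of the published Brazil nut response matrix,
which ships with the package as a transcription (28 variables × 2
services); the classifier reproduces all its letters and the headline
ratios (seed: 8 neutralized of 11 divergent; AGB: 10 density-dominated of
13 divergent). The classifier is pure and total over the 9³ triple space
and is tested against an independently enumerated rule table.

## Synthetic worlds

The generator's defaults are the reference study conditions: a
0.25° × 0.25° extent near 12.7° S, 12 rectangular non-overlapping
concessions averaging 761 ha, tree density ~0.35/ha (3.5 parents/km² ×
10 offspring, 60 m Gaussian dispersal), a linear annual-precipitation
gradient driving density (β = +0.5 on the z-scored surface) opposed by the
per-tree seed-production gradient (β = −0.4) — the trade-off scenario —
13% structural non-producers and quasi-Poisson dispersion 4.

Surfaces are linear gradients or Gaussian-smoothed random fields, min-max
rescaled into the documented study-area ranges (so range validation passes
by construction); pairwise correlation targets can be imposed for
collinearity emulation. Tree locations follow an inhomogeneous Thomas
process — Poisson parents from the log-linear intensity, Poisson offspring
displaced by an isotropic Gaussian, re-drawn when displaced outside the
concession union so counts are conserved and every tree lies inside a
concession. Optional CNDDD thinning removes each tree with probability
`strength · g(covariate) · exp(−d_NN/nn_scale)` with g min-max rescaled to
[0, 1]: mortality concentrates near conspecifics on high-g ground, which
measurably de-clusters the pattern (tested via the aggregation index). Note
the total count of a cluster process is over-dispersed relative to Poisson
— var ≈ N·(1 + offspring mean) — which the count-conservation test uses as
its tolerance.

Per-tree marks: DBH is log-normal (median ≈ 55 cm, σ_ln = 0.45, truncated
at 10 cm — an adult Brazil nut stand, where most stems are far above the
inventory threshold); height is a concave power of DBH with log-normal
scatter; seed production is 0 with probability π = 0.13 (structural
non-producers, recorded as explicit zeros and marked in a ground-truth
column) and otherwise negative binomial around a log-linear environmental
mean calibrated to 3 latas/tree, with the NB size chosen so the
quasi-Poisson dispersion at the mean equals the configured φ. The observed
zero share therefore exceeds π, because the count law contributes sampling
zeros on top of the structural mass; recovery tests measure the structural
fraction.

Seeding: one master seed spawns fixed sub-streams for environment,
concessions, locations and fitness, so changing fitness parameters never
perturbs locations (tested).

What the generator does *not* emulate: real concession shapes, spatially
correlated measurement error, harvester-specific reporting bias, temporal
dynamics, or any fitted resemblance to the real Madre de Dios data beyond
the summary ranges above. Passing recovery tests therefore demonstrates
that the estimators detect the planted structure under realistic sample
sizes and noise — not that the real data satisfy the generating model.

## Problem sizes and determinism

Default test-suite problem sizes are chosen as representative desk-scale
analyses: ~3,000 trees over ~9,000 ha and ~1,500 grid cells per synthetic
world; 50 replicates for recovery frequencies; 1,000 cells × 50 points for
the CSR calibration; 5,000 observations for dispersion recovery; 10⁴ trees
for the zero-inflation check. All stochastic tests fix their seeds; all
pipeline stages are deterministic given the config seed, and rerunning a
pipeline with an identical config reproduces fit tables byte-for-byte.

## Known limitations

- No PQL random-intercept GLMM; clustered sandwich errors are the grouping
  mechanism. With few concessions (< ~10 clusters) the cluster-robust
  p-values are anti-conservative.
- The aggregation index is confined to within-cell information; trees'
  true nearest neighbours across cell borders are invisible by design
  (that is what the edge exclusion compensates for).
- GeoTIFF I/O is not provided; rasters are exchanged as ESRI ASCII grids
  with a JSON sidecar, and vector data as GeoJSON.
- The half-up rounding of cell seed mass to lata multiples introduces a
  ≤ 0.5-lata per-cell discretization that is immaterial at the fitted
  scales but makes cell sums in lata units non-conservative by design;
  conservation is exact on the kg scale.
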