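# Methods

`mitoquant` quantifies three mitochondrial phenotypes from two-channel 2-D
confocal optical sections — morphology (aspect ratio, form factor),
membrane integrity (Manders colocalization of an outer-membrane marker such
as TOMM20 against an inner-membrane/matrix marker such as PMPCB), and mass
(the count of matrix-positive objects) — and carries the per-neuron metrics
into hierarchical group statistics and a factor analysis of mixed data.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic-data tests do and do not establish.

## Image model and calibration

All quantification operates on raw intensities; deconvolution, when used at
all in imaging workflows, is cosmetic and is never applied here.

The size calibration equates 15 px with 0.7 µm, giving the default pixel
size of 0.0467 µm/px. The companion anchor of 45 px for 2.2 µm implies a
slightly different calibration (0.0489 µm/px); the 15-px anchor wins
because it defines the detection floor that separates mitochondrial objects
from background. Both anchors are expressed in pixels in the filtering
rules, so the choice affects only the µm annotations, not the filtering.

## Segmentation and morphometrics

The matrix channel is thresholded (Otsu's method on a 256-bin histogram by
default; a fixed threshold is available), connected components are labeled
with 8-connectivity (matching common particle-analysis defaults;
4-connectivity is available), and a size filter is applied:

- components with size < 15 px are background and discarded; size >= 15 px
  is retained. The boundary is assigned to the retained set because the
  retention rule is what defines the analyzable objects.
- "size" is a length. The default measure is the maximum-caliper (Feret)
  diameter, which recovers the programmed end-to-end length of synthetic
  capsules within ±2 px. The moment-ellipse major axis, also available,
  systematically overestimates flat-ended rods (a 45-px capsule measures
  ~50 px), which would distort the filter boundaries; skeleton length
  (which under-measures a 15-px rod as 14 steps) is the third option.
- components longer than 45 px — the single-organelle maximum — contribute
  `ceil(size/45)` to the per-image object count, so aggregated-like
  structures are counted as multiple organelles. The per-image count is the
  "mitochondrial mass" readout.

Per-object descriptors: aspect ratio is the major/minor axis ratio of the
moment-equivalent ellipse; circularity is 4πA/P², clamped to ≤ 1 before
inversion into the form factor 1/circularity. The perimeter is the Crofton
estimate: the chain-code perimeter is biased high on digitized round
objects (a digital disk would measure circularity ≈ 0.91 rather than
≈ 0.98), which would inflate every form factor. Components with a zero
minor axis or zero perimeter (single pixels, collinear runs) are flagged
degenerate: they still count toward mass but are excluded from aspect-ratio
and form-factor summaries, with NaN reported.

Skeletons are single-pixel-wide medial axes; skeleton length counts steps
between 8-adjacent skeleton pixels (1 axially, √2 diagonally), skipping a
diagonal step whenever an axial 2-path shortcuts it, so an L-turn of three
pixels measures 2.

Line profiles are bilinear interpolations of both channels along a segment,
with distances in µm. The size-calibration helper reproduces the
pre-quantification procedure heuristically: it returns the smallest
full-width-at-half-maximum among peaks whose prominence exceeds a stated
fraction (default 20%) of the profile's dynamic range.

## Colocalization

Channel A is the matrix signal, channel B the membrane signal, analyzed
image-wide (an optional ROI mask is supported) to match the per-image
analysis unit; M1 is then matrix→membrane overlap and M2 membrane→matrix.

- **Costes automatic threshold.** The regression of B on A is orthogonal
  (total least squares, principal axis of the joint distribution), per the
  original formulation; a nonpositive slope aborts with a diagnostic, since
  descending a negative trend is meaningless. The scan steps T_A downward
  through every observed intensity level of A — exact and image-adaptive,
  which is what makes equality with an exhaustive per-level oracle
  achievable — and stops at the first level where the Pearson coefficient
  of the pixels below both thresholds is ≤ 0 (levels where it is undefined
  are skipped). A pixel is below the pair of thresholds iff
  max(a_i, (b_i − c)/s) < T_A, so the scan is computed from prefix sums
  over pixels sorted by that quantity in O(n log n). Exhausting all levels
  returns floor thresholds with a flag.
- **Manders coefficients.** The default denominators are the
  above-own-threshold intensity sums (the thresholded variant used by
  common plugin implementations); the classic whole-sum variant is
  selectable. At zero thresholds on nonnegative images the two coincide.
  An empty reference channel raises rather than returning 0/0.
- **Randomization control.** Channel B is partitioned into square tiles
  (default 5 px ≈ the lateral PSF scale at 0.0467 µm/px and ~250 nm
  resolution; both channels are cropped to whole tiles), tile positions are
  permuted (199 rounds by default), and p = (1 + #{null r ≥ observed r}) /
  (rounds + 1) — the add-one estimator, which cannot return 0 and is a
  valid p-value under the null.

## Synthetic image generator

Objects are capsules (rectangles with semicircular caps) at uniform random
orientation, lengths uniform in 0.7–2.2 µm and width 0.45 µm — the size
band the filtering rules target. The matrix channel renders the capsule
interior at unit amplitude. The membrane channel renders the capsule at
unit amplitude plus an outer rim (dilation by `shell_offset_px`, default
1 px, minus the capsule) at 0.7 amplitude — the dimmer out-of-focus tail of
the membrane envelope as seen in a 2-D section, where membrane above and
below the focal plane projects over the whole organelle footprint. A
strictly ring-shaped membrane channel would be the 3-D reality but not the
2-D image: it would push the noiseless overlap fractions far below what
intact organelles actually show, whereas this rendering keeps analytic
M1 = 1 and M2 ≈ 0.85–0.9 per intact object.

An `integrity_prob` parameter renders each object in both channels
(intact) or, with the complementary probability, in only one channel —
membrane-only or matrix-only according to `single_channel_bias` — emulating
organelles whose inner/outer marker correspondence is lost. The placement,
integrity and noise random streams are decoupled substreams of one seed, so
lowering `integrity_prob` with the seed fixed only flips objects from
intact to single-channel; this coupling is what makes "overlap never
increases as integrity decreases" a theorem rather than a tendency, and the
tests assert it.

Ground truth carries the noiseless grids, per-object records, and analytic
M1/M2 computed by pixel sums at zero threshold (defined as 0 when a
reference channel is empty, the disjoint-support limit). Noise is optional
Poisson resampling of signal-plus-background followed by additive Gaussian
read noise (default SD 2 at amplitude 120 and background 10 — a moderately
bright confocal regime); there is no PSF convolution, no 3-D stack, no
shot-to-shot gain variation.

What passing on these images shows: the measurement chain (threshold →
label → filter → Manders/Costes) recovers programmed object counts and
overlap fractions and agrees with brute-force oracles. What it does not
show: robustness to optical blur, uneven illumination, tissue
autofluorescence, or marker heterogeneity within organelles — real-tissue
behavior must be validated on real images.

## Cohort model and mixed-model inference

The cohort generator draws animals within the four sex × genotype cells and
neurons within animals: y = cell mean + animal intercept (SD `sd_animal`) +
residual (SD `sd_resid`). The default design is 3/3/5/3 animals with
30/20/24/30 neurons each (90/60/120/90 neurons per cell). Default responses
program a female-KO integrity deficit (M2 0.75 vs 0.85, i.e. 2 residual
SDs), a slight KO elongation tendency (aspect ratio 1.95 vs 1.90), and no
mass differences — the qualitative pattern the downstream statistics are
meant to resolve. M2 draws are truncated to [0, 1] and counts rounded to
nonnegative integers; at the default SDs truncation is a < 10⁻³ tail event
and does not materially bias the cell means.

The mixed model is a random-intercept LMM fitted by REML, profiling the
variance ratio λ = σ_u²/σ_e²: for fixed λ the covariance is block diagonal
and the Woodbury identity gives O(n) GLS per evaluation; λ is located by an
81-point log-grid scan over [1e−8, 1e8] followed by bounded scalar
minimization (tolerance far below 1e−8 on λ), always comparing against the
λ = 0 boundary (which collapses to ordinary two-way ANOVA). In balanced
designs the estimates coincide with the closed-form ANOVA moment
estimators, and the suite cross-checks against an independent REML
implementation.

Marginal means of the four cells come from the fixed-effect estimates;
all six pairwise contrasts are tested with the studentized-range (Tukey)
adjustment, P(q_{4,df} ≥ √2 |t|). Error degrees of freedom use the
containment rule, animals − 4 — conservative relative to Kenward–Roger or
Satterthwaite, a deliberate simplification that shifts p-values slightly
upward. Responses are modeled on the raw scale (counts as Gaussian, M2
untransformed), matching how such data are commonly presented; a logit
transform can be applied by the caller before fitting.

## Factor analysis of mixed data

Quantitative columns (aspect ratio, M2, object count) are standardized with
divisor n; each qualitative level's indicator (sex, genotype) is divided by
√(level proportion) and centered. The SVD of the combined matrix scaled by
1/√n gives eigenvalues (squared singular values), per-variable
contributions (squared loadings × 100, qualitative variables aggregated
over their levels), correlation-circle coordinates for quantitative
variables, and row scores with variance λ_s per dimension. Total inertia is
K + Σ(c_q − 1) = 5 for this table structure, so five nontrivial dimensions.
The divisor-n convention follows the reference implementation of the
method; it perturbs eigenvalues only at order 1/n. The sign of each
dimension is fixed by forcing its largest-magnitude quantitative loading
positive. Eigenvalues below 1e−10 of total inertia are treated as null
(exact collinearity).

Three quantitative variables are used (aspect ratio, M2, count): the
integrative analysis is meant to relate morphology, integrity and mass, and
dropping aspect ratio would reduce it to a two-variable correlation.
M1 is excluded as largely redundant with M2 on intact-dominated images.

## Pipeline

One image yields one neuron record (the per-image analysis unit);
multi-ROI-per-image analysis is future work. Unreadable files are logged
and skipped, with row counts conserved (records out + failures = images
in). Runs write CSVs plus a manifest (config snapshot, seeds, counts);
re-running a manifest's config reproduces every CSV byte-identically.

## Problem sizes in the verification suite

Simulation-based checks use sizes chosen to give stable estimates at
desk scale: 500 replicates for the randomization-validity and
mixed-model-recovery checks, 200 for the power analysis at the default
design, 20 images for oracle-equality sweeps, 128×128 px fields with 8–10
objects for ground-truth recovery. The acceptance script
(`scripts/acceptance.py`) recomputes all of these from scratch at whatever
seed is supplied.

## Known limitations

- No 3-D, no PSF model, no Airyscan or deconvolution simulation.
- No watershed or learned segmentation; touching organelles merge unless
  the aggregate rule splits them arithmetically.
- Containment df only; no Kenward–Roger/Satterthwaite.
- No GLMM for counts; no logit link for proportions.
- FAMD has no supplementary variables, imputation, or rotation.
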