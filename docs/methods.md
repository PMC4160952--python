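# Methods

`cogmap` re-implements, against synthetic data with known ground truth, the
full analysis chain of a carry-over fMRI experiment on spatial coding: an
observer views snapshots of a familiar square virtual room that vary in
*place* (camera position), *view* (the location the camera aims at) and
*heading* (the camera's allocentric compass direction), and the analyses ask
whether and how these three features — and the metric distances between
them — are reflected in voxel responses.

## Room geometry and the stimulus set

The room is a square of side 2 (room units; only relative distances matter,
all regressors are z-scored downstream). Eight camera positions occupy the
four corners and four side midpoints; views reuse the same eight locations
as camera targets; eight landmarks hang on the walls, two per side. Heading
is the bearing from place to view quantized to the eight 45° compass bins
(ties round to the lower bin index; with these coordinates no bearing falls
exactly on a bin boundary). Landmark visibility is an angular-sector test
with the 74° horizontal field of view: a landmark is visible when its
bearing deviates from the aiming direction by at most half the FOV. The room
is convex and landmarks wall-mounted, so no additional occlusion geometry is
required.

The published stimulus map is available only as a figure, so the packaged
32-snapshot set (`src/cogmap/data/room.yaml`) is a constrained
reconstruction. It was selected (by randomized combinatorial search, frozen
once) to satisfy, simultaneously:

* the printed exemplar labels — P1→V6 heads south, P6→V8 heads east, and
  the two snapshots share exactly landmarks L4 and L5 (landmark-similarity
  count 2);
* coverage — every place, view and heading occurs, all 32 (place, view)
  pairs distinct, place and view counts within 3–5;
* the reported design collinearity — over all ordered pairs of distinct
  conditions, r(heading change, place change) = 0.205 and r(heading change,
  view change) = 0.370 (reported: 0.18 and 0.39);
* the corner/side structure of the matched-view control (25 of 28 place
  pairs share at least one view) and the direction of the
  landmark-distribution check (corresponding views *less* similar,
  paired t over 28 pairs = +3.7).

Exactly uniform view and heading counts (4 each) are incompatible with the
reported collinearity under this geometry — with full balance the best
achievable r(heading, place) is ≈0.35 — so the set trades exact balance for
the published correlation structure, which the analyses are sensitive to.
Corner places can only produce three distinct headings (their bearings to
the other perimeter points span 90°), so same-place pairs occasionally share
a heading; such mixed repeats are labelled `all_different`, as only pure
single-feature repeats define the adaptation conditions.

## Carry-over sequences

Target order follows a serially balanced sequence: an Euler circuit
(Hierholzer's algorithm with seeded tie-breaking) on the complete digraph
with self-loops over the n conditions. The full cycle for n = 32 has
32² + 1 = 1025 targets and a perfectly uniform ordered-pair count matrix;
the study-sized sequence (4 runs × 176 targets = 704) truncates one seeded
circuit, keeping the pair-count spread at ≤ 1. How the original 704 trials
were drawn from the balance cycle is not public; truncation is this
package's choice. Circuits are redrawn (up to 200 attempts) until every run
contains every condition, which per-run pattern estimation requires; at run
lengths where that is unattainable the generator warns and keeps the best
draw. Catch trials (rate 25/176) and ten 4-volume fixation blocks per run
are inserted at seeded positions; 1% of targets are flagged as missed
responses. Timing mirrors the paradigm: 1.913 s stimulus + 0.478 s gap
(TR 1.914 s); the source description gives two inconsistent fixation
durations (7656 and 7757 ms, both "4 volumes"), and 7.656 s = 4 TR is used.

Each target trial is labelled relative to the immediately preceding target:
`all_same`, `same_place`, `same_view`, `same_heading`, `all_different`, or
`excluded` (first target of a run, missed response, or following a
fixation, catch, or missed trial). Five pairwise change covariates attach
to included trials: place change, view change (Euclidean), heading change
(angular, ≤ 180°), texture change (χ², below) and landmark similarity
(shared-landmark count).

## Texture model

Since the actual room renders are not reproduced, each condition gets a
synthetic grayscale proxy: every visible landmark contributes an oriented
grating patch (orientation/frequency identify the landmark, horizontal
position tracks its bearing), over a heading-dependent luminance gradient
and shared deterministic noise. Proxies are passed through a V1-like filter
bank (2 scales × 6 orientations × even/odd Gabors + 2 center-surround = 26
zero-mean unit-norm kernels — the original bank's parameters are not
public; this is a standard approximation), per-pixel responses are
vector-quantized against a 100-texton k-means codebook learned across the
image set, and images are compared by the χ² statistic between their
normalized texton histograms (unhalved convention; only relative values
matter because the covariate is z-scored). The resulting texture table
correlates positively with view distance and landmark dissimilarity, the
property the texture-change confound regressor exists to control.

## Synthetic BOLD generator

Voxels form a population **mixture** of distinct cell types — place cells
(Gaussian tuning to the observer's location), spatial view cells (Gaussian
tuning to the viewed location), head-direction cells (wrapped-Gaussian,
period 360°), and optionally location cells that respond both when standing
at and when looking at their preferred location (the substrate for
place/view cross-decoding). Mixture weights are population proportions; a
zero weight silences a feature. A multiplicative single-voxel combination
of all three kernels was evaluated and rejected: its pattern distances are
a saturating transform of view distance that the landmark predictor fits
better than the linear view predictor, making the planted map-like
structure unrecoverable by linear RDM regression; the mixture code matches
both the physiology the paradigm invokes and the analyses' estimand.
Defaults: tuning widths 0.8 room units (heading 60°), gains uniform in
[0.5, 1.5], preferred locations drawn one tuning width beyond the walls so
corner places are not under-represented by boundary truncation.

Two further generator properties keep the analyses correctly specified:

* per-condition voxel-average responses are equalized (the uniform
  component is removed per condition), so the single-trial-type adaptation
  GLMs see no condition-identity confound in the region average;
* trial amplitudes are multiplicative-linear in the within-run z-scored
  change covariates — amplitude = (1 − suppression·[exact repeat]) ×
  (1 + Σ slope·z(change)), clipped at 0.05 — exactly the linear modulator
  the distance GLM estimates. All-same trials receive only the suppression
  factor.

Signal is built at 16× oversampling (sticks at trial onsets, scaled by the
trial amplitude and the condition's pattern column, convolved with the
canonical HRF), then sampled at TR, plus sinusoidal drift (default period
300 s) and stationary AR(1) Gaussian noise. Cohorts default to the study
layout (16 subjects × 4 runs × 176 targets); per-subject tuning widths are
log-normally jittered (relative SD 0.1) and all randomness descends from a
single master seed through `SeedSequence` spawning. Volumes can be written
as 4-D NIfTI over the voxel grid with BIDS-style events tables and a
ground-truth manifest.

## GLM machinery

The canonical HRF is the standard double-gamma (peak delay 6 s, undershoot
delay 16 s, dispersions 1, ratio 1/6; peak ≈ 5 s), normalized by its
fine-grid peak so kernels at different sampling rates agree. Designs
convolve per-condition sticks at 16× oversampling and append a
discrete-cosine high-pass basis (periods > 128 s) and a constant. Parametric
modulators are z-scored within run, serially orthogonalized per an explicit
plan (defaults: view ⊥ texture, view ⊥ landmark, heading ⊥ landmark — the
shared variance is deliberately credited to the confound), then expanded to
polynomial orders 1–3 with each order residualized against the lower ones;
orthogonalization happens *before* convolution (a documented choice; the
source is silent on the order).

Estimation is two-pass prewhitening: OLS, pooled lag-1 residual
autocorrelation across voxels (one AR(1) per run, as in the original
ReML-based scheme, which this Cochrane–Orcutt-style estimator replaces at
far lower cost), AR(1) whitening of data and design, re-estimation. The
pooled rho inherits the small negative OLS bias (≈ −p/T), which is
inferentially harmless (verified: whitened and OLS estimates agree within
one standard error under white noise, and the empirical type-I rate of
contrast t-tests under AR(1) noise is within [0.03, 0.07] at α = 0.05).
Group inference uses one-sample/paired t-tests with explicit tails and
repeated-measures ANOVA (statsmodels) for condition × ROI interactions.
ROI-level analyses use Bonferroni at p < 0.01; whole-grid maps would use
Benjamini–Hochberg FDR in place of topological random-field FDR.

## Analyses

**Adaptation (label model).** One regressor per relation label plus texture
and landmark covariates; contrasts same-place/view/heading/all-same minus
all-different per subject; group one-tailed t in the reduction direction.

**Distance-modulated adaptation.** All included non-identical targets form
one trial type with polynomial modulators (orders 1–3). Two models, since
heading change correlates with both place and view change: place/view
(place, view, texture, landmark) and heading (heading, texture, landmark —
texture retained in both, a symmetric-default choice where the source is
ambiguous). Positive linear loadings = response grows with change.

**Decoding.** Per-run 32-condition GLMs on unsmoothed data (catch and
missed trials modeled separately and discarded) give run × condition ×
voxel patterns. For each pair of the eight places/views/headings, a linear
SVM (C = 1) is trained under leave-one-run-out cross-validation with
recursive feature elimination: voxels halved per step by absolute weight to
a floor of 10% of the initial count, the level chosen by an inner
leave-one-run-out split within the training folds (the original's RFE
schedule is unspecified; this is the documented default). The matched-view
control restricts each place pair to views visible from both places (25/28
pairs in the packaged set; the rest are reported as skipped). The
searchlight applies any pattern-level statistic over spherical
neighborhoods (default 9-mm diameter; at 3-mm voxels, 19 voxels), clipped
at volume borders.

**RSA.** Euclidean RDM of run-averaged patterns (per-run averaging
available behind a flag), regressed on geometry-derived predictor RDMs
(place, view, heading, texture, landmark = proportion of non-shared
visible landmarks), each z-scored over the off-diagonal upper triangle;
intercept always included; condition number checked. Same two models as
the adaptation analysis; group one-tailed t with Bonferroni p < 0.01.

**Cross-decoding.** For each location pair, train the SVM to separate
snapshots taken *from* the two locations and test it on snapshots *aimed
at* them (and the reverse). Conditions involving both locations at once
carry conflicting labels and are excluded from both sets. The
landmark-distribution check computes, per place pair, whether a place's
visible-landmark distribution is closer to its corresponding view's or the
other view's (positive t = corresponding view less similar, the direction
that rules the confound out as a cross-decoding shortcut).

## What the synthetic data do and do not show

Passing recovery tests establishes that the chain is correctly specified
for its own generative model: planted linear distance effects, population
codes and shared location channels are detected with calibrated error
rates, and absent effects stay null. They do not certify performance on
real BOLD: the generator has no motion, physiological noise, spatial
autocorrelation, nonlinear HRF variability or between-region heterogeneity,
and its amplitude model is exactly the estimand of the GLM.

One structural property deserves emphasis: heading is a deterministic
function of (place, view), and heading categories have nearly disjoint
place multisets in any stimulus set over this geometry. Leave-one-run-out
decoding tests the same 32 conditions it trains on, so a pure place code
also separates most heading pairs (≈0.75 mean accuracy under the default
generator). Feature-specific *decoding* in this paradigm is therefore not
fully disentangleable — the original study makes the same concession for
view and heading decoding — whereas the distance-modulation and RSA
analyses, which model the features jointly, do attribute planted effects
to the correct feature.

## Problem sizes and numerical choices

Recovery tests and the acceptance script use reduced sizes chosen for a
single-CPU run: 6–16 subjects, 2–4 runs of 128–176 targets, 16–200 voxels,
20 master seeds for the slope-recovery sweep, 1000 cohort simulations for
the RSA null. Tolerances: noiseless GLM round-trip < 1e-6 (achieved
~1e-14); collinearity ±0.05 (the geometry is a reconstruction); RSA null
type-I within [0.005, 0.02] at α = 0.01; cross-decoding "chance" within
±0.06. Degenerate inputs: zero-variance covariates are dropped from
designs; all-zero contrasts, rank-deficient designs, empty masks and
zero-variance group samples raise errors; χ² bins with zero total mass are
skipped; the AR(1) rho estimate is guarded against zero-residual runs and
clipped to (−0.99, 0.99).
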