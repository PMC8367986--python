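# Methods

This note documents the models implemented in `vasnorm`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## Vessel morphometry

**Segmentation.** The published workflows this pipeline serves describe
"classical image processing" without parameters, so the implementation is
deliberately parameter-light and fully specified: tissue = Gaussian
smoothing (σ = 2 px) of the DAPI channel, Otsu threshold, hole filling,
removal of specks < 64 px; vessels = Gaussian smoothing (σ = 1 px) of the
CD31 channel, rolling-ball background subtraction (radius 30 px), Otsu
threshold restricted to tissue pixels (a fixed-percentile override is
available), removal of objects < 20 px, intersection with the tissue mask,
8-connected labelling.  8-connectivity avoids fragmenting thin diagonal
vessels; the object counts reported are connected components in the 2-D
section, with no attempt at 3-D vessel identity.

**Local thickness.** At pixel *p* the thickness is twice the radius of the
largest mask-inscribed disc containing *p*, with the inscribed radius at a
pixel taken as EDT − 0.5 px.  This pixel-width convention makes an
n-pixel-wide bar read exactly n; discrete discs and tubes read their true
diameter to within ±1 px, which is the resolution limit of the
representation.  Implementation: all mask pixels are visited in decreasing
EDT order and their inscribed discs painted with a running maximum, which
reproduces the exhaustive inscribed-disc search exactly (verified against a
brute-force oracle in the tests).  The per-vessel summary diameter is the
median of the thickness map over the vessel's medial axis (mean and max are
also emitted); the pixel-pooled thickness distribution is the default
read-out, since thickness histograms are usually pooled over pixels.

**Density and distances.** Vessel density = labelled objects / tissue area,
converted to vessels/cm² via the pixel pitch; the tissue-to-vessel distance
map is the exact (not chamfer) EDT of the vessel mask complement, reported
in µm for every tissue pixel, 0 on vessels.

**Pixel pitch.** The suppression rule equates 10 px with 3.2 µm, which
fixes the default pitch at 0.32 µm/px; it is a configuration value for
images acquired at other magnifications.

## Pericyte coverage

αSMA suppression is object-level: a connected αSMA object is retained in
full when any of its pixels lies within the suppression radius (default
10 px, Euclidean, closed boundary — exactly 10 px is kept) of a vessel,
because cells, not pixels, are the unit of annotation.  Consensus is
pixel-level by default (a pixel is accepted when marked by ≥ `min_votes` of
k annotators, default 3 of 4), with an object-level mode (objects matched
across annotators at IoU ≥ 0.5) behind a flag for workflows that vote per
marked area.  A vessel counts as covered when an accepted pericyte object
overlaps it or approaches within the adjacency radius; the same 10 px scale
is reused for adjacency (one proximity scale), configurable.  Per-tumour
coverage is the unweighted mean of region fractions; a vessel-weighted
pooled fraction is also emitted.  Regions are caller-supplied — no rule for
selecting regions of interest is imposed.

## DCE-MRI perfusion

**Acquisition model.** Spoiled gradient echo at TR = 1.15 ms, TE = 0.6 ms,
nominal 5° flip angle; 50 frames of ~9 s; gadolinium bolus starting at the
beginning of frame 11.  T2*/TE decay is ignored (TE = 0.6 ms is negligible)
and the effective flip angle is an input — B1/actual-flip-angle mapping is
upstream of this package.

**Signal → concentration.** Baseline T1 comes either from a variable-flip-
angle fit (linearised SPGR relation, per voxel; non-physical slopes
flagged) or a supplied value (default 1.5 s, typical tumour tissue at high
field).  M₀ is calibrated per voxel from the mean of the pre-injection
frames; each frame is inverted to R₁(t), and C(t) = (R₁(t) − R₁₀)/r₁ with
r₁ = 3.8 s⁻¹·mM⁻¹ by default (gadodiamide at high field; configurable).
Signal values outside the invertible range are clamped and flagged rather
than propagated as NaN.

**iAUC.** Trapezoidal integration of C(t) from the start of the injection
frame over a 90 s window, expressed as a fixed linear functional (weight
vector) of the frame concentrations.  Window edges falling between frames
are handled by integrating the piecewise-linear interpolant exactly, which
makes sub-windows exactly additive and gives a closed-form null standard
deviation σ_null = σ_C·√(Σwᵢ²) for the enhancing-voxel criterion
(default: enhancing ⇔ iAUC > 2·σ_null).  The subject-level summary is the
median over masked voxels (robust to clamped voxels); the mean is also
emitted.

**Core/rim.** The core is the deepest `round(N/5)` voxels by Euclidean
distance to the mask boundary (array edges count as boundary), with ties
broken by distance to the mask centroid and then voxel index so the
partition is deterministic.  Pre/post-treatment change is summarised per
subject as Δ = post − pre of the summary iAUC and compared between groups
with a two-tailed unpaired t test (pooled variance by default, Welch by
option).  "Responder" labelling (Δ > 0 in the core) is a sign convention
only, clearly exposed as such.

## Growth delay and survival

Volumes are the ellipsoid formula V = π/6·l·w·h.  Endpoint times are the
first crossing of 400 mm³, linearly interpolated in volume between the
bracketing measurements; animals that never reach the endpoint are censored
at their last observation, included in Kaplan–Meier/log-rank, and excluded
(flagged) from the delay means.  The group comparison is ordinary one-way
ANOVA with classic Tukey HSD (studentised range, pooled variance) — with
zero within-group variance the degenerate conventions F = 0, p = 1 (equal
means) or F = ∞, p = 0 are applied explicitly.  "Brown–Forsythe" is
implemented in both of its standard senses: the robust ANOVA for equality
of means (F* with Satterthwaite denominator df; the default, matching the
phrase "equality of the means") and the median-centred Levene test for
equality of variances (`kind="variances"`).  Kaplan–Meier estimation and
the log-rank test are delegated to lifelines; the tests verify both against
hand product-limit bookkeeping and a brute-force hypergeometric
observed-minus-expected oracle.

**Known limitation — small-sample log-rank.** The log-rank p-value uses the
asymptotic chi-square reference.  With complete events and fewer than ~30
animals per arm it is measurably anticonservative (empirical type-I error
~0.07 at 8/arm, ~0.055 at 20/arm under an exponential null); the
calibration checks therefore run in the large-sample regime (50/arm), where
the empirical rate is at the nominal 0.05.  Conclusions driven by borderline
log-rank p-values at typical pre-clinical group sizes (5–15) should be
treated with caution.

## Synthetic-data generator

The generator's role is to provide ground truth for recovery testing; its
defaults are the study conditions of the pipeline it validates.

* **Sections** (default 512×512 px at 0.32 µm/px, 20 vessels of radius
  3–8 px): vessels are constant-radius tubes around smoothed random-walk
  centerlines inside an elliptical tissue region, mutually separated by at
  least 4 px; the walk's turning rate is capped so the bend radius exceeds
  the tube radius (vessels do not kink tighter than their own calibre, and
  a self-overlapping envelope would read thicker than its nominal
  diameter).  Exactly `floor(n·f + 0.5)` vessels are flagged for pericyte
  coverage; each flagged vessel receives one αSMA blob within 5 px of its
  wall and at least 14 px from every other vessel, so the simulated
  coverage fraction is unambiguous at the 10 px adjacency scale.  Channel
  intensities are constant levels plus Gaussian noise.  Not emulated:
  intensity gradients, staining heterogeneity, vessel branching, 3-D
  structure — so passing recovery tests demonstrates correctness of the
  geometry pipeline, not robustness to stain variability.
* **Annotator votes**: per-object false negatives (each annotator misses
  each true object with probability fn) and spurious disc-shaped false
  positives at rate fp per true object.  Annotators err independently;
  correlated annotator bias is not modelled.
* **DCE series** (default 8×8×4 voxels, 50 frames of 9 s, bolus at frame
  11): per-voxel concentration is a known amplitude times a unit-peak
  gamma-variate curve (shape 2, scale 15 s; peak 30 s post injection) —
  chosen over a two-compartment model because the analysis only integrates
  concentration, and the gamma variate has a closed-form incomplete-gamma
  integral that makes the integration oracle exact (trapezoid error 0.15%
  at 9 s sampling).  Signal noise is additive Gaussian by default (Rician
  optional); at the simulated SNR the difference is immaterial and Gaussian
  keeps the noiseless roundtrip exact.  The 5 s bolus-infusion duration is
  carried as metadata; dispersion is already in the curve shape.
* **Growth studies** (default: 7 controls and 10 treated, growth rate
  0.15 day⁻¹, 10-day arrest, start volume uniform in 100–120 mm³,
  measurements every 2 days ≈ three per week, 5% calliper CV): true volume
  V(t) = V₀·exp(k·max(0, t − arrest)); measured dimensions are the
  sphere-equivalent diameter times independent log-normal factors of unit
  mean (calliper error scales with size).  Growth is exponential throughout
  — no Gompertzian slowing, regrowth heterogeneity, or cure fraction unless
  configured via censoring at the study horizon.

Every generator is a pure function of its parameters including the seed;
pipeline runs derive all stage seeds from one root seed via named
substreams.

## Numerical conventions

* Flag counts and core sizes round half up (`floor(x + 0.5)`), never
  banker's rounding.
* The suppression/adjacency boundary is closed: exactly 10 px is retained.
* EDT is always the exact Euclidean transform; array edges count as
  background for boundary-distance purposes (masks are padded before the
  transform).
* Degenerate statistics are explicit conventions, not NaN: identical groups
  give t = 0, p = 1 (flagged); no events at all gives a flagged undefined
  log-rank.
* Problem sizes in the test-suite and acceptance script (64×64 oracle
  rasters, 200-vessel coverage sections, 10×10×10 noisy DCE grids, 1000
  null simulations, 100 end-to-end repetitions) were chosen as the smallest
  sizes at which each property is informative.
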