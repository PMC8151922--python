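# Methods

This note records the models, conventions and numerical choices behind
`renotex`, in the order the pipeline runs them.

## Synthetic cohort generator

**What it emulates.** The generator produces per-kidney grayscale images
with the statistical structure a sonographer uses to stage CKD, plus the
scalar covariates of the study cohort. Each image is a vertical stack of
three tissue bands — cortex, corticomedullary transition, medulla/sinus —
with one 50×50 ROI window centered in each band (default frame 160×64 px;
any geometry that holds three disjoint windows is accepted).

**Speckle model.** Ultrasound speckle is approximated by correlated
multiplicative Gamma noise: a white Gaussian field is smoothed periodically
by a Gaussian kernel of scale `corr_length_px`, standardized exactly (the
effective kernel's ℓ₂ norm is computed analytically, so the marginal is
exactly N(0, 1)), and mapped through the probability integral transform to a
Gamma(k, 1/k) marginal. The result is a unit-mean positive field with
variance 1/k and correlation scale `corr_length_px`; it multiplies the
band's mean echo level, is clipped to [0, 255] and rounded to 8 bits. This
is a standard texture-level surrogate for fully developed speckle: it
reproduces multiplicative, positively skewed, spatially correlated noise
without modeling beamforming or point-spread-function physics (explicitly
out of scope, as is DICOM output).

Two consequences worth knowing: clipping at 255 biases the sample mean
slightly below `mean_echo` when `mean_echo · noise` has tail mass above 255
(≤ 5 % for every default profile; the severe cortex, echo 160 at k = 4, is
the worst case), and the `speckle_shape → ∞` limit is implemented as
noise-free, giving a constant raster.

**Corticomedullary boundary.** The middle band's mean profile is a vertical
tanh ramp between the cortex and medulla echo levels, centered on the
band's own mean echo. Its width is `1 + (1 − s)·(band_height/3)` pixels,
where `s` is `boundary_sharpness`: s = 1 concentrates the full echo swing
into roughly one row (crisp interface), s = 0 spreads it over a third of the
band (the blurred interface of advanced disease).

**Per-class defaults.** Kidney size (bipolar length, cm) and eGFR
(mL/min/1.73 m², metadata only) use the study cohort's per-class mean ± sd:
sizes 11.7 ± 0.46 / 9.14 ± 2.00 / 7.07 ± 1.70, eGFR 105 ± 16.7 / 40 ± 9.7 /
4 ± 4.2 for normal / mild & moderate / severe. Size draws are truncated
below at 0.5 cm (the severe sd admits nonphysical values; the truncation
shifts the severe mean by < 3·10⁻⁴ cm and is negligible for the others).
eGFR is drawn untruncated: it is descriptive metadata, never a classifier
input, and clipping Normal(4, 4.2²) at zero would bias its mean by more
than one unit.

The texture knobs encode directions that are clinically described but not
quantified anywhere, so their magnitudes are this package's calibration
choices, chosen once to be realistic and documented as free parameters:

| class | cortex echo | cortex shape k | corr. length (px) | boundary sharpness |
|---|---|---|---|---|
| normal | 60 | 10 | 1.5 | 1.0 |
| mild & moderate | 110 | 6 | 2.0 | 0.5 |
| severe | 160 | 4 | 2.5 | 0.2 |

Echo rises (fibrosis), heterogeneity rises (k falls) and texture coarsens
(correlation length grows) with severity; the medulla/sinus band stays at
echo 160, k = 6 throughout. The boundary band's mean echo is the midpoint
of its neighbors.

**Determinism.** Each record draws from an independent child stream spawned
from the cohort seed (`numpy.random.SeedSequence`), so cohorts are
reproducible bit-for-bit and record-by-record regardless of generation
order. Per record the draw order is fixed: size, eGFR, cortex band,
boundary band, medulla band.

**What passing tests do not show.** The generator has three homogeneous
horizontal bands, stationary speckle and exact class-conditional
distributions; real sonograms have curved anatomy, depth-dependent gain,
shadowing, probe pressure variation and label noise. Perfect separability
of the synthetic classes (and the pipeline's 100 % held-out accuracy on
defaults) therefore demonstrates that the pipeline recovers class structure
of the kind described — not that any particular accuracy transfers to
clinical data.

## Preprocessing

Per ROI (full-frame use is possible but the default operates on the cropped
window), two stages in fixed order:

1. **Histogram equalization** with the discrete mapping
   `out(v) = round((cdf(v) − cdf_min)/(1 − cdf_min) · (levels − 1))`,
   `levels` = 256 by default. A constant window (degenerate histogram) maps
   to all zeros. The mapping is monotone, so intensity ordering is
   preserved.
2. **Range filter**: max − min over a 3×3 window with replicate padding
   (zero padding would manufacture edge responses at ROI borders). The
   window is the smallest standard neighborhood; no guidance existed for a
   different choice.

Both toggles and both parameters are recorded in every feature table's
provenance header, because which preprocessed image feeds the texture stage
is an open question in this analysis family — downstream results are only
comparable when the header matches. Note that equalization largely removes
mean-brightness differences between ROIs; class information then travels
through texture shape (grain size, heterogeneity, edges) and the size
feature.

## Co-occurrence features

**Quantization.** Linear equal-width binning of the inclusive intensity
range into Ng 1-based levels; by default the ROI's own min–max range
(`image_minmax`), with `full_range` ([0, 255]) available. Ng = 8 by
default: the convention of the common co-occurrence toolboxes, and small
enough that a 50×50 window populates an 8×8 matrix densely. A constant
window maps to level 1.

**Matrix.** For each orientation (0° → (0, d), 45° → (−d, d), 90° →
(−d, 0), 135° → (−d, −d), rows growing downward; d = 1 default) every
in-bounds ordered pixel pair is counted; symmetric mode (default) adds the
transpose before normalizing, making p = pᵀ and px = py. The Table of
marginal quantities — px, py, p_{x+y}, p_{x−y}, their means and variances,
and the entropies HX, HY, HXY, HXY1, HXY2 — is computed with the
0·log 0 = 0 convention; natural log by default, log₂ switchable.

**Descriptors.** All 19 second-order descriptors are evaluated per
orientation and angle-averaged. Published formula tables for this family
disagree in places, so two dialects are implemented and the choice is
recorded in provenance:

* `as_printed` (default): cluster prominence with exponent 3 and cluster
  shade with exponent 4; the inverse-difference inner sum starting at the
  second column; the second information measure of correlation without the
  square root.
* `classical_haralick`: exponent 4 prominence / exponent 3 shade, inverse
  difference over the whole matrix, and the square-rooted second
  information measure.

Neither dialect is asserted as ground truth; both are validated against an
independent brute-force evaluator. Conventions for degenerate matrices:
correlation = 0 when either marginal variance vanishes, and both
information measures of correlation = 0 on a zero-entropy (single-cell)
matrix — this avoids NaN propagation on constant ROIs. The unsubscripted μ
in cluster prominence/shade and sum-of-squares variance is read as
μ = Σᵢⱼ i·p(i, j) = μx (= μy in symmetric mode), the standard
interpretation. One published quirk is preserved deliberately: under the
printed first information measure of correlation,
imc1 = (HXY − HXY1)/max(HX, HY) ≤ 0 always, since HXY1 − HXY is a
Kullback–Leibler divergence. Another is its consequence: on a single-cell
matrix the printed inverse difference (inner sum from column 2) is 0 where
the classical one is 1.

All summation indices are 1-based gray levels (i, j ∈ 1..Ng,
k = i + j ∈ 2..2Ng, k = |i − j| ∈ 0..Ng − 1).

## Feature fusion and tables

Sample vector ordering is fixed: cortex (19), boundary (19), medulla (19),
size_cm — 58 values; the texture block alone is 57. ROI coordinates are
0-based and half-open, which removes off-by-one ambiguity. Tables are CSV
with a single `# provenance:` JSON header line (preprocess + feature
configuration, cohort seed, config hash) and round-trip floats exactly
(`%.17g` on write, round-trip parsing on read). A record that fails
extraction aborts the run with every offender named — silently dropping
rows would corrupt the class balance. Kidney size is treated as an opaque
positive scalar in cm.

## Classifier

A single tanh hidden layer of 10 units between the 58 inputs and the 3-way
softmax output. The architecture is sometimes described as "10 hidden
layers"; the single-layer-of-10 reading matches the reporting style of the
classic pattern-recognition toolboxes this setup follows, and a literally
stacked variant is available via `NetworkConfig.hidden_layers` for
comparison.

* **Split**: seeded random assignment with n_train = round(0.70 n),
  n_val = round(0.15 n), n_test = n − n_train − n_val (741 → 519/111/111);
  optional stratified mode keeps per-partition class proportions within one
  record.
* **Scaling**: per-feature min–max from the *training partition only*,
  mapped to [−1, 1]; out-of-range inputs at predict time are clipped,
  constant features map to 0. The descriptors span wildly different scales,
  so unscaled training is ill-conditioned.
* **Optimization**: full-batch Adam (lr 0.01, β = 0.9/0.999), Glorot-uniform
  initialization from the config seed, mean cross-entropy loss; at most
  1000 epochs. Early stopping halts training once the validation loss has
  not improved for 6 consecutive epochs (the classic "max validation
  failures" rule) and restores the weights of the best validation epoch.
  With no validation partition the best epoch is judged by training loss.
* **Determinism**: identical (table, split, config) reproduce identical
  weights; the model serializes to a single JSON file (weights, scaler,
  config, history, best epoch).

## Evaluation

Confusion matrices use the fixed class order (normal, mild & moderate,
severe). Classification rate = 100·trace/total percent; misclassification
rate is its complement, so the two sum to 100 identically. ROC curves are
one-vs-rest per class over the predicted class probability with tied scores
grouped into one threshold step; AUC is the trapezoidal area, which equals
the Mann–Whitney concordance probability with ties counting ½ — the test
suite verifies this equivalence against brute-force pair enumeration. Rates
print to one decimal in the CLI; JSON reports keep full precision. A
resubstitution report over the full cohort is emitted alongside the three
partition reports, since aggregate figures in this analysis family are
sometimes quoted either way.

## Problem sizes used by the test suite

The acceptance-level tests run the study-scale configuration: 741 images at
160×64 px, 100,000 kidney-size draws per class for calibration (3-standard-
error tolerance), 200 matched-seed replicates for the echo-severity
ordering, 200 random small images against the brute-force descriptor
oracle, and the full pipeline over 5 seeds for the held-out accuracy check
(median ≥ 0.90). These sizes keep the full suite under a minute while
leaving Monte-Carlo tolerances comfortably tight.

## Known limitations

* The generator's geometry is schematic (flat bands, no organ contour); it
  supports testing the measurement chain, not training clinically useful
  models.
* Descriptor dialect ambiguity is surfaced, not resolved: published
  per-class descriptor tables in this analysis family contain internally
  inconsistent rows (probabilities above 1, duplicated rows, negative
  entropies), so they are treated as qualitative context only and never as
  numeric oracles.
* Multi-distance co-occurrence aggregation (d > 1) is configurable but
  unexercised by defaults; no other texture families (run-length, LBP,
  wavelets) are provided.
* No automatic ROI localization: ROI windows come from the manifest, as in
  the manual-placement workflow this pipeline mirrors.
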