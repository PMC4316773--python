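# Methods

## The analysis model

Every measurement domain is reduced to the same object: a scene space, the
n × n matrix of Pearson correlations between per-scene representations.
First-order similarity is always Pearson r (no rank or distance variants).
For second-order analysis the strict upper triangle is vectorized in
row-major order — length n(n−1)/2, 4950 pairs at n = 100 — and
Fisher-transformed, z = atanh r, so correlation-valued entries are
approximately normal before they are themselves correlated, regressed, or
resampled. Behavioral matrices carry log-mean ratings rather than
correlations and are therefore never Fisher-transformed; downstream
operations treat the two scales identically as vectors over scene pairs.

Assumptions worth stating explicitly:

- Pair entries are treated as exchangeable observations in second-order
  correlation, regression and the bootstrap. They are not strictly
  independent (each scene participates in n−1 pairs); parametric p-values
  at the pair level are therefore anti-conservative, which is one reason
  the bootstrap is preferred for model-fit comparisons.
- Missing cells (behavioral pairs with no surviving observations,
  zero-variance rows) propagate as NaN and all second-order statistics use
  pairwise-complete entries; hierarchical regression drops incomplete rows
  listwise to keep the nested fits on one common sample.

## Neural pattern reduction

Trial-level voxel data are indexed (scene, repetition, timepoint, voxel)
with uniform timepoint spacing (2 s default, 0–8 s epoch). The scene
pattern is the mean over repetitions, then over the timepoints whose onset
lies in the closed peak window [6, 8] s — with 2 s spacing exactly the 6 s
and 8 s samples, the average response peak. Repetitions with missing data
are averaged over the available ones (count logged). Voxels enter in
row-major grid order from the ROI mask, recorded in metadata, so patterns
are bit-reproducible. Participant averaging is the cell-wise mean of raw
r-values; averaging in Fisher space first is available behind
`fisher_first=True` since the order of those two operations is a genuinely
open choice.

## Descriptor implementations

**GIST.** 32 oriented band-pass filters (8 orientations × 4 scales) built in
the frequency domain: Gaussian in log-frequency (bandwidth 0.65 octaves,
center frequencies one octave apart from 0.25 cycles/px) crossed with a
Gaussian in orientation, DC response zero. Squared complex response
magnitudes are averaged on a 4 × 4 grid → 512 dimensions. A constant image
maps to exactly zero.

**HOG 2×2.** Per 8 × 8-pixel cell: 18 contrast-sensitive orientation bins,
9 contrast-insensitive bins, and 4 normalization-block energy (texture)
features, each normalized against the four surrounding 2 × 2 cell blocks
with truncation at 0.2 (31-d per cell). 2 × 2 spatially overlapping cells
are stacked into 124-d block descriptors, quantized against a k-means
codebook, and histogrammed on 1 × 1 / 2 × 2 / 4 × 4 pyramid grids (L0–L2);
each level's vector (length k × cells) is L2-normalized. The codebook size
for HOG is not fixed by the method definition and is configurable (default
k = 300). The signed bin count is configurable; 16 bins make a 90°
rotation an exact 4-bin permutation, which the tests exploit as an oracle.

**Self-similarity.** At dense sample points, the 5 × 5 center patch is
compared with every displaced patch within a 40 px radius via
exp(−SSD / (25 · var)), the standard similarity surface for this
descriptor; the surface is pooled by maximum into 4 radial × 10 angular
log-polar bins (40-d). Points whose window exits the image are skipped and
zero-variance patches excluded, both counted. Descriptors are quantized
into 300 visual words.

**Dense SIFT family.** Fixed-grid sampling (stride 8 px, 16 px patch), 4 × 4
spatial sub-bins × 8 orientation bins of gradient magnitude (128-d),
L2-normalized with truncation at 0.2 and renormalization; no keypoint
detection or rotation invariance, as appropriate for dense sampling.
Hue-SIFT runs the same machinery on the HSV hue channel; RGB-SIFT
concatenates per-channel descriptors (384-d). Hue-histogram features are
local hue samples embedded on the unit circle (cos h, sin h) so k-means
quantization respects circular distance.

**Bag of visual words.** Seeded k-means (10 restarts) with centroids
canonicalized by sorting on the first coordinate (lexicographic
tie-break), nearest-centroid assignment with ties to the lowest index,
L2-normalized count histograms. An empty descriptor set yields the zero
vector with a warning rather than an error.

**Geometric-class maps.** Per-class probability maps in [0, 1] are
block-averaged to 8 × 8 (64-d per class, "all" = concatenation). Real
geometric-class classifiers are out of scope; the synthetic module supplies
maps.

**Attribute reweighting.** For each attribute, v = variance (population,
ddof 0) of the per-category mean scores; the column is scaled by exp(v).
The per-category mean — not per-scene scores — is the deliberate reading:
the weighting should reflect between-category separability. The functional
form exp(v) is the simplest consistent choice; any positive scaling
preserves within-attribute scene ranking, which is the tested invariant.

## Behavioral aggregation

Ratings arrive as HITs of 11 trials containing exactly one catch trial (an
identical pair whose correct answer is 8). Exclusions, in order: (1) a HIT
whose catch trial was answered with anything but 8 is dropped wholesale;
(2) a rater who failed ≥ 2 catch trials *and* used only the responses
{1, 8} is removed entirely — such data cannot be distinguished from button
mashing. Both thresholds are configurable because the boundary between the
two rules is qualitative. Surviving non-catch responses are
natural-log-transformed (the pooled distribution is strongly right-skewed;
the log base only rescales and cannot affect later correlations) and
averaged per unordered pair; empty cells stay missing. A response of 8 on a
non-catch pair is kept as a valid rating — discarding it would bias the
average for genuinely near-identical pairs.

## Synthetic data: what it emulates, and what it does not

- **Images** are per-category oriented gratings: each category draws an
  (orientation, spatial-frequency, hue) triple; exemplars jitter those
  parameters and add pixel noise. This gives descriptors genuine
  within-category structure (verified: mean within-category GIST similarity
  exceeds between-category) without any photographic content. It does not
  emulate scene semantics, clutter, or the layout statistics real
  photographs have, so passing recovery tests show the *pipeline* is
  correct, not that any particular descriptor is a good scene model.
- **Attribute tables** are category means (spread `category_effect`) plus
  exemplar noise — the covariance structure, not the semantics, of
  classifier confidences. Default table width is 84 attributes.
- **Voxel data** embed a target correlation structure exactly: the signal
  matrix is built as L Qᵀ where L Lᵀ is the target matrix and Q an
  orthonormal, zero-column-mean basis, so the voxel-wise Pearson
  correlation of the noiseless patterns *equals* the target to machine
  precision (this requires n_voxels ≥ n_scenes + 1). Per-trial white noise
  (sd relative to unit signal) and a peristimulus amplitude profile
  (attenuation 0.3 outside the peak-window samples) are layered on top.
  Hemodynamics, temporal autocorrelation and scanner noise spectra are
  deliberately not modeled. A mixture whose implied matrix is not positive
  semidefinite is an impossible target and raises; the nearest correlation
  matrix can be requested explicitly and is flagged in metadata.
- **Ratings** discretize the standardized true pair similarity plus
  Gaussian noise (sd 1) onto 1–7 through fixed cut points with marginal
  probabilities (0.50, 0.22, 0.11, 0.07, 0.05, 0.03, 0.02) — a majority of
  "different" responses, giving pooled sample skewness above 1 and thereby
  the regime that motivates the log transform. Only this aggregate shape
  is calibrated; per-pair response distributions are not constrained.
  Raters complete ~17 HITs each; planted bad raters answer catch trials
  incorrectly and use only {1, 8}, exactly matching the downstream
  whole-rater exclusion rule so exclusion counts are checkable.

## Numerical choices

- Fisher clamp: |r| = 1 maps to atanh(1 − 1e−7) with sign, so identical
  synthetic scenes cannot produce infinities; the inverse recovers r to
  1e−12 away from the clamp.
- Symmetry tolerance for similarity-matrix validation: 1e−10.
- Constant-row detection uses exact peak-to-peak zero, not a std threshold.
- Hierarchical regression fits nested OLS by rank-revealing least squares;
  cumulative R is clipped to [0, 1] and increments floored at 0 (they are
  nonnegative analytically; floating point can produce −1e−16). The
  increment test is an F-test on ΔR² — the conventional test for a block
  increment — with Bonferroni flags against a declared family (default 39
  correlations) plus uncorrected flags.
- Bootstrap: the resampling unit is the scene-pair entry, jointly across
  target and both models — pairs are the observations entering every
  correlation. Percentile CI (BCa was considered and rejected as
  unnecessary complexity at these sample sizes); multiple-comparison
  control widens the CI level to 1 − (1 − level)/family. Degenerate
  resamples are redrawn and counted. Models are compared on r², with the
  signs of the full-sample correlations reported alongside, because a
  negatively correlated model can still rank high on fit and the sign is
  then interpretively important.
- k-means ties and restarts as above; all stochastic functions take an
  explicit seed and use one `numpy` Generator per call — no global state.

## Problem sizes

Recovery and calibration checks run at desk scale, chosen to finish in
seconds-to-minutes while leaving the statistics well-resolved: 30 scenes
(435 pairs), 120 voxels, 6 repetitions and noise sd 1.0 for the
weight-order recovery (100 seeded runs); 190-pair vectors, 1000 bootstrap
iterations and 200 runs for null calibration. At these conditions the
(0.6, 0.3, 0.1) mixture ranking is recovered essentially always; pushing
trial noise to sd ≈ 2 is where recovery begins to drop below 95%, and by
sd 10 the recovered ranking is uninformative — the documented working
range of the generator's noise dial.

## Known limitations

- Scanner-side preprocessing (motion correction, GLM, filtering) and ROI
  definition are out of scope; the package consumes trial-level arrays and
  masks as given.
- The pair-level bootstrap ignores the dependence induced by shared scenes;
  a scene-level resampling option exists for sensitivity analysis.
- Synthetic images exercise low-level descriptors meaningfully but cannot
  validate semantic attribute models against real photographs.
- Split-half reliability splits repetitions (odd/even or first/second
  half); it does not model session-specific drift.
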