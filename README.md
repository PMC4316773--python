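# scenespace

Representational similarity analysis (RSA) of visual scenes across three
measurement domains: voxel patterns from scene-selective cortex, behavioral
similarity ratings, and computer-vision scene models.

The question the package addresses: *which image representations predict how
the brain groups scenes?* Every candidate representation — a voxel pattern
per scene in a region of interest (ROI), a descriptor vector per scene from
a computer-vision model, or the average similarity rating per scene pair —
induces a **scene space**: the n × n matrix of pairwise Pearson correlations
between scenes,

&nbsp;&nbsp;&nbsp;&nbsp;*S*ᵢⱼ = corr(**x**ᵢ, **x**ⱼ).

Scene spaces are compared at second order: each matrix's strict upper
triangle (n(n−1)/2 pairs; 4950 for 100 scenes) is vectorized, Fisher
z-transformed (z = atanh r), and correlated across methods. On top of this
the package provides

- **model ranking** per target (e.g., per ROI): candidate models sorted by
  their correlation with the neural scene space;
- **ordered hierarchical regression**: predictor blocks entered
  low-level → high-level, reporting cumulative multiple R and the increment
  ΔR each block contributes, with an F-test on each R² increment;
- **bootstrap model comparison**: scene pairs resampled with replacement
  (1000 iterations), a percentile 95% CI on r²_A − r²_B, significant when 0
  falls outside it.

Implemented scene models: GIST (8 orientations × 4 scales × 4 × 4 grid =
512-d), HOG 2×2 spatial pyramid (L0–L2) over a k-means codebook,
self-similarity descriptors (5 × 5 patch, 40 px window, log-polar pooling,
300 visual words), hue histogram and dense / hue / RGB SIFT bag-of-words
(k ∈ {50, 250, 400, 1000}), geometric-class probability maps pooled to
8 × 8, and attribute-classifier score tables with exponentiated-variance
reweighting. Behavioral ratings (1–7, 8 = identical; HITs of 11 trials with
one identical-pair catch trial) are cleaned by catch-trial exclusion and
log-transformed before per-pair averaging.

A synthetic-data module generates all four input kinds with known ground
truth — including voxel data whose induced scene space is an exact, known
weighted mixture of model scene spaces plus noise — so every stage of the
pipeline can be validated by parameter recovery.

## Worked example

Embed a known 0.6 / 0.3 / 0.1 mixture of three orthogonal model scene
spaces into noisy voxel data (30 scenes, 120 voxels, 6 repetitions,
peristimulus samples at 0–8 s), rebuild the neural scene space from the
6–8 s window, and ask which model explains it:

```python
import scenespace as sc

spaces = sc.orthogonal_scene_spaces(n_scenes=30, n_spaces=3, seed=7)
mix = sc.GroundTruthMixture(spaces, weights=(0.6, 0.3, 0.1), noise_sd=1.0, seed=8)
trials = sc.gen_voxel_patterns(mix, n_voxels=120, n_repetitions=6,
                               n_timepoints=5, peak_window=(3, 4))

patterns = sc.build_scene_patterns(trials, window=(6, 8))
neural = sc.upper_triangle(sc.pairwise_similarity(patterns.values),
                           transform="fisher_z")

models = {f"model{k}": spaces[k] for k in range(3)}
for label, r in sc.rank_models(neural, models):
    print(f"{label}: r = {r:+.3f}")

fit = sc.hierarchical_regression(neural, list(models.items()))
for lab, R, dR, p in zip(fit.labels, fit.cumulative_r, fit.delta_r, fit.p):
    print(f"block {lab}: cumulative R = {R:.3f}, dR = {dR:.3f}, p = {p:.2e}")

bt = sc.bootstrap_model_difference(neural, spaces[0], spaces[1],
                                   n_iter=1000, seed=9)
print(f"r2 difference = {bt.estimate:.3f}, "
      f"95% CI [{bt.ci_low:.3f}, {bt.ci_high:.3f}], significant = {bt.significant}")
```

Output:

```
model0: r = +0.724
model1: r = +0.378
model2: r = +0.150
block model0: cumulative R = 0.724, dR = 0.724, p = 9.71e-72
block model1: cumulative R = 0.817, dR = 0.093, p = 1.96e-35
block model2: cumulative R = 0.830, dR = 0.014, p = 4.13e-08
r2 difference = 0.380, 95% CI [0.280, 0.466], significant = True
```

The ranking recovers the mixing-weight order (0.6 > 0.3 > 0.1), each
model's regression block adds variance in the same order, and the bootstrap
confirms the dominant model fits significantly better than the runner-up.

A command-line front end mirrors the pipeline stages
(`scenespace simulate | extract | similarity | compare | report`); run
`scenespace --help` for details.

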