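# Methods

This note documents the models, parameters and design choices behind
`adiposcan`, and what the synthetic experiments do and do not demonstrate.

## Synthetic phantoms

Real whole-body T1-weighted scans contrast bright adipose tissue against
dim lean tissue over 90–120 transverse slices whose count varies with body
height. The phantom generator reproduces the *statistical* structure of
such data, not the physics: no relaxation-time modeling, coil profiles or
k-space artifacts.

A phantom is a stack of elliptical cross-sections — head, neck, torso with
laterally extended arm cylinders, abdomen, pelvis, legs — on a voxel grid
with axis order (vertical, sagittal, coronal). Body girth scales with
`sqrt(BMI / 25)`; sex toggles the shoulder/hip width ratio and an anterior
breast bulge. Seven disjoint anatomical depot regions (subcutaneous ring,
upper and lower deep visceral core, thigh, arm, neck, breast) carry the
fat model: a depot with fraction *f* has `round(f · |region|)` of its
voxels set to fat intensity (1.0) and the rest to lean intensity (0.3),
with the fat voxels chosen by a seeded, spatially smoothed priority field
so fat forms contiguous clumps. Gaussian texture noise (SD 0.03) is added
inside the body and clipped to stay positive; background is exactly 0.
Every generator call is a pure function of its seed.

The planted fat-voxel counts per depot are recorded on the volume, which
makes compartment-volume recovery exactly testable and gives saliency
scoring a ground truth.

### Label model

Labels are drawn from an explicit generative chain whose every parameter
lives in `LabelModelConfig`:

- sex ~ Bernoulli(0.5); age ~ N(48, 12²) years; BMI ~ N(28, 4.5²) kg/m²
  (clipped to 18–45, reflecting a risk-enriched screening population);
- diabetes status ~ Bernoulli(prevalence 0.30). In the default `volume`
  mode positives receive +0.40 lower-visceral depot fraction (≈0.70 vs
  ≈0.30); in `pattern` mode positives get (lower, upper) visceral
  fractions (0.55, 0.15) and negatives (0.15, 0.55), so combined visceral
  load — and hence every benchmark input — is matched between groups;
- insulin sensitivity (Matsuda-like, AU) = 18 − 16·visc_lower − 4·thigh
  + N(0, 1.5²), floored at 0.5;
- glycemia increases with the insulin-sensitivity deficit. Non-diabetic
  values are clipped below the diagnostic cut-offs; diabetic values are
  drawn from a component that crosses them by construction, so the
  threshold diagnosis reproduces the planted status exactly and
  prediabetes (IFG 5.6–6.9 mmol/l, IGT 7.8–11.0 mmol/l, the common
  research band definitions) emerges from the same chain. HbA1c is
  generated in % and converted with mmol/mol = (% − 2.15) × 10.929;
- follow-up events use exponential hazards `h0 · exp(β · ΔHbA1c)` (diabetes
  h0 = 0.02/yr, β = 0.9; microalbuminuria h0 = 0.03/yr, β = 0.5) with
  uniform censoring on [0.25, 9.75] years and administrative censoring at
  10 years, giving a mean follow-up near 4 years with a wide spread.

A separate utility draws stand-alone 128-dimensional "embedding-like"
vectors from a four-component Gaussian mixture whose component means are
sampled with SD three times the within-component SD — at 128 dimensions
this yields unambiguous, well-separated subtypes. This is the default
subtype mixture used by the clustering analyses when no trained network is
in the loop.

### What the phantoms do not emulate

Scanner bias fields, motion artifacts, organ texture, anatomical
covariance beyond the modeled depots, repeated measurements of one person,
and any real-world label noise. Passing tests therefore demonstrate that
the *pipeline* recovers planted structure under its stated assumptions,
not that the method achieves any particular accuracy on clinical data.

## Preprocessing

- **Shape.** Variable-height volumes are linearly interpolated along the
  vertical axis to a fixed slice count, then the whole grid is linearly
  downsampled (anti-aliased) to the network input dimensions. Full-scale
  profile: 95×150×250 → 85×110×135. The coarser vertical resolution
  receives no further interpolation correction. Masks travel through the
  same transforms with argmax assignment, which preserves disjointness.
- **Intensity.** Non-body voxels are zeroed before any statistic is
  computed (background identification falls back to an Otsu threshold plus
  largest connected component when no mask is provided). Body voxels are
  standardized to mean 0 / SD 1 — by default with pooled training-fold
  statistics, so all scans receive one shared transform; a per-scan switch
  exists — truncated at ±3 SD and shifted by 3.01, leaving the body
  minimum strictly positive and distinct from air at exactly 0. The band
  and shift are package choices; only the mean-0/SD-1 standardization and
  the strict positivity are contract.
- **Labels.** Continuous labels are min–max scaled to [0, 1] on
  training-fold extrema; the stored inverse transform converts a
  normalized MAE back to absolute units (MAE_abs = MAE_norm × range). A
  missing label masks that subject out of the corresponding head's loss
  only, rather than dropping the scan for all eight tasks; strict whole-row
  exclusion remains available.
- **Outliers.** An isolation forest on exactly four features — insulin
  sensitivity, BMI, HbA1c, total adipose volume — with configurable
  contamination (default 0.02), seeded.
- **Split.** 70/15/15 stratified by BMI tertile × insulin-sensitivity
  tertile × diabetes status. Singleton strata merge into the nearest
  stratum (Manhattan distance on bin coordinates) so every stratum holds
  more than one sample. Fold counts use controlled rounding: every
  stratum-fold cell is the floor or ceiling of its exact quota while the
  global totals are hit exactly, so per-stratum proportions sit within one
  sample of the targets.

## Network and training

The classifier is a 3D DenseNet: 5×5×5 initial convolution (8 filters) →
batch normalization → 2× max pooling → three [dense block → transition]
stages → flatten → FC 512 → FC 256 → FC 128 (embedding) → per-task heads.
Dense layers use the pre-activation composite BN → ELU → 3×3×3
convolution and append 18 feature maps each (no bottleneck); transitions
compress channels by 0.5 with a 1×1×1 convolution and halve each axis by
average pooling. All activations are exponential-linear except the final
regression nodes; weights use He initialization; dropout (0.2) follows
each FC layer. Binary heads are 2-node softmax pairs — required so
attribution can differentiate exactly the node matching the true label —
and regression heads are linear.

The loss is an equally weighted sum of per-head cross-entropy and
mean-absolute-error terms with per-head missing-label masks. Adam starts
at 1e-4 with a cyclic exponentially decaying schedule
`lr(e) = init_lr · 0.98^e · (0.75 + 0.25·cos(2πe / 20))` (equal to
`init_lr` at epoch 0); validation AUROC/MAE are logged once per epoch and
the checkpoint with the highest validation diabetes AUROC is selected,
ties to the earliest epoch.

The forward/backward engine is hand-written NumPy (im2col convolutions,
reshape-trick pooling, standard batch-norm backward); its gradients are
verified against central finite differences, and the same backward pass
yields exact input gradients for attribution. Two places need explicit
tie/degeneracy rules: max-pool backward splits gradient equally among tied
maxima, and average pooling zero-pads odd axes with the pad included in
the divisor.

### Scaled-down profile

The full-scale configuration (85×110×135 inputs, 4 layers per block,
250 epochs) is far beyond a CPU session, so the default `tiny` profile
runs the identical pipeline at reduced size: raw in-plane 22×37,
normalized 24×22×37, final 20×16×20 (vertically finer than a proportional
scaling because the planted contrasts vary along the body axis), 2 layers
per block, 12 epochs over 300 phantoms, and an initial learning rate of
1e-3 — the 1e-4 default is calibrated to hundreds of epochs, and a 12-epoch
run at that rate leaves the output heads essentially at initialization.
Augmentation ranges scale with the grid (pad ≤ 1 voxel, rotations ≤ 5°/2°,
body-only Gaussian noise at 5% of body SD); the pattern-signal experiment
disables the spatial transforms entirely because a one-voxel translation
is the size of the structure being detected. Validation and test volumes
are centered only.

## Attribution and region scoring

Attribution is gradients×input: the per-voxel product of input intensity
with the gradient of one output node. Classification maps use the node of
the subject's true label; regression maps keep positive gradient
components only (negative classification gradients are retained by
default; a positive-only switch exists). Zero input voxels therefore have
exactly zero attribution. For display, maps are smoothed (Gaussian σ = 2),
contrast-clipped at the 99th percentile and mean-projected along the
sagittal axis into the coronal view.

Region scoring mechanizes expert heatmap rating with two statistics over
the phantom's ground-truth depot masks:

- a binary **highlight call** — the region captures at least 10% of the
  attainable overlap with the map's top-5% attribution voxels, where
  attainable means `min(|top set|, |region|)`. Normalizing by the
  attainable overlap is deliberate: the visceral depots are under 1% of
  the grid, so demanding 10% of the raw top set would make a full-scoring
  small region impossible. The report is the fraction of maps highlighting
  each region;
- a graded **mean-attribution rank** — mean attribution per voxel inside
  each region, after normalizing each map to unit mean, averaged over
  maps. This is the statistic used to ask which region dominates a label's
  heatmaps, since binary calls can saturate on strongly localized signals.

## Clustering and outcomes

Embeddings are all-continuous, so the Gower distance reduces to the mean
of range-normalized absolute differences over the 128 dimensions, with
ranges taken on the clustered sample; the matrix is symmetric, zero on the
diagonal and bounded by [0, 1]. Partitioning around medoids runs classic
BUILD + SWAP (first-improvement sweeps; SWAP only accepts cost-decreasing
exchanges, so the objective is non-increasing, and on ≤ 12 points the
result matches exhaustive medoid enumeration). The cluster count is chosen
by maximal average silhouette width over k = 2..8; ties prefer smaller k.
Cluster robustness is the clusterwise bootstrap Jaccard index: each of B
(default 100; 50 in the pipeline default) resamples is re-clustered at the
selected k and each original cluster is matched to its maximum-Jaccard
counterpart on the unique resampled points. The pipeline clusters each sex
stratum independently and merges the reports; a switch disables the
stratification.

Outcome analysis uses lifelines: Kaplan–Meier curves per cluster for
incident diabetes and microalbuminuria, the multivariate log-rank test
(validated against a permutation reference in the tests), and Cox
proportional-hazards fits with cluster indicators plus adjustment
covariates (sex + age + BMI, baseline HbA1c, baseline uACR as supplied).
Scaled Schoenfeld-style residuals are emitted as a diagnostic artifact for
visual review, not auto-judged.

## Benchmarks

The conventional comparison uses exactly three inputs — total, visceral
and upper-extremity adipose volumes, read from the phantom ground-truth
masks at a fat threshold of 0.6 (midway between lean and fat intensity) —
fed to four families with standard defaults: logistic/linear regression,
5-nearest-neighbors, 200-tree random forests, RBF support-vector machines,
all behind a standardizing scaler. AUROC for the scarce-positive diabetes
and prediabetes labels is computed on pooled validation + test folds (the
network is scored the same way); regression uses the test fold.

## Known limitations

- Phantom anatomy is crude (ellipses, no organs); absolute performance
  numbers on phantoms say nothing quantitative about clinical scans.
- The NumPy engine is single-threaded matmul-bound; it is sized for the
  tiny profile, and building the full-scale model is supported but
  training it is not practical without hardware acceleration.
- Batch normalization uses running statistics for inference; very small
  training runs can leave those statistics noisy, which is visible as
  epoch-to-epoch validation jitter.
- The bootstrap Jaccard matching ignores cluster-size priors; with many
  tiny clusters the index is optimistic.
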