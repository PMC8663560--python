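# adiposcan

Deep-learning phenotyping of body-fat distribution from whole-body MRI,
rebuilt as a tested, reproducible pipeline on synthetic phantoms.

Type 2 diabetes is driven less by total fat mass than by *where* fat
accumulates: visceral depots in the deep abdomen promote insulin
resistance, while subcutaneous and thigh fat are comparatively inert.
Whole-body T1-weighted MRI renders adipose tissue bright and lean tissue
dim, so a 3D scan is a voxel map of an individual's fat distribution.
`adiposcan` implements the full analysis chain for asking whether diabetes
and related traits are detectable from such scans alone, for researchers
who want to study, extend or stress-test the method without access to a
clinical cohort:

1. **Synthetic cohort generation** (`adiposcan.synthgen`) — label-conditioned
   whole-body phantoms (stacked elliptical cross-sections, bright-fat /
   dark-lean contrast, 90–120 transverse slices) with a documented
   generative model coupling anatomical fat depots to metabolic labels:
   insulin sensitivity falls with lower-visceral and thigh fat load,
   glycemia rises as insulin sensitivity falls, and diabetes is diagnosed
   from glycemic thresholds (fasting glucose > 7.0 mmol/l, 2 h glucose
   ≥ 11.1 mmol/l, HbA1c ≥ 48 mmol/mol). Follow-up for incident diabetes and
   microalbuminuria (uACR ≥ 30 mg/g) is drawn from glycemia-dependent
   exponential hazards.
2. **Preprocessing** (`adiposcan.preprocess`) — vertical linear
   interpolation of variable-height scans to 95 slices, downsampling of the
   95×150×250 grid to 85×110×135 (full-scale profile), body-voxel
   standardization to mean 0 / SD 1 with truncation and a positive shift,
   isolation-forest outlier removal, min–max label normalization with
   per-head missing-label masking, and a stratified 70/15/15 split.
3. **Model** (`adiposcan.nn`) — a multi-task 3D DenseNet (growth factor 18,
   5×5×5 initial convolution, 3 dense blocks, FC widths 512/256/128,
   exponential-linear units, He initialization, Adam with a cyclic
   exponentially decaying learning rate) with softmax pairs for the four
   binary labels (sex and three diabetes definitions) and linear heads for
   age, BMI, insulin sensitivity and HbA1c. The 128-unit penultimate layer
   is the embedding. Forward and backward passes are implemented directly
   in NumPy, so input gradients are available exactly.
4. **Saliency** (`adiposcan.saliency`) — gradients×input attribution per
   output node (the node matching the true label for classification,
   positive gradients for regression), Gaussian/contrast postprocessing,
   coronal mean projections, and automated anatomical region scoring
   against the phantoms' ground-truth depot masks.
5. **Subphenotyping** (`adiposcan.cluster`) — partitioning around medoids
   with Gower distances on the embeddings, cluster count selected by
   average silhouette width, bootstrap Jaccard stability, and outcome
   analysis with Kaplan–Meier curves, log-rank tests and adjusted
   proportional-hazards models.
6. **Benchmarks** (`adiposcan.evaluate`) — conventional models (linear,
   k-nearest-neighbor, random forest, support-vector) on segmented fat
   compartment volumes (total, visceral, upper extremity), compared
   head-to-head with the network.

## Worked example

Train on a 300-phantom cohort in which diabetes-positive subjects carry an
elevated lower-visceral fat fraction (the `tiny` profile scales the voxel
grids to ~1/6 linear size so this runs in about two minutes on one CPU):

```python
from adiposcan.config import LabelModelConfig, PROFILES, RunConfig
from adiposcan.pipeline import prepare_cohort, train_signal_model

cfg = RunConfig(n_subjects=300, epochs=12, seed=11,
                label_model=LabelModelConfig(signal="volume"))
data = prepare_cohort(cfg, PROFILES["tiny"])
net, history, epoch, metrics = train_signal_model(data, cfg, PROFILES["tiny"])
print("selected epoch:", epoch)
for name, value in metrics.items():
    print(f"  {name}: {value:.3f}")
```

prints (held-out = pooled validation + test folds):

```
selected epoch: 9
  auroc_sex: 0.976
  auroc_diabetes: 0.919
  auroc_prediabetes: 0.636
  auroc_diabetes_ext: 0.700
  mae_age: 0.371
  mae_bmi: 0.198
  mae_insulin_sensitivity: 0.199
  mae_hba1c: 0.153
```

Sex is read from body morphology almost perfectly; the planted diabetes
signal is recovered at AUROC 0.92; the regression errors are on the
normalized [0, 1] label scale (multiply by the training-fold range for
absolute units). Attribution maps for the held-out diabetes-positive
subjects concentrate in the planted region — mean gradients×input
attribution per voxel, normalized within each map:

```
region mean attribution (diabetes maps):
  visceral_lower: 14.80
  visceral_upper: 13.23
  subcutaneous: 6.23
  thigh: 4.61
  breast: 4.10
  neck: 2.86
  arm: 1.97
```

Clustering embedding vectors drawn from the generator's default
four-subtype mixture selects four clusters by average silhouette width:

```python
from adiposcan.synthgen import generate_embedding_mixture
from adiposcan.cluster import gower_matrix, pam_silhouette

X, _ = generate_embedding_mixture(400, seed=1)
res = pam_silhouette(gower_matrix(X), range(2, 9), seed=0)
print(res.k)          # 4
print(res.silhouette) # {2: 0.335, 3: 0.453, 4: 0.611, 5: 0.432, ...}
```

The command line mirrors the library: `adiposcan run-all --profile tiny
--seed 0 --out runs/demo` executes simulate → preprocess → train → explain
→ cluster → evaluate and writes every report (metrics, benchmark
comparison, region report, cluster assignments, survival tables) plus a
manifest with the configuration hash and all stage seeds.

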