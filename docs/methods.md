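# Methods

## Problem and model

The package predicts an ordinal clinical outcome (mRS 0–4) for acute
ischemic stroke patients from six co-registered, skull-stripped MRI
parameter maps (ADC and five perfusion-derived maps: MTT, TTP, Tmax, CBV,
CBF). Cohorts in this setting are tiny and heavily imbalanced, so the
problem is treated as few-shot *similarity* learning rather than direct
classification: a twin (siamese) network scores whether two patients belong
to the same outcome grade, and a held-out patient inherits the grade of the
most similar training patient.

Assumptions inherited from the data regime:

* volumes of one case are mutually registered and skull-stripped; no
  bias-field correction or intensity standardization is applied (ADC and
  perfusion maps do not require it);
* the outcome is ordinal, which motivates reporting a macro-averaged
  absolute grade error alongside classification metrics;
* per-case resolution varies, hence the fixed resample to a common grid.

## Pipeline order

For each leave-one-case-out fold, with the held-out case excluded from
every step: (1) resize all volumes to the working grid and extract the
three middle axial slices per modality; (2) stage-1 balancing: augment each
minority class up to the largest class's count; (3) subtract the voxelwise
per-modality mean of the training slabs (originals + augmented) from the
training and the held-out slabs; (4) stage-2 balancing: build the pair set
and split it 7:3 (stratified by pair label) into training and validation
pairs; (5) train the twin network from scratch; (6) classify the held-out
case against the fold's original samples only.

## Key parameters

| Parameter | Default | Notes |
|---|---|---|
| working grid | 150×150×21 voxels | middle slices: depth indices ⌊D/2⌋−1 … ⌊D/2⌋+1 (9,10,11) |
| augmentation | rotation ±10°, zoom 0.9–1.1, translation ±10%, shear ±0.1, both flips | magnitudes are conventional mild settings; one draw per augmented sample, shared by all six maps |
| pair allocation | ⌊S/Z⌋ per label pair | S same-class pairs, Z = C(M,2) label pairs |
| optimizer | SGD, lr 10⁻⁴, momentum 0.9, batch 32 | ≤20 epochs; early stop when the train-loss decrease is ≤10⁻⁴, then `patience` (1) more epochs |
| init | dense weights ~ N(0, 0.01); batch-norm γ=1, β=0; conv He-normal | conv layers may instead load externally pretrained weights; nothing here downloads them |
| similarity | (1+cos)/2 with ε=10⁻⁸ in the denominator | zero-norm embedding → cosine 0 → similarity 0.5 |
| toy backbone | 2 conv blocks (8, 16 filters), same head | first block frozen, mirroring the frozen-backbone policy |

## Interpretations where the design was open

* **Normalization of the cosine** is fixed as s = (1+cos)/2: total,
  symmetric, and maps into [0, 1]. With ReLU embeddings cos ≥ 0 anyway, so
  the choice only matters for degenerate inputs.
* **The subtracted training mean is an image** (one value per voxel
  position and modality), not a scalar, and augmented samples contribute to
  it — they are training data in the fold.
* **Augmentation acts on the prepared 150×150×3 slabs** (in-plane 2-D
  transforms shared across the three slice-channels), not on the raw 3-D
  volumes; the network consumes slabs, and in-plane transforms are the
  standard choice for them.
* **Augmentation sources are cycled round-robin** over the class's
  originals in a seeded shuffled order, so every original contributes
  before any repeats.
* **Non-integer S/Z** floors, keeping the per-label-pair allocation exactly
  equal at the price of |DP| slightly below S. When ⌊S/Z⌋ = 0 (toy-sized
  sets) the dissimilar set is empty and a warning is raised.
* **Early stop** semantics: once an epoch's training-loss decrease is
  ≤ 10⁻⁴, training runs `patience` more epochs and halts.
* **Validation pairs** only monitor loss; early stopping watches the
  training loss.
* **Per-class AUC scores** are the maximum similarity to each class's
  original samples (one-vs-rest), the natural score function for a
  max-similarity classifier.
* **Zero denominators** in precision/recall/F1/MCC yield 0, which keeps
  every metric total and matches the reported zeros for never-predicted
  classes. Classes absent from the truth vector are dropped from MAE^M's
  average with a warning.
* **Singleton classes**: a fold whose held-out class has no remaining
  training exemplar still runs; its prediction is structurally wrong and is
  counted like any other fold.
* **Parameter accounting** counts batch-norm moving statistics as
  non-trainable and frozen-layer weights as non-trainable; a frozen layer
  is never registered with the optimizer, so its weights are bit-identical
  after training.

## Numerical engine

No deep-learning framework is used: the branches run on a small grouped
numpy engine (3×3 same-padding convolution via im2col, 2×2 max pooling,
batch normalization with momentum 0.99 and ε=10⁻³, dense layers,
backpropagation, momentum SGD) in float32. The six per-modality branches
are one grouped layer stack evaluated in batched BLAS calls.
Backpropagation stops at the first trainable layer, so frozen backbone
blocks cost only a forward pass. Similarities are clipped to
[10⁻⁷, 1−10⁻⁷] inside the cross-entropy. All randomness flows from
explicit seeds (per-fold sub-seeds are spawned from the run seed), so runs
are bit-reproducible; analytic gradients of the loss head are verified
against central finite differences in the test suite.

## Synthetic data

The generator emulates the *structure* of an acute-stroke cohort, not its
physics: each case is a "brain" ellipsoid with Gaussian intensity noise and
a single lesion ellipsoid shared by all six maps (mimicking
co-registration), scaled by a fixed signed per-modality contrast (ADC, CBV,
CBF drop in the lesion; MTT, TTP, Tmax rise). The lesion amplitude is
`effect_size × (1 + grade)`, monotone in the label so ordinal error is
meaningful. Defaults define the study conditions: class counts
(4, 18, 11, 7, 3) — a 43-case cohort with an 18-case majority and a 3-case
minority — volumes 64×64×21, effect 1.0, noise 0.2 (signal five times the
noise). Lesion centres jitter by ±12% of the volume (biased to the
mid-axial band so the middle slices see the lesion) and lesion axes by ±3%,
deliberately below the amplitude gap between adjacent grades so the class
signal, not lesion-volume variation, dominates.

What passing on this data does and does not show: it validates the
machinery — balancing, pairing, leakage-free folds, optimization, metrics —
and that the pipeline recovers a strong, label-monotone signal. It says
nothing about real perfusion physics, scanner variability, lesion
morphology, or the attainable accuracy on clinical cohorts.

## Problem sizes used in tests and the acceptance script

Desk-scale runs use the toy backbone (filters 4 and 8) on a 12×12×7 working
grid with 3 training epochs at lr 0.05 — chosen as the smallest
configuration in which training demonstrably separates same-class from
dissimilar-class pairs on separable data. The architecture checks always
build the full VGG16 branch at 150×150×3; nothing about the accounting is
scaled down. The full-fidelity configuration (vgg16 backbone, 150×150×21
grid, lr 10⁻⁴, 20 epochs) is available through the same interfaces
(`pmfesn evaluate --backbone vgg16`), but training it is a GPU-scale
undertaking and offers no pretrained initialization offline.

## Known limitations

* Random conv initialization is the offline default; results with
  externally pretrained backbone weights will differ.
* The similarity head saturates at 0.5 from below for dissimilar pairs
  (ReLU embeddings make cos ≥ 0), so the cross-entropy on dissimilar pairs
  is bounded away from 0; ranking, not calibration, drives the classifier.
* Per-class AUC is undefined (reported as missing) for classes lacking a
  positive or negative case.
* k-fold or bootstrap evaluation, hard-negative mining, intensity/elastic
  augmentation, and alternative similarity metrics are out of scope.
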