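# Methods

## Problem and model

`polypcad` implements a computer-aided-diagnosis pipeline that classifies
colorectal polyps in CT colonography subvolumes as benign (hyperplastic
polyp, regular mucosa, lipomatous polyp) or premalignant (tubular,
tubulovillous, villous and serrated adenoma, adenocarcinoma). Two model
variants exist: **noSEG** consumes a single-channel 50×50×50 HU image crop
around the polyp centre; **SEG** consumes a second channel holding the
binary expert segmentation mask. Each variant is a deep ensemble whose
output score is the unweighted arithmetic mean of its member networks'
logistic outputs (0 = benign, 1 = premalignant).

A member network is a compact 3-D residual CNN: three blocks with
(16, 32, 64) filters; each block runs two 3×3×3 convolutions on the main
branch (the first with stride 2) and a single-filter stride-2 3×3×3
convolution on the shortcut branch, whose one-channel output is broadcast-
added across the main branch's channels. Ceil-mode SAME padding yields the
spatial chain 50 → 25 → 13 → 7, which is asserted at build time. Global
average pooling over the final 7³ grid, dropout, and a fully connected
layer produce the logistic score. With unclear published wiring for the
"id" shortcut of the second convolution in each block, we use a single
residual addition per block; the printed output shapes constrain and
confirm this choice.

The network engine is written directly on numpy float32 arrays: patch
extraction (im2col/col2im) runs in numba kernels, the contractions in
BLAS, and the backward pass is hand-derived layer by layer. This keeps the
package self-contained on a CPU-only scientific Python stack; gradients
are validated against finite differences in the test suite.

## Training protocol

Each member is trained independently on its own random 80–20
train-validation split of the cohort (splits are drawn over segmentations;
a `groups` argument switches to patient-level grouping). Optimisation is
plain SGD on binary cross-entropy, learning rate 0.01, batch size 8.
Early stopping monitors the validation AUC: when it has not strictly
exceeded its running maximum for `patience_epochs` consecutive epochs,
training stops and the best epoch's weights are restored. Ties are treated
as "no improvement" (strict inequality).

Weights are initialised He-normal (fan-in) for the rectified convolution
stack — Glorot scaling left the pooled features two orders of magnitude
too small and stalled the head — with zero biases; the final linear layer
is Glorot-uniform. Training augmentation defaults to random 50³ cropping
from a 60³ context volume, the one augmentation the training protocol
states. A "full" mode adds per-axis flips and right-angle rotations; it is
opt-in because it destroys the fixed air-lumen/wall orientation of the
phantoms and measurably slows learning. Validation and test inputs are
only centre-cropped, never augmented.

Two parameter profiles bundle the defaults: **standard** (50 members,
patience 64, max 1000 epochs) and **desk** (5 members, patience 6,
max 50 epochs), the latter sized so the full pipeline runs in minutes on
one CPU. All randomness flows from named integer seeds (split seed,
initialisation seed, shuffle/augmentation/dropout streams) recorded per
member, so every training run is bit-reproducible.

## Synthetic phantoms

The phantom generator renders a schematic air-lumen / soft-tissue-wall
interface: lumen −1000 ± 30 HU, wall slab and polyp 40 ± 20 HU (mean ±
noise SD), with one sessile polyp protruding from the wall. The polyp
surface is a star-shaped radius field r(v) = r₀(1 + λ·s(v)), where s is a
normalized sum of random angular bumps and λ the lobulation amplitude as a
fraction of the radius. The radius field is rescaled so the maximal
antipodal chord equals the requested diameter (plus a half-voxel
compensation for voxel-centre measurement), keeping the mask-derived
maximum 3-D diameter within the intended size strata after half-up
rounding. Premalignant lesions add separability-scaled lobulation
(+0.30·s per unit separability) and intra-lesional texture, a Gaussian
random field (correlation length ≈ 1.5 voxels) scaled to +55·s HU.
At separability 0 the two class-conditional distributions are identical by
construction; at separability 1 the in-mask HU standard deviation — a
trivial mask-aware feature — separates the classes with AUC ≈ 1.

Cohorts emulate the screening-study bookkeeping: one to three polyps per
patient, each lesion rendered in supine and prone positions that share
shape parameters but draw independent noise and a random 90°-multiple
in-plane rotation, class counts matching the requested prevalence within
rounding, and sizes drawn from the ≤5 / 6–9 / ≥10 mm strata. Volumes and
masks are written as NIfTI with spacing in the header, the manifest as
CSV. The phantoms deliberately omit haustral folds, tagging residue,
scanner physics and anatomy; passing tests demonstrate that the pipeline's
machinery works end-to-end, not that it would reach any particular
performance on clinical data.

## Scaled-down validation experiments

The desk-scale experiments use 5-member ensembles trained for at most 50
epochs. The test suite's recovery experiment simulates ≈110 training and
≈65 test segmentations (30 / 15 patients); `scripts/acceptance.py` uses
≈100 / ≈50 (25 / 13 patients) to keep a full from-scratch rerun of both
model variants within minutes; the null control re-simulates smaller
training cohorts (8 patients) over three seeds with a full-size test
cohort.

The **recovery** experiment (separability 1.0) and the **null control**
(separability 0.0, expected test AUC ≈ 0.5) use single-stratum cohorts
(`size_mix = (0, 1, 0)`, 6–9 mm). The reason is an instrument-design one:
polyp size is class-balanced by construction, so at this cohort size the
3–15 mm diameter spread is pure nuisance variance for the
global-average-pooled features — linear probes on untrained-network
embeddings show the class signal is invisible in mixed-size cohorts
(AUC ≈ 0.6) yet clearly present when size is held fixed (AUC ≈ 0.85), at
identical class-contrast settings. The generator's own calibration
feature (in-mask HU standard deviation) is itself size-invariant, so the
size-controlled cohort tests the same signal the generator calibrates.
Full-size-mix cohorts remain the generator default everywhere else.

## Grad-CAM++ explanations

Class-activation volumes are computed at the final convolutional stage
(the third residual addition, 7³×64). Because the head is global average
pooling plus a linear unit, the gradient of the pre-logistic score with
respect to a feature voxel in channel k is the constant w_k/343, and the
Grad-CAM++ α weights take a closed form under the usual exp-score lift;
the exp factor cancels under the final max-normalization. The rectified
weighted feature sum is upsampled trilinearly to 50³ and normalized by its
maximum, all-zero maps staying all-zero, so activations lie in [0, 1].
Ensemble maps average the per-member normalized maps and re-normalize.
The coverage statistic is the fraction of segmentation-mask voxels with
activation ≥ 0.25 (threshold inclusive); the published normalization and
upsampling details are unstated, so these are recorded package choices and
reported mean-coverage figures from clinical data are not comparison targets.

## Evaluation protocol

AUC is the Mann-Whitney statistic with ties counted half (equal to
trapezoidal ROC integration; verified against an all-pairs oracle to
1e−12). The operating threshold is chosen among midpoints of adjacent
distinct scores plus sentinels to maximise specificity subject to
sensitivity ≥ 80 %, ties resolved toward the larger threshold, prediction
rule score ≥ threshold ⇒ premalignant. By default the threshold is fitted
on the scores being evaluated (the replication mode of the study, which
selected its threshold on the test set); a pre-fitted threshold can be
supplied instead. Percentages are rounded half-up to whole percent,
the standard convention for reported fraction/percent pairs. Size subgroups use the
mask-derived maximum 3-D diameter (boundary-voxel computation, identical
to all-pairs) rounded half-up and binned ≤5 / 6–9 / ≥10 mm.

## Numerical and degenerate-input choices

* HU normalization: clip to [−1000, 400], map affinely to [0, 1], applied
  exactly once (flagged on `ModelInput`).
* Crops are half-open windows [c−25, c+25) with no implicit padding;
  out-of-bounds crops raise.
* Empty masks raise for diameter and coverage; single-class label vectors
  raise for AUC and threshold selection before any training starts.
* All-zero heat maps normalize to all-zero (0/0 := 0); Grad-CAM++ α is set
  to 0 where its denominator vanishes.
* float32 throughout the network; BCE uses the softplus form for
  stability; the sigmoid is evaluated piecewise to avoid overflow.

## Known limitations

* Clinical-data performance requires the original screening cohorts and
  trained weights, which are not redistributable; nothing here estimates
  it.
* Learning-rate 0.01 with plain SGD learns the image-only (noSEG) phantom
  task only marginally at desk scale: individual members oscillate between
  chance and AUC ≈ 0.8 across epochs, and best-validation-epoch selection
  on a ~20-segmentation validation side is noisy, so small noSEG ensembles
  remain well below the mask-assisted SEG ensemble on the same cohort, as
  expected when the mask channel supplies localization for free. The desk
  profile demonstrates the machinery, not the full-scale protocol's
  performance (50 members, patience 64).
* The numpy/numba engine is single-threaded and tuned for batch 8 at 50³;
  it is not a general-purpose deep-learning library.
* Patient-level split grouping is available but not the default, matching
  the per-segmentation accounting of the study design.
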