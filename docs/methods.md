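# Methods

`histoadapt` implements unsupervised domain adaptation for patch-based
classification of H&E-stained whole-slide images (WSIs): a labeled *source*
domain trains a convolutional patch classifier; an unlabeled *target*
domain — same tissue classes, different staining and morphology — is
classified either after stain-normalizing its patches to source references,
or after adversarially fine-tuning a copy of the network on target data.
Everything is exercised end-to-end on a bundled synthetic H&E generator
that provides exact ground truth.

## Color model and stain normalization

Pixels follow the Beer–Lambert law in base-10 optical density (OD):
`I_ch = I0_ch · 10^(−(S c)_ch)`, with `S ∈ R^{3×2}` the stain matrix (unit
columns: hematoxylin, eosin) and `c ≥ 0` the per-pixel stain
concentrations. `rgb_to_od` floors pixel values at 1, so the round trip
`od_to_rgb(rgb_to_od(x)) = x` is bit-exact for all pixel values ≥ 1;
value 0 is not invertible under this convention and maps back to 1.

Two estimators invert the model from pixels alone:

* **Macenko (geometric).** Pixels with OD norm above β = 0.15 are
  projected onto the two leading principal directions of their covariance;
  the stain vectors are the directions at the α = 1 and 100−α percentiles
  of the polar angle, rectified and renormalized. β and α follow the
  convention of the original geometric method; the degenerate (rank-1)
  cloud of a single-stain image is rejected via an eigenvalue-ratio test
  (λ2/λ1 < 1e-4).
* **SPCN (sparse NMF).** `||OD − S C||_F² + λ||C||_1` (λ = 0.1) is
  minimized by alternating multiplicative updates with unit column norms
  re-imposed on `S` each iteration; deterministic given the init seed.
  Failure to reach a relative objective decrease below 1e-3 sets a
  `converged=False` flag rather than raising, since downstream inference
  must still produce a prediction.

Normalizing a patch to a reference re-expresses its concentrations in the
reference's stain basis after matching robust per-stain scales (99th
percentile of nonnegative concentrations, floored at 1e-6). The white
point is fixed at I0 = 255 per channel unless configured otherwise.

Stain ordering is canonicalized by the blue-channel coefficient
(hematoxylin column has the larger one); ties in split assignment,
majority votes, and all stochastic steps are governed by explicit seeds.

## Patch pipeline

Slides enter as plain rasters and are tiled on a regular grid (0-based,
half-open coordinates). A patch is kept when at least half its pixels are
tissue, where tissue means luminance below 0.8 of white — a fixed cut that
is deterministic and adequate for synthetic data (Otsu thresholding would
be the natural swap-in for real slides). Splits are assigned per patient
(80% train / 20% test, with 10% of training patients as validation), so no
patient spans the train/test divide; a reshuffle loop (max 100 tries)
enforces that both classes appear on the training side, and in the test
side when it holds at least two patients.

## Networks

The classifier is fully convolutional: six conv stages, each followed by
batch normalization and ReLU, dropout 0.5 after stages 5 and 6, then a 1×1
prediction convolution whose spatial maps are averaged into class scores
(global average pooling — the pooling operator is our choice; parameter
count is therefore independent of input size). The pooled stage-6
activations are the 64-dimensional (tiny preset) feature vector consumed
by the classifier head, the domain discriminator, and the Siamese head.
The `tiny` preset (16/32/32/32/32 channels, 64-channel stage 6) targets
CPU-scale experiments; a `full_scale` preset with AlexNet-like widths
(96/256/384/384/256, 4096) exists for completeness but is not exercised by
the test suite. Exact widths are a design choice: the architecture
constraints (structure, dropout placement, no fully connected layers in
the classifier) are fixed, the sizes are not.

The discriminator is three fully connected stages (500/500 hidden units,
BN+ReLU after the first two) ending in a logistic domain probability. The
Siamese head concatenates the pooled features of two weight-sharing
branches and applies a single linear stage with a sigmoid. The head is
**zero-initialized**: a random head injects noise-scale gradients into the
shared backbone long before it can learn anything at the fixed adaptation
learning rate, which measurably hurt the ablation comparison; with zero
weights the head starts exactly uninformative (probability 0.5 for every
pair, zero gradient into the backbone) and its influence grows only as it
learns real same-WSI structure. At evaluation the pair score is averaged
over both input orders.

All layers are implemented in a small numpy layer library
(`histoadapt.nn`) with explicit backward passes (im2col convolutions,
train/eval-mode batch-norm backward, inverted dropout) and SGD-momentum /
Adam optimizers. Gradient correctness is pinned by a float64 directional
finite-difference test at 1e-6 relative tolerance.

## Training

**Stage 1 (source).** Mini-batch SGD, momentum 0.9, weight decay 5e-4
(weights only), initial learning rate 1e-3 annealed ×0.1 every
⌈epochs/3⌉ epochs. Training patches are resized then randomly cropped
(the 256→224 ratio is preserved at every scale; horizontal flipping is
available but off by default); validation and test use a single center
crop. The best-validation checkpoint is returned.

**Stage 2 (adaptation).** The source network is frozen (its parameter
hash is asserted unchanged). A copy becomes the target network; Adam at a
fixed 1e-5 learning rate trains it together with the discriminator. Each
iteration: (i) the discriminator is updated on
`LadvD = −E_s log D(f_s) − E_t log(1−D(f_t))`; (ii) gradients of
`LadvM = −E_t log D(f_t)` (inverted domain label) flow into the target
backbone; (iii) gradients of the Siamese binary cross-entropy `Ls` on a
pair batch (half same-WSI, half cross-WSI, WSIs drawn uniformly) are added,
and one Adam step applies the summed update — the joint objective
`Lt = La + Ls`. Applying (ii) and (iii) as two separate Adam steps replays
momentum into the backbone twice per iteration and was rejected for
distorting the La-vs-Lt ablation. Probabilities are clamped to
[1e-7, 1−1e-7] before logarithms; any non-finite loss aborts with a state
dump. Source batches come from the source training split; target batch
normalization statistics keep updating during adaptation, which is itself
a significant part of how the network adapts to a stain shift.

Adaptation uses four independent seeded random streams (batch sampling,
pair sampling, and the dropout of each path), so ablations that disable
one loss leave the remaining randomness untouched — a common-random-
numbers design that makes the paired La-vs-Lt comparison meaningful at
small scale.

## Inference and evaluation

The stain-normalization route samples N_l reference patches uniformly
without replacement from the source training split (failures are
resampled and logged), normalizes each target patch to every reference,
and averages the resulting logits with equal weights before the softmax;
patches whose every normalization fails fall back to the raw patch so the
majority vote always has a full complement of votes. WSI labels are the
majority over patch predictions, ties broken toward the class favored by
the mean high-grade probability. Paired classifier comparisons use the
exact conditional McNemar test (binomial on the discordant counts, two-
sided, capped at 1; mid-p available), which is valid at any discordant
count and exhaustively checkable.

## Synthetic data

Each domain is a `SyntheticDomainSpec`: stain vectors given as two angles
in a fixed nonnegative 2-plane of OD space (defaults 50°/10°; valid cone
roughly 0–66°); per-stain maximum concentrations (1.0/0.6 OD); background
intensity 255; Gaussian pixel noise (sd 2 by default, 0 for estimation
oracles); per-class blob-process textures; and a per-WSI truncated-normal
density multiplier (sd 0.15) that correlates patches within a WSI.
Hematoxylin is a Poisson process of Gaussian nuclear blobs (defaults: 2
vs 8 blobs per 1e3 px² for low vs high grade, mean radius 3 px); eosin is
a smooth low-frequency cytoplasm field suppressed where nuclei are dense
(nuclei displace cytoplasm — this also guarantees near-pure stain pixels,
without which geometric stain estimation is ill-posed); lumen discs carve
near-white holes. Generation is bit-reproducible from a seed via spawned
`SeedSequence` streams.

The generator emulates exactly the three structures the methods exploit —
recoverable stain geometry, class-separable texture, within-WSI
correlation. It does not emulate scanner optics, compression artifacts,
pen marks, tissue folds, multi-resolution pyramids, or the morphological
richness of real glands; passing tests therefore demonstrate the
correctness and qualitative behavior of the algorithms, not clinical
performance.

## Scaled study conditions

Tests and the acceptance script run a desk-scale study: 64×64 patches,
tiny preset, 10 WSIs per class × 12 patches per domain, 10 training
epochs at batch 16, and 500 adaptation iterations at batch 16 (the config
defaults keep the full-scale values: batch 128, 2000 iterations). The
target domain differs from the source by a 15° stain rotation plus a
reduced class-texture contrast (densities 3.5/6.5 instead of 2/8). Under
these conditions the source net reaches ≥90% validation accuracy, the
adapted target net beats the source-only baseline (medians over 3 seeds),
ensembling 10 references shrinks the across-draw accuracy sd relative to
a single reference, and a held-out logistic probe shows source/target
feature separability falling toward chance after adaptation. At this
scale and the fixed 1e-5 learning rate the Siamese term is a weak
regularizer: the head learns slowly, so the full objective tracks the
adversarial-only ablation closely rather than clearly exceeding it.

## Known limitations

* Two stains only; no GAN-based normalization.
* The reference-selection problem (which source image to normalize to) is
  deliberately exposed as explicit seeding rather than a heuristic.
* The `full_scale` preset is untrained here; no pretrained weights ship.
* Whether target class predictions during adaptation should flow through
  the retained classifier head or be influenced by the Siamese head only
  via shared features is ambiguous; we retain the copied classifier for
  predictions and treat the Siamese head as auxiliary.
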