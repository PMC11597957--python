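# Methods

## Model and procedure

The core object is a pair of convolutional encoders f_q (query) and f_k
(key) with identical architecture, mapping an RGB image to a unit vector in
R^128. Training iterates over two-view minibatches: each image is augmented
twice (random resized crop → horizontal flip p=0.5 → color jitter with
brightness/contrast/saturation 0.4 and hue 0.1 applied as a block with
p=0.8 → per-channel normalization, in that fixed order, normalization
exactly once and last). View A passes through f_q, view B through f_k
without gradients. The per-example loss is the temperature-scaled
(1+K)-way softmax cross-entropy with the positive key as target index 0;
the K negatives are the current contents of a FIFO feature queue. After
each step: SGD (momentum 0.9, weight decay 1e-4, cosine-annealed learning
rate over the epoch budget) updates f_q only; f_k is updated as
θ_k ← m·θ_k + (1−m)·θ_q; the batch of keys replaces the oldest queue rows
(ring buffer, pointer advances modulo queue size). Per-example losses are
averaged over the batch so learning-rate semantics are batch-size
independent.

The key encoder is initialized as an exact copy of the query encoder. The
queue is initialized with seeded random unit vectors and then *warm-filled*
with key-encoder features of augmented training images before epoch 1.
Without warm-filling, the first epoch competes against random negatives,
which makes its loss artificially close to zero and the loss curve
non-monotone by construction; with realistic negatives from the start, the
loss decays from epoch 1 as training proceeds.

### Encoders

ResNet18/34 use the CIFAR recipe: the 7×7 stride-2 stem convolution is
replaced by 3×3 stride-1 (padding 1) and the stem max pool is removed,
appropriate for the 96-px-and-below working resolutions. Every batch norm
is a split batch norm: in training mode the batch is partitioned into
`num_bn_splits` (default 8) contiguous groups, each normalized with its own
statistics under shared affine parameters — emulating per-device statistics
of multi-GPU training on one device; running statistics are the arithmetic
mean over split statistics and drive the eval path, so `num_splits=1` *is*
standard batch norm. Encoder outputs are L2 normalized (required for the
cosine-similarity queue and KNN machinery). For ResNet18/34 the head is a
single linear 512w/64 → 128 map; the 2048→2048→ReLU→128 projection head is
used by the SimCLR path on top of a ResNet50-style backbone whose first
convolution is 3×3 stride 1 *without* padding (that variant's stated stem
modification, applied only there).

A `width` parameter scales all channel counts (default 64, the standard
recipe). Desk-scale runs in the tests and acceptance script use width 16,
chosen so a full 40-epoch study runs in minutes on one CPU; the
architecture, recipe and all contracts are width-independent.

### KNN monitor

The memory bank holds eval-transformed train-split features from the query
encoder (eval transform: deterministic resize + normalization). Each test
embedding takes its k = 200 most cosine-similar bank rows (k clamped to the
bank size), weights them w_i = exp(sim_i / 0.1), sums the weights per class
and predicts the argmax; scores are normalized to probabilities for
reporting, which leaves the argmax unchanged. Tie-breaks are deterministic:
equal similarities resolve to the lower bank index (stable sort), equal
class scores to the smaller class index. The monitor runs after every
epoch; accuracy is the percentage of test items whose vote matches the
label.

### SimCLR variant

A single encoder + projection head, in-batch NT-Xent loss (every anchor's
positive is its paired view, negatives are the remaining 2B−2 rows, τ =
0.5), LARS optimizer (trust coefficient 0.001; bias and batch-norm
parameters excluded from adaptation and weight decay, both flag-
controlled), linear warmup over 10 epochs to the base learning rate 0.2
then cosine annealing, weight decay 1e-6, 32-px inputs. No downstream
classifier is trained on this path; features are exported to 2-d with
seeded t-SNE (perplexity 50, requiring N > 3·perplexity).

### Supervised baseline

A ResNet whose final layer is replaced by a `num_classes` output, Adam at
lr 1e-3, cross-entropy, batch 32, 20 epochs, stratified 80/20 split,
rotation ±10° / flip / resize-224 / center-crop / ImageNet-normalization
transforms. The single held-out 20% serves as both validation and test
(the monitoring and the reported accuracy use the same split); the
best-held-out-accuracy epoch's parameters are retained. Pretrained
ImageNet weights are supported only through a local `.npz` weights file
(`weights_path`); the default is seeded random initialization so every run
is self-contained and offline.

## Synthetic data generator

The generator emulates the statistical structure of a withheld, balanced,
class-per-folder animal-emotion corpus: `n_classes` (default 7, then named
after Panksepp's systems) × `n_per_class` (default 300) PNG images of
`image_size`² px (default 96). Each class owns a generative rule — a body
ellipse at a class-specific orientation, an "ear" triangle at a
class-specific rim position, and a class hue band — degraded by
`signal_strength` ∈ [0,1] (1 = fully deterministic class features, 0 = class
features uniformly random). `nuisance_strength` scales label-independent
variation: low-frequency background texture, global brightness jitter and
pixel noise; small geometric jitter is always present. Balanced classes
make uniform-guessing accuracy exactly 100/k %. Every image's RNG derives
from (seed, class, index), so datasets are byte-identical across runs.

Defaults for the desk-scale study: signal 0.9, nuisance 0.3 — strong but
not perfect class signal, the regime in which contrastive learning has
something to learn and something to ignore.

What the generator does *not* emulate: pose articulation, breed/identity
variation, occlusion, viewpoint and camera statistics of real photographs.
Consequently, class evidence here is far more linearly accessible than in
real data — an *untrained* random-weight encoder already scores well above
chance through the KNN monitor, because mean-color statistics survive
random convolutions. Passing tests therefore demonstrate that the training
machinery is correct and that contrastive pretraining adds a large margin
over the untrained control — not that any particular accuracy would be
reached on real animal images.

## Numerical choices

- All network computation is float32; losses and KNN votes are accumulated
  in float64. Cross-entropies use max-shifted log-sum-exp.
- Batch-norm normalization uses biased variance in both train and eval
  paths; running statistics update with momentum 0.1.
- Batches are dropped when smaller than the batch size (and any batch not
  divisible by the split count is skipped), since split batch norm requires
  equal groups; training batch sizes must be divisible by `num_bn_splits`.
- Queue size default 4096; desk-scale runs use 256 (order of the training
  set size) so the negative pool turns over every few steps.
- EMA updates touch parameters only; the key encoder's batch-norm running
  statistics evolve from its own forward passes.
- L2 normalization guards the zero vector with an epsilon of 1e-12;
  LARS guards zero weight/gradient norms by falling back to ratio 1.
- t-SNE, classification metrics (precision/recall/F1/support) and the
  estimator bases come from scikit-learn; everything else is implemented
  in-package.

## Design choices where the design was open

- Memory-bank features come from the query encoder: it is the deliverable
  artifact, and the monitor should measure it.
- Normalization statistics are the ImageNet values on every path (a single
  convention across supervised and contrastive pipelines).
- Crop scale defaults to (0.2, 1.0), the conventional contrastive range;
  exposed in `AugmentationConfig`.
- No learning-rate warmup for the momentum-contrast path (warmup belongs to
  the SimCLR recipe only).
- Split batch norm stands in for any key-batch shuffling; no shuffling is
  performed.
- The loss over the queue is the default; an in-batch NT-Xent option
  (`loss="inbatch"`, gradients through the query rows only) allows the
  comparison between the two formulations.
- Class indices are 0-based in lexicographic folder order; generated
  datasets also write a manifest CSV recording the mapping.

## Problem sizes

The test suite and the acceptance script run the full pipeline at desk
scale: 7 classes × 60 images at 32 px, width-16 ResNet18, batch 64, queue
256, 40 epochs for the contrastive run and 12 epochs for the matched
supervised baseline — sizes chosen so the complete study executes in
minutes on a single CPU while still exhibiting the qualitative phenomena of
interest (loss decay, monitor lift over the untrained control, supervised ≥
unsupervised ordering).

## Known limitations

- The numpy engine is single-device and eager; wall-clock cost limits desk
  runs to narrow encoders and small images. Full-width, 96-px, thousands-of-
  epochs training of the kind the method targets on GPUs is out of reach of
  the bundled engine.
- The synthetic benchmark's easiness compresses the dynamic range between
  methods near the top of the accuracy scale (both routes can saturate at
  100%).
- Eval-mode batch-norm backward returns input gradients only (sufficient
  for frozen-feature use; parameter gradients are defined only in training
  mode).
- `pretrained=True` without a local weights file is an error by design; no
  weights are bundled or downloaded.
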