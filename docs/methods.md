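# Methods

This note records the scientific and numerical choices behind the package:
what the model computes, what the synthetic data does and does not emulate,
and where the design was genuinely open.

## Model

The classifier maps an RGB frame to two logits (smoke, smoke-free) through
four stages.

**Convolutional tokenization.** The stem is conv3×3 stride 2 → GELU →
maxpool3×3 stride 2 → residual block (conv–GELU–conv plus shortcut) → one or
more conv3×3 stride 2 layers, flattened into an N×C token sequence with a
learnable, zero-initialized positional table. The operator order is fixed;
widths and total stride are configuration. The default preset has total
stride 8 and width C (64 in the small models); a ViT-B/16-compatible preset
(stride 16, 768 channels, class token on) exists for the 197×768 sequence
convention. Stem convolutions use replicate (edge) padding so a spatially
constant frame yields identical tokens everywhere — a useful diagnostic
invariant that zero padding would break at borders. GELU is the exact form
x·Φ(x) (scipy's normal CDF), not the tanh approximation.

**Encoder.** L MetaFormer blocks at a single grid resolution (no pyramid
stages; only the block count L is prescribed by the training protocol, and a
single-resolution stack is the simplest structure consistent with it). Per
block: the token sequence is reshaped to a channel-first grid (the
token/channel dimension interchange), mixed, reshaped back, then passed
through the channel MLP residual `z = y + W2·GELU(W1·LN(y))` with expansion
ratio 4.

**Token mixer.** Parallel depthwise convolutions with "same" zero padding —
7×7 (the large-kernel ConvNeXt ingredient) and 3×3 — each followed by its
own batch normalization, plus an identity branch. Two structural decisions
here were open and are worth recording:

- *The identity branch is the mixer's residual path.* Writing the block as
  `y = x + mixer(x)` **and** giving the mixer an internal identity branch
  would add the input twice and destroy the residual-identity property
  (zero weights ⇒ identity map). In the RepVGG family the identity branch
  *is* the shortcut, and that is the reading implemented: with the identity
  branch enabled (default) the mixer output is the block's mixer half;
  an explicit `x +` is added only when the identity branch is disabled.
- *Branch normalization is batch-norm, not layer-norm.* Single-path fusion
  requires a normalization that is an affine per-channel map with frozen
  statistics at inference; batch norm folds into the convolution, layer
  norm does not. LayerNorm is kept only before the MLP, where nothing is
  fused. The identity branch carries no normalization, so the
  "identity-normalization ⇒ pass-through" limit is exact.

Token mixing is depthwise-only; all cross-channel mixing lives in the MLP,
matching both pooling-based mixers (channel-independent) and ConvNeXt's
depthwise stage. A class token, when configured, bypasses the mixer and
participates in the MLP; the default path has no class token.

**Re-parameterization.** For each branch, `k' = k·γ/√(σ²+ε)` and
`b' = β − μ·γ/√(σ²+ε)` folds the frozen batch norm into the kernel; smaller
kernels are zero-embedded centred in the 7×7 frame; the identity branch
contributes a centred Dirac kernel; kernels and biases sum. Fusion is done
in float64 and cast to float32 once. The equivalence contract is ≤1e-5 per
block and ≤1e-4 on whole-model logits in float32 — exact equality is
impossible in floating point, and these bounds reflect rounding accumulated
over reordered sums and L blocks at O(1) activation scale. Fusion is exposed
as an in-memory transform (`deploy_model`, which refuses models whose
normalization statistics are not frozen, i.e. still in training mode) and as
a checkpoint-to-checkpoint CLI (`fuse`); fused checkpoints carry a topology
tag and re-fusing is refused, while fusing an already-fused mixer is the
identity. The single-path memory argument (no second activation buffer held
for the shortcut add) is documented here but not asserted by tests, being
allocator-dependent.

**Head.** Sequence pooling: a learned scalar score per token,
softmax-normalized over the sequence, weights a token average; the pooled
feature passes through a linear 2-class layer (an optional one-hidden-layer
head exists behind a config flag; the linear head is the default as the
more specific reading of the architecture). Softmax over two logits rather
than a single sigmoid unit keeps the TP/FP/FN/TN bookkeeping symmetric.

## NumPy implementation

No deep-learning framework is used: every layer (conv via im2col, depthwise
conv, max pooling, batch/layer norm, GELU, linear, sequence pooling)
implements an explicit backward pass on float32 arrays, and AdamW (decoupled
weight decay on ≥2-D parameters only) performs the updates. The correctness
contract for all of this is `tests/test_layers.py`, which checks every
analytic gradient against central finite differences. Determinism: all
randomness flows through `numpy.random.Generator` seeded from explicit
integers; a model seed fixes its initialization bit-for-bit, and repeated
forward passes are bit-stable on one host.

## Synthetic data

The generator emulates the *statistical structure* of an
endoscopy-with-rendered-smoke corpus, not its pixel content:

- **Base frames**: red-dominant (mean R > mean B by construction),
  low-texture multi-octave value noise in each channel, a radial vignette,
  and 0–3 Gaussian specular highlights emulating wet-tissue glints.
- **Smoke plumes**: strictly positive fractal noise times a Gaussian
  envelope centred at the plume position. The envelope is floored at
  exp(−1.5²/2) and rescaled, so the plume has compact support of radius
  1.5σ with σ = (0.08 + 0.30·density)·min(H, W): support area is strictly
  monotone in density (nested disks) until the disk leaves the frame, and
  the peak is linear — hence strictly monotone — in intensity. Intensity 1
  corresponds to a peak additive luminance of 230 before noise modulation.
- **Compositing**: scalar per-pixel addition of the plume luminance to all
  three channels (the luminance reading of additive smoke), clipped to
  [0, 255]; clipping rather than rescaling because addition models a
  saturating sensor. Pixels outside the plume support are bit-identical to
  the base frame.
- **Sampling ranges**: intensity U[0.3, 1.0], density U[0.3, 0.9], position
  uniform with a 15 % border margin. The lower bounds keep every
  smoke-labelled image visibly smoky, so the labels are learnable at small
  scale; the true parameter distributions of renderer-based corpora are not
  published, and these ranges are declared, not inferred.

Not emulated: physically based scattering, smoke color casts, temporal
coherence across frames, camera noise, real tissue anatomy. Passing tests
therefore demonstrate that the architecture, training loop and fusion are
correct and that the synthetic task is learnable — not that the model
reaches any particular accuracy on real endoscopic video.

Dataset construction is exact: the configuration must yield integer
per-(split, label) counts (e.g. 5,000 total, smoke fraction 1/5, test
fraction 0.24 → 3,800/1,200 split with 760/240 smoke), otherwise it is
rejected with an explanatory error. Builds are byte-for-byte reproducible
from the seed, including the PNGs.

## Training and evaluation

Bilinear resize to the square input size, channels scaled to [0, 1]; random
horizontal flip (p = 0.5) in training; cross-entropy; AdamW at initial lr
0.001 with exponential decay (default factor 0.9 per epoch, the factor
itself being configurable since only "exponential decay from 0.001" is
prescribed); batch size 32. Cross-validation uses stratified, seeded k-fold
splits of the train split for variance reporting; the final reported model
is trained on the full train split — how a cross-validated protocol maps to
a single test metric was open, and this is the convention adopted. The
optimizer (AdamW) and batch size were likewise unprescribed defaults.

Evaluation accumulates TP/FP/FN/TN with smoke as the positive class;
accuracy and sensitivity are recomputed from the stored counts (never
cached separately), so the two can never disagree. Sensitivity is NaN with
a warning when the evaluated set has no positives. Evaluation is invariant
to example order and batch size, and fused-topology evaluation yields
identical counts to the multi-branch topology (a corollary of the fusion
contract, asserted directly in the tests). Throughput is a median of
repeated wall-clock passes after warm-up, reported for information only.

## Problem sizes used in tests and the acceptance script

The reference protocol (224×224, L = 10, 50 epochs, 10-fold CV on 3,800
training images) is implemented and exposed (`TrainConfig.reference_protocol()`),
but the packaged experiments run a reduced instance chosen as this
package's standard small-scale configuration: 64×64 frames, 500 images
(400 train / 100 test at the same 4:1 ratio), L = 2, width 64, 10 epochs,
single CPU. On this task the model reaches ≥0.95 test accuracy in at least
4 of 5 seeds (typically 1.00 on most seeds), which is the package's
property-based stand-in for external-data benchmark numbers: those depend
on a non-redistributable corpus, GPU-scale training and specific hardware,
and are out of scope here.

## Known limitations

- Positional embeddings are tied to one input size per model; no
  interpolation across sizes at inference.
- The renderer is procedural, not physical; see the non-emulated list.
- Single-resolution encoder only; no pyramid/multi-stage variants, no
  attention mixers, no comparison architectures.
- CPU-only NumPy execution: throughput numbers are orders of magnitude
  below GPU framework implementations and are never treated as results.
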