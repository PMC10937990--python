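# Methods

## The model

`cmixup` implements curriculum-scheduled Mixup inside a SimSiam-style siamese
self-supervised learner, plus the supervised fine-tuning and multi-class
evaluation that measure what the pretraining bought.

**Siamese objective.** Two stochastic augmentations x_i, x_j of one source
image pass through a shared encoder-plus-projector f and a predictor h,
giving projections z = f(x) and predictions p = h(z). The loss is the
symmetrized negative cosine similarity with a stop-gradient on each
projection:

    L = −½ · [ cos(p_1, sg(z_2)) + cos(p_2, sg(z_1)) ]

No negative pairs, no momentum encoder; the stop-gradient is the mechanism
that prevents the constant-embedding collapse.

**Mixed positive view.** The second view is replaced by a convex combination
with the anchor:

    x̃_j = λ·x_i + (1 − λ)·x_j,      λ ∈ [0, 0.5]

and the loss becomes L = −½·[cos(p_i, sg(z̃_j)) + cos(p̃_j, sg(z_i))]. At
λ = 0 this reduces — exactly, end-to-end — to the plain siamese objective;
the identity is asserted in the tests at the image level. Large λ makes the
positive resemble the anchor (an easy prediction target), small λ restores
the fully independent view (hard).

**Curriculum.** λ is drawn per batch from Beta(α_t, α_t), and the
concentration α_t — not λ itself — follows a monotone non-increasing
schedule from `alpha_max` (default 0.2) to `alpha_min` (default 1e-4) over
the training horizon. Because Beta(α, α) with α < 1 is U-shaped, half of the
raw draws would exceed ½ and make the anchor the majority ingredient of its
own "positive"; a hard cap λ ← min(raw, 0.5) guarantees the second view
always contributes at least half. As α_t → 0 the capped draws collapse onto
{0}, so the end of training is statistically the plain-Mixup/vanilla-siamese
regime. Four schedulers are provided (`step` with `step_size` equal
intervals — the default, with 8 intervals —, `linear`, `cosine_anneal`,
`constant`); all satisfy α(0) = alpha_max, α(T) = alpha_min, monotone
non-increasing. The published closed form of the step schedule is
internally inconsistent with its stated limits (it reaches 0 rather than
the lower bound at the end of training); we implement the piecewise-constant
decay that the stated limits describe:
α_t = alpha_max − (alpha_max − alpha_min)·⌊i·S/T⌋/S, clamped to the bounds.

**Augmentation.** Endoscopic images carry diagnostic signal in colour, so
the colour half of the standard siamese recipe is weakened — no grayscale,
no Gaussian blur, multiplicative brightness/contrast/saturation jitter at
0.25 instead of 0.4, hue untouched — and the geometric half is strengthened:
horizontal and vertical flips (p = 0.5 each) and, with probability 0.5, one
of translation (≤ 10% of the side), rotation (≤ 30°), or scaling
([0.8, 1.2]), chosen uniformly. A random resized square crop (area fraction
[0.6, 1.0]) precedes the flips to keep the mutual information between views
down; it can be disabled (`crop: false`). The affine magnitudes and the crop
retention are our own choices where the recipe leaves them open; all are
exposed in config. Geometry uses bilinear interpolation with reflective
edges; every stage preserves the [0, 1] range and the square output size.

## Optimization protocol

Pretraining: SGD, initial learning rate 0.01, momentum 0.9, weight decay
1e-4, cosine decay of the learning rate to 0 over the epochs; default 100
epochs, batch 64. The curriculum advances once per epoch; λ is redrawn per
batch (per-sample draws behind `lambda_granularity: sample`). Fine-tuning:
100 epochs, batch 64, learning rate 0.001, weight decay 0, cross-entropy;
`full_finetune` (default) updates all weights, `linear_probe` freezes the
backbone and fits a multinomial logistic regression on its features.

## Architecture

The documented full-scale encoder is ResNet-50 with its output projected to
2048 dimensions; the predictor is the bottleneck MLP 2048 → 512 → 2048. A
single-linear predictor is available (`predictor_single_layer`), but the
bottleneck is the default since a hidden width of 512 presupposes a hidden
layer. The projector is a 3-layer MLP with batch norm after every linear and
no activation after the last (depth configurable). For desk-scale work a
`tiny_cnn` backbone (three conv/BN/ReLU blocks, 64 features) is first-class
and used throughout the tests, with a narrow projector (64) and predictor
hidden width 32.

The networks run on a compact numpy reverse-mode autodiff toolkit inside the
package (`cmixup.nn`): broadcasting arithmetic, matmul, im2col convolution,
max-pooling, batch norm, and `detach` — the stop-gradient primitive. Every
differentiable primitive is validated against central finite differences in
the test suite, and the stop-gradient contract is checked both as an
exactly-zero autodiff gradient and against a finite difference of the loss
with the stopped branch frozen. Initialization is He-uniform for weights and
fan-in-scaled uniform for biases (a zero bias can make a sample's prediction
vector exactly zero when its ReLU block is dead, which the cosine loss
rejects); all initialization is driven by an explicit seeded generator.

## Synthetic corpus

The generator emulates a small multi-class image collection with the two cue
families that distinguish endoscopic classes: colour (a per-class base hue)
and spatial structure (oriented sinusoidal stripes with class-specific
frequency and orientation). Nuisance variation — stripe phase, brightness
jitter (±15%), additive Gaussian pixel noise (default sd 0.05), optional
class imbalance (counts interpolated from `images_per_class` down to
`images_per_class/imbalance_ratio`) — varies per image. Pixels live in
[0, 1]; noise is clipped there. Generation is bit-deterministic in the spec
(including its seed).

What it does not emulate: photorealistic tissue texture, specular
highlights, the scope-position inset of real endoscopy frames, inter-class
ambiguity (adjacent severity grades), or label noise. Consequently, passing
tests demonstrate the machinery — scheduling, mixing, optimization,
non-collapse, evaluation — not clinical-grade representation quality; the
synthetic task is linearly separable by design (a least-squares pixel probe
beats chance by a wide margin, which the tests assert), so even a
random-initialization probe can saturate it.

## Desk-scale study conditions

The training smoke experiment uses a 4-class, 32-px corpus of 280 images
(200 unlabeled for pretraining, 80 labeled), the `tiny_cnn` encoder, 20
pretraining epochs at batch 64, and a 4:1 labeled split; the linear probe is
compared against the same probe on a randomly initialized backbone over 3
seeds at matched budget. These sizes are the package's desk-scale operating
point: large enough for the loss to fall and the collapse diagnostic to be
meaningful, small enough to run on one CPU core in about a minute.
`scripts/acceptance.py` re-runs exactly this pipeline from scratch and
writes the measured numbers.

## Numerical choices and edge cases

- Cosine similarities use exact L2 normalization; a zero-norm vector raises
  instead of being epsilon-guarded, since it signals a degenerate model.
- The λ-cap is a hard clip; `cap_mode: reflect` (λ ← min(raw, 1 − raw))
  folds the U-shape instead, for experimentation.
- Train/test split: test share is ⌊n/5⌋ (uniform over items, per the
  protocol's plain random split); a stratified variant sits behind a flag.
- Undefined per-class metric ratios (0/0) score 0 and are logged; macro
  averaging is the default because per-class specificity reporting and class
  imbalance both argue for weighting classes equally, with
  `average="weighted"` available.
- Unreadable image files are skipped with a warning; an empty retained class
  is a configuration error.
- Checkpoints are `.npz` weight archives plus a JSON sidecar holding the
  config snapshot and traces.

## Known limitations

- The numpy substrate is single-threaded and desk-scale; ResNet-50 forward
  passes work (and are tested) but full-scale 512-px pretraining is outside
  its intended envelope.
- Batch-norm statistics make the pretraining loss batch-composition
  dependent; determinism is guaranteed only under the provided seeded
  loops (which are bit-reproducible run-to-run).
- The probe comparison on the synthetic corpus bounds, but cannot
  demonstrate, the advantage of pretraining on hard natural-image tasks.
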