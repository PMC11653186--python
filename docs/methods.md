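# Methods

## Search model

The search object is a variable-length chromosome of integer gene pairs,
one `(filter_count, filter_size)` pair per convolutional layer; a second
chromosome type holds dense-layer widths for the frozen-backbone head
search. All genes have inclusive integer bounds (`[1, max_filters]`,
`[1, max_filter_size]`, `[min_neurons, max_neurons]`); minimum values are
fixed at 1. The chromosome is stored as interleaved `(count, size)` pairs
so that every structural operation (length crossover, structural mutation)
moves whole layers rather than splitting a layer's two genes.

The evolutionary loop per generation: evaluate every unevaluated
individual; retain the `elitism_k` best under a deterministic total order
(fitness descending, generation born ascending, genome JSON ascending);
refill to `population_size` with children of uniformly chosen elite
parents. Equal-length parents recombine by per-gene uniform crossover
(gene from parent 1 with probability `crossover_prob`); unequal-length
parents recombine by the length crossover, whose child length is uniform
on the interval spanned by the parents' lengths and whose layers are
copied from a uniformly chosen parent long enough to donate. Children are
then mutated: each scalar gene independently, with probability
`mutation_rate`, receives an integer perturbation uniform on
`{−d, …, −1, 1, …, d}` with `d = ⌈0.1·(hi − lo)⌉`, clamped to bounds.
The refill re-draws a child (up to 10 times) if its genome already occurs
in the next generation: re-evaluating an identical chromosome wastes a
full network training, and on small landscapes duplicate children
measurably slow convergence. Stopping: `max_generations`, or a plateau —
`patience` consecutive generations without a strict best-fitness
improvement beyond 1e-9.

Design choices made where the design was genuinely open:

- **Parent selection** is uniform over the elite pool, not
  fitness-proportional — the simplest mechanism consistent with selecting
  "parents with high fitness".
- **Elitism default** is `⌈population_size / 4⌉`.
- **Structural mutation** (insert/delete one random layer with probability
  `mutation_rate`) exists behind a flag, off by default, for searches where
  elites may collapse to a single chromosome length.
- **Fitness during search** is evaluated on a validation split only; the
  test split touches nothing but the final retrained winner. This avoids a
  selection leak that would otherwise inflate reported test accuracy.

## Network template

A chromosome with layers `(n₁,k₁)…(n_L,k_L)` builds: per layer a same-padded
stride-1 convolution (`n_i` filters, `k_i × k_i` kernel), batch
normalization, ReLU; a 2×2/stride-2 max-pool after every second conv block
(so `⌊L/2⌋` pools); then flatten and a single sigmoid output unit trained
with binary cross-entropy. Same padding means spatial size changes only at
pools, which keeps shape feasibility a simple function of input size and
depth (`min(H, W) ≥ 2^⌊L/2⌋`). Activations, pooling positions and the
dropout rate (0.5 in the head template) are template metadata, not genes.

The dense-head variant is flatten → dropout → dense(width₁) → … → sigmoid
output over the features of a frozen convolutional extractor. Tests use
`StandInBackbone`, a fixed seeded random-weight two-stage conv net, so no
pretrained weights are required; any feature extractor with a `transform`
method can stand in its place.

Training uses Adam (learning rate 1e-3 default, β₁ = 0.9, β₂ = 0.999) on a
float32 numpy backend written for this package: convolution as k² shifted
matrix products, exact reverse-mode gradients, logit-form BCE for
stability. The per-genome search budget defaults to 5 epochs with a
30-epoch final retrain of the winner: cheap noisy fitness for exploration,
a full budget only where it matters.

## Scoring formulas

- Confusion fitness `F = TP/(TP+FP+FN)` (true negatives excluded).
- Percentage accuracy `100·correct/total` — the default GA fitness.
- Binary and categorical cross-entropy, natural log, probabilities clipped
  to `[1e-7, 1−1e-7]`; on binary one-hot problems the two coincide (a
  property test enforces agreement to 1e-9).
- Error rate = mean absolute difference between label vectors, which on
  hard binary labels is exactly the misclassification fraction and
  complements accuracy/100 to 1.
- Structural cost `αL + βF + γE` with nonnegative weights.

## Synthetic data

The generator emulates only the statistical cue that distinguishes a
pneumonia-like radiograph — localized bright opacity mass — not anatomy.
Class 0 is a smooth low-frequency background (Gaussian-filtered noise,
standardized per image, mapped to `background_level` = [0.25, 0.55]) plus
pixel noise (`noise_sd` = 0.05); class 1 adds 1–3 soft elliptical Gaussian
blobs with peak brightness `intensity_lift` and radius 8–20% of image
width. Standardizing the background pins every class-0 image's mean at the
same value, so separability is carried entirely by lesion mass and is
therefore *certifiable*: a brute-force mean-intensity threshold rule
(threshold swept on the training split, both polarities) provides a
classifier-independent ceiling check. At lift 0.5 the oracle exceeds 95%
test accuracy; at lift 0 the classes are identical by construction and any
classifier sits at chance.

What the generator does **not** model: exposure drift between images, rib
and cardiac structure, resolution variability, label noise, class
imbalance. Passing tests therefore demonstrate that the search loop
optimizes what it measures on a clean, separable task — not that the
evolved architectures transfer to clinical radiographs.

Images are written as 8-bit PNG in a `{split}/{NORMAL,PNEUMONIA}` tree and
reloaded as float arrays in [0, 1]; round trips are exact up to 1/255.

## Augmentation

Training-split augmentation composes horizontal flip (probability 0.5),
rotation uniform in ±20°, center-anchored zoom in [0.9, 1.1], and
shifts uniform in ±10% of each dimension, as one affine warp with bilinear
interpolation and edge-value fill; intensities are clipped back to [0, 1].
Augmented sets are the union of originals and `multiplier` transformed
copies, labels inherited. The pipeline driver augments the training split
only. Blur is deliberately not part of the set; zoom is read as a scale
factor range.

## Problem sizes and numerical choices

The package targets desk scale: 32×32 to 64×64 single-channel images,
populations of 5–20, at most 6 conv layers. The acceptance pipeline uses
200 images per class at 32×32, population 6, ≤ 4 generations, ≤ 3 layers
and ≤ 32 filters, 5-epoch search budget and 30-epoch final retrain —
enough for the separable synthetic task to be learned to ≥ 90% test
accuracy in minutes on one CPU. Plateau tolerance is 1e-9; probability
clipping 1e-7; batch-norm ε 1e-5 with momentum 0.9 running statistics;
ties in survivor selection are broken deterministically so whole runs are
bit-reproducible given a seed.

## Known limitations

- The trainer is single-threaded CPU numpy; it is not meant for
  full-resolution radiographs or large filter counts.
- Fitness of a failed training (shape infeasibility, numerical blow-up) is
  defined as 0, which silently removes such chromosomes from the gene pool
  rather than surfacing them; the run manifest records only survivors.
- The surrogate fitness used to test GA mechanics (negative L1 distance to
  a hidden chromosome) is unimodal; recovery rates there do not bound
  performance on deceptive landscapes.
- Uniform parent selection over the elite pool applies weak selective
  pressure within the pool; fitness-proportional or tournament selection
  would change convergence behavior and is intentionally out of scope.
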