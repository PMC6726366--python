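# Methods

## Problem and approach

A migrating cell's shape is causally linked to where it will move
next: the actin-driven protrusion marks the front, the contracting
trailing edge marks the rear, and under phase-contrast optics a bright
halo outlines the body. `cellheading` trains a convolutional network
to predict, from a single image patch of a cell at one time point, the
quadrant of its future net displacement — upper right, upper left,
lower left, or lower right in image coordinates (y grows downward) —
and then interrogates the trained network with three attribution
methods to see which morphological features carried the decision.

## Direction annotation

Given a tracked trajectory in micrometers, each anchor frame is
labelled by the displacement vector (Δx, Δy) at the first later
evaluation point whose net displacement strictly exceeds one cell
diameter (default 18 µm, the average NIH/3T3 fibroblast diameter).
The quadrant predicates are Δx ≥ 0 / Δx < 0 crossed with Δy ≤ 0
("upper", since y is down) / Δy > 0. Cells whose remaining track never
exceeds the threshold are excluded. The crossing search always runs on
a fixed 15-minute evaluation grid; tracks acquired faster (e.g. every
3 or 5 minutes) are first subsampled to that grid, keeping every
(15/interval)-th point from the first. Whether the crossing search for
fast-acquired tracks should instead use the native grid is genuinely
open; the 15-minute grid is the default here because it makes the
motility statistics and the annotation consistent, and the interval is
a parameter everywhere.

Two motility statistics summarize each annotated anchor: average speed
v = ΣΔd / Δt (path length over time to crossing) and directionality
k = Δr / ΣΔd (net over path length, 1 for straight motion).

## Synthetic data generator

There is no deposited movie data, so validation runs on a seeded
generator whose construction guarantees the task is solvable:

* **Motion** — a persistent random walk: heading_{t+1} ~ von
  Mises(heading_t, κ), step length max(0, N(speed_mean, speed_sd)) ·
  interval, reflecting walls (reflection also flips the heading
  component so morphology stays consistent with motion).
* **Morphology** — each cell is a dark ellipse (semi-axes 9 × 6.75 µm)
  plus a broad cosine-tapered protrusion lobe (12 µm, half-width 40°)
  ahead of the heading, a narrow tail spike (7 µm, half-width 16°)
  behind it, and a bright halo ring around the outline; background
  0.5, body 0.22, halo 0.78, additive Gaussian noise (σ = 0.02),
  values clipped to [0, 1].
* **Coupling** — the drawn protrusion axis equals the direction of the
  *next* displacement exactly (optional jitter is off by default), so
  the patch deterministically encodes the next step and statistically
  encodes the label, which depends on the displacement accumulated
  until the 18-µm crossing.

Defaults: 200 cells, 40 frames, 15-minute interval, 1536² px field at
0.65 µm/px (≈200 cells/mm², sparse enough that patches are dominated
by their center cell; initial positions keep ≥45 µm separation),
speed 0.7 ± 0.15 µm/min, κ = 40. The motility values were fixed once,
during generator design, by measuring the Bayes ceiling of the task:
the quadrant of the rendered heading agrees with the eventual label
for ≈94–95 % of anchors at these settings (the residual comes from
anchors whose heading sits near a quadrant boundary while the
crossing takes 2–3 steps). A weaker persistence (κ = 8) drops the
ceiling to ≈82 %, leaving too little headroom for any classifier to
demonstrate recovery. These cells are therefore deliberately fast and
strongly persistent compared with typical fibroblast cultures; the
generator emulates the *geometry* of the prediction problem, not
population-level motility statistics.

What the generator does **not** emulate: optical texture inside the
cell body, shape fluctuation and ruffling, cell–cell collisions and
contact inhibition (overlapping cells simply overdraw in id order),
division, focus drift, and illumination gradients. Passing the
recovery test therefore shows the pipeline and network function as
designed — it does not certify accuracy on real microscopy.

## Patches

Each annotated anchor yields a square crop centered on the tracked
position (128 px for the synthetic data; configurable, matching the
dataset-specific crop sizes used with real movies), edge-replicated at
frame borders, bilinearly resized to the network input side, and
min–max normalized to [0, 1] (constant crops become all zeros).
Geometric augmentation of training folds multiplies them six-fold:
identity, horizontal and vertical reflection, and rotations by 90°,
180°, 270° (counterclockwise in the displayed image). Because a
rotated image of a right-moving cell shows an upward-moving cell, the
label is transformed by the same isometry — reflections swap the
matching quadrant pair, each 90° rotation advances the quadrant by
one. A flag preserves the literal alternative (labels untouched).

Splits are stratified by label at the patch level (mirroring per-class
count tables); an optional grouped mode keeps all patches of one cell
in a single split to preclude within-cell leakage.

## Network and training

The classifier is a fixed 14-layer stack: conv(5×5, 8) → conv(5×5,
32) → pool → conv(3×3, 40) → conv(5×5, 32) → pool → conv(5×5, 48) →
conv(5×5, 64) → pool → conv(5×5, 64) → conv(5×5, 72) → pool →
fc(1000) → fc(4), ReLU after every conv and after fc(1000), dropout
0.3 after fc(1000), softmax output. Convolutions are stride-1 with
same (zero) padding: the architecture only closes (four 2×2 pools
mapping 128 → 8, or 64 → 4) under same padding, so that is the one
consistent reading. At 128-px input the stack has 4,996,284 trainable
parameters (4,609,000 of them in fc(1000)); a historically reported
figure of ~163 k for this layer table is not reproducible under any
standard padding convention, and this package reports the count it
actually builds.

Weights are He-normal (σ = √(2/fan-in)), biases zero. Training is SGD
with momentum (base learning rate 0.021, momentum 0.5) on stratified
batches of 46 augmented patches for 50 epochs (15 at desk scale),
minimizing class-weighted softmax cross-entropy with w_k = ΣN/(n·N_k);
the batch loss is Σ wᵢℓᵢ / Σ wᵢ so the effective step size does not
depend on the batch's class mix. 4-fold stratified cross-validation
records validation ACA and MCA every epoch and keeps the
per-criterion best epoch; the checkpoint selected across folds is the
one with the highest validation MCA (ties: earlier epoch, lower
fold), since MCA is also the criterion used downstream for feature
analysis; selection by ACA is a flag.

ACA = 100 · trace/total on the test confusion matrix; CCR_k = 100 ·
diagonal_k / rowsum_k; MCA = mean of CCR_k (empty classes are dropped
from the mean with a warning). Chance level for four classes is 25 %
for both.

### NumPy implementation notes

No deep-learning framework is available in the target environment, so
the network is implemented directly on NumPy. Arrays are NHWC;
convolutions are lowered to one BLAS matrix product per layer per
batch through an im2col buffer filled by a compiled (numba) span-copy
kernel, and the backward pass reuses the buffer for the weight
gradient and scatter-adds the input gradient with the adjoint kernel.
GEMM orientations were chosen after profiling: products are arranged
as (pixels × features) · (features × channels), the shape
single-threaded OpenBLAS handles well; the naive transposed
orientation is up to 10× slower. For 5×5 kernels on feature maps of
16 px and larger (and 3×3 at 32 px and larger) the convolution instead
runs in the frequency domain — rFFT of the zero-padded input, one
small complex matrix product per frequency bin over the channel
dimension, inverse rFFT — which computes the identical same-padded
correlation (cross-checked against the im2col path to 10⁻¹⁰) while
skipping the 25-fold buffer expansion; this roughly doubles training
throughput on one core. Training runs in float32; gradient
checks and all attribution runs use float64. Max-pool ties route to
the first element in row-major window order, both for gradients and
for winner-take-all relevance routing; argmax label ties resolve to
the lowest class index.

## Attribution

* **Guided backpropagation** starts from the spatial maximum of one
  feature map of the last convolutional layer (post-ReLU; ties to the
  first position row-major) and walks the analytic backward pass with
  the guided gate at every ReLU: the signal is zeroed where the
  forward activation was ≤ 0 or the incoming signal is < 0. With
  every gate open (all-positive networks) the map equals the plain
  gradient; a non-positive target yields an all-zero map.
* **Deep Taylor decomposition** assigns the pre-softmax score of the
  predicted class as output relevance R_f and propagates it down with
  the z⁺ rule (positive weights only, biases excluded) through dense
  and convolutional layers, winner-take-all through max pooling,
  identity through ReLU, and the z^B rule with box bounds [0, 1] at
  the layer reading the input. This is the standard rule set for
  ReLU networks with box-constrained inputs; the relevances are
  non-negative and, with zero biases, sum to R_f (machine-precision
  conservation on single layers, < 10⁻³ relative through the full
  stack; a small ε guards empty denominators). A non-positive class
  score has no positive evidence to decompose and returns a zero map
  with a warning.
* **Occlusion** replaces the 7×7 window centered at each pixel
  (cropped at borders) with the patch mean (zero-fill optional), runs
  the forward pass, and records the negated class score — pre-softmax
  by default for linearity, with a softmax flag; the class defaults
  to the true label when supplied, else the unoccluded prediction.
  The per-pixel scores are min–max normalized to integers in
  [0, 255]; a flat map (constant predictor) normalizes to zeros.

## Desk-scale problem sizes

The end-to-end synthetic experiment (`run_synthetic_experiment`)
defaults to 96-px crops resized to 64×64 (the tighter crop lets the
cell fill most of the input at this resolution), 15 epochs, and a
stratified subsample of 200 annotated anchors split 50/15/35 % —
test-heavier than the conventional 60/20/20 so the held-out accuracy
has a usefully small standard error at this size, while the pool
still feeds 4-fold CV. These sizes keep a complete run to roughly ten
minutes on one CPU core; all of them are ordinary function arguments,
and full-scale runs (128-px patches, 50 epochs, all anchors) use the
same code path.

## Known limitations

* Single-threaded NumPy training is ~100× slower than a GPU
  framework; the package is sized for method validation, not
  large-scale training.
* The synthetic generator's realism limits are listed above; in
  particular no claim about real phase-contrast data follows from the
  recovery experiment.
* DTD conservation is exact only with zero biases; trained networks
  have non-zero biases, which the z⁺ rule deliberately excludes, so
  relevance is then conserved only approximately.
* Occlusion at 128² input runs 16 384 forward passes per map —
  minutes per patch on one core.
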