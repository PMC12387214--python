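# Methods

## Model

The classifier is a compact attention-augmented CNN for ten-class fundus
screening. Feature extraction interleaves depthwise-separable convolutions
(a per-channel 3×3 spatial convolution followed by a 1×1 cross-channel
projection) with channel attention: squeeze-and-excitation (SE) gates in
blocks 1 and 3 rescale channels by sigmoid factors in (0,1) computed from a
bottleneck (reduction r) over the global-average-pooled channel descriptor;
the global-context (GC) gate in block 2 rescales by 1 + sigmoid(·), i.e.
factors in (1,2), so it can only amplify; block 4 is a residual block whose
projected skip keeps gradients flowing at the widest part of the network.
All convolutions are stride-1 with same padding; all spatial reduction is
done by 2×2 max-pools with floor semantics for odd extents (75→37, 9→4).
The head is GAP → Dense(1024) → Dense(512) → Dense(N) with ReLU and dropout
0.5 on both hidden layers and a max-subtracted softmax.

Conventions that pin down the exact parameter budget (16,552,114 trainable,
8,960 non-trainable for the default spec):

* every convolution — including depthwise and the SE/GC projections — and
  every dense layer carries a bias;
* batch normalization sits after the stem convolution, after the depthwise
  and the pointwise convolution in each DSConv block, and after each of the
  three convolutions in the residual block (4,480 BN channels in total);
  each BN channel holds 2 trainable values (γ, β) and 2 moving statistics;
* the SE bottleneck width is floor(C/r), required to be ≥ 1;
* the residual addition has no trailing activation;
* memory figures are count × 4 bytes, reported in MiB (trainable) and KiB
  (non-trainable) to 2 decimals.

The head width follows the tabulated 1024 → 512 progression rather than the
equation-level 512 → 512 reading, since only the former reproduces the
totals above; this is deliberate and verified by a closed-form accounting
oracle in the tests.

### Numerical engine

No deep-learning framework is used. All layers are implemented in NumPy
(float64, NHWC): convolutions via im2col + GEMM, and each layer carries an
analytic backward pass validated against central finite differences in the
test suite. Softmax is computed with max subtraction; the cross-entropy
clamps true-class probabilities at 1e-12 (with a warning) before the log.
Weights are He-initialized (fan-in) from a seeded generator; biases start
at zero, BN at γ=1, β=0 with zero/unit moving statistics. BN's moving-stat
momentum defaults to 0.99; reduced-scale configurations use a smaller value
(0.8) because with only a few hundred optimizer steps the moving estimates
would otherwise lag far behind the batch statistics that training uses,
leaving validation metrics artificially at chance.

## Data pipeline

Images are loaded from a one-directory-per-class tree, converted to RGB,
resized bilinearly to the target size and scaled by 1/255. Class indices
follow sorted directory names and are recorded in a manifest.

SMOTE balances every class to the majority count in flattened pixel space:
each synthetic sample is x + u·(x′ − x) with u drawn once per sample,
uniform in (0,1), x a uniformly chosen class member and x′ one of its k = 5
nearest same-class neighbors (Euclidean; neighbor search via
scikit-learn). Originals are preserved unchanged; k is clipped to
class_size − 1 with a warning for very small classes; singleton classes are
rejected. Balancing runs before splitting, matching the published order in
which per-class test supports are ~15% of the balanced (not the raw) class
size; this leaks interpolated information across splits, so a
`split_first` option performs the leak-free order (split, then balance the
training portion only).

The 70/15/15 split uses two-level largest-remainder rounding: the global
split totals are fixed first by largest remainder (ties to the later
split), then per-class floor allocations are topped up one sample at a
time — at most one leftover per split per class — toward the split with the
largest remaining global shortfall. Consequence: per-class fractions are
exact to ±1 sample, the splits partition the indices exactly, and on a
balanced 10×1509 set the test split holds 2,264 samples with per-class
supports in {226, 227}.

Augmentation is on-the-fly (resampled every epoch, never applied to
validation/test): per-image uniform draws of rotation, width/height shift,
shear and zoom within the configured ranges and a 0.5-probability
horizontal flip, composed as a single center-anchored affine warp with
bilinear interpolation and edge fill, clipped back to [0,1]. Full-scale
defaults are rotation ≤20°, shift ≤10%.

## Training

Adam (β₁=0.9, β₂=0.999, ε=1e-7) minimizes mean cross-entropy plus
λ·Σw² — applied to the two hidden dense kernels by default (the penalty's
tabulated placement under the classification head), with `l2_global=True`
switching to all trainable tensors. Callbacks run in the order
checkpoint → plateau → early-stop: the checkpoint tracks the best
validation *accuracy* (whose weights are restored at the end), while the
plateau schedule (×0.5 after 5 stagnant epochs, floor 1e-6, counter resets
on improvement and after each reduction) and early stopping (15 stagnant
epochs) monitor validation *loss* with zero min-delta. The last partial
batch is kept; training indices are reshuffled per epoch from the run
seed; a non-finite training loss aborts with a diagnostic. Single-threaded
runs with a fixed seed are bit-reproducible.

## Evaluation

The confusion matrix is a plain tally (rows true, columns predicted).
Per-class precision/recall/F1 use the one-vs-rest TP/FP/FN decomposition;
macro averages are unweighted means; overall accuracy is trace/total.
Metrics with zero denominators (e.g. a never-predicted class) are reported
as 0 and flagged with a warning. Text reports round to 3 decimals.

## Explainability

Grad-CAM weighs each channel of a tapped activation A^k by the spatial mean
of ∂y^c/∂A^k (y^c the pre-softmax logit) and rectifies the weighted sum;
Grad-CAM++ weighs gradient contributions per position with
α = g²/(2g² + Σ A·g³) — the closed form the second/third derivatives of
exp(y^c) reduce to under the standard diagonal simplification — and
accumulates α·ReLU(g) per channel. Raw maps are rectified, bilinearly
upsampled to the input resolution and min–max normalized to [0,1]; an
identically zero map is returned as zeros, and the α denominator is guarded
at 1e-8. The default tap is the residual block's pre-pool output (the
deepest spatial layer); any block output, pre- or post-pool, can be tapped.
Normalized Grad-CAM maps are invariant to positive rescaling of the logits.
Grad-CAM++ coincides with Grad-CAM when the gradient is a uniform positive
constant *and* per-channel activation sums agree (e.g. a single-channel
layer) — the property checked in the tests.

## Synthetic fixture

The generator renders a circular retinal field (radial falloff over a
reddish tint, an optic disc, two vessel arcs, pixel noise) and one lesion
program per class: swollen bright disc (disc edema), pale cupped disc
(glaucoma), scattered dark-red dots (diabetic retinopathy), peripheral
pigment speckle (retinitis pigmentosa), corner wedge (pterygium), central
serous blister ring, pale macular patch (macular scar), tessellated texture
(myopia), pale peripheral fold sector (retinal detachment), clean field
(healthy). Default per-class counts follow the study's imbalance profile
(1509/1349/…/101/17, total 5335); only four of the ten counts are published,
so the other six are explicit configuration chosen once to close the total.

Design choices worth knowing:

* Stochastic lesion programs (dots, speckle, texture) draw from fixed
  per-class layouts with jitter no larger than the lesion footprint. This
  keeps each class compact in pixel space so that mean between-class
  distance exceeds mean within-class distance for every pair — the
  separability contract a classification fixture must satisfy. Fully random
  placement would make the within-class spread of dot patterns exceed their
  distance to the clean-field class.
* Each image records its lesion's bounding box (half-open pixel
  intervals); programs that plant one compact lesion are flagged
  `localized`, and only those participate in saliency-containment checks —
  a diffuse program's box is the whole field and would make the check
  vacuous.
* The lesions are caricatures tuned for separability and localization
  testing. Passing tests on this fixture demonstrates that the pipeline,
  optimizer, metrics and saliency mapping are correct and that the model
  can learn localized evidence; it says nothing about accuracy on real
  fundus photographs, which vary in ways (acquisition, anatomy, pathology
  continua) the generator does not emulate.

## Scaled-down benchmark

Full-scale training of the 16.6M-parameter network on a real dataset is
outside what a CPU test suite can do, so the end-to-end guarantee is
property-based at reduced scale: a narrow spec (stem 8, blocks
16/32/64/128, SE reduction 4, head 64/32, dropout 0.25, BN momentum 0.8)
on 96×96 synthetic images (227 images across the ten classes, SMOTE-balanced
to 500), trained 15 epochs with Adam at 1e-3 and λ=1e-3 under mild
augmentation. Across three seeds this reaches seed-averaged held-out
macro-F1 well above the 0.6 bar, and Grad-CAM peaks (block-3 tap, 12×12
resolution) fall inside the planted lesion box in ≥70% of correctly
classified held-out localized-lesion cases pooled over the three runs. The
reduced problem sizes are the package's own choice of a benchmark that a
single CPU completes in minutes while still exercising every pipeline
stage.

## Known limitations

* Training is CPU-bound NumPy; full-scale runs (150×150, 16.6M parameters,
  thousands of images) are possible but slow — the engine is built for
  correctness and auditability, not throughput.
* SMOTE in raw pixel space is memory-hungry at full resolution
  (d = 67,500); interpolating images also produces ghosting artifacts, an
  inherent property of pixel-space SMOTE, not a defect of the
  implementation.
* The published balance-before-split order leaks interpolated information
  into validation/test; it is reproduced deliberately and a leak-free
  option is provided.
* Saliency containment is a statistical property of a well-trained model,
  not a per-image guarantee; small models on coarse taps can localize
  adjacent to, rather than inside, very small lesions.
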