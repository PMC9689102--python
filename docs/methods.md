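# Methods

This note documents the models and procedures implemented in
`cystoseg`, the assumptions behind them, and the choices made where the
underlying method descriptions left the design open.

## Pre-processing

**Guided filter.** Noise reduction uses the box-window linear-model
guided filter with the image as its own guide, applied per channel.
For each window the output is the local linear fit
`q = mean(a)·I + mean(b)` with `a = var(I)/(var(I)+eps)` and
`b = (1−a)·mean(I)`. Box means near the frame are taken over the
clipped window (integral images divided by true pixel counts), so the
dark vignetted corners are smoothed without padding bias. The
user-facing strength dial `r ∈ [0,5]` maps linearly to the window
half-width `w = round(2r)` (so `r = 5` is a 21-pixel box). `r = 0`
short-circuits to an exact identity. The edge regularizer defaults to
`eps = 1e-3` on the [0,1] intensity scale; both `k = 2` and `eps` are
package choices — the method itself fixes neither — and both are
exposed in configuration.

**Unsharp masking.** Sharpening each RGB channel separately changes
pixel hues, so the enhancement multiplies all three channels by a
single luminance-derived factor

    R_i = P_i · (1 + λ·(1 − lum(P_filtered,i) / lum(P_i))),

with luminance approximated as the channel mean `(R+G+B)/3`. This
preserves the channel ratios (the hue) at every pixel where no
clamping to [0,1] occurs. Pixels with luminance below `1e-6` skip
sharpening entirely: the formula divides by `lum(P_i)`, and black
vignette corners would otherwise blow up.

**Stage wiring.** Two requirements shape the pipeline: `r` and `λ`
must act as *independent* dials, and the four data-augmentation
versions (original / filtered / sharpened / enhanced) must be four
distinct frames. If the unsharp mask's low-pass were the `r`-dial
guided filter itself, `r = 0, λ = 5` would collapse to the identity;
if the pipeline output were based on the raw input, `r = 5, λ = 0`
would discard the filtering. The pipeline therefore sharpens the
*noise-reduced* frame and estimates its low-pass with a
fixed-strength guided filter (`usm_lowpass_r = 5`, decoupled from
`r`). With that wiring, (r, λ) = (0,0)/(5,0)/(0,5)/(5,5) produce
exactly the original/filtered/sharpened/enhanced variants.

**Resize and standardization.** Geometric normalization is an optional
margin crop followed by bilinear resampling (half-pixel-centre
convention, border-clamped) to a square `target_size` (default 160,
the model input). Standardization is per image with one mean and one
standard deviation pooled over all pixels and channels (population
denominator); a constant frame maps to zeros with a logged warning.
Dataset-level statistics were the plausible alternative; per-image
statistics need no fitted state and keep every frame self-contained.

## Pixel classifier

The pipeline defines a model *contract*: any callable from a
standardized `(N, H, W, 3)` batch to `(N, H, W, 7)` per-pixel scores.
Decoding takes the per-pixel argmax (ties to the lowest class index,
for determinism), which is invariant to monotone per-pixel transforms,
so models may emit logits or probabilities.

The bundled reference network is a compact NumPy encoder–decoder:
three conv + leaky-ReLU stages with 2× max-pooling, a bottleneck, and
a mirrored decoder with nearest-neighbour upsampling and skip
concatenations, closed by a 1×1 7-channel head (≈26 k parameters at
the default width of 8 base channels). Gradients are hand-derived per
layer; optimization is Adam. Two safeguards matter at this scale:
leaky ReLUs (slope 0.1) instead of plain ReLUs, and global
gradient-norm clipping at 5.0. Without them a fraction of random
initializations collapses early (dead units / unstable first updates)
and never recovers within a desk-scale budget; with them training is
reliable across seeds. Initialization (He-normal from a seed) and
epoch shuffling are fully deterministic, so equal seeds give
bit-identical loss histories.

`TrainConfig` defaults mirror the full-scale regime (γ = 2, learning
rate 7·10⁻⁵, batch 64, 1000 epochs); every field is expected to be
overridden for desk-scale work. The tests and the acceptance script
use 64 × 64 scenes, batch 4, learning rate 3·10⁻³ and 30 epochs — a
deliberate reduction that trains in seconds on one CPU.

## Losses and class balancing

The training loss is the α-balanced focal loss. Scores are softmaxed
inside the loss; per pixel with true class c*,

    FL = −α_{c*} · (1 − p_{c*})^γ · log(p_{c*}),

mean-reduced over pixels and batch. Probabilities are floored at
`1e-12` inside the log so the loss stays finite. With `γ = 0` and all
`α = 1` the implementation reduces exactly to softmax cross-entropy
(asserted to 1e-10 in tests). The analytic gradient
(`dFL/dp_t · p_t(δ − p)`) is verified against finite differences.

Class weights `α_c ∝ 1/f_c` come from the training-set pixel
frequencies and are normalized so the rarest present class has weight
1 — any positive rescale is equivalent up to learning rate, and
max-normalization keeps weights in (0, 1]. A class absent from the
training masks receives the maximum weight 1 and a warning.

## Polygon extraction

A pixel is *boundary* if any of its 4-neighbours has a different class
or it lies on the image border (out-of-frame counts as different, so
lesions touching the frame edge are still outlined). Simplification
runs before boundary detection: any pixel with more than four
differing 8-neighbours is reassigned to the majority neighbour class
(ties to the lowest index), simultaneously per pass, at most 2 passes
by default since each pass shrinks regions slightly (a rectangle's
corner has exactly 5 differing neighbours and is chamfered — expected
behaviour of the rule). For this count, out-of-frame is treated as the
pixel's own class so image edges are not eroded.

The tracer seeds at the lexicographically smallest remaining boundary
pixel of a class and repeatedly steps to the next one, scanning the
8-neighbourhood clockwise starting from the previous step's direction
(first step: East), widening the search over Chebyshev rings of radius
2…5 on dead ends. Every visited pixel is consumed, which guarantees
termination. A chain closes once it has ≥ 3 vertices and returns
within Chebyshev distance 1 of its seed; a dead-ended chain still
within distance 5 of the seed closes there (keeping the cyclic
vertex-gap invariant ≤ 5), otherwise it is discarded as noise and
counted in the diagnostics. Tracing repeats until the class's boundary
pool is empty, so the vertex totals plus discarded noise pixels always
equal the boundary-set size.

Polygon area is the shoelace value `½|Σ r_i × r_{i+1}|`
(orientation-independent); polygons under `min_area_frac` of the frame
(default 0.25 %, i.e. 64 px at 160 × 160) are discarded, with the
boundary case kept (area ≥ threshold). Overlays stroke each closed
loop with 1-pixel Bresenham segments in the class colour; only cyan
(cancer) and green (artifact) are externally mandated, the rest of the
palette is fixed by the package for reproducibility. The normal-tissue
class is never outlined.

## Per-image evaluation protocol

Each image reduces to two presence bits per side (prediction, truth):
*has malignant content* and *has benign content*. The malignant
category compares the malignant bits directly; every image is
applicable. All four benign outcome definitions carry a "no malignant
region" side condition, so the benign category applies only to images
where neither prediction nor truth contains malignant pixels; within
that subset the benign bits are compared the same way. An image with
both malignant and benign ground truth is therefore handled by the
malignant category alone. This reading is frozen as an exhaustive
9-case table in the tests. Sensitivity (= recall), precision and
F-score are reported in percent at 4 decimal places; zero denominators
yield NaN markers, never exceptions.

Per-class Dice excludes classes absent from both maps from the mean
(configurably countable as 1 instead); the protocol averages over
classes without addressing absence, and excluding undefined classes
avoids rewarding trivially empty predictions.

## Synthetic scenes

The generator emulates only the features the pipeline stages care
about: a reddish-pink background with smooth low-frequency texture, a
radial vignette (dark corners exercise the zero-luminance guard),
additive Gaussian pixel noise, and 0–4 mutually disjoint blobby
ellipses (sinusoidally modulated radius, random orientation and
eccentricity) with class-characteristic colour shifts and speckle.
Lesion areas are enforced by rasterized pixel count within the
requested range via bounded rejection sampling; the mask is the exact
generator geometry, so ground truth is correct by construction.
Default lesion areas are 200–1200 px on a 160 × 160 frame (≈0.8–4.7 %
of the image, scaled proportionally at other sizes) — large enough to
survive the 64 px area filter and small enough to keep the class
balance realistic for the balancing experiments.

What the generator does *not* model: specular highlights, optics and
motion blur, instrument geometry, bleeding, or clinically plausible
lesion morphology. Tests passing on these scenes demonstrate the
correctness and wiring of the pipeline's algorithms, not clinical
detection performance on real cystoscopy.

Dataset plumbing saves each scene in the four enhancement versions and
splits 90:5:5 *by scene*, all four versions co-travelling, which is
deliberately stricter than quadrupling before splitting: the four
versions of one frame are near-duplicates and would otherwise leak
across splits.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale as the
package's own working sizes: 64 × 64 training scenes (20 pairs, 30
epochs) for the overfit-capacity check, 32 × 32 scenes (12 pairs, 8
epochs, 5 seeds per arm) for the class-balancing comparison, 100
scenes for the split-plumbing check, and 160 × 160 maps for all
polygon-geometry checks. Tolerances: standardization and Dice
arithmetic to 1e-6; focal-loss reductions to 1e-10; the shoelace
Monte-Carlo cross-check to 2 % (bounding-box sampling, 10⁵ points);
percentages printed to 4 decimals.

## Known limitations

- The reference network is a correctness- and contract-focused model;
  it makes no claim to the accuracy of large pretrained encoders.
- Contour tracing emits one closed loop per traced chain; a region
  with holes yields separate loops for outer and inner boundaries
  rather than a single polygon with holes.
- The per-image protocol reduces each frame to presence bits; it does
  not localize which lesion was missed (the Dice metric covers
  localization).
- Frames are processed independently; no temporal smoothing across
  video frames.
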