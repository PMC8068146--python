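# Methods

## Problem and model

The package segments low-altitude RGB imagery of early-season crop fields
into three classes — background (0), crop canopy (1), and vacancy (2, bare
soil where plants failed) — and summarizes a field by its vacancy ratio

    VR = V / (C + V),

the vacant area over the planted-plus-vacant area, with the relative error
|VR_f − VR_p| / VR_f between reference and predicted ratios as the
application-level score.  The relative form is deliberate: a fixed absolute
gap matters less when the field is already badly vacant, and the error is
strict when the true ratio is small.

The network is an encoder–decoder CNN built around strip pooling.  Strip
pooling averages a C×H×W feature map along entire rows (1×W kernel) or
columns (H×1 kernel),

    y^h_i = (1/W) Σ_j x_{i,j},      y^v_j = (1/H) Σ_i x_{i,j},

producing directional profiles that carry long-range context — matched to
the long, narrow shape of many planting gaps.  The strip pooling module
(SPM) turns the profiles into an attention gate: each profile passes a
depthwise kernel-3 1-D convolution, is broadcast back to H×W, the two maps
are fused (element-wise sum by default), and a 1×1 convolution + group
normalization + sigmoid produce a gate that multiplies the input.  The mixed
pooling module (MPM) handles compact gaps: a 1×1 reduction (2048→1024
channels at full width), adaptive average pooling at grids {1,2,3} with 1×1
branch convolutions, bilinear upsampling and fusion by summation, a 3×3
anti-aliasing convolution, an SPM, and a 1×1 projection back.

The encoder trunk is a bottleneck ResNet re-phased into Start/Middle/End
blocks per stage: the Start block keeps the residual sum un-activated (no
ReLU on the identity path, so early negative signals survive), Middle blocks
use pre-activation ordering with the first normalization of the first
Middle block elided, and the End block appends GN+ReLU so the stage output
is normalized and activated.  The re-phasing is parameter-neutral: the
elided and appended normalizations cancel exactly, which the tests assert.
All normalization is group normalization (default 32 groups, reduced by gcd
when a layer is narrower), so statistics are per-sample and training at
batch size 4 is well behaved.  An SPM follows every block whose 3×3
convolution runs at 512 (×width) channels, i.e. the whole final stage.

Stage strides under the default output stride 16 are (4, 4, 16, 16): stage
2 keeps stride 4 and stage 3 downsamples by 4, with dilation 2 in stage 4.
This is the only geometry under which the decoder's two ×4 bilinear
upsamplings — encoding → stage-2 skip, then skip resolution → input
resolution — restore full resolution exactly, so we adopt it.  The decoder
reduces the fused encoding to 512 (×width) channels, upsamples ×4,
concatenates a 1×1-reduced skip (48 channels at full width), applies three
3×3 convolutions at 256 (×width) channels, projects to 3 class planes, and
upsamples ×4.

The SPM and MPM branches run in parallel on the stage-4 features, each
behind its own 1×1 reduction to 1024 (×width) channels, and fuse by
element-wise sum (a `concat` option exists; the wiring between the two
modules is genuinely underdetermined, and parallel-sum is our reading).
During training an auxiliary head (3×3 + 1×1 convolutions, upsampled to
full resolution) on the stage-1 features adds a second loss term with
proportion λ=0.4 ("loss reuse"), keeping gradient signal alive on small
datasets; λ is configurable, as no canonical value exists.

## Loss and optimization

The loss is class-weighted multinomial cross-entropy,
loss(x, class) = weight[class]·(−x[class] + log Σ_j exp x[j]), with default
weights (0.8, 1, 1.2) for (background, crop, vacancy) — upweighting the rare
vacancy class — computed with a shifted log-sum-exp.  The default reduction
divides the summed weighted losses by the summed applied weights (so
uniformly rescaling the weights changes nothing); `reduction="mean"`
divides by the pixel count instead and reproduces the per-pixel closed
forms (e.g. 1.2·ln 3 for a lone class-2 pixel at uniform logits).  The
optimizer is Adam at base learning rate 0.01, batch size 4, no schedule.
Per-epoch validation keeps the best-mIoU checkpoint.

## Numerical stack

The network runs on a compact reverse-mode automatic-differentiation engine
over NumPy (`spinet.grad`): broadcasted arithmetic with gradient
un-broadcasting, reductions, im2col convolution (stride/padding/dilation),
depthwise 1-D convolution, 3×3/2 max pooling, and a separable linear-map
primitive that implements both bilinear resizing (half-pixel centers, edge
clamping) and adaptive average pooling as constant matrices applied along
each spatial axis.  Every primitive is validated against central finite
differences in float64.  Group normalization is composed from the
arithmetic primitives, so its backward pass needs no hand-derived formula.
Parameters are float32, He-initialized from a seeded generator; model
construction, data order and augmentation draws all derive from the single
config seed, making training runs bit-reproducible.

One numerical caveat surfaced during development: group normalization after
global (1×1) pooling is degenerate when a group holds a single element —
the normalized value is identically zero and the branch receives no
gradient.  The MPM pyramid branches therefore normalize with a single group
(layer-norm style across branch channels).

## Synthetic scenes

The generator emulates what a drone frame of an early-season field looks
like at desk scale: a darker border strip (background), a green-dominant
multi-octave value-noise canopy (crop), and bare-soil vacancies of two
families — rotated rectangles with aspect ratio ≥ 4 (the strip-shaped gaps
strip pooling targets) and rotated ellipses (compact gaps) — with darker
rims and additive Gaussian pixel noise (σ=6).  Shape sizes are resampled
with a square-root area correction until the realized V/(C+V) is within
±25% relative of the requested target (default 0.10, a realistic
early-season vacancy level; ±30% is the contract the tests check), or the
generator rejects with a diagnostic.  Default scene geometry (256×256,
3 strips, 4 blobs, 6% border) scales proportionally via
`SceneParams.for_size`.

What the scenes do *not* emulate: perspective distortion, shadows cast by
canopy height, weeds and residue that confuse real color statistics,
inter-row soil visible through sparse canopy, and annotation noise.  The
classes here are separable by color alone (a linear probe exceeds 0.9
accuracy, which a test enforces), so passing the learnability checks shows
the pipeline trains and converges correctly — not that the architecture
would reach any particular accuracy on field imagery.

Augmentations mirror the training pipeline of the source setting: random
rotation, random horizontal/vertical flips, Gaussian noise, plus
salt-and-pepper noise, histogram equalization, sharpening and blur as
standalone operators.  "10% random rotation" is ambiguous between a
probability and a magnitude; we draw the angle uniformly from ±18° (10% of
a half-turn) and apply with probability 0.5, filling exposed corners with
the background class.  Photometric operators never touch the mask;
geometric operators use nearest-neighbor mask resampling.

## Desk-scale study conditions

Tests and the acceptance script exercise a toy preset: one block per stage,
width multiplier 1/8 (stage channels 32/64/128/256), 8 normalization
groups, 64×64 scenes, 32 training + 8 held-out scenes, 25 epochs × 8
batches = 200 Adam iterations.  These sizes keep a full train/evaluate
cycle under a minute on one CPU core while leaving every architectural
mechanism (staging, SPM, MPM, skip decoder, auxiliary loss) in play.

## Degenerate inputs and tie-breaks

Prediction argmax breaks ties toward the lowest class index (background);
inputs not divisible by 16 are reflection-padded and cropped back.  mIoU
averages only classes with nonzero union; VR is undefined (reported as
`None`, never 0) when the field has no crop and no vacancy, and the VR
error is undefined when the reference ratio is zero.  Dataset splits use
largest-remainder apportionment (110 items at 8:1:2 → exactly 80/10/20),
with ties broken in (train, val, test) order.

## Known limitations

- The engine is CPU-only and unbatched beyond NumPy's BLAS; full-width
  depth-101 training is out of reach here, and no pretraining is supported.
- The vertical strip-pool summation index follows dimensional consistency
  (a column mean averages H entries) where the printed formula's bound is
  inconsistent.
- Strip-branch fusion (sum vs product) and SPM/MPM wiring are
  underdetermined in the source description; both choices sit behind flags
  (`fusion`, `encoder_fusion`) with the additive/parallel-sum defaults
  documented above.
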