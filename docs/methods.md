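# Methods

## Model and assumptions

The network is a DeepLabV3-flavoured encoder–decoder for binary (lesion vs
skin) segmentation. The input is an RGB image scaled to [0, 1]; the output is
one logit per pixel, and `sigmoid(logit) >= 0.5` (configurable threshold)
defines the predicted lesion mask. All convolutions use zero padding sized to
preserve spatial dimensions unless a stride is stated, so every block has a
checkable shape contract. The axis convention is NCHW, 0-based.

The backbone exposes two taps: mid-level at stride 8 and high-level at the
output stride (8 or 16; at 8 the last stage trades stride for dilation 2 in
the DeepLab manner). The decoder assumes the high tap — after the multi-scale
encoder block — is bilinearly ×2-upsampled inside the fusion block to meet
the mid tap, which fixes the tap strides at (8, 16) for the default
configuration. The fusion block's output (or, with fusion disabled, the
encoder output) feeds the grouped coordinate attention, then a 1×1 classifier
and bilinear upsampling to input resolution. The wiring order — multi-scale
block in the encoder, attention after fusion in the decoder — is the only
order consistent with each block's input contract.

Block-level choices where the design was genuinely open:

- **MDSDC.** The dual attention operates on the projected combined map
  (width `out_channels`), not on the raw 5-branch concatenation; this keeps
  the gates cheap and makes the final 1×1 conv a square projection. The
  text-described residual is included: `out = Conv(w_c⊙F + w_s⊙F + F)`.
  Every conv is followed by BN+ReLU except the two sigmoid-gated attention
  convs and the final projection (BN only), matching ASPP convention. The
  spatial gate consumes the concatenated channel-avg and channel-max maps.
  The FC reduction defaults to 16 (SE convention) and must divide
  `out_channels` — the width the bottleneck actually sees.
- **GGCAM.** One bottleneck (1×1 conv → BN → ReLU → 1×1 conv, then sigmoid)
  is shared across both pooling directions and all groups. Directional
  pooled avg and max profiles are summed, not concatenated, before the
  bottleneck. Groups default to G=4 with divisibility enforced; the
  bottleneck reduction defaults to 1 because per-group widths are already
  small. Gates are named for the axis they collapse and broadcast along it.
- **MHLFF.** Upsampling is bilinear, non-corner-aligned (the segmentation
  decoder convention). The high path's 1×1 conv reduces to `fused_channels`
  before the dilated 3×3, making the elementwise sum dimensionally
  consistent. No activation occurs inside either path; the single ReLU after
  the sum is the block's only nonlinearity.
- **Ablation switches.** A disabled multi-scale block is replaced by a 1×1
  projection to the same width (so the decoder contract is unchanged), a
  disabled fusion block bypasses the mid tap, and disabled attention is the
  identity. Parameter-count deltas between ladder variants therefore equal
  each block's own analytic count, which the tests assert exactly.

## Numerical core

The package carries its own array-valued reverse-mode autodiff engine
(`dmffnet.nn`): tape-based tensors over float64 NumPy arrays with the op set
a segmentation network needs. Convolution gathers the k² kernel-tap strided
views of the padded input and contracts with `einsum`; its adjoint scatters
tap contributions back with strided slice-adds. Bilinear resampling is a
separable pair of interpolation matrices (half-pixel centers, rows summing
to 1), so its adjoint is the transposed contraction; resampling a constant
map returns the constant exactly. Max reductions split ties evenly. Batch
normalization is composed from differentiable primitives; in training mode it
uses batch statistics (momentum 0.1 running updates, eps 1e-5), in eval mode
the running statistics. Every primitive is validated against central finite
differences at 1e-5–1e-6 tolerance in the test suite. Float64 throughout
makes CPU runs bit-reproducible for a fixed seed; there is no
platform-dependent threading nondeterminism.

Degenerate inputs are defined rather than undefined: a constant feature map
exports an all-zero heatmap (avoiding 0/0 in min–max normalization);
probability clamping at 1e-7 bounds the BCE loss; metric classes absent from
both masks score 1 (correctly predicted absence), absent from only one score
0; the poly schedule clamps to 0 with a warning past the final iteration;
non-finite activations abort the forward pass naming the offending block.

## Training protocol and parameters

Defaults follow the standard dermoscopy-segmentation recipe: 180 epochs,
batch size 8, input 512×512, SGD with momentum 0.9, initial learning rate
7·10⁻³ decayed by `(1 − it/max_it)^0.9` per iteration, augmentation by
random horizontal/vertical flips (p=0.5 each) and random crops of 0.8–1.0 of
each side (resized back), applied jointly to image and mask. Adam is
available as an alternative optimizer. Validation runs every epoch; model
selection is by validation MIoU; best and last checkpoints are written as
`.npz` state archives that embed the network configuration. Aggregate
metrics pool confusion counts over the dataset (micro-averaging), with
per-image rows reported alongside.

Desk-scale runs in the examples, tests, and acceptance script use the `tiny`
backbone at 64×64 (or 32×32) with narrower block widths, and the overfit
scenario — 8 synthetic images, 300 full-batch iterations — uses Adam at
lr 1e-3, the standard choice for a quick small-batch fit. These sizes are the
package's own desk-scale defaults; the full-size configuration above remains
available unchanged.

## Synthetic data: what it does and does not emulate

The generator produces, deterministically per (seed, index): a skin-toned
background with an illumination gradient and mild pixel noise; one lesion
whose boundary is an ellipse radially perturbed by 2–4 random sinusoidal
harmonics (amplitudes 0.03–0.12), filled darker and alpha-blended through a
Gaussian blur (σ = 2 px default) of its support; optional thin dark
polyline "hairs" (0–4 by default), drawn last so a zero count leaves the
render untouched; and a global contrast factor drawn from 0.6–1.0. The mask
is the sharp pre-blur support; the lesion area fraction is rejection-sampled
into 0.05–0.40 of the frame (error after 100 attempts). These ranges are
chosen to mimic typical dermoscopy framing: a single central-ish lesion
occupying a minority of the field, soft borders, moderate occlusion.

It does **not** emulate: multi-focal or highly eccentric lesions, color
variegation within a lesion, vignetting, ruler/gel artifacts, specular
highlights, or the full texture statistics of real dermoscopy. Passing tests
therefore demonstrate that the architecture, gradients, metrics, and
training loop are correct and that the network can fit lesion geometry of
this class; they say nothing about clinical-grade generalization, which
requires real datasets and full-scale training outside this package's scope.

## Accounting conventions

Parameter counts are exact sums of trainable array sizes. MACs are analytic:
`k²·C_in·C_out·H_out·W_out / groups` per convolution (output sizes recorded
during a probe forward pass) plus `in·out` per fully connected layer; FLOPs
are reported as 2·MACs and labelled as such, since the community is split on
the convention. Branch "weight counts" used in the parameter-economy checks
count convolution weights only (no BN or bias), which is the like-for-like
comparison between separable and dense branches.

## Known limitations

- CPU-only and float64: throughput is desk-scale; full 512×512, 180-epoch
  training is supported by the code but impractical without acceleration.
- Binary segmentation only (`num_classes=1` with sigmoid); no multi-class
  averaging, boundary-distance metrics, deep supervision, or test-time
  augmentation.
- No pretrained weights; both backbones initialize from a seed (He-normal).
- The `.npz` checkpoint format stores float64 state; files are a few MB for
  the default widths.
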