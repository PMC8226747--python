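# Methods

This note records the models, conventions, and numerical choices behind
`nucseg`, and what the bundled synthetic benchmark does and does not
demonstrate.

## Stain model and Macenko normalization

A transmitted-light H&E tile follows the Beer–Lambert law: with incident
intensity `I_t` (default 240), a pixel with stain concentrations
`c = (c_H, c_E)` has intensity `I = I_t · 10^(−M c)`, where `M` is the 3×2
matrix of the hematoxylin and eosin unit absorption vectors in RGB optical
density (OD) space. Conversion to OD, `OD = log10(I_t / I)`, therefore makes
stain mixing linear. Intensities are clamped to ≥ 1 before the logarithm so
OD stays finite, and negative OD (pixels brighter than `I_t`) clips to 0.

The per-tile stain basis is estimated by the Macenko procedure:

1. drop pixels with *any* OD channel ≤ β (default 0.15) — the strictest
   reading of "low OD" background removal; an all-channel rule is available
   via `NormalizationConfig.beta_rule`;
2. take the plane of the top-2 right singular vectors of the remaining OD
   cloud; a second singular value below 1% of the first raises a
   "degenerate stain plane" error (the 1% floor absorbs uint8 quantization
   noise, which alone contributes ≈0.4% relative spread);
3. project onto the plane, compute in-plane angles, and take the α-th and
   (100−α)-th percentile angles (α = 1 by default) as the robust extremes;
4. map the two extreme directions back to OD space, clip tiny negative
   components, renormalize. The vector with the larger red OD component is
   hematoxylin (hematoxylin absorbs red most strongly); green breaks ties.

Fewer than 100 surviving pixels raises an "insufficient tissue" error.

Normalization computes per-pixel concentrations against the tile's own basis
by least squares (negatives clipped to 0), rescales each stain channel so
its 99th percentile matches the reference maxima, and re-renders through the
reference basis. The reference basis is the canonical H&E OD matrix
(H = [0.5626, 0.7201, 0.4062], E = [0.2159, 0.8012, 0.5581]). The reference
maximum concentrations default to the canonical pair (1.9705, 1.0308) scaled
by 0.75: the scale was chosen once so that the standard appearance of a
typical tile centers near the 8-bit midpoint (127), which is how normalized
histograms are expected to look; both the basis and the maxima are
configurable (YAML or a user reference image).

## Network

The segmentation network is a VGG-style encoder–decoder with residual skip
connections: four encoder blocks of (2, 2, 3, 3) conv(3×3)+BN+ReLU units
with channel widths (64, 128, 256, 512), each followed by a 2×2 stride-2
max-pool; a mirrored decoder preceded by max-unpooling; and a final 3×3
conv+BN down to 2 channels followed by a pixel softmax — 20 convolution
layers and 15,279,174 trainable parameters in total. The skip link of block
*n* carries the activation of the block's *first* encoder conv unit and adds
it element-wise (identity mapping, no learned projection) to the output of
the decoder block's second-to-last conv unit, just before the block's final
conv. Channel concatenation and no-skip variants exist for ablations;
identity addition is weight-free, so add and none variants have identical
parameter counts, while concatenation widens the conv that follows each
sink.

Conventions fixed where the design was open:

- **Unpooling** uses the argmax indices recorded by the paired encoder
  max-pool (the network's SegNet lineage); plain nearest-neighbour 2×
  upsampling is available as `unpool_mode="nearest"`.
- **Odd sizes**: pooling floors (125 → 62) and the unpool restores the
  recorded pre-pool size (62 → 125), which is what makes the 500×500 trace
  close exactly. Inputs must be ≥ 16×16 to survive four pooling stages.
- **Classifier unit**: the output row's parameter count fixes conv+BN; no
  ReLU is applied before the softmax (a ReLU there would zero both logits
  on confident-background pixels and stall their gradient).
- **Initialization** is fan-in-scaled normal (std `sqrt(2/fan_in)`), seeded;
  biases and BN shifts start at zero, BN scales at one.
- **Width multiplier** — an extension for desk-scale work — scales every
  hidden width (never the 3-channel input or 2-channel output).

The implementation is a small numpy layer framework (NHWC, float32; float64
for gradient checks): im2col+GEMM convolution with the input gradient
computed as a second GEMM against the flipped transposed kernel, spatial
batch norm (momentum 0.1 running statistics for inference), max-pool with
int8 window-argmax indices, and explicit reverse-order backpropagation.
Conv biases are retained even though batch norm makes them redundant (their
gradient through BN is exactly zero) because the reference parameter ledger
counts them.

## Training

Defaults follow the reference training recipe: Adam (β₁ = 0.9, β₂ = 0.999), learning
rate 1e-4, batch 4, 30 epochs, L2 5e-4, gradient threshold 8. Choices made
where the recipe is silent:

- Cross-entropy uses the natural logarithm, computed per pixel over all
  pixels of the batch (M = batch pixels), probabilities clamped to
  [1e-7, 1 − 1e-7]. Soft-Dice and focal (γ = 2, α = 0.25) losses are the
  ablation alternatives.
- The gradient threshold is applied as global L2-norm clipping of the
  concatenated gradient vector (per-element clamping via
  `clip_mode="element"`); clipping happens after the L2 term is added and
  before the Adam moment update.
- L2 regularization applies to convolution kernels only, not biases or BN
  parameters (the usual framework convention).
- No class weighting by default, despite background/nucleus imbalance;
  per-class weights are exposed in `TrainConfig`.
- Images are scaled to [0, 1]; shuffling and initialization derive from the
  config seed, so runs are bit-reproducible.
- Ties at exactly 0.5/0.5 in mask prediction resolve to background.

## Offline augmentation

Both presets are fixed pipelines (no per-epoch randomness): grid-crop every
tile, h-flip the crops, v-flip crops+h-flips (16 per tile), then fixed
translate/crop/resize passes over that base set. Translating by (dx, dy)
and discarding what leaves the canvas equals cropping the surviving
(H−|dy|)×(W−|dx|) window, which is then resized back (bilinear for images,
exact nearest-neighbour index mapping for masks, so labels never
interpolate). The 1000×1000 preset (crop 500 @ stride 500; translate
+10/+10, then −5/−5 and +5/+5 each with h-flips) yields 96 outputs per tile;
the 512×512 preset (crop 502 @ stride 10, resized back to 512 so all
outputs share one shape; translate +5/+5 and −5/−5) yields 48. The counts
are content-independent. The reference recipe description says "random
translation" but then lists exact offsets; the fixed offsets reproduce the
reference ledger, and a seeded random-offset mode can be composed from
`TranslateCropResize` steps directly.

## Metrics

Instances come from 8-connected components of the binary network output (no
postprocessing), labeled in raster order of first pixel. The 50% object
criterion is read as IoU ≥ 0.5 — under which matching is effectively unique
— with a ≥50%-of-GT-coverage rule available (`rule="gt-coverage"`).
Matching is greedy on descending IoU, one-to-one, ties broken by (gt, pred)
id. AJI walks ground-truth instances in id order, pairs each with the
still-unused prediction of maximal Jaccard (ties to the lower pred id), and
divides summed matched intersections by summed matched unions plus all
unmatched pixels on both sides; the standard union-form denominator is
used. Degenerate conventions: two empty masks score Dice = AJI = 1; zero
denominators in precision/recall/F1 give 0. Tests verify both greedy
procedures against brute-force oracles (exhaustive matching enumeration and
plain set arithmetic) on small random masks.

## Synthetic tiles

The simulator emulates 40× H&E tiles through the same Beer–Lambert model
the normalizer inverts. Nuclei are rotated ellipses (semi-axes 4–10 px,
uniform rotation), placed by rejection sampling: a candidate overlapping
more than `overlap_fraction` (default 0.1) of its own area with existing
nuclei is rejected; overlap pixels belong to the later instance. Counts are
Poisson with areal density 7e-4 nuclei/pixel (≈700 on a 1000×1000 tile,
typical of multi-organ benchmark tiles). Masks are exact: membership is the
ellipse inequality evaluated at pixel centers.

The extranuclear tissue is a smooth field (Gaussian-blurred noise, blur
radius 8% of the short side, rescaled to [0, 1], raised to a per-slide
`sparsity` exponent) modulating eosin between 0.05 and a per-slide ceiling
(0.9–1.15) plus a weak cytoplasmic hematoxylin uptake (0.02–0.15) — real
cytoplasm takes up some hematoxylin, and that co-uptake is also what keeps
dense-tissue pixels above the β threshold. Nuclei draw per-instance
hematoxylin levels in 0.9–1.4 and weak eosin 0.05–0.15. Slide styles jitter
the canonical basis component-wise (sd 0.05) and draw sparsity
(log-uniform 0.6–1.8), overall staining intensity (log-uniform 0.85–1.25),
and sensor noise sd (2–4 intensity levels); per-pixel lognormal
concentration jitter (σ = 0.08) supplies texture.

What this does not emulate: chromatin texture inside nuclei, touching
nuclei with shared boundaries and occlusion, organ-specific morphology,
out-of-focus regions, and non-H&E artifacts (folds, pen marks). Passing the
bundled benchmarks therefore demonstrates implementation correctness and
end-to-end learnability, not clinical-grade accuracy on real slides.

## Scaled-down end-to-end benchmark

The recovery experiment trains the quarter-width network (≈0.96 M
parameters) for 15 epochs on 200 seeded 128×128 tiles (batch 4, 750 Adam
steps — fully on CPU) and evaluates 60 held-out tiles: held-out pixel Dice
≥ 0.80 and object F1 ≥ 0.70 at the fixed seed. Sixty evaluation tiles keep
the mean object F1 stable (its per-tile spread is large because merged
touching nuclei are scored per instance). These problem sizes are the
package's desk-scale benchmark; full-scale training on real 1000×1000
datasets is out of scope here and would follow the same code paths with the
full-width spec and 30 epochs.

## Known limitations

- The numpy network trains on CPU only; full-width training on real
  datasets is impractical without a GPU framework backend.
- Macenko estimation needs both stains present; very pale or single-stain
  tiles raise errors by design rather than returning a wrong basis.
- The augmentation presets assume the reference datasets' native tile sizes (2×2 crop
  grids); other geometries need custom recipes.
- Whole-slide (pyramidal) images and magnifications other than 40× are not
  handled.
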