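# Methods

## Problem setting

Berry number is the dominant driver of grapevine yield, and automated
counting from field imagery systematically undercounts because leaves
occlude part of every bunch. `leafless` treats the problem as a domain
transfer: images taken before defoliation (berries partly hidden) form
an *occluded* domain, images of the same canes after defoliation form a
*non-occluded* domain, and a conditional GAN learns the mapping from the
first to a plausible member of the second. Counting then runs on the
generated, revealed scene instead of the occluded one.

All per-pixel semantics ride on the three-class *berry mask*:
background = 0, berry-edge = 127, berry = 255. The edge class separates
touching berries so that connected components of the berry class are
individual berries.

## Pipeline components

### Registration and patching (`align`)

The two acquisition passes differ by an approximate planar similarity.
A 4-parameter Helmert transform (scale *s*, rotation θ, translations
t_r, t_c) is estimated from manually clicked keypoint pairs. With the
substitution a = s·cosθ, b = s·sinθ the model is linear in its
parameters, so the estimate is a closed-form least-squares solution and
is exact (to numerical precision) whenever the correspondences are
consistent with a single similarity. Images are resampled through the
inverse map — bilinear for grayscale, nearest-neighbour for masks so
the label alphabet {0, 127, 255} survives — and out-of-source pixels
are filled with black. RGB is collapsed to grayscale with ITU-R BT.601
weights (0.299/0.587/0.114; configurable), making the method
independent of berry colour. Patches are carved with a sliding window
(default 656 px window, 162 px stride), keeping only fully interior
windows.

### Synthetic occlusion (`occlusion`)

Aligned natural pairs are too scarce and too imprecisely registered to
train on, so occluded partners are synthesised from non-occluded
patches: a leaf template (grayscale texture + binary alpha) is rotated
by an angle drawn from {−50, −30, −10, 0, 10, 30, 50, 70} degrees and
overlaid opaquely. In the mask, covered pixels become background, and a
closure band of berry-edge pixels (width 3 px by default) is laid where
the leaf abuts surviving berry pixels, so cut berries keep closed,
countable contours. The band is implemented as morphological dilation
of the surviving berry pixels into the footprint, clipped to the
closure width.

Leaves are split disjointly into 18 training and 6 test templates; each
training patch receives up to 9 occluded versions, each test patch up
to 3. A pair is kept only if the non-occluded mask's non-background
fraction strictly exceeds 1/24 and the occluded mask retains at least
one non-background pixel. The fraction rule is stated ambiguously in
the field (background vs non-background); the non-background reading is
the default because the literal background reading is satisfied by
almost any patch, and the literal variant remains available behind a
flag. Placement is uniform over offsets that keep at least 25% of the
footprint on the patch (configurable); opaque overlay is assumed since
no blending rule is specified anywhere.

### Toy data

No vineyard imagery is redistributable with the package, so a toy
generator emulates the relevant structure: bright near-circular berries
(default radius 6–9 px, intensity 170–235) in a bunch on a darker
background (intensity 20–60, Gaussian noise σ = 4), with interiors
labelled berry and 2 px edge rings, placed by rejection sampling with
non-overlapping outer disks. Default geometry guarantees every planted
berry passes all counting filters, so planted counts are exactly
recoverable on noiseless scenes — the property the tests exploit.
When a requested berry cannot be packed it is skipped and the returned
planted count reflects what was rendered (`strict_packing=True` raises
instead). Toy leaf templates are lobed random polygons.

What the toy data does *not* emulate: berry-on-berry occlusion, blur,
uneven illumination, segmentation errors in the reference masks,
misregistration between domains, and dense multi-leaf canopies.
Passing toy-scale tests therefore demonstrates correctness of the
machinery and the expected qualitative behaviour of the method, not
field-level accuracy.

### Domain transfer (`pix2pix`, `nn`)

The translator is a Pix2Pix-style conditional GAN over stacked
grayscale+mask channels (mode `GB`; mode `B` uses the mask alone). The
generator is an encoder–decoder with skip connections; the
discriminator is a patch classifier emitting a score map over local
receptive fields. Both adversarial terms are least-squares losses:

    l_D = ½ (l_MSE(D(x, x̃_non); 0) + l_MSE(D(x, x_non); 1))
    l_G = l_MSE(D(x, x̃_non); 1) + λ · l1(x_non, x̃_non),   λ = 100

The discriminator *minimises* l_D; the generator's adversarial target
is the real label, the standard least-squares-GAN convention and the
only coherent reading of the loss pair. The L1 term dominates and is
what drives faithful reconstruction; the adversarial term sharpens
output statistics.

Training uses Adam (β₁ = 0.5, β₂ = 0.999 — the established convention
for this architecture; not separately tuned here), learning rate
0.0004 held constant for the first half of training and decayed
linearly to zero over the second half (full-scale schedule: 600 epochs,
constant for 300; `lr(e) = lr0 · (E − e)/(E − E_c)` for e ≥ E_c, which
is continuous at the boundary and extrapolates to exactly zero at
epoch E). Per-epoch augmentation resizes each pair with
nearest-neighbour interpolation (286 full scale, 72 toy scale), applies
one shared random crop (256 / 64) and one shared flip (probability 0.5,
mirror about the vertical axis; the axis is configurable because the
convention is ambiguous), and maps intensities affinely to [−1, 1]. At
test time only the affine scaling is applied. Generated output is
mapped back to [0, 255]; the mask channel is then thresholded
([0, 50) → 0, [50, 180) → 127, [180, 255] → 255; boundary pixels to the
higher class so the binning is total and idempotent) before any
counting.

The network engine is a small in-package implementation: im2col-based
strided convolutions and their adjoint transposed convolutions,
instance normalisation, leaky-ReLU/ReLU/tanh, and Adam, all in float32
NumPy with manual backpropagation, verified layer-by-layer against
central finite differences. An optional decoder variant replaces
transposed convolutions with bilinear upsampling + 3×3 convolution to
suppress checkerboard artifacts; it is off by default. Training is
bit-deterministic given the seed.

Toy-scale model: 64×64 crops, base width 16, three encoder levels plus
bottleneck (features 32→16→8→4 px), batch size 4. These sizes were
chosen once as the smallest configuration that cleanly learns the toy
task; the full-scale 286/256 settings remain the constructor defaults.

### Counting (`counting`)

Counting runs on berry-class pixels only (8-connected by default;
configurable). Every component must pass four filter stages, evaluated
in order, with the first failing stage recorded:

1. **size** — area ≥ 25 px;
2. **shape** — minor/major axis ratio ≥ 0.3, axes taken from the
   eigenvalues of the second central moment matrix scaled to
   equivalent-ellipse full lengths (a 1/12 per-pixel variance term
   keeps thin regions from degenerating; single pixels report both
   axes as 1);
3. **fill** — area ≥ 0.5 · πr² with r = (minor + major)/4, i.e. the
   component must fill at least half the circle implied by its mean
   semi-axis. The 0.5 fraction is an exposed default: the upstream
   description says only that the actual area is compared to the
   expected area;
4. **edge support** — at least half the component's boundary pixels
   (pixels with a 4-neighbour outside the component) must have a
   berry-edge pixel in their 8-neighbourhood. This operationalises
   "well surrounded by an edge"; the threshold is exposed.

Per-berry size statistics report the pixel area and the
equivalent-circle diameter 2·√(area/π), the only diameter definition
consistent with the reported area.

### Evaluation (`evaluation`)

Because the method promises a *plausible* scene rather than the true
one, pixel-exact comparison is the wrong yardstick; the harness
computes:

- **Occluded-domain reconstruction** — the generated output is
  re-occluded with the exact leaf that built the input; visible pixels
  must ride through the translation unchanged. By construction the
  reconstruction matches the true input exactly on the footprint away
  from the closure rim; inside the ~3 px rim the closure bands may
  differ when the generated berries differ near the leaf boundary,
  which is also where deviations concentrate in practice.
- **Mask similarity** — Pearson correlation (on raw label values by
  default; a one-hot-plane mode weights classes equally), per-class IoU
  (empty union defined as 1 — both masks agreeing the class is absent —
  so per-patch aggregation stays NaN-free), binary IoU after merging
  berry and berry-edge, and categorical *generation maps* that separate
  the acceptable berry↔edge confusions from the non-acceptable
  transitions involving background.
- **Counting accuracy** — counts on occluded inputs and generated
  outputs against the reference count, summarised by the coefficient of
  determination against the identity line (R² = 1 − SS_res/SS_tot with
  residuals taken from y = x; an OLS variant is available) and by the
  distribution of relative deviations (count − ref)/ref, histogrammed
  at 2% bin width (correlation histograms use 0.01 bins).

Every aggregate is recomputable from per-patch artifacts written to
disk.

## The toy benchmark

`leafless.benchmark.run_toy_benchmark` runs the whole chain from one
seed: 30 toy scenes → ~215 training / ~18 test pairs (24 toy leaves,
18/6 split, 9/3 multiplicity, admissibility filtering) → 30 training
epochs at toy scale → evaluation on the test split. The run takes a few
minutes on one CPU. The benchmark's claim is directional: counts on
generated outputs sit closer to the reference than counts on occluded
inputs (smaller mean |relative deviation|, at-least-as-high R²), and
the generator's L1 component falls over training.

## Numerical choices and degenerate inputs

- Thresholding bands are half-open with boundary pixels to the higher
  class; the mapping is total and idempotent.
- Correlation on constant inputs raises (undefined) rather than
  returning a sentinel; R² requires non-constant references.
- IoU: empty union → 1.0; empty intersection with non-empty union → 0.
- Component axes: eigen-decomposition of a symmetric 2×2 matrix;
  eigenvalues are clipped at zero before the square root.
- All randomness flows through `numpy.random.Generator` objects seeded
  from a single master seed; datasets, scenes, training and evaluation
  are reproducible bit-for-bit.

## Known limitations

- The toy benchmark's occlusion signal is mild (single leaf per patch,
  mean |relative count deviation| of occluded inputs of a few percent);
  conclusions about heavy-canopy regimes cannot be drawn from it.
- The counting filter stages 3 and 4 are principled operationalisations
  of qualitative descriptions, with exposed thresholds, not re-derived
  constants.
- The discriminator contributes little at toy scale where the L1 term
  dominates; adversarial dynamics (mode collapse, artifact textures)
  only become interesting at full scale, which this package does not
  attempt on CPU.
- No pretrained weights ship with the package, and the upstream
  segmentation network that produces berry masks for natural imagery is
  out of scope: masks are inputs (real pipeline) or synthesised (toy
  pipeline).
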