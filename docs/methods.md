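# Methods

`octvessel` quantifies the self-organized microvascular network of a 3D
in-vitro blood–brain-barrier (BBB) construct from optical coherence
tomography (OCT) image stacks.  The construct is a fibrin hydrogel in a
transwell insert: endothelial cells, pericytes and astrocytes form tubular
lumens inside the gel, and an endothelial monolayer seals the gel bottom,
so lumens reaching the bottom surface are *open* — perfusable from the
basolateral compartment — while lumens floating inside the gel are
*closed*.  A permeability assay sees only the open structures; their total
endothelial surface area `A` converts a measured permeability–surface-area
product into the effective permeability coefficient `Pe = PSe / A`.

## Stack geometry and preprocessing

OCT acquires the sample as a *y*-stack of x-z cross-sections (B-scans):
600 frames of 600 × 60 px at 10 µm/px laterally and 10 µm frame spacing.
Analysis uses the converted geometry — a *z*-stack of x-y frames — and the
conversion is the pure index transpose `out[z, y, x] = in[y, z, x]`; no
voxel is interpolated anywhere in the pipeline.  Row 0 of each
cross-section is taken to be the gel bottom, so frame 0 of the converted
stack is the bottom surface; all depths are measured from it.

Because scattering blurs OCT images progressively, microvessels are rarely
visible past 300–350 µm; stacks are truncated with strict floor semantics
(`floor(max_depth / spacing)` frames, default 350 µm → 35 frames).

Contrast preprocessing is classic histogram equalization,
`out = (cdf(v) − cdf(v_min)) / (1 − cdf(v_min))`, computed **per frame**
by default: the depth-dependent brightness decay means one stack-wide map
would trade deep-frame contrast for surface-frame contrast.  A pooled
per-stack map is available (`per_frame=False`).  Constant frames are
returned unchanged (degenerate CDF).  Equalization is rank-based and
therefore idempotent up to quantization, and it preserves within-frame
intensity ordering.

Intensities live in [0, 1] internally; TIFF round-trips restore the source
integer dtype exactly.  Binary masks are written as 8-bit {0, 255}.

## Synthetic phantom

No public OCT datasets of this construct exist, so every stage is
validated on a synthetic phantom that emulates the acquisition: bright
tissue whose mean level decays as `exp(−depth / depth_decay_um)`
(default e-folding 150 µm), multiplicative log-normal speckle with unit
mean (`sigma` default 0.3 — speckle is the natural noise model for
coherent imaging), dark circular lumen cross-sections along
monotone-in-z centerlines, a bright culture-insert edge ring at
r = 250 px, a dark central depression spanning the first ~5 frames
(the interfacial-tension dimple of the hydrogel), and per-frame Gaussian
blur growing linearly with depth (`1 px + 0.05 px/frame`).

Open tubes anchor at frame 0 and never extend past 350 µm; closed tubes
float inside the gel.  Default scene: 5 open + 2 closed tubes with radii
drawn uniformly from 20–40 µm.  Two rasterization choices keep the
analytic truth representable on the grid: tube radii snap to whole pixels
(the imaging grid cannot express sub-pixel radii), and centerline anchors
and jitter move in whole-pixel steps — off-grid discs digitize differently
from frame to frame, with perimeter errors up to −21% at 2 px radius,
which would make the stated recovery tolerances unattainable under any
estimator.  The recorded truth per tube is the exact voxel mask, the
cylinder diameter `2r` and the lateral area `π·d·h` with
`h = frames spanned × spacing`.

What the phantom does **not** model: OCT speckle correlation and the
physics of coherent imaging, branching/anastomosing vessel trees,
non-circular lumen cross-sections, tissue heterogeneity, and refraction
artifacts.  Passing recovery tests therefore demonstrates correctness of
the measurement chain on idealized tubes, not detector performance on real
tissue.

## Morphological detector (MIP)

Per frame: Gaussian blur (σ = 1 px) → local-mean adaptive threshold
(block 51 px, subtractive offset) → inversion so the dark lumens become
foreground → erosion (disc r = 2 px) → opening (disc r = 2 px) →
8-connected component area filter (10–5000 px) → intersection with the
region-of-interest mask.  The erosion radius default of 2 px compensates
the point-spread dilation of dark lumens at the 10 µm/px sampling; with
1 px the detected blobs remain systematically larger than the true
cross-sections and mid-depth agreement saturates near κ ≈ 0.5.

The ROI mask removes the two structures that defeat thresholding: the
bright insert-edge ring (a centered disc of r = 250 px is kept) and the
central surface depression (a per-frame tissue-presence mask).  Tissue
presence is a stated reconstruction: Otsu's threshold on a blurred copy
(σ ≈ 1% of the frame diameter), falling back to half the median when Otsu
latches onto the ring on uniform frames; enclosed holes smaller than 5% of
the frame (lumens) are refilled; the largest connected region is kept.

The threshold offset is the one parameter calibrated against reference
ground truth: a grid search maximizing mean per-frame Cohen's kappa, ties
broken toward the smaller absolute offset.

## Random-forest pixel classifier (RF)

A re-implementation of the trainable-segmentation concept: per-pixel
features (raw intensity plus Gaussian, gradient magnitude, Laplacian of
Gaussian, difference of Gaussians and local variance at σ = 1, 2, 4, 8 px;
21 features by default), a 100-tree random forest trained on sparse
lumen/background labels, probability threshold 0.5, and morphological
closing (disc, default r = 2 px) as post-processing.  Label refinement
retrains on the union of previous labels and corrections with the same
seed.  Everything is deterministic under a fixed seed.  The documented
failure mode — a classifier trained on one contrast polarity applied to
the opposite one — is reproduced in the tests.

## Patch plumbing and external detectors

Image-translation networks operate on 256 × 256 patches, so frames are
split into the minimal uniform covering grid: `ceil(dim/256)` patches per
axis with offsets evenly spaced from 0 to `dim − 256` (rounded) — 3 × 3
patches at offsets {0, 172, 344} for 600-px frames.  Stitching averages
overlapping pixels and, for binary output, thresholds at 0.5 with ties
counting as foreground; `stitch(split(f)) == f` exactly.  Flip
augmentation emits original + horizontal + vertical flips (3×; the 180°
rotation is available behind a switch).  The network itself is out of
scope: any producer of per-frame probability maps (files or a callable)
plugs in through `external_segment`, which validates geometry and applies
the ≥ 0.5 rule.

## Evaluation

Per-frame agreement with ground truth uses binary Cohen's kappa,

    κ = 2 (TP·TN − FN·FP) / ((TP+FP)(FP+TN) + (TP+FN)(FN+TN)),

equal to `(p_o − p_e)/(1 − p_e)`.  Frames where both raters are constant
have an undefined κ and score 0, flagged rather than dropped.  A variant
without the factor 2 (which scores 0.5 at perfect agreement) exists purely
for auditing against sources that print that form.  Depth profiles place
frame *i* at depth `i × spacing`; the cross-dataset summary reports the
grand mean over all frames with min/max over per-dataset means.
Detector-vs-truth equivalence of summary measurements (counts, areas,
diameters) uses a two-sided paired t-test; zero-variance differences
return p = 1 with a warning, since such data carry no evidence either way.

## 3D quantification

Lumen masks are labelled with 3D connected components (26-connectivity by
default; 6 and 18 available).  A component is open iff it has a voxel in
frame 0; because segmentation dropout at the very bottom frame would
misclassify an open vessel, the anchor can be widened to the first N
frames (`anchor_frames`).

**Diameter** is the per-frame minimum caliper (min Feret) width of the
component's cross-section, averaged over occupied frames and scaled by the
pixel pitch.  The caliper projects pixel centers onto 180 directions and
adds one pixel for the pixel footprint.  The +1 px correction is
deliberate: the bare center span under-reads digitized discs (a radius-2 px
disc spans only 2.83 px across its diagonal), beyond the one-pixel
tolerance the truth recovery is held to, while with the correction every
whole-pixel radius from 2 to 10 px lands within 0.9 px of its continuous
diameter and a single pixel measures exactly 1 px with no special floor
rule.

**Lateral surface area** is the per-frame cross-section perimeter × pixel
pitch × frame spacing, summed over occupied frames — a Riemann sum of the
tube's side-wall area generalizing "circumference × number of frames" to
varying cross-sections.  The default perimeter estimator is the mean of
the 4-direction Crofton intercept estimate and the classical weighted
pixel-edge count: on digitized convex sections the two err in opposite
directions (Crofton over-reads staircase inflation by up to +11% on a
3-px-radius disc; the edge count under-reads cut corners by up to −10% at
2 px), and their mean stays within ~7% down to 2 px radius.  Both pure
estimators remain selectable (`estimator="crofton"` / `"edge"`).

`Pe = PSe / A` is provided as a helper on the summed open surface area.

## Problem sizes and numerical conventions

Validation runs use the full acquisition frame size (600 × 600 px,
35 frames) for the geometry, recovery and detector benchmarks, and
miniature 64-px stacks for unit tests.  The detector-floor benchmark uses
the noise-free phantom (speckle σ = 0): rank-based equalization stretches
the darkest tissue tail toward the lumen intensity range, so even 5%
multiplicative speckle halves mid-depth κ — a real limitation of the
morphological chain on speckled data, consistent with its mediocre
performance on real OCT stacks.  Tie rules: binary stitching maps 0.5 to
foreground; calibration ties go to the smaller |offset|; κ of degenerate
frames is 0.  Random-forest and phantom randomness are fully seeded.

## Known limitations

- The tissue-presence heuristic inside the ROI mask is a reconstruction;
  its constants (Otsu fallback, 5% hole-fill fraction) are tuned to the
  phantom's geometry proportions and may need adjustment for other
  insert/depression geometries.
- Open/closed classification keys on frame 0 only (configurable anchor);
  a detector that misses the bottom frame of a vessel demotes it to
  closed.
- Surface-area and diameter estimators are documented conventions on
  digitized shapes; sub-pixel vessels (radius < 2 px) are outside their
  validated range.
- The pipeline assumes one cross-section per vessel per frame (monotone
  tubes); branching networks are not modelled.
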