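# Methods

This note documents the models and procedures implemented in
`chromoseg`, the parameters that matter, the synthetic data the tests
run on, and the design choices taken where the underlying methods are
conventionally interactive or under-specified.

## Inputs and conventions

Inputs are single-channel 8/16-bit multi-page TIFF z-stacks, axis order
(z, y, x), 0-based. Voxel size (dz, dy, dx) in µm may come from an
argument or TIFF metadata; when unknown it defaults to (1, 1, 1) and
areas are reported in px² (a `units` column makes the fallback
explicit). Both pipelines segment 2D z-projections, not volumes:
chromocenters are thin relative to slice spacing (0.35–0.43 µm against
0.05–0.1 µm pixels in typical acquisitions), so a maximum projection
retains them while keeping every downstream object 2D. Annotation masks
are tri-level 8-bit images — 0 background, 128 nucleus, 255
chromocenter — with the invariant that every 255 pixel lies inside a
nucleus region.

## Classical pipeline

**Nucleus detection.** The projection (max by default; population-std
available) is median-filtered over a disk (default radius 2 px; the
radius is a config knob, as the appropriate value depends on noise
grain), thresholded by minimum cross entropy, hole-filled, and filtered
to regions ≥ `min_area` (default 500 px, which rejects debris and
plastid-sized blobs at typical magnifications). Components are
4-connected to avoid diagonal bridges between adjacent nuclei.

The minimum cross-entropy threshold (Li & Lee) minimizes
`−m_low·log µ_low − m_high·log µ_high` over candidate thresholds t,
where m and µ are the summed and mean intensity of the classes
`{g < t}` and `{g ≥ t}`; a class with zero summed intensity contributes
nothing. The implementation scans the full integer grid (all 256 levels
for 8-bit) via histogram cumulative sums, breaking ties toward the
lower threshold for determinism; an exhaustive per-pixel recomputation
of the objective serves as the test oracle. A constant image has no
two-class reconstruction and raises a degenerate-histogram error.

**Touching nuclei** are split by a marker watershed on the Euclidean
distance transform, with markers at distance-transform maxima separated
by at least `0.5·√min_area` — a separation scale tied to the smallest
admissible nucleus, so the splitter cannot fragment a single nucleus
into pieces smaller than the area filter would keep.

**Curation** replaces interactive ROI editing with a JSON edit list:
label ids to remove and polygons (pixel-vertex lists) to add. Additions
are rasterized, must not overlap existing nuclei, and are tagged
`added` against the detector's `auto`; labels are renumbered
consecutively, survivors first.

**Chromocenter segmentation.** Per nucleus, the stack is cropped around
the ROI (15% margin), and the largest eigenvalue of the 3D structure
tensor is computed: Gaussian-derivative gradients at `sigma_grad`
(default 1 px) form the outer-product tensor, smoothed componentwise at
`sigma_int` (default 3 px), whose top eigenvalue per voxel highlights
strong local intensity variation. The z-derivative is scaled by dx/dz
so anisotropic stacks contribute physically comparable gradients; a
single-slice stack degenerates cleanly to a 2D tensor. The feature is
z-projected (max) and segmented by a batch H-watershed.

The H-watershed exposes the three controls of its interactive
ancestor as parameters: `h` (seed dynamics threshold — a maximum
survives if it stands at least h above the highest saddle linking it to
a higher peak; `h_rel` expresses h as a fraction of the in-mask
intensity range), `intensity_threshold` (a floor below which no pixel
is labeled), and `peak_flooding` (each region truncated to pixels ≥
(1 − pf/100) of its peak). By convention the global maximum's dynamics
equals the in-mask range, so `h_rel = 1` suppresses every seed. The
neutral defaults (h = 10% of range, floor 0, flooding 100%) reproduce
the plugin's out-of-the-box behaviour — flooding 100% partitions the
whole mask — so quantitative use sets a flooding around 30–50%; the
analysis settings used throughout the examples and acceptance runs are
`h_rel = 0.10`, `peak_flooding = 30`, `sigma_int = 1`.

Because the tensor feature responds to the *edges* of foci (and to the
nuclear envelope), two mitigations apply: the nucleus mask is eroded by
`mask_erosion` px (default 2) before seeding, excluding rim responses,
and segmented outlines still run slightly generous — measured HF from
the classical pipeline sits above the generating ground truth. Relative
comparisons between conditions are unaffected, which is why
heterochromatin phenotyping should always be read against an internal
control group measured with identical settings.

## Morphometrics

Per nucleus, on the maximum projection of the raw stack: nucleus area,
CC count, per-CC RAF, HF = ΣCC/nucleus area, RHI = mean CC intensity /
mean nucleus intensity, RHF = HF × RHI. The nucleus mean *includes* CC
pixels (the denominator is the whole nucleus); with that convention
RHF collapses algebraically to (total CC intensity)/(total nucleus
intensity), an identity the tests verify to 1e-9 together with
Σ RAF = HF and invariance of all three ratios under intensity
rescaling. A nucleus with no detected CC reports HF = RHI = RHF = 0 and
cc_count = 0 rather than missing values, so group statistics never drop
nuclei silently.

## Mask comparison

Whole-mask agreement is the Dice coefficient 2|A∩B|/(|A|+|B|), with
dice(∅, ∅) = 1 (perfect agreement on absence). Object-level agreement
pairs labels greedily by descending pixel overlap, each object used at
most once, ties broken by label id; unmatched objects carry Dice 0.
Greedy matching is deterministic and auditable; on segmentation-like
instances (each object overlapping its counterpart most) it attains the
exhaustive max-total-overlap assignment, which the tests verify by
brute force on small instances. Adversarial overlap structures where
greedy is suboptimal exist but do not arise when comparing
segmentations of the same scene.

## Learned cascade

Three U-Nets (encoder–decoder with skip connections, 3×3 convolutions,
ReLU, 2× max-pool / nearest-upsample, sigmoid output) run in sequence:

1. *Region proposal*: trained on whole downscaled fields against the
   union of dilated nucleus masks; its thresholded heatmap's connected
   components become bounding boxes (15% margin), each intended to
   contain one nucleus. Mask-then-box is simpler and better determined
   than box regression at these training-set sizes.
2. *Nucleus segmentation*: per-fragment (box crop resized to the model
   input, bilinear for intensities, nearest for masks, per-image
   min–max normalization to [0, 1]).
3. *Chromocenter segmentation*: same fragments; its mask is intersected
   with the nucleus mask, so the tri-level containment invariant holds
   by construction. Training fragments default to ground-truth nucleus
   boxes (predicted boxes are also supported).

Heatmaps are per-pixel object probabilities in [0, 1]; binarization
uses 0.5 by default so no human decision enters the cut, and lowering a
threshold can only grow the corresponding mask (monotonicity). Preset
couples (nucleus, CC) = (0.5, 0.5), (0.5, 0.25), (0.8, 0.2) are
provided because chromocenter sensitivity benefits from a lower cut
when foci are faint. Fragment predictions are mapped back through the
inverse resize and overlapping fragments merge by pixelwise maximum
probability — deterministic and order-independent.

The network is implemented directly in NumPy — im2col convolutions,
hand-derived backpropagation (verified against central finite
differences in the tests), Adam (lr 3e-3 default), and a combined
binary-cross-entropy + soft-Dice loss, which keeps gradients alive on
the small foregrounds chromocenters present. Everything is float32 and
seeded: a fixed config reproduces initial weights and the training
history bit for bit on one machine. Checkpoints are single `.npz`
archives with the config embedded as JSON. Augmentation (flips, 90°
rotations, ±15° rotations, intensity scale/γ, additive noise) applies
identical geometric transforms to image and mask with nearest-neighbour
mask interpolation, and is seeded.

Desk-scale configuration: depth 2, 8 base filters, 64×64 inputs, batch
8, 10 epochs, 64 training fragments (~33k parameters, under a minute
per stage on one CPU core). This is deliberately small — large enough
for the synthetic task, small enough that the full train/evaluate cycle
runs inside a test suite.

## Synthetic scenes

The generator renders fields of elliptical nuclei (default 256×256,
7 slices, 8-bit; background ≈ 6, nucleoplasm ≈ 70 with a smooth ±8%
texture; a Gaussian axial profile stands in for the through-focus
falloff) containing soft-edged disk-shaped foci at a configured
contrast, plus optional touching pairs (p = 0.2), sub-threshold debris
blobs outside nuclei (p = 0.3), and Gaussian (σ = 2) + Poisson
(scale 0.5) noise added last. Ground truth — tri-level mask and full
morphometric records — is computed on the noiseless rendering, so it is
exact up to 8-bit rounding of the written image.

Phenotype presets encode the qualitative regimes of interest: `light`
(8–10 conspicuous foci, contrast 2.5), `dark` (4–8 fainter foci,
contrast 1.4, larger nuclei), `ddm1` (4–8 small foci, contrast 1.6,
small nuclei). Each preset also carries a target RHF band (0.15–0.18,
0.08–0.11, 0.05–0.08 respectively, typical of published measurements in
the corresponding conditions); focus radii are rescaled per nucleus so
the analytic RHF — using RHI ≈ c/(1 + HF(c−1)) at contrast c — lands in
the band. Correlation-style checks of the learned cascade instead use a
custom wide-HF configuration (2–12 foci, radii 1.5–4 px, no RHF
targeting), because rank correlation is uninformative when the
generating HF spread is narrower than the measurement noise.

What the generator does *not* emulate: optics (PSF, depth-dependent
blur), chromatic or stage drift, nucleoli, partial nuclei at field
edges, and the full morphological diversity of real tissue. Passing
tests therefore demonstrate correctness of the algorithms and
recoverability under controlled conditions, not segmentation quality on
real micrographs — models intended for real data should be trained on
real annotated images via the same API.

## Numerical choices and edge cases

- Threshold ties → lower threshold; foreground is `g ≥ t`.
- std projection uses the population (divide-by-N) convention.
- Median filter: disk footprint, reflected edges, radius 0 = identity.
- Structure-tensor eigenvalues are clipped at 0 (round-off can produce
  −1e-18 on flat regions).
- Watershed splitting marker separation: `0.5·√min_area`, minimum 1 px.
- Empty proposal sets, nuclei with zero chromocenters, and per-nucleus
  segmentation failures (logged, others continue) are all defined
  states, not errors.
- Box margins round half away from zero; crops clip at image bounds.

## Known limitations

- Classical chromocenter outlines are edge-biased (see above); absolute
  HF/RHF from the classical pipeline is systematically high while
  between-condition contrasts are preserved.
- The faint-focus regime (`dark`, `ddm1`) over-segments at low `h`;
  per-condition tuning of `h` and `peak_flooding` remains necessary,
  exactly as interactive use of the original tools required.
- Greedy object matching is not globally optimal on adversarial overlap
  structures.
- The NumPy U-Net targets desk-scale experiments; it is not optimized
  for large images or GPUs.
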