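# Methods

This note documents the models and procedures implemented in `deepwise`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that make runs reproducible.

## Coordinate and rasterization conventions

All geometry is 0-based with `x` along columns and `y` along rows, origin
top-left.  Pixel `(r, c)` occupies the unit square `[c, c+1) × [r, r+1)`; a
pixel belongs to a polygon iff its center `(c+0.5, r+0.5)` is inside under
the even-odd rule.  This makes rasterization unambiguous and exactly
invertible for hole-free shapes: mask→polygon tracing walks the pixel-edge
lattice (foreground kept on the right), so every traced vertex is a lattice
point and re-rasterizing reproduces the pixel set bit for bit.  Components
that touch only diagonally are traced as a single pinched loop (consistent
with 8-connected labelling); interior holes are filled before tracing —
cell annotations are simple closed regions, and multi-ring polygons are
deliberately not represented.

Annotations are exchanged as VIA 2.x project JSON (polygon regions with
paired `all_points_x`/`all_points_y`).  Older VIA dialects are rejected
loudly rather than half-supported.  A COCO-style export uses uncompressed
RLE (column-major counts beginning with the zero run).

## Stained-cell preprocessing

Stained plasma cells are blue/purple; unstained material (chiefly red blood
cells) and the slide background are pinkish.  The removal pipeline is:

1. **Contrast stretch.**  Per channel, `v' = clip((v − p_lo)·255/(p_hi −
   p_lo), 0, 255)`, with `p_lo`/`p_hi` the 2nd/98th percentiles by default.
   Percentile (rather than min/max) anchoring is robust to specular
   outliers.  A channel whose percentiles coincide is passed through
   unchanged.  The stretch is monotone per channel and idempotent once the
   configured percentiles already span the dynamic range.
2. **Greenish detection.**  After stretching, unstained material ends up
   green-dominant; a pixel is flagged iff `G − max(R, B) ≥ τ` with τ = 10
   by default.  Dominance is the simplest testable operationalization of
   "greenish"; τ is exposed in `UnstainedRule`.
3. **Cleanup.**  Morphological opening with a Euclidean disk of radius 2,
   then removal of components below 50 px.  Both defaults are stated at the
   2560×1920 source-image scale; the component threshold scales linearly
   with image area (`UnstainedRule.scaled_to`), the radius is kept fixed
   since chroma-noise speckle size does not scale with the field of view.
4. **Replacement.**  Flagged pixels are replaced by the per-channel
   background median plus zero-mean Gaussian noise with the background's
   median absolute deviation (seeded); all other pixels are bit-exact
   copies of the input.  A flat statistical fill (rather than inpainting)
   is used because the goal is only that removal leaves no spurious
   segmentable region, and it is exactly reproducible.

The background model is estimated from pixels outside the union of
annotated cells and detected unstained pixels; estimation fails loudly if
that union covers the frame.

A hue channel (RGB→HSV hue scaled to [0, 255], achromatic pixels mapped to
0) is provided for visual inspection of stained/unstained separability; the
pipeline itself never uses it.

## Deep-wise augmentation

The augmentation grows only the minority class.  Per output image, drawn
from one seeded RNG stream in a documented order (background, cell count,
patch indices, transforms, placements):

- **Extraction.**  Each annotated cell is cropped to its bounding box with
  its rasterized polygon as an isolation mask; mask pixels are verbatim
  copies of the source image.
- **Transforms.**  Default set {flip_h, flip_v, rot90, rot180, rot270} —
  exact pixel permutations, so cell pixel values and mask areas are
  conserved exactly.  Free-angle rotation (bilinear color,
  nearest-neighbor mask, expanded canvas) is available but off by default
  because it resamples.
- **Placement.**  Positions are rejection-sampled subject to: a pasted cell
  covers at most 10% of any original annotated cell's area; pairwise IOU
  between pasted masks is at most 0.1 (letting cells touch, as clusters
  do); and a pasted cell's k-dilated mask may not intersect another pasted
  cell's k-eroded interior.  The last constraint is what makes interior
  preservation hold for *every* pasted cell simultaneously — without it a
  later paste or its blend band could overwrite an earlier cell's interior.
  Original annotations are always kept; each pasted cell contributes one
  traced polygon.  A patch that cannot be placed within `max_attempts` is
  skipped with a warning; zero successes is an error.
- **Edge-band blending.**  With band half-width k (default 3), interior =
  mask ⊖ k, band = (mask ⊕ k) \ interior, using the 3×3 square
  (Chebyshev-disk) structuring element per step.  Band pixels solve the
  discrete Poisson equation per RGB channel with 4-connectivity: guidance
  Laplacian from `g = composite` inside the mask and `g = background`
  outside; Dirichlet values from the composite on interior pixels and the
  background elsewhere; band pixels lying on the image border are fixed to
  the background (which also keeps the system non-singular when a band
  reaches the frame).  The system is symmetric positive definite and is
  solved by conjugate gradients to relative residual 1e-8 (default),
  initialized at the guidance values, then quantized half-to-even into
  [0, 255].  k = 3 keeps the recomputed annulus narrow so nearly all of
  each cell's pathological content is untouched.  Gradient-domain blending
  restricted to the band was chosen over a learned feature-loss blend: it
  is deterministic, CPU-scale, and satisfies the stated preservation
  properties exactly; a learned refinement would be an extension point,
  not a replacement.

Guaranteed invariants (tested): interiors bit-identical to the transformed
patch; pixels outside all dilated masks bit-identical to the background;
non-cell pixel count never increases from background to augmented image;
with zero guidance the band solution obeys the discrete maximum principle.

## Evaluation

Predictions are matched to ground truths greedily, one-to-one: predictions
in descending score order (ties or missing scores: descending best IOU,
then index), each claiming its highest-IOU unclaimed ground truth if that
IOU reaches the threshold (default 0.5).  Precision = TP/(TP+FP), recall =
TP/(TP+FN); with zero predictions, precision is 1.0 when there are also
zero ground truths and 0.0 otherwise (symmetrically for recall).  Mean IOU
averages matched pairs only, so the three numbers stay independent:
unmatched instances affect precision/recall, not the IOU average.  Dataset
aggregation is macro (unweighted per-image mean, default) or micro (pooled
counts); both are computed since reported instance metrics in the
literature rarely state which was used.  Greedy matching can fall short of
the exhaustive assignment optimum; the tests compare it against exhaustive
search on small instance sets and count (rather than forbid) the rare
shortfalls.

## Synthetic generator

The generator emulates the properties the toolkit's logic depends on, not
the appearance of any real dataset:

- pinkish-white background, mean (240, 212, 205), pixel noise σ 3 (+4
  texture);
- stained cells as ellipse pairs: cytoplasm mean (120, 110, 170), nucleus
  mean (70, 50, 120) at 45% of the cell area with a small random offset;
  semi-axes 14–26 px, 6–12 cells per 512×512 frame;
- unstained cells, mean (205, 205, 170), semi-axes 8–14 px, drawn *under*
  stained cells so occlusion occurs;
- clusters: with probability 0.3 (1.0 in the `clustered` preset) a new cell
  is seeded adjacent to an existing one with touching or slightly
  overlapping cytoplasm (verified on the rasters);
- per-cell color jitter (σ 5–6) plus per-pixel texture noise (σ 4).

The unstained mean is deliberately pale pink-tan rather than saturated
pink: a linear per-channel stretch can only make a class green-dominant if
its green channel sits high *relative to the green distribution* while red
and blue do not, so the class is placed just below the background in R,
near it in G, and well below in B.  This reproduces the qualitative green
shift of unstained material under contrast stretching that the
preprocessing exploits.  Cell density matters for the same reason: the 2nd
percentile must fall inside the stained (dark) population for the stretch
to be anchored by it, which is why the default stained-cell count
corresponds to a realistically dense smear; very sparse fields degrade the
stretch, as they would in real data.  Consequences of the noise model:
occasional unstained cells drift toward the decision margin and thin
visible slivers of mostly-occluded cells are erased by the opening, so
recovery is evaluated pooled over images, not per cell.

Because the generator's cells are smooth noise-free ellipses with hard
edges, passing tests demonstrate the pipeline's logic (separability,
topology, preservation, accounting, determinism) — they say nothing about
texture-level realism, stain variation, or focus artifacts in real
microscopy, and the color model is not the SegPC distribution.

Every image is a pure function of its seed; dataset-level seeds are derived
from a master seed, and regeneration is byte-identical.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale: 192×192–512×512 canvases,
cells scaled accordingly, bands of a few hundred unknowns.  These sizes were
chosen so the full suite exercises every property in seconds while leaving
the algorithms identical at full 2560×1920 scale (the generator accepts
full-size dimensions).  All intensity quantization rounds half-to-even;
all randomness flows from explicit integer seeds through
`numpy.random.default_rng`; the band solver's CG is deterministic given its
inputs.  Degenerate inputs fail loudly: empty masks, polygons with fewer
than three vertices, exclusion masks covering the frame, transforms that
empty a mask, and non-convergent solves all raise with context.

## Known limitations

- Multi-ring (holed) polygons are not represented; traced components are
  filled.
- Pasted cells may occlude up to 10% of an original cell or each other's
  band pixels; traced ground truth polygons keep the full pasted mask
  (slightly amodal under occlusion).
- Greedy matching is not globally optimal (documented above).
- The hue channel is inspection-only; no hue-based removal pipeline is
  provided.
- 16-bit imagery is not supported.
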