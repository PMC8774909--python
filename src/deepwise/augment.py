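"""Minority-class ("deep-wise") cell augmentation with edge-band blending.

Instance-segmentation datasets of myeloma smears are imbalanced: cell pixels
are the minority class against a large non-cell majority.  Whole-image
augmentation (flips, crops, color jitter) grows both classes together.  This
module instead grows only the minority class: annotated cells are extracted
with their polygon masks, flipped/rotated, and composited onto existing
training images, so every new pixel introduced is a cell pixel.

The defining property of the method is *interior preservation*: pasted cells
keep their pathological pixel content verbatim.  Only a narrow band around
each pasted cell's outline — between the mask eroded by ``k`` and dilated by
``k`` — is recomputed, by solving the discrete Poisson equation per channel
with the composite as guidance and Dirichlet values taken from the fixed
interior and exterior pixels.  Everything outside the dilated mask stays
bit-identical to the background; everything inside the eroded mask stays
bit-identical to the transformed patch.

One integer seed drives background choice, patch choice, transform choice and
placement through a single RNG stream (in that order, per output image), so
augmented datasets are exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg
from skimage import transform as sktransform

from .io_formats import (
    AnnotatedImage,
    AnnotationError,
    PolygonAnnotation,
    mask_to_polygon,
    rasterize_polygon,
)

logger = logging.getLogger("deepwise.augment")

#: 3x3 square (Chebyshev disk of radius 1): one erosion/dilation step.
_STEP_SE = np.ones((3, 3), dtype=bool)

#: Exact-permutation transforms applied by default; ``rot_free`` resamples and
#: is therefore opt-in.
DEFAULT_TRANSFORMS = ("flip_h", "flip_v", "rot90", "rot180", "rot270")

#: Label assigned to traced annotations of pasted cells.
DEFAULT_PASTE_LABEL = "myeloma"


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class CellPatch:
    """A cell cropped to its bounding box with a boolean isolation mask.

    ``patch`` keeps the full rectangular crop (pixels outside the mask are
    retained as local context) but only mask pixels are ever composited.
    """

    patch: np.ndarray
    mask: np.ndarray
    source_id: str
    transform_log: tuple = ()

    def __post_init__(self) -> None:
        self.patch = np.asarray(self.patch)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.patch.shape[:2] != self.mask.shape:
            raise AnnotationError("patch and mask shapes differ")
        if not self.mask.any():
            raise AnnotationError("cell patch mask is empty")


@dataclass(frozen=True)
class BlendSpec:
    """Edge-band blending parameters.

    ``band_halfwidth`` is the morphological half-width k of the blended
    annulus; the Poisson system uses 4-connectivity and is solved by conjugate
    gradients to relative residual ``solver_tol``.
    """

    band_halfwidth: int = 3
    connectivity: int = 4
    solver_tol: float = 1e-8
    max_iter: int = 2000

    def __post_init__(self) -> None:
        if self.band_halfwidth < 1:
            raise ValueError("band_halfwidth must be >= 1")
        if self.solver_tol <= 0:
            raise ValueError("solver_tol must be positive")
        if self.connectivity != 4:
            raise ValueError("only 4-connectivity is supported")


@dataclass(frozen=True)
class PlacementPolicy:
    """Constraints of rejection-sampled cell placement.

    ``max_overlap_existing`` caps the fraction of any original annotated
    cell's area a pasted cell may cover; ``max_overlap_pasted`` caps the IOU
    between pasted cells (small positive values let pasted cells touch,
    emulating clusters).  Pasted cells are additionally kept clear of each
    other's blend interiors so interior preservation holds for every cell.
    """

    n_cells_per_image: tuple = (2, 5)
    max_overlap_existing: float = 0.1
    max_overlap_pasted: float = 0.1
    max_attempts: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.max_overlap_existing <= 1 and 0 <= self.max_overlap_pasted <= 1):
            raise ValueError("overlap fractions must be in [0, 1]")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")
        lo, hi = self.n_cells_per_image
        if not (1 <= lo <= hi):
            raise ValueError("n_cells_per_image must be a nonempty range >= 1")


@dataclass(frozen=True)
class Placement:
    """Provenance record of one successfully pasted cell.

    ``patch_list_index`` is the index of the placed patch within the list
    handed to :func:`place_cells` (callers can map it back to their pool).
    """

    source_id: str
    transforms: tuple
    row: int
    col: int
    mask_area: int
    patch_list_index: int = -1


# ---------------------------------------------------------------------------
# Extraction and geometric transforms
# ---------------------------------------------------------------------------

def extract_cells(annotated: AnnotatedImage) -> list:
    """Extract one :class:`CellPatch` per polygon annotation.

    The patch is the bounding-box crop of the image; the mask is the
    rasterized polygon restricted to the crop.  Annotations that rasterize to
    an empty mask are skipped with a warning.
    """
    h, w = annotated.shape
    patches = []
    for idx, ann in enumerate(annotated.annotations):
        full = rasterize_polygon(ann, h, w)
        if not full.any():
            logger.warning(
                "annotation %d of %s rasterizes to an empty mask; skipped",
                idx, annotated.identifier,
            )
            continue
        rows, cols = np.nonzero(full)
        r0, r1 = int(rows.min()), int(rows.max()) + 1
        c0, c1 = int(cols.min()), int(cols.max()) + 1
        patches.append(
            CellPatch(
                patch=annotated.image[r0:r1, c0:c1].copy(),
                mask=full[r0:r1, c0:c1].copy(),
                source_id=annotated.identifier,
            )
        )
    return patches


def transform_patch(patch: CellPatch, op: str, angle: float | None = None) -> CellPatch:
    """Apply one geometric transform to a patch (raster and mask together).

    Flips and 90-degree rotations are exact pixel permutations (mask area is
    conserved exactly).  ``rot_free`` rotates by an arbitrary angle on an
    expanded canvas with bilinear color / nearest-neighbor mask resampling,
    then re-crops to the mask's bounding box.
    """
    if op == "flip_h":
        img, msk = patch.patch[:, ::-1].copy(), patch.mask[:, ::-1].copy()
        logged = "flip_h"
    elif op == "flip_v":
        img, msk = patch.patch[::-1].copy(), patch.mask[::-1].copy()
        logged = "flip_v"
    elif op in ("rot90", "rot180", "rot270"):
        k = {"rot90": 1, "rot180": 2, "rot270": 3}[op]
        img, msk = np.rot90(patch.patch, k).copy(), np.rot90(patch.mask, k).copy()
        logged = op
    elif op == "rot_free":
        if angle is None:
            raise ValueError("rot_free requires an angle")
        img_f = sktransform.rotate(
            patch.patch.astype(np.float64), angle, resize=True, order=1,
            preserve_range=True, cval=0.0,
        )
        msk = sktransform.rotate(
            patch.mask.astype(np.float64), angle, resize=True, order=0,
            preserve_range=True, cval=0.0,
        ) > 0.5
        if not msk.any():
            raise AnnotationError("degenerate transform: mask became empty")
        rows, cols = np.nonzero(msk)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        img = np.clip(np.round(img_f[r0:r1, c0:c1]), 0, 255).astype(np.uint8)
        msk = msk[r0:r1, c0:c1]
        logged = f"rot_free({angle:g})"
    else:
        raise ValueError(f"unknown transform {op!r}")
    return CellPatch(
        patch=img,
        mask=msk,
        source_id=patch.source_id,
        transform_log=patch.transform_log + (logged,),
    )


# ---------------------------------------------------------------------------
# Edge band and Poisson blend
# ---------------------------------------------------------------------------

def edge_band(mask: np.ndarray, k: int):
    """Split the frame around a mask into (interior, band, exterior boundary).

    interior = mask eroded k times with the 3x3 square; band = (mask dilated
    k times) minus interior; exterior boundary = the first ring outside the
    dilated mask.  The three sets are disjoint and interior ∪ band ⊇ mask.
    If erosion empties the interior, the band is the whole dilated mask
    (logged).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise AnnotationError("edge_band of an empty mask")
    interior = ndimage.binary_erosion(mask, structure=_STEP_SE, iterations=k)
    dilated = ndimage.binary_dilation(mask, structure=_STEP_SE, iterations=k)
    if not interior.any():
        logger.info("erosion emptied the interior; band is the whole dilated mask")
    band = dilated & ~interior
    exterior_boundary = ndimage.binary_dilation(dilated, structure=_STEP_SE) & ~dilated
    return interior, band, exterior_boundary


def band_solution(
    composite: np.ndarray,
    background: np.ndarray,
    mask: np.ndarray,
    spec: BlendSpec = BlendSpec(),
):
    """Solve the per-channel Poisson system on the blend band.

    Unknowns are band pixels not on the image border (border band pixels are
    Dirichlet-fixed to the background).  For unknown p the equation is
    ``deg(p)·f_p − Σ_{q unknown} f_q = Σ_{q fixed} b_q + Lap_g(p)`` over
    4-neighborhoods, with guidance ``g = composite`` inside the mask and
    ``g = background`` outside, and Dirichlet values from the composite on
    interior pixels and from the background elsewhere.

    Returns ``(rows, cols, values)`` where ``values`` is an (n, 3) float64
    array of the unquantized solution, plus the ``(interior, band)`` masks.
    """
    composite = np.asarray(composite)
    background = np.asarray(background)
    mask = np.asarray(mask, dtype=bool)
    if composite.shape != background.shape or mask.shape != composite.shape[:2]:
        raise AnnotationError("composite, background and mask shapes disagree")
    h, w = mask.shape
    interior, band, _ = edge_band(mask, spec.band_halfwidth)

    border = np.zeros((h, w), dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    unknown = band & ~border

    rows, cols = np.nonzero(unknown)
    n = rows.size
    comp_f = composite.astype(np.float64)
    back_f = background.astype(np.float64)
    g = np.where(mask[:, :, None], comp_f, back_f)
    # Dirichlet field: composite on the fixed interior, background elsewhere.
    dirichlet = np.where(interior[:, :, None], comp_f, back_f)

    if n == 0:
        return rows, cols, np.empty((0, 3), dtype=np.float64), interior, band

    index = np.full((h, w), -1, dtype=np.int64)
    index[rows, cols] = np.arange(n)

    diag = np.zeros(n, dtype=np.float64)
    off_i: list = []
    off_j: list = []
    b = np.zeros((n, 3), dtype=np.float64)
    lap = np.zeros((n, 3), dtype=np.float64)

    for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        nr, nc = rows + dr, cols + dc
        in_img = (nr >= 0) & (nr < h) & (nc >= 0) & (nc < w)
        # Unknowns are off the border, so all 4 neighbors are in-image; keep
        # the guard for safety with 1-pixel-wide frames.
        idx = np.flatnonzero(in_img)
        nbr = index[nr[idx], nc[idx]]
        diag[idx] += 1.0
        lap[idx] += g[rows[idx], cols[idx]] - g[nr[idx], nc[idx]]
        is_unknown = nbr >= 0
        off_i.extend(idx[is_unknown].tolist())
        off_j.extend(nbr[is_unknown].tolist())
        fixed = idx[~is_unknown]
        b[fixed] += dirichlet[nr[fixed], nc[fixed]]

    data = np.concatenate([diag, -np.ones(len(off_i))])
    mat_i = np.concatenate([np.arange(n), np.asarray(off_i, dtype=np.int64)])
    mat_j = np.concatenate([np.arange(n), np.asarray(off_j, dtype=np.int64)])
    A = sparse.coo_matrix((data, (mat_i, mat_j)), shape=(n, n)).tocsr()
    rhs = b + lap

    values = np.empty((n, 3), dtype=np.float64)
    x0 = g[rows, cols]
    for ch in range(3):
        sol, info = cg(A, rhs[:, ch], x0=x0[:, ch].copy(),
                       rtol=spec.solver_tol, maxiter=spec.max_iter)
        if info != 0:
            residual = np.linalg.norm(A @ sol - rhs[:, ch])
            raise RuntimeError(
                f"Poisson band solve did not converge in {spec.max_iter} "
                f"iterations (channel {ch}, residual {residual:.3e})"
            )
        values[:, ch] = sol
    return rows, cols, values, interior, band


def blend_edge(
    composite: np.ndarray,
    background: np.ndarray,
    mask: np.ndarray,
    spec: BlendSpec = BlendSpec(),
) -> np.ndarray:
    """Blend only the edge band of a pasted cell.

    Interior pixels (mask eroded k) stay bit-identical to ``composite``;
    pixels outside the dilated mask stay bit-identical to ``background``; the
    band is the quantized (half-to-even) Poisson solution.
    """
    rows, cols, values, interior, band = band_solution(composite, background, mask, spec)
    out = np.asarray(background).copy()
    out[interior] = np.asarray(composite)[interior]
    # Border band pixels are Dirichlet = background and are already in place.
    out[rows, cols] = np.clip(np.round(values), 0, 255).astype(np.uint8)
    return out


# ---------------------------------------------------------------------------
# Placement and dataset-level augmentation
# ---------------------------------------------------------------------------

def _paste(image: np.ndarray, patch: CellPatch, r0: int, c0: int) -> np.ndarray:
    out = image.copy()
    h, w = patch.mask.shape
    region = out[r0:r0 + h, c0:c0 + w]
    region[patch.mask] = patch.patch[patch.mask]
    return out


def _full_frame_mask(patch: CellPatch, shape, r0: int, c0: int) -> np.ndarray:
    full = np.zeros(shape, dtype=bool)
    h, w = patch.mask.shape
    full[r0:r0 + h, c0:c0 + w] = patch.mask
    return full


def place_cells(
    background: AnnotatedImage,
    patches: list,
    policy: PlacementPolicy = PlacementPolicy(),
    spec: BlendSpec = BlendSpec(),
    rng: np.random.Generator | None = None,
):
    """Composite and blend patches onto a background image.

    Positions are rejection-sampled (seeded) subject to the policy: a pasted
    cell may cover at most ``max_overlap_existing`` of any original annotated
    cell's area, pairwise pasted IOU is capped at ``max_overlap_pasted``, and
    pasted cells stay out of each other's blend interiors.  Each accepted
    patch is composited over the current image state and its edge band
    blended.  Output annotations are the originals plus one traced polygon
    per pasted cell (originals are never removed).

    Returns ``(AnnotatedImage, [Placement])``.  A patch that fails placement
    after ``max_attempts`` is skipped with a warning; zero successful
    placements raise ``RuntimeError``.
    """
    if not patches:
        raise AnnotationError("no patches to place")
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    H, W = background.shape
    image = background.image.copy()
    orig_masks = [
        rasterize_polygon(ann, H, W) for ann in background.annotations
    ]
    orig_areas = [int(m.sum()) for m in orig_masks]

    placed: list = []          # (mask, interior, dilated)
    placements: list = []
    new_annotations: list = []

    for patch_idx, patch in enumerate(patches):
        ph, pw = patch.mask.shape
        if ph > H or pw > W:
            logger.warning("patch larger than background; skipped")
            continue
        interior_p, band_p, _ = edge_band(patch.mask, spec.band_halfwidth)
        accepted = False
        for _ in range(policy.max_attempts):
            r0 = int(rng.integers(0, H - ph + 1))
            c0 = int(rng.integers(0, W - pw + 1))
            mask_full = _full_frame_mask(patch, (H, W), r0, c0)
            ok = True
            for om, oa in zip(orig_masks, orig_areas):
                if oa and (mask_full & om).sum() / oa > policy.max_overlap_existing:
                    ok = False
                    break
            if ok:
                interior_full = np.zeros((H, W), dtype=bool)
                interior_full[r0:r0 + ph, c0:c0 + pw] = interior_p
                dilated_full = ndimage.binary_dilation(
                    mask_full, structure=_STEP_SE, iterations=spec.band_halfwidth
                )
                for pm, pi, pd in placed:
                    inter = (mask_full & pm).sum()
                    union = (mask_full | pm).sum()
                    if union and inter / union > policy.max_overlap_pasted:
                        ok = False
                        break
                    # Keep blend interiors mutually untouched: the defining
                    # interior-preservation property must hold for every cell.
                    if (dilated_full & pi).any() or (interior_full & pd).any():
                        ok = False
                        break
            if not ok:
                continue
            composite = _paste(image, patch, r0, c0)
            image = blend_edge(composite, image, mask_full, spec)
            polys = mask_to_polygon(mask_full)
            if len(polys) > 1:
                # A disconnected transformed mask traces to several loops;
                # annotate the largest one.
                logger.info("pasted mask traced to %d components; keeping largest", len(polys))
                polys.sort(key=lambda p: p.shoelace_area(), reverse=True)
            new_annotations.append(PolygonAnnotation(polys[0].vertices, label=DEFAULT_PASTE_LABEL))
            placed.append((mask_full, interior_full, dilated_full))
            placements.append(
                Placement(
                    source_id=patch.source_id,
                    transforms=patch.transform_log,
                    row=r0,
                    col=c0,
                    mask_area=int(mask_full.sum()),
                    patch_list_index=patch_idx,
                )
            )
            accepted = True
            break
        if not accepted:
            logger.warning(
                "patch from %s failed placement after %d attempts; skipped",
                patch.source_id, policy.max_attempts,
            )

    if not placements:
        raise RuntimeError("augmentation produced no new cells")
    out = AnnotatedImage(
        image=image,
        annotations=list(background.annotations) + new_annotations,
        identifier=background.identifier,
    )
    return out, placements


def build_patch_pool(train: list) -> list:
    """Extract the global cell-patch pool from a training set, in dataset
    order (the pool indices recorded in augmentation manifests refer to this
    ordering)."""
    pool: list = []
    for annotated in train:
        pool.extend(extract_cells(annotated))
    return pool


def augment_dataset(
    train: list,
    n_out: int,
    policy: PlacementPolicy = PlacementPolicy(),
    spec: BlendSpec = BlendSpec(),
    transforms: tuple = DEFAULT_TRANSFORMS,
):
    """Generate ``n_out`` augmented images from a training set.

    Builds the global cell-patch pool with :func:`extract_cells`, then for
    each output image draws — in this documented order, from one RNG seeded
    by ``policy.seed`` — a background (uniform over ``train``), a cell count
    (uniform over ``policy.n_cells_per_image``), patch indices, one transform
    per patch (plus an angle when ``rot_free`` is drawn), and finally the
    placement samples consumed by :func:`place_cells`.

    Returns ``(images, annotations, manifest)`` where ``annotations`` maps
    output identifiers to polygon lists (VIA-writable) and ``manifest``
    records per-image provenance.
    """
    if not train:
        raise AnnotationError("empty training set")
    pool = build_patch_pool(train)
    if not pool:
        raise AnnotationError("training set has zero usable annotations")

    rng = np.random.default_rng(policy.seed)
    lo, hi = policy.n_cells_per_image
    images: list = []
    annotations: dict = {}
    manifest: list = []
    for i in range(n_out):
        bg = train[int(rng.integers(len(train)))]
        n_cells = int(rng.integers(lo, hi + 1))
        chosen = []
        pool_indices = []
        for _ in range(n_cells):
            j = int(rng.integers(len(pool)))
            op = transforms[int(rng.integers(len(transforms)))]
            if op == "rot_free":
                chosen.append(transform_patch(pool[j], op, angle=float(rng.uniform(0.0, 360.0))))
            else:
                chosen.append(transform_patch(pool[j], op))
            pool_indices.append(j)
        placed, records = place_cells(bg, chosen, policy, spec, rng=rng)
        identifier = f"aug_{i:04d}.png"
        out = AnnotatedImage(
            image=placed.image, annotations=placed.annotations, identifier=identifier
        )
        images.append(out)
        annotations[identifier] = out.annotations
        manifest.append({
            "identifier": identifier,
            "background": bg.identifier,
            "cells": [
                {
                    "source": r.source_id,
                    "pool_index": pool_indices[r.patch_list_index],
                    "transforms": list(r.transforms),
                    "row": r.row,
                    "col": r.col,
                    "mask_area": r.mask_area,
                }
                for r in records
            ],
        })
    return images, annotations, manifest
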