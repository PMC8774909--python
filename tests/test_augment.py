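"""Cell extraction, transforms, edge banding and Poisson edge blending."""

import numpy as np
import pytest

from deepwise import (
    AnnotatedImage,
    AnnotationError,
    BlendSpec,
    CellPatch,
    PlacementPolicy,
    PolygonAnnotation,
    blend_edge,
    edge_band,
    extract_cells,
    place_cells,
    rasterize_polygon,
    transform_patch,
)
from deepwise.augment import band_solution

from conftest import random_blob


def _random_patch(rng, h=9, w=7):
    mask = np.zeros((h, w), dtype=bool)
    mask[1:-1, 1:-1] = True
    return CellPatch(
        patch=rng.integers(0, 256, size=(h, w, 3)).astype(np.uint8),
        mask=mask,
        source_id="fixture",
    )


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

class TestExtractCells:
    def test_one_patch_per_annotation(self, small_train):
        annotated = small_train[0]
        patches = extract_cells(annotated)
        assert len(patches) == len(annotated.annotations)
        for patch in patches:
            assert patch.mask.any()
            assert patch.patch.shape[:2] == patch.mask.shape

    def test_rectangular_annotation_mask_pixel_count(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        ann = PolygonAnnotation(((2, 3), (6, 3), (6, 6), (2, 6)))  # 4x3 = 12 px
        annotated = AnnotatedImage(img, [ann], "rect")
        (patch,) = extract_cells(annotated)
        assert patch.mask.sum() == 12

    def test_mask_pixels_copied_verbatim(self, small_train):
        annotated = small_train[1]
        full_masks = [
            rasterize_polygon(a, *annotated.shape) for a in annotated.annotations
        ]
        for patch, full in zip(extract_cells(annotated), full_masks):
            rows, cols = np.nonzero(full)
            r0, c0 = rows.min(), cols.min()
            assert np.array_equal(
                patch.patch[patch.mask],
                annotated.image[full],
            )
            assert patch.mask.sum() == full.sum()

    def test_zero_annotations_empty_list(self):
        annotated = AnnotatedImage(np.zeros((5, 5, 3), dtype=np.uint8), [], "empty")
        assert extract_cells(annotated) == []


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

class TestTransformPatch:
    @pytest.mark.parametrize("op", ["flip_h", "flip_v"])
    def test_double_flip_is_identity(self, rng, op):
        patch = _random_patch(rng)
        twice = transform_patch(transform_patch(patch, op), op)
        assert np.array_equal(twice.patch, patch.patch)
        assert np.array_equal(twice.mask, patch.mask)
        assert twice.transform_log == (op, op)

    @pytest.mark.parametrize("op", ["flip_h", "flip_v", "rot90", "rot180", "rot270"])
    def test_permutation_transforms_conserve_mask_area(self, rng, op):
        blob = random_blob(rng, shape=(15, 12))
        patch = CellPatch(
            patch=rng.integers(0, 256, size=(15, 12, 3)).astype(np.uint8),
            mask=blob, source_id="blob",
        )
        out = transform_patch(patch, op)
        assert out.mask.sum() == patch.mask.sum()
        # pixel multiset of the cell is conserved exactly
        assert sorted(map(tuple, out.patch[out.mask])) == \
               sorted(map(tuple, patch.patch[patch.mask]))

    def test_free_rotation_of_disk_preserves_area_within_5pct(self, rng):
        yy, xx = np.mgrid[0:20, 0:20]
        disk = (yy - 9.5) ** 2 + (xx - 9.5) ** 2 <= 8.0 ** 2
        patch = CellPatch(
            patch=rng.integers(0, 256, size=(20, 20, 3)).astype(np.uint8),
            mask=disk, source_id="disk",
        )
        out = transform_patch(patch, "rot_free", angle=30.0)
        assert abs(out.mask.sum() - disk.sum()) / disk.sum() <= 0.05

    def test_unknown_transform_rejected(self, rng):
        with pytest.raises(ValueError):
            transform_patch(_random_patch(rng), "shear")


# ---------------------------------------------------------------------------
# Edge band
# ---------------------------------------------------------------------------

class TestEdgeBand:
    def test_single_pixel_band_is_neighborhood(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 3] = True
        interior, band, exterior = edge_band(mask, 1)
        assert not interior.any()
        expected = np.zeros((7, 7), dtype=bool)
        expected[2:5, 2:5] = True
        assert np.array_equal(band, expected)

    def test_square_interior_by_brute_force_erosion(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True  # 10x10
        interior, band, exterior = edge_band(mask, 1)
        # brute force: a pixel is interior iff its full 3x3 neighborhood is set
        expected = np.zeros_like(mask)
        for r in range(1, 13):
            for c in range(1, 13):
                expected[r, c] = mask[r - 1:r + 2, c - 1:c + 2].all()
        assert np.array_equal(interior, expected)
        assert interior.sum() == 64

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_sets_disjoint_and_cover_mask(self, rng, k):
        for _ in range(10):
            mask = random_blob(rng, shape=(24, 24))
            interior, band, exterior = edge_band(mask, k)
            assert not (interior & band).any()
            assert not (interior & exterior).any()
            assert not (band & exterior).any()
            assert ((interior | band) & mask).sum() == mask.sum()


# ---------------------------------------------------------------------------
# Poisson edge blending
# ---------------------------------------------------------------------------

def _dense_band_oracle(composite, background, mask, spec):
    """Independent dense assembly + direct solve of the blend system."""
    h, w = mask.shape
    from scipy import ndimage

    se = np.ones((3, 3), dtype=bool)
    interior = ndimage.binary_erosion(mask, se, iterations=spec.band_halfwidth)
    dilated = ndimage.binary_dilation(mask, se, iterations=spec.band_halfwidth)
    band = dilated & ~interior
    border = np.zeros((h, w), dtype=bool)
    border[[0, -1], :] = True
    border[:, [0, -1]] = True
    unknown = band & ~border
    coords = list(zip(*np.nonzero(unknown)))
    index = {rc: i for i, rc in enumerate(coords)}
    comp = composite.astype(float)
    back = background.astype(float)
    g = np.where(mask[:, :, None], comp, back)
    dirich = np.where(interior[:, :, None], comp, back)
    n = len(coords)
    sol = np.zeros((n, 3))
    for ch in range(3):
        A = np.zeros((n, n))
        b = np.zeros(n)
        for i, (r, c) in enumerate(coords):
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if not (0 <= rr < h and 0 <= cc < w):
                    continue
                A[i, i] += 1.0
                b[i] += g[r, c, ch] - g[rr, cc, ch]
                if (rr, cc) in index:
                    A[i, index[(rr, cc)]] -= 1.0
                else:
                    b[i] += dirich[rr, cc, ch]
        sol[:, ch] = np.linalg.solve(A, b)
    return coords, sol, interior, band, dilated


class TestBlendEdge:
    def test_fixed_point_when_composite_equals_background(self, rng):
        background = rng.integers(0, 256, size=(20, 20, 3)).astype(np.uint8)
        mask = np.zeros((20, 20), dtype=bool)
        mask[6:14, 6:14] = True
        out = blend_edge(background.copy(), background, mask, BlendSpec(band_halfwidth=2))
        assert np.array_equal(out, background)

    def test_single_unknown_harmonic_mean_of_boundary(self):
        """One band unknown with zero guidance Laplacian solves to the mean of
        its four Dirichlet neighbors (10 + 30 + 20 + 20)/4 = 20."""
        background = np.zeros((3, 3, 3), dtype=np.uint8)
        background[1, 0] = 10
        background[1, 2] = 30
        background[0, 1] = 20
        background[2, 1] = 20
        background[1, 1] = 20  # guidance value at the pasted pixel
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        composite = background.copy()
        out = blend_edge(composite, background, mask, BlendSpec(band_halfwidth=1))
        assert tuple(out[1, 1]) == (20, 20, 20)

    def test_band_solution_matches_dense_direct_solve(self, rng):
        spec = BlendSpec(band_halfwidth=2, solver_tol=1e-12)
        for trial in range(5):
            mask = np.zeros((26, 26), dtype=bool)
            blob = random_blob(rng, shape=(16, 16), n_grow=60)
            mask[5:21, 5:21] = blob
            if not mask.any():
                continue
            background = rng.integers(0, 256, size=(26, 26, 3)).astype(np.uint8)
            patch = rng.integers(0, 256, size=(26, 26, 3)).astype(np.uint8)
            composite = np.where(mask[:, :, None], patch, background)
            rows, cols, values, interior, band = band_solution(
                composite, background, mask, spec
            )
            coords, oracle, *_ = _dense_band_oracle(composite, background, mask, spec)
            assert list(zip(rows.tolist(), cols.tolist())) == coords
            assert np.max(np.abs(values - oracle)) < 1e-6

    def test_interior_and_exterior_bit_exact(self, rng):
        spec = BlendSpec(band_halfwidth=2)
        mask = np.zeros((30, 30), dtype=bool)
        mask[8:22, 8:22] = True
        background = rng.integers(0, 256, size=(30, 30, 3)).astype(np.uint8)
        patch = rng.integers(0, 256, size=(30, 30, 3)).astype(np.uint8)
        composite = np.where(mask[:, :, None], patch, background)
        out = blend_edge(composite, background, mask, spec)
        from scipy import ndimage
        se = np.ones((3, 3), dtype=bool)
        interior = ndimage.binary_erosion(mask, se, iterations=2)
        dilated = ndimage.binary_dilation(mask, se, iterations=2)
        assert np.array_equal(out[interior], composite[interior])
        assert np.array_equal(out[~dilated], background[~dilated])

    def test_maximum_principle_with_zero_guidance(self, rng):
        """With composite == background (zero guidance) every band value lies
        within the range of its Dirichlet boundary; check on the float
        solution of a smooth background."""
        yy, xx = np.mgrid[0:24, 0:24]
        ramp = (10 * xx).clip(0, 255).astype(np.uint8)
        background = np.stack([ramp] * 3, axis=-1)
        mask = np.zeros((24, 24), dtype=bool)
        mask[8:16, 8:16] = True
        rows, cols, values, interior, band = band_solution(
            background.copy(), background, mask, BlendSpec(band_halfwidth=2)
        )
        lo, hi = background.min(), background.max()
        assert values.min() >= lo - 1e-6 and values.max() <= hi + 1e-6


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

class TestPlaceCells:
    def _patches(self, small_train):
        return extract_cells(small_train[0])

    def test_annotation_bookkeeping(self, small_train):
        bg = small_train[1]
        patches = self._patches(small_train)
        policy = PlacementPolicy(n_cells_per_image=(1, 3), max_attempts=100, seed=21)
        out, placements = place_cells(bg, patches, policy, BlendSpec())
        assert len(out.annotations) == len(bg.annotations) + len(placements)
        assert out.annotations[:len(bg.annotations)] == bg.annotations

    def test_pasted_iou_cap_enforced(self, small_train):
        bg = small_train[1]
        patches = self._patches(small_train) * 3
        policy = PlacementPolicy(max_overlap_pasted=0.1, max_attempts=60, seed=5)
        out, placements = place_cells(bg, patches, policy, BlendSpec())
        h, w = bg.shape
        masks = [rasterize_polygon(a, h, w)
                 for a in out.annotations[len(bg.annotations):]]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                inter = (masks[i] & masks[j]).sum()
                union = (masks[i] | masks[j]).sum()
                assert inter / union <= 0.1 + 1e-9

    def test_noncell_pixels_never_increase(self, small_train):
        bg = small_train[2]
        patches = self._patches(small_train)
        policy = PlacementPolicy(n_cells_per_image=(1, 3), max_attempts=100, seed=8)
        out, _ = place_cells(bg, patches, policy, BlendSpec())
        h, w = bg.shape

        def noncell(annotated):
            union = np.zeros((h, w), dtype=bool)
            for a in annotated.annotations:
                union |= rasterize_polygon(a, h, w)
            return (~union).sum()

        assert noncell(out) <= noncell(bg)

    def test_zero_placements_is_an_error(self, small_train):
        bg = small_train[0]
        giant = CellPatch(
            patch=np.zeros((500, 500, 3), dtype=np.uint8),
            mask=np.ones((500, 500), dtype=bool),
            source_id="too-big",
        )
        with pytest.raises(RuntimeError, match="no new cells"):
            place_cells(bg, [giant], PlacementPolicy(), BlendSpec())
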