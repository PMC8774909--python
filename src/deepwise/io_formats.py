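"""Polygon annotation I/O and rasterization.

Cell ground truth travels through the toolkit as polygons in VGG Image
Annotator (VIA) 2.x project JSON — one ``regions`` entry per cell, with
``shape_attributes`` of type ``polygon`` holding paired ``all_points_x`` /
``all_points_y`` vertex lists.  This module reads and writes that format,
rasterizes polygons to per-instance boolean masks, and traces masks back to
polygons so that pasted (augmented) cells can be re-annotated.

Coordinate convention (used everywhere in the package): 0-based, ``x`` is the
column axis and ``y`` the row axis, origin at the top-left.  Pixel ``(r, c)``
spans the unit square ``[c, c+1) × [r, r+1)`` and its center is
``(c + 0.5, r + 0.5)``.  A pixel belongs to a polygon iff its center is inside
under the even-odd rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

logger = logging.getLogger("deepwise.io")

DEFAULT_LABEL = "myeloma"

#: 8-connectivity structuring element for component labelling.
_EIGHT = np.ones((3, 3), dtype=bool)


class AnnotationError(ValueError):
    """Invalid annotation content or an unreadable annotation file."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolygonAnnotation:
    """A single cell outline.

    Parameters
    ----------
    vertices
        Ordered ``(x, y)`` pairs in continuous image coordinates.  The polygon
        is implicitly closed (last vertex connects back to the first).
    label
        Free-text category; defaults to ``"myeloma"``.
    """

    vertices: tuple
    label: str = DEFAULT_LABEL

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(verts) < 3:
            raise AnnotationError(
                f"polygon needs at least 3 vertices, got {len(verts)}"
            )
        object.__setattr__(self, "vertices", verts)

    def validate_for(self, height: int, width: int) -> None:
        """Raise :class:`AnnotationError` unless all vertices lie in
        ``[0, width] × [0, height]``."""
        for x, y in self.vertices:
            if not (0.0 <= x <= width and 0.0 <= y <= height):
                raise AnnotationError(
                    f"vertex ({x}, {y}) outside image frame {width}x{height}"
                )

    def shoelace_area(self) -> float:
        """Unsigned analytic polygon area."""
        v = np.asarray(self.vertices, dtype=float)
        x, y = v[:, 0], v[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    def perimeter(self) -> float:
        v = np.asarray(self.vertices, dtype=float)
        return float(np.linalg.norm(np.diff(np.vstack([v, v[:1]]), axis=0), axis=1).sum())


@dataclass
class AnnotatedImage:
    """An RGB raster plus its polygon cell annotations."""

    image: np.ndarray
    annotations: list
    identifier: str

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3 or img.shape[0] < 1 or img.shape[1] < 1:
            raise AnnotationError(f"expected HxWx3 image, got shape {img.shape}")
        if img.dtype != np.uint8:
            raise AnnotationError(f"expected uint8 channel intensities, got {img.dtype}")
        self.image = img
        h, w = img.shape[:2]
        for ann in self.annotations:
            ann.validate_for(h, w)

    @property
    def shape(self) -> tuple:
        return self.image.shape[:2]


# ---------------------------------------------------------------------------
# VIA 2.x project JSON
# ---------------------------------------------------------------------------

def read_via_json(path) -> dict:
    """Read a VIA 2.x project JSON into ``{image id: [PolygonAnnotation]}``.

    Only polygon regions are kept; other region shapes (rect, circle, ...) are
    skipped with a logged warning.  A missing ``label`` region attribute maps
    to ``"myeloma"``.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"malformed VIA JSON in {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise AnnotationError(f"{path}: VIA project must be a JSON object")

    metadata = data.get("_via_img_metadata", data)
    out: dict = {}
    for key, entry in metadata.items():
        if key.startswith("_via_"):
            continue  # settings/attributes blocks of a raw project file
        if not isinstance(entry, dict) or "regions" not in entry:
            raise AnnotationError(
                f"unsupported VIA dialect: entry {key!r} has no 'regions' key"
            )
        regions = entry["regions"]
        if isinstance(regions, dict):
            raise AnnotationError(
                f"entry {key!r} stores regions as a dict (VIA 1.x export); "
                "only VIA 2.x project JSON is supported"
            )
        image_id = entry.get("filename", key)
        annotations = []
        for idx, region in enumerate(regions):
            shape = region.get("shape_attributes", {})
            name = shape.get("name")
            if name != "polygon":
                logger.warning(
                    "skipping non-polygon region %d (shape %r) in image %r",
                    idx, name, image_id,
                )
                continue
            xs = shape.get("all_points_x")
            ys = shape.get("all_points_y")
            if xs is None or ys is None or len(xs) != len(ys):
                raise AnnotationError(
                    f"image {image_id!r} region {idx}: missing or mismatched "
                    "'all_points_x'/'all_points_y'"
                )
            if len(xs) < 3:
                raise AnnotationError(
                    f"image {image_id!r} region {idx}: polygon has "
                    f"{len(xs)} points (< 3)"
                )
            label = region.get("region_attributes", {}).get("label", DEFAULT_LABEL)
            annotations.append(PolygonAnnotation(tuple(zip(xs, ys)), label))
        out[image_id] = annotations
    return out


def write_via_json(annotations: Mapping[str, Sequence[PolygonAnnotation]], path) -> None:
    """Write ``{image id: [PolygonAnnotation]}`` as VIA 2.x project JSON.

    Coordinates are serialized as JSON numbers (exact for doubles), so a
    write → read round trip reproduces vertices with zero error.
    """
    metadata = {}
    for image_id, anns in annotations.items():
        regions = []
        for ann in anns:
            regions.append({
                "shape_attributes": {
                    "name": "polygon",
                    "all_points_x": [v[0] for v in ann.vertices],
                    "all_points_y": [v[1] for v in ann.vertices],
                },
                "region_attributes": {"label": ann.label},
            })
        metadata[f"{image_id}-1"] = {
            "filename": image_id,
            "size": -1,
            "regions": regions,
            "file_attributes": {},
        }
    project = {
        "_via_settings": {"project": {"name": "deepwise"}},
        "_via_img_metadata": metadata,
        "_via_attributes": {"region": {"label": {"type": "text"}}, "file": {}},
        "_via_data_format_version": "2.0.10",
    }
    with open(path, "w") as fh:
        json.dump(project, fh)


# ---------------------------------------------------------------------------
# Rasterization and boundary tracing
# ---------------------------------------------------------------------------

def rasterize_polygon(polygon: PolygonAnnotation, height: int, width: int) -> np.ndarray:
    """Rasterize a polygon to an ``(height, width)`` boolean mask.

    A pixel is set iff its center ``(c + 0.5, r + 0.5)`` lies inside the
    polygon under the even-odd (crossing-number) rule.  Degenerate polygons
    with zero enclosed area yield an empty mask (logged, not an error).
    """
    polygon.validate_for(height, width)
    verts = np.asarray(polygon.vertices, dtype=float)
    mask = np.zeros((height, width), dtype=bool)

    # Candidate pixels: centers within the polygon's bounding box.
    c_lo = max(int(np.ceil(verts[:, 0].min() - 0.5)), 0)
    c_hi = min(int(np.floor(verts[:, 0].max() - 0.5)), width - 1)
    r_lo = max(int(np.ceil(verts[:, 1].min() - 0.5)), 0)
    r_hi = min(int(np.floor(verts[:, 1].max() - 0.5)), height - 1)
    if c_lo > c_hi or r_lo > r_hi:
        logger.info("polygon rasterized to an empty mask (degenerate extent)")
        return mask

    xs = np.arange(c_lo, c_hi + 1, dtype=float) + 0.5
    ys = np.arange(r_lo, r_hi + 1, dtype=float) + 0.5
    X = xs[None, :]
    Y = ys[:, None]
    inside = np.zeros((ys.size, xs.size), dtype=bool)
    nxt = np.roll(verts, -1, axis=0)
    for (x1, y1), (x2, y2) in zip(verts, nxt):
        if y1 == y2:
            continue  # horizontal edges never cross a horizontal ray
        crosses = (y1 > Y) != (y2 > Y)
        x_at = x1 + (Y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (X < x_at)

    mask[r_lo:r_hi + 1, c_lo:c_hi + 1] = inside
    if not mask.any():
        logger.info("polygon rasterized to an empty mask (zero enclosed area)")
    return mask


# Lattice directions for crack following: right, down, left, up (y grows down).
_STEP = {"R": (1, 0), "D": (0, 1), "L": (-1, 0), "U": (0, -1)}
# At a saddle vertex (two diagonal foreground pixels) the turn that keeps an
# 8-connected component on a single boundary loop, keyed by incoming direction.
_SADDLE_TURN = {"U": "L", "D": "R", "R": "U", "L": "D"}


def _trace_boundary(component: np.ndarray) -> list:
    """Trace the outer boundary of one hole-free 8-connected component.

    The walk follows pixel-edge "cracks" on the integer lattice with the
    foreground on its right-hand side, so every vertex is a lattice point and
    re-rasterizing the polygon under the center/even-odd rule reproduces the
    component's pixel set exactly.  Diagonal-only contacts are traversed as a
    pinch point (visited twice), keeping one loop per 8-connected component.
    """
    h, w = component.shape

    def inside(x: int, y: int) -> bool:
        return 0 <= x < w and 0 <= y < h and component[y, x]

    rows, cols = np.nonzero(component)
    r0 = int(rows.min())
    c0 = int(cols[rows == r0].min())
    start = (c0, r0, "R")  # top-left pixel; the pixel above is background

    points = [(float(c0), float(r0))]
    x, y, d = start
    while True:
        dx, dy = _STEP[d]
        x, y = x + dx, y + dy
        nw = inside(x - 1, y - 1)
        ne = inside(x, y - 1)
        sw = inside(x - 1, y)
        se = inside(x, y)
        options = []
        if se and not ne:
            options.append("R")
        if sw and not se:
            options.append("D")
        if nw and not sw:
            options.append("L")
        if ne and not nw:
            options.append("U")
        nd = _SADDLE_TURN[d] if len(options) == 2 else options[0]
        if (x, y, nd) == start:
            break
        if nd != d:
            points.append((float(x), float(y)))
        d = nd
    return points


def mask_to_polygon(mask: np.ndarray) -> list:
    """Trace a boolean mask into one polygon per 8-connected component.

    Holes are filled before tracing (cell annotations are simple closed
    regions; multi-ring polygons are not represented), so a component with a
    hole round-trips to its filled pixel set.  For hole-free components,
    ``rasterize_polygon`` of each output reproduces its component exactly.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise AnnotationError("no foreground")
    labels, n = ndimage.label(mask, structure=_EIGHT)
    polygons = []
    for i in range(1, n + 1):
        component = ndimage.binary_fill_holes(labels == i)
        polygons.append(PolygonAnnotation(tuple(_trace_boundary(component))))
    return polygons


# ---------------------------------------------------------------------------
# COCO-style uncompressed RLE (column-major counts, leading zero-run)
# ---------------------------------------------------------------------------

def mask_to_rle(mask: np.ndarray) -> dict:
    """Encode a boolean mask as uncompressed COCO RLE.

    Counts follow the COCO convention: the mask is flattened column-major and
    run lengths alternate starting with the number of leading zeros.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    flat = mask.flatten(order="F")
    if flat.size == 0:
        return {"size": [h, w], "counts": []}
    changes = np.flatnonzero(np.diff(flat))
    bounds = np.concatenate(([0], changes + 1, [flat.size]))
    counts = np.diff(bounds).tolist()
    if flat[0]:
        counts = [0] + counts
    return {"size": [h, w], "counts": counts}


def rle_to_mask(rle: dict) -> np.ndarray:
    """Decode uncompressed COCO RLE back to a boolean mask."""
    h, w = rle["size"]
    counts = rle["counts"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    value = False
    for count in counts:
        flat[pos:pos + count] = value
        pos += count
        value = not value
    if pos != h * w:
        raise AnnotationError(f"RLE counts sum to {pos}, expected {h * w}")
    return flat.reshape((h, w), order="F")


def convert_via_to_coco(via_path, images_dir, out_path) -> dict:
    """Convert VIA polygon annotations to a COCO-style instance file with
    uncompressed RLE segmentations (single category ``myeloma``)."""
    images_dir = Path(images_dir)
    via = read_via_json(via_path)
    coco = {
        "images": [],
        "annotations": [],
        "categories": [{"id": 1, "name": DEFAULT_LABEL}],
    }
    ann_id = 1
    for img_idx, (image_id, anns) in enumerate(sorted(via.items()), start=1):
        img = read_image(images_dir / image_id)
        h, w = img.shape[:2]
        coco["images"].append(
            {"id": img_idx, "file_name": image_id, "height": h, "width": w}
        )
        for ann in anns:
            m = rasterize_polygon(ann, h, w)
            if not m.any():
                logger.warning("skipping empty rasterization in %s", image_id)
                continue
            rows, cols = np.nonzero(m)
            bbox = [int(cols.min()), int(rows.min()),
                    int(cols.max() - cols.min() + 1), int(rows.max() - rows.min() + 1)]
            coco["annotations"].append({
                "id": ann_id,
                "image_id": img_idx,
                "category_id": 1,
                "segmentation": mask_to_rle(m),
                "area": int(m.sum()),
                "bbox": bbox,
                "iscrowd": 0,
            })
            ann_id += 1
    with open(out_path, "w") as fh:
        json.dump(coco, fh)
    return coco


# ---------------------------------------------------------------------------
# Image files (8-bit RGB; BMP, PNG, TIFF)
# ---------------------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Read an image file as an HxWx3 uint8 array (gray promoted, alpha dropped)."""
    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        raise AnnotationError(f"{path}: only 8-bit imagery is supported, got {arr.dtype}")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3:
        raise AnnotationError(f"{path}: unexpected image shape {arr.shape}")
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return np.ascontiguousarray(arr[:, :, :3])


def write_image(path, image: np.ndarray) -> None:
    image = np.asarray(image)
    if image.dtype != np.uint8:
        raise AnnotationError("images are written as 8-bit RGB")
    iio.imwrite(path, image)
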