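"""Seeded synthetic microscopy-like images with exact ground truth.

The generator emulates, at desk scale, the features of stained bone-marrow
smears that the rest of the toolkit must handle: a bright pinkish-white
background, stained plasma cells drawn as ellipse pairs (a darker blue/purple
nucleus inside a lighter blue/purple cytoplasm), pale unstained cells that
may lie underneath stained cells, and clusters whose cytoplasm is touching or
slightly overlapping.  Cells are analytic ellipses rather than learned
textures: the properties under test (color separability, touching topology,
occlusion) do not require realism, and ellipses give exact area and ground
truth oracles.

The color model is stylized, not fit to any real staining distribution: the
unstained class is placed so that a per-channel percentile contrast stretch
turns it green-dominant (the separation the preprocessing exploits), while
background and stained cells stay non-green-dominant.

Every image is fully determined by its seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import binary_dilation

from .io_formats import (
    AnnotatedImage,
    AnnotationError,
    PolygonAnnotation,
    mask_to_rle,
    rasterize_polygon,
    write_image,
    write_via_json,
)

logger = logging.getLogger("deepwise.synthgen")

_ELLIPSE_VERTICES = 48


@dataclass(frozen=True)
class ColorModel:
    """Per-class color: mean RGB plus a cell-level jitter SD (intensity units)."""

    mean: tuple
    sd: float


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterization of the synthetic image generator.

    Counts are inclusive integer ranges.  ``cluster_prob`` is the chance that
    a stained cell is seeded adjacent to an existing one with touching or
    slightly overlapping cytoplasm.  ``texture_noise_sd`` is per-pixel
    Gaussian noise added on top of the per-cell color jitter.
    """

    width: int = 512
    height: int = 512
    n_stained: tuple = (6, 12)
    n_unstained: tuple = (3, 10)
    cluster_prob: float = 0.3
    background: ColorModel = ColorModel((240.0, 212.0, 205.0), 3.0)
    nucleus: ColorModel = ColorModel((70.0, 50.0, 120.0), 6.0)
    cytoplasm: ColorModel = ColorModel((120.0, 110.0, 170.0), 6.0)
    unstained: ColorModel = ColorModel((205.0, 205.0, 170.0), 5.0)
    stained_axes: tuple = (14.0, 26.0)
    unstained_axes: tuple = (8.0, 14.0)
    nucleus_fraction: float = 0.45
    texture_noise_sd: float = 4.0
    max_attempts: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.n_stained, self.n_unstained):
            if not (0 <= lo <= hi):
                raise ValueError("count ranges must be nonempty and non-negative")
        if not (0.0 <= self.cluster_prob <= 1.0 and 0.0 < self.nucleus_fraction <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        for cm in (self.background, self.nucleus, self.cytoplasm, self.unstained):
            if any(not (0.0 <= v <= 255.0) for v in cm.mean):
                raise ValueError("color means must lie in [0, 255]")


@dataclass(frozen=True)
class CellMeta:
    """Per-cell generation record (ground truth for property tests)."""

    kind: str            # "stained" | "unstained"
    center: tuple
    axes: tuple
    rotation: float
    cluster_id: int      # -1 for unclustered/unstained cells
    nucleus_center: tuple | None = None   # stained cells only
    nucleus_axes: tuple | None = None


@dataclass
class SynthTruth:
    stained_annotations: list
    unstained_mask: np.ndarray   # visible (not occluded) unstained pixels
    cells: list = field(default_factory=list)


def _ellipse_polygon(cx, cy, a, b, theta, width, height) -> PolygonAnnotation:
    phi = np.linspace(0.0, 2.0 * np.pi, _ELLIPSE_VERTICES, endpoint=False)
    x = a * np.cos(phi)
    y = b * np.sin(phi)
    ct, st = np.cos(theta), np.sin(theta)
    xs = np.clip(cx + ct * x - st * y, 0.0, float(width))
    ys = np.clip(cy + st * x + ct * y, 0.0, float(height))
    return PolygonAnnotation(tuple(zip(xs.tolist(), ys.tolist())))


def _paint(canvas, mask, model: ColorModel, rng) -> None:
    shift = rng.normal(0.0, model.sd, size=3)
    canvas[mask] = np.asarray(model.mean) + shift


def generate_image(config: SynthConfig):
    """Generate one synthetic image; returns ``(AnnotatedImage, SynthTruth)``.

    Painting order: background, unstained cells, stained cells (cytoplasm
    then nucleus), so unstained cells can lie underneath stained ones.
    Per-pixel texture noise is added last.
    """
    rng = np.random.default_rng(config.seed)
    w, h = config.width, config.height
    canvas = np.empty((h, w, 3), dtype=np.float64)
    canvas[:, :] = np.asarray(config.background.mean)
    canvas += rng.normal(0.0, config.background.sd, size=(h, w, 1))

    cells: list = []

    # --- unstained cells -------------------------------------------------
    n_un = int(rng.integers(config.n_unstained[0], config.n_unstained[1] + 1))
    unstained_painted = np.zeros((h, w), dtype=bool)
    for _ in range(n_un):
        a = rng.uniform(*config.unstained_axes)
        b = rng.uniform(*config.unstained_axes)
        theta = rng.uniform(0.0, np.pi)
        margin = max(a, b) + 2.0
        cx = rng.uniform(margin, w - margin)
        cy = rng.uniform(margin, h - margin)
        poly = _ellipse_polygon(cx, cy, a, b, theta, w, h)
        mask = rasterize_polygon(poly, h, w)
        _paint(canvas, mask, config.unstained, rng)
        unstained_painted |= mask
        cells.append(CellMeta("unstained", (cx, cy), (a, b), theta, -1))

    # --- stained cells ---------------------------------------------------
    n_st = int(rng.integers(config.n_stained[0], config.n_stained[1] + 1))
    annotations: list = []
    stained_masks: list = []
    stained_meta: list = []
    next_cluster = 0
    for _ in range(n_st):
        placed = False
        for _attempt in range(config.max_attempts):
            a = rng.uniform(*config.stained_axes)
            b = rng.uniform(*config.stained_axes)
            theta = rng.uniform(0.0, np.pi)
            margin = max(a, b) + 2.0
            cluster_id = -1
            if stained_meta and rng.uniform() < config.cluster_prob:
                ref = stained_meta[int(rng.integers(len(stained_meta)))]
                ref_r = float(np.mean(ref.axes))
                new_r = float(np.mean((a, b)))
                dist = (ref_r + new_r) * rng.uniform(0.80, 0.98)
                ang = rng.uniform(0.0, 2.0 * np.pi)
                cx = ref.center[0] + dist * np.cos(ang)
                cy = ref.center[1] + dist * np.sin(ang)
                if not (margin <= cx <= w - margin and margin <= cy <= h - margin):
                    continue
                cluster_id = ref.cluster_id if ref.cluster_id >= 0 else next_cluster
            else:
                cx = rng.uniform(margin, w - margin)
                cy = rng.uniform(margin, h - margin)
            poly = _ellipse_polygon(cx, cy, a, b, theta, w, h)
            mask = rasterize_polygon(poly, h, w)
            area = int(mask.sum())
            if area == 0:
                continue
            ok = True
            for prev_mask, prev_meta in zip(stained_masks, stained_meta):
                overlap = (mask & prev_mask).sum() / area
                in_same_cluster = cluster_id >= 0 and (
                    prev_meta is ref or prev_meta.cluster_id == cluster_id
                )
                if in_same_cluster:
                    if overlap > 0.35:
                        ok = False
                        break
                elif overlap > 0.0:
                    ok = False
                    break
            if not ok:
                continue
            if cluster_id >= 0:
                # Touching means dilated-by-1 rasters intersect the reference.
                ref_idx = stained_meta.index(ref)
                ref_mask = stained_masks[ref_idx]
                if not (binary_dilation(mask, np.ones((3, 3), bool)) & ref_mask).any():
                    continue
                if ref.cluster_id < 0:
                    stained_meta[ref_idx] = replace(ref, cluster_id=cluster_id)
                    next_cluster += 1
            _paint(canvas, mask, config.cytoplasm, rng)
            nuc_scale = float(np.sqrt(config.nucleus_fraction))
            off = rng.uniform(-0.15, 0.15, size=2) * np.array([a, b])
            nuc_poly = _ellipse_polygon(
                cx + off[0], cy + off[1], a * nuc_scale, b * nuc_scale, theta, w, h
            )
            nuc_mask = rasterize_polygon(nuc_poly, h, w) & mask
            _paint(canvas, nuc_mask, config.nucleus, rng)
            annotations.append(poly)
            stained_masks.append(mask)
            meta = CellMeta(
                "stained", (float(cx), float(cy)), (a, b), theta, cluster_id,
                nucleus_center=(float(cx + off[0]), float(cy + off[1])),
                nucleus_axes=(a * nuc_scale, b * nuc_scale),
            )
            stained_meta.append(meta)
            placed = True
            break
        if not placed:
            raise AnnotationError(
                f"infeasible geometry: could not place stained cell after "
                f"{config.max_attempts} attempts"
            )

    cells.extend(stained_meta)  # after cluster-id back-fills

    canvas += rng.normal(0.0, config.texture_noise_sd, size=(h, w, 3))
    image = np.clip(np.round(canvas), 0, 255).astype(np.uint8)

    stained_union = np.zeros((h, w), dtype=bool)
    for m in stained_masks:
        stained_union |= m
    visible_unstained = unstained_painted & ~stained_union

    annotated = AnnotatedImage(image=image, annotations=annotations,
                               identifier=f"synth_seed{config.seed}")
    truth = SynthTruth(stained_annotations=list(annotations),
                       unstained_mask=visible_unstained, cells=cells)
    return annotated, truth


def generate_dataset(config: SynthConfig, n_images: int, out_dir):
    """Write ``n_images`` synthetic images plus VIA JSON and a truth sidecar.

    Per-image seeds are derived deterministically from ``config.seed`` (the
    master seed), so regeneration with the same master seed reproduces the
    dataset byte for byte.  Returns the list of ``(AnnotatedImage,
    SynthTruth)`` pairs.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.default_rng(config.seed).integers(0, 2**31 - 1, size=n_images)
    results = []
    via: dict = {}
    truth_sidecar: dict = {}
    for i, seed in enumerate(seeds):
        cfg = replace(config, seed=int(seed))
        annotated, truth = generate_image(cfg)
        name = f"synth_{i:03d}.png"
        annotated.identifier = name
        write_image(out_dir / name, annotated.image)
        via[name] = annotated.annotations
        truth_sidecar[name] = {
            "unstained_rle": mask_to_rle(truth.unstained_mask),
            "cells": [
                {
                    "kind": c.kind,
                    "center": list(c.center),
                    "axes": list(c.axes),
                    "rotation": c.rotation,
                    "cluster_id": c.cluster_id,
                    "nucleus_center": list(c.nucleus_center) if c.nucleus_center else None,
                    "nucleus_axes": list(c.nucleus_axes) if c.nucleus_axes else None,
                }
                for c in truth.cells
            ],
        }
        results.append((annotated, truth))
    write_via_json(via, out_dir / "annotations.json")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth_sidecar, fh)
    return results


#: Named presets for the command line: sparse fields, heavy clustering, and
#: many unstained cells likely to be occluded by stained ones.
PRESETS = {
    "sparse": {"n_stained": (2, 4), "n_unstained": (2, 5), "cluster_prob": 0.0},
    "clustered": {"n_stained": (4, 8), "cluster_prob": 1.0},
    "occluded": {"n_unstained": (10, 18), "cluster_prob": 0.3},
}


def preset_config(name: str, **overrides) -> SynthConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return SynthConfig(**params)
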