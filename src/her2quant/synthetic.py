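"""Synthetic IHC patch and slide generator with exact ground truth.

The generator renders the staining physics the scoring pipeline assumes:
white background (full transmission), blue-violet hematoxylin nuclei drawn as
filled ellipses, and brown DAB membrane rings drawn as 2 px annuli whose
stained arc covers a controllable fraction of the circumference.  Pixels are
composed by the Beer-Lambert law in optical density space
(``I_c = round(255 * 10**(-sum_s OD_sc * conc_s))``) and quantized to 8 bits
round-half-up, so every rendered intensity has a closed form and the
generator doubles as the round-trip oracle for color deconvolution.

Slides are dyadic pyramids with tissue occupying an irregular tinted region
on white background; per-tile cell parameters are apportioned so the slide's
three aggregate indexes (staining intensity, positive-cell ratio,
circumferential-membrane cell ratio) fall strictly inside the target IHC
class's reference intervals.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy.optimize import brentq
from skimage import draw

from .errors import InvalidInputError, PatchTooCrowdedError
from .slide_io import Pyramid
from .stains import StainVectors, luma, rgb_from_od
from .types import BinaryMask, RgbImage

#: Default cell geometry (pixels at ~0.5 um/px, 20x).
MEMBRANE_RADIUS = 8.0
NUCLEUS_AXIS_RANGE = (3.6, 4.6)
HEMATOXYLIN_OD_RANGE = (0.50, 0.85)
INCOMPLETE_RANGE = (0.35, 0.60)
#: Faint hematoxylin wash over slide tissue (cytoplasm background).
TISSUE_TINT_OD = 0.10

#: Per-class sampling windows for slide-level targets.  Each window lies
#: strictly inside the class's reference interval (see scoring.DEFAULT_TABLE)
#: *and* on the correct side of the midpoint decision boundaries, with margin
#: for rasterization/segmentation noise.
GENERATOR_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "0": {"intensity": (0.0, 0.0), "positive": (0.0, 0.0), "circumferential": (0.0, 0.0)},
    "1+": {"intensity": (0.10, 0.16), "positive": (0.045, 0.11), "circumferential": (0.08, 0.33)},
    "2+": {"intensity": (0.18, 0.35), "positive": (0.14, 0.23), "circumferential": (0.47, 0.58)},
    "3+": {"intensity": (0.55, 0.605), "positive": (0.26, 0.325), "circumferential": (0.63, 0.88)},
}

#: In the "ambiguous staining" mode, 1+ and 2+ slide intensities are drawn
#: from a window that is legal for both classes but straddles their decision
#: boundary, so staining alone cannot separate them while the other two
#: indexes still can.
AMBIGUOUS_INTENSITY: dict[str, tuple[float, float]] = {
    "1+": (0.150, 0.185),
    "2+": (0.150, 0.185),
}

IHC_CLASSES = ("0", "1+", "2+", "3+")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SyntheticCellSpec:
    """Ground truth for one rendered cell."""

    center: tuple[float, float]
    nucleus_axes: tuple[float, float]
    membrane_radius: float
    membrane_completeness: float
    dab_od: float
    is_positive: bool
    hematoxylin_od: float = 0.65
    orientation: float = 0.0
    arc_start: float = 0.0

    def __post_init__(self) -> None:
        if self.membrane_radius <= max(self.nucleus_axes):
            raise InvalidInputError("membrane_radius must exceed nucleus axes")
        if not 0.0 <= self.membrane_completeness <= 1.0:
            raise InvalidInputError("membrane_completeness must be in [0, 1]")


@dataclass
class SyntheticGroundTruth:
    """Per-cell and per-slide truth emitted alongside every rendered raster."""

    cells: list[SyntheticCellSpec]
    tissue_mask: BinaryMask
    cell_label_image: np.ndarray
    target_class: str | None
    rng_seed: int
    tile_size: int | None = None
    tile_origins: list[tuple[int, int]] = field(default_factory=list)
    tile_stats: list[dict] = field(default_factory=list)
    aggregate: dict[str, float] = field(default_factory=dict)

    @property
    def n_positive(self) -> int:
        return sum(c.is_positive for c in self.cells)


def expected_intensity(dab_od: float, vectors: StainVectors | None = None) -> float:
    """Closed-form staining intensity of a pure-DAB pixel at concentration ``dab_od``.

    Matches the measurement definition: ``1 - luma/255`` of the transmitted
    color, before 8-bit quantization.
    """
    vectors = vectors or StainVectors.hdab()
    rgb = 255.0 * np.power(10.0, -dab_od * vectors.od_dab)
    return float(1.0 - luma(rgb[None, None, :])[0, 0] / 255.0)


def dab_od_for_intensity(target: float, vectors: StainVectors | None = None) -> float:
    """Invert :func:`expected_intensity` (monotone in the DAB concentration)."""
    if target <= 0.0:
        return 0.0
    vectors = vectors or StainVectors.hdab()
    return float(brentq(lambda d: expected_intensity(d, vectors) - target, 0.0, 6.0))


def compose_from_od(
    od_h_map: np.ndarray,
    od_dab_map: np.ndarray,
    vectors: StainVectors | None = None,
) -> np.ndarray:
    """Beer-Lambert forward composition of two concentration maps to RGB.

    Serves as the round-trip oracle for :func:`her2quant.stains.deconvolve`.
    """
    vectors = vectors or StainVectors.hdab()
    h = np.asarray(od_h_map, dtype=float)
    d = np.asarray(od_dab_map, dtype=float)
    if h.shape != d.shape:
        raise InvalidInputError("concentration maps must share a shape")
    if h.min() < 0 or d.min() < 0:
        raise InvalidInputError("concentration maps must be non-negative")
    od = h[..., None] * vectors.od_hematoxylin + d[..., None] * vectors.od_dab
    return rgb_from_od(od)


# ---------------------------------------------------------------------------
# cell layout and rendering


def _sample_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_dist: float,
    offset: tuple[float, float] = (0.0, 0.0),
) -> list[tuple[float, float]]:
    """Rejection-sample ``n`` centers with pairwise distance >= ``min_dist``."""
    centers: list[tuple[float, float]] = []
    lo_r, hi_r = margin, shape[0] - margin
    lo_c, hi_c = margin, shape[1] - margin
    if n > 0 and (hi_r <= lo_r or hi_c <= lo_c):
        raise PatchTooCrowdedError("patch too small for the cell margin")
    attempts, limit = 0, max(2000, 400 * n)
    arr = np.empty((0, 2))
    while len(centers) < n:
        if attempts >= limit:
            raise PatchTooCrowdedError(
                f"placed {len(centers)}/{n} cells after {attempts} attempts"
            )
        attempts += 1
        pt = (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))
        if arr.size and (np.hypot(arr[:, 0] - pt[0], arr[:, 1] - pt[1]) < min_dist).any():
            continue
        centers.append(pt)
        arr = np.vstack([arr, pt])
    return [(r + offset[0], c + offset[1]) for r, c in centers]


def _make_specs(
    rng: np.random.Generator,
    centers: list[tuple[float, float]],
    positive: list[bool],
    complete: list[bool],
    dab_od: float,
    membrane_radius: float = MEMBRANE_RADIUS,
) -> list[SyntheticCellSpec]:
    specs = []
    for center, pos, comp in zip(centers, positive, complete):
        axes = np.sort(rng.uniform(*NUCLEUS_AXIS_RANGE, size=2))[::-1]
        h_od = rng.uniform(*HEMATOXYLIN_OD_RANGE)
        theta = rng.uniform(0.0, np.pi)
        arc = rng.uniform(0.0, 2 * np.pi)
        if pos:
            completeness = 1.0 if comp else rng.uniform(*INCOMPLETE_RANGE)
        else:
            completeness = 0.0
        specs.append(
            SyntheticCellSpec(
                center=(float(center[0]), float(center[1])),
                nucleus_axes=(float(axes[0]), float(axes[1])),
                membrane_radius=float(membrane_radius),
                membrane_completeness=float(completeness),
                dab_od=float(dab_od) if pos else 0.0,
                is_positive=bool(pos and dab_od > 0),
                hematoxylin_od=float(h_od),
                orientation=float(theta),
                arc_start=float(arc),
            )
        )
    return specs


def _arc_pixels(spec: SyntheticCellSpec, shape: tuple[int, int]):
    """Pixel coordinates of the stained membrane arc (2 px wide annulus)."""
    r0, c0 = spec.center
    rad = spec.membrane_radius
    lo_r = max(int(r0 - rad - 2), 0)
    hi_r = min(int(r0 + rad + 3), shape[0])
    lo_c = max(int(c0 - rad - 2), 0)
    hi_c = min(int(c0 + rad + 3), shape[1])
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    dist = np.hypot(rr - r0, cc - c0)
    ring = (dist >= rad - 1.0) & (dist < rad + 1.0)
    if spec.membrane_completeness < 1.0:
        ang = np.mod(np.arctan2(rr - r0, cc - c0), 2 * np.pi)
        rel = np.mod(ang - spec.arc_start, 2 * np.pi)
        ring &= rel <= spec.membrane_completeness * 2 * np.pi
    return rr[ring], cc[ring]


def _render_cells(
    shape: tuple[int, int],
    specs: list[SyntheticCellSpec],
    vectors: StainVectors,
    tint_od: float = 0.0,
    tint_mask: np.ndarray | None = None,
):
    od_h = np.zeros(shape, dtype=float)
    od_dab = np.zeros(shape, dtype=float)
    label = np.zeros(shape, dtype=np.uint16)
    for i, spec in enumerate(specs, start=1):
        rr, cc = draw.ellipse(
            spec.center[0],
            spec.center[1],
            spec.nucleus_axes[0],
            spec.nucleus_axes[1],
            shape=shape,
            rotation=spec.orientation,
        )
        od_h[rr, cc] = np.maximum(od_h[rr, cc], spec.hematoxylin_od)
        rr2, cc2 = draw.disk(spec.center, spec.membrane_radius + 1.0, shape=shape)
        label[rr2, cc2] = i
        if spec.dab_od > 0 and spec.membrane_completeness > 0:
            rr3, cc3 = _arc_pixels(spec, shape)
            od_dab[rr3, cc3] = spec.dab_od
    if tint_od > 0:
        tm = np.ones(shape, bool) if tint_mask is None else tint_mask
        od_h = od_h + tint_od * (tm & (od_dab == 0))
    rgb = compose_from_od(od_h, od_dab, vectors)
    return rgb, od_h, od_dab, label


# ---------------------------------------------------------------------------
# public generators


def make_patch(
    n_cells: int,
    positive_fraction: float = 0.0,
    completeness: float = 1.0,
    dab_od: float = 0.8,
    rng_seed: int = 0,
    size: int = 256,
    *,
    vectors: StainVectors | None = None,
    membrane_radius: float = MEMBRANE_RADIUS,
    min_center_distance: float | None = None,
    tint_od: float = 0.0,
) -> tuple[RgbImage, SyntheticGroundTruth]:
    """Render one RGB patch with exact per-cell ground truth.

    Exactly ``round(n_cells * positive_fraction)`` cells carry a DAB membrane
    arc covering ``completeness`` of their circumference at peak optical
    density ``dab_od``; the rest are counterstain-only.  Identical arguments
    and seed give bit-identical output.
    """
    if n_cells < 0:
        raise InvalidInputError("n_cells must be >= 0")
    if not (0.0 <= positive_fraction <= 1.0 and 0.0 <= completeness <= 1.0):
        raise InvalidInputError("fractions must lie in [0, 1]")
    if size < 64:
        raise InvalidInputError("size must be >= 64")
    vectors = vectors or StainVectors.hdab()
    rng = np.random.default_rng(rng_seed)
    min_dist = min_center_distance or (2 * membrane_radius + 4.0)
    margin = membrane_radius + 6.0
    centers = _sample_centers(rng, n_cells, (size, size), margin, min_dist)
    n_pos = _round_half_up(n_cells * positive_fraction)
    order = rng.permutation(n_cells) if n_cells else np.empty(0, int)
    positive = np.zeros(n_cells, bool)
    positive[order[:n_pos]] = True
    specs = _make_specs(
        rng, centers, positive.tolist(), [True] * n_cells, dab_od, membrane_radius
    )
    # scalar-completeness patches: every positive cell gets the same arc length
    for s in specs:
        if s.is_positive:
            s.membrane_completeness = float(completeness)
            s.is_positive = bool(dab_od > 0 and completeness > 0)
            if not s.is_positive:
                s.dab_od = 0.0
    rgb, _, _, label = _render_cells((size, size), specs, vectors, tint_od)
    truth = SyntheticGroundTruth(
        cells=specs,
        tissue_mask=BinaryMask(label > 0),
        cell_label_image=label,
        target_class=None,
        rng_seed=rng_seed,
        tile_size=size,
    )
    return RgbImage(rgb), truth


def make_overlapping_pair(
    rng_seed: int = 0,
    size: int = 128,
    *,
    separation_factor: float = 1.2,
    nucleus_radius: float = 6.0,
    membrane_radius: float = 9.0,
    vectors: StainVectors | None = None,
) -> tuple[RgbImage, SyntheticGroundTruth]:
    """Two adherent cells at ``separation_factor * membrane_radius`` spacing.

    The nuclei merge into a single connected blob, exercising the
    distance-transform watershed split.
    """
    vectors = vectors or StainVectors.hdab()
    rng = np.random.default_rng(rng_seed)
    sep = separation_factor * membrane_radius
    theta = rng.uniform(0.0, np.pi)
    mid = size / 2.0
    dr, dc = (sep / 2.0) * np.sin(theta), (sep / 2.0) * np.cos(theta)
    specs = []
    for sign in (-1.0, 1.0):
        specs.append(
            SyntheticCellSpec(
                center=(mid + sign * dr, mid + sign * dc),
                nucleus_axes=(nucleus_radius, nucleus_radius * 0.95),
                membrane_radius=membrane_radius,
                membrane_completeness=0.0,
                dab_od=0.0,
                is_positive=False,
                hematoxylin_od=float(rng.uniform(*HEMATOXYLIN_OD_RANGE)),
                orientation=float(rng.uniform(0, np.pi)),
            )
        )
    rgb, _, _, label = _render_cells((size, size), specs, vectors)
    truth = SyntheticGroundTruth(
        cells=specs,
        tissue_mask=BinaryMask(label > 0),
        cell_label_image=label,
        target_class=None,
        rng_seed=rng_seed,
        tile_size=size,
    )
    return RgbImage(rgb), truth


def _clamped_count(
    quota: float, denominator: int, window: tuple[float, float]
) -> int:
    """Round ``quota`` keeping ``count / denominator`` inside ``window``.

    Small denominators make the achievable ratios coarse; rounding alone can
    step outside the sampled class window, so the count is clamped to the
    nearest feasible integer (best-effort round when no integer fits).
    """
    if denominator <= 0:
        return 0
    count = _round_half_up(quota)
    lo = math.ceil(window[0] * denominator - 1e-9)
    hi = math.floor(window[1] * denominator + 1e-9)
    if lo <= hi:
        count = min(max(count, lo), hi)
    return min(max(count, 0), denominator)


def _apportion(total: int, weights: list[int]) -> list[int]:
    """Largest-remainder apportionment of ``total`` over integer weights."""
    wsum = sum(weights)
    if wsum == 0 or total == 0:
        return [0] * len(weights)
    quotas = [total * w / wsum for w in weights]
    base = [int(math.floor(q)) for q in quotas]
    short = total - sum(base)
    order = np.argsort([base[i] - quotas[i] for i in range(len(weights))])
    for i in order[:short]:
        base[i] += 1
    return base


@dataclass
class SlidePlan:
    """Sampled per-tile cell specs and the implied slide-level truth."""

    class_label: str
    tile_size: int
    tile_specs: list[list[SyntheticCellSpec]]
    dab_od: float
    aggregate: dict[str, float]
    tile_stats: list[dict]


def plan_slide(
    class_label: str,
    n_tiles: int,
    rng: np.random.Generator,
    *,
    tile_size: int = 512,
    cells_per_tile: tuple[int, int] = (35, 56),
    ambiguous_staining: bool = False,
    vectors: StainVectors | None = None,
) -> SlidePlan:
    """Sample slide-level targets for ``class_label`` and lay out every tile.

    Positive and complete cells are apportioned across tiles by largest
    remainder so the slide totals match the sampled targets to within one
    cell, keeping the aggregates strictly inside the class windows.
    """
    if class_label not in IHC_CLASSES:
        raise InvalidInputError(f"unknown IHC class {class_label!r}")
    if n_tiles < 1:
        raise InvalidInputError("n_tiles must be >= 1")
    ranges = GENERATOR_RANGES[class_label]
    int_window = ranges["intensity"]
    if ambiguous_staining and class_label in AMBIGUOUS_INTENSITY:
        int_window = AMBIGUOUS_INTENSITY[class_label]
    intensity_target = float(rng.uniform(*int_window))
    p_pos = float(rng.uniform(*ranges["positive"]))
    c_frac = float(rng.uniform(*ranges["circumferential"]))
    dab = dab_od_for_intensity(intensity_target, vectors)

    counts = [int(rng.integers(*cells_per_tile)) for _ in range(n_tiles)]
    total = sum(counts)
    total_pos = _clamped_count(total * p_pos, total, ranges["positive"])
    pos_counts = _apportion(total_pos, counts)
    total_complete = _clamped_count(
        total_pos * c_frac, total_pos, ranges["circumferential"]
    )
    complete_counts = _apportion(total_complete, pos_counts)

    margin = MEMBRANE_RADIUS + 6.0
    min_dist = 2 * MEMBRANE_RADIUS + 4.0
    tile_specs, tile_stats = [], []
    for n, npos, ncomp in zip(counts, pos_counts, complete_counts):
        centers = _sample_centers(rng, n, (tile_size, tile_size), margin, min_dist)
        order = rng.permutation(n)
        positive = np.zeros(n, bool)
        positive[order[:npos]] = True
        complete = np.zeros(n, bool)
        complete[order[:ncomp]] = True
        specs = _make_specs(rng, centers, positive.tolist(), complete.tolist(), dab)
        tile_specs.append(specs)
        tile_stats.append({"n_cells": n, "n_positive": npos, "n_complete": ncomp})

    aggregate = {
        "staining_intensity": expected_intensity(dab, vectors) if total_pos else 0.0,
        "positive_cell_ratio": total_pos / total if total else 0.0,
        "circumferential_ratio": total_complete / total_pos if total_pos else 0.0,
    }
    return SlidePlan(class_label, tile_size, tile_specs, dab, aggregate, tile_stats)


def make_slide(
    class_label: str,
    n_tiles: int = 4,
    rng_seed: int = 0,
    *,
    tile_size: int = 512,
    n_levels: int = 4,
    ambiguous_staining: bool = False,
    cells_per_tile: tuple[int, int] = (35, 56),
    vectors: StainVectors | None = None,
) -> tuple[Pyramid, SyntheticGroundTruth]:
    """Render a small pyramidal slide of the requested IHC class.

    The level-0 canvas holds the content tiles on a tile-aligned grid inside
    a white border; an irregular faintly hematoxylin-tinted blob marks the
    tissue.  Levels are 2x-downsampled copies.
    """
    vectors = vectors or StainVectors.hdab()
    rng = np.random.default_rng(rng_seed)
    plan = plan_slide(
        class_label,
        n_tiles,
        rng,
        tile_size=tile_size,
        cells_per_tile=cells_per_tile,
        ambiguous_staining=ambiguous_staining,
        vectors=vectors,
    )
    cols = math.ceil(math.sqrt(n_tiles))
    rows = math.ceil(n_tiles / cols)
    border = tile_size
    shape = (rows * tile_size + 2 * border, cols * tile_size + 2 * border)
    origins = [
        (border + (i // cols) * tile_size, border + (i % cols) * tile_size)
        for i in range(n_tiles)
    ]

    specs: list[SyntheticCellSpec] = []
    for (r0, c0), tile in zip(origins, plan.tile_specs):
        for s in tile:
            s.center = (s.center[0] + r0, s.center[1] + c0)
            specs.append(s)

    # tissue blob: padded tile rectangles plus seeded boundary bumps
    blob = np.zeros(shape, bool)
    pad = 64
    for r0, c0 in origins:
        blob[r0 - pad : r0 + tile_size + pad, c0 - pad : c0 + tile_size + pad] = True
    rmin, rmax = border - pad, border + rows * tile_size + pad
    cmin, cmax = border - pad, border + cols * tile_size + pad
    for _ in range(12):
        side = rng.integers(4)
        if side in (0, 1):
            center = ((rmin, rmax)[side], rng.uniform(cmin, cmax))
        else:
            center = (rng.uniform(rmin, rmax), (cmin, cmax)[side - 2])
        axes = rng.uniform(24, 64, size=2)
        rr, cc = draw.ellipse(center[0], center[1], axes[0], axes[1], shape=shape)
        blob[rr, cc] = True

    rgb, _, _, label = _render_cells(shape, specs, vectors, TISSUE_TINT_OD, blob)
    pyramid = Pyramid.from_level0(rgb, n_levels)
    truth = SyntheticGroundTruth(
        cells=specs,
        tissue_mask=BinaryMask(blob),
        cell_label_image=label,
        target_class=class_label,
        rng_seed=rng_seed,
        tile_size=tile_size,
        tile_origins=origins,
        tile_stats=plan.tile_stats,
        aggregate=plan.aggregate,
    )
    return pyramid, truth


def write_ground_truth(out_dir, truth: SyntheticGroundTruth) -> None:
    """Persist truth as JSON (cells, stats) + 16-bit label TIFF + mask PNG."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells = [
        {
            "center": list(c.center),
            "nucleus_axes": list(c.nucleus_axes),
            "membrane_radius": c.membrane_radius,
            "membrane_completeness": c.membrane_completeness,
            "dab_od": c.dab_od,
            "is_positive": c.is_positive,
        }
        for c in truth.cells
    ]
    payload = {
        "target_class": truth.target_class,
        "rng_seed": truth.rng_seed,
        "tile_size": truth.tile_size,
        "tile_origins": [list(o) for o in truth.tile_origins],
        "tile_stats": truth.tile_stats,
        "aggregate": truth.aggregate,
        "cells": cells,
    }
    (out / "ground_truth.json").write_text(json.dumps(payload, indent=1))
    tifffile.imwrite(out / "cell_labels.tif", truth.cell_label_image)
    tifffile.imwrite(
        out / "tissue_mask.tif", truth.tissue_mask.pixels.astype(np.uint8) * 255
    )
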