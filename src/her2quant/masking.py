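"""Tissue/background separation and tile enumeration.

Whole slides are mostly white background; masking a low-resolution level
before any per-tile work typically discards ~75 % of the area.  The mask is
built in HSV space: background is near-white (zero saturation, undefined
hue), tissue carries both saturation and a non-white hue, so each of the H
and S channels is thresholded by Otsu's method and the per-channel masks are
combined (AND by default).  Small speckle components and small holes (e.g.
thin membranes whose hue falls on the background side) are filtered.
"""
from __future__ import annotations

import warnings

import numpy as np
from skimage.color import rgb2hsv
from skimage.morphology import remove_small_holes, remove_small_objects

from .errors import DegenerateHistogramError, InvalidInputError
from .types import BinaryMask, RgbImage, TileGrid


def otsu_threshold(histogram: np.ndarray) -> int:
    """Threshold of a 256-bin histogram maximizing between-class variance.

    Pixels with value ``<= t`` form the lower class.  Ties are broken toward
    the smallest threshold.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.shape != (256,):
        raise InvalidInputError("expected a 256-bin histogram")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("histogram occupies fewer than two bins")
    bins = np.arange(256, dtype=float)
    w0 = np.cumsum(hist)
    m0 = np.cumsum(hist * bins)
    total, msum = w0[-1], m0[-1]
    w0 = w0[:-1]
    m0 = m0[:-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    var_b = np.zeros(255)
    mu0 = np.divide(m0, w0, out=np.zeros(255), where=valid)
    mu1 = np.divide(msum - m0, w1, out=np.zeros(255), where=valid)
    var_b[valid] = (w0 * w1)[valid] * (mu0 - mu1)[valid] ** 2
    return int(np.argmax(var_b))  # argmax returns the smallest maximizer


def _channel_mask(channel_u8: np.ndarray) -> np.ndarray | None:
    """Otsu foreground (value > t) of one uint8 channel; None if degenerate."""
    hist = np.bincount(channel_u8.ravel(), minlength=256).astype(float)
    try:
        t = otsu_threshold(hist)
    except DegenerateHistogramError:
        return None
    return channel_u8 > t


def tissue_mask(
    image: RgbImage | np.ndarray,
    combine: str = "and",
    min_component_fraction: float = 0.001,
) -> BinaryMask:
    """Separate tissue from white background on one pyramid level.

    The H and S channels (scaled to 0-255) are each thresholded by
    :func:`otsu_threshold`; tissue is the high side of each (saturated,
    non-white hue).  Components and holes smaller than
    ``min_component_fraction`` of the mask area are filtered.
    """
    if isinstance(image, RgbImage):
        pixels, level, ds = image.pixels, image.level, image.downsample
    else:
        pixels, level, ds = np.asarray(image), 0, 1
    hsv = rgb2hsv(pixels)
    masks = []
    for ch in (0, 1):  # hue, saturation
        u8 = np.floor(hsv[..., ch] * 255.0 + 0.5).astype(np.uint8)
        m = _channel_mask(u8)
        if m is not None:
            masks.append(m)
    if not masks:
        warnings.warn("degenerate H and S histograms: all-background slide")
        return BinaryMask(np.zeros(pixels.shape[:2], bool), level, ds)
    if combine == "and":
        mask = np.logical_and.reduce(masks)
    elif combine == "or":
        mask = np.logical_or.reduce(masks)
    else:
        raise InvalidInputError(f"unknown combine mode {combine!r}")
    area = int(mask.sum())
    if area:
        min_size = max(1, int(np.ceil(min_component_fraction * area)))
        mask = remove_small_objects(mask, connectivity=2, max_size=min_size - 1)
        mask = remove_small_holes(mask, connectivity=2, max_size=min_size - 1)
    return BinaryMask(mask, level, ds)


def enumerate_tiles(
    mask: BinaryMask | np.ndarray,
    tile_size: int,
    min_tissue_fraction: float = 0.25,
) -> TileGrid:
    """All non-overlapping level-0 tiles with enough tissue, row-major.

    ``tile_size`` is in level-0 pixels and must be divisible by the mask's
    downsample factor; tiles clipped by the slide edge are not emitted.
    """
    if isinstance(mask, BinaryMask):
        pixels, ds = mask.pixels, mask.downsample
    else:
        pixels, ds = np.asarray(mask, bool), 1
    if tile_size % ds:
        raise InvalidInputError("tile_size must be divisible by the mask downsample")
    s = tile_size // ds
    nr, nc = pixels.shape[0] // s, pixels.shape[1] // s
    grid = TileGrid(tile_size=tile_size)
    if nr == 0 or nc == 0:
        return grid
    frac = (
        pixels[: nr * s, : nc * s]
        .reshape(nr, s, nc, s)
        .mean(axis=(1, 3))
    )
    for i in range(nr):
        for j in range(nc):
            if frac[i, j] >= min_tissue_fraction:
                grid.tiles.append((i * tile_size, j * tile_size, float(frac[i, j])))
    return grid
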