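"""Multi-resolution slide container and plain-file readers/writers.

A :class:`Pyramid` holds the dyadic level stack of a whole-slide raster in
memory.  Slides are persisted as multi-page TIFF (one page per level, level 0
first); a single PNG/TIFF page is read as a one-level pyramid.  Vendor WSI
formats are out of scope; convert externally or plug in a reader that yields
the same level stack.
"""
from __future__ import annotations

import math
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.transform import resize

from .errors import InvalidInputError


def downsampled_levels(level0: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """Build a dyadic pyramid: level k has dims ``ceil(level-0 dims / 2**k)``."""
    levels = [np.asarray(level0, dtype=np.uint8)]
    h, w = level0.shape[:2]
    for k in range(1, n_levels):
        hk, wk = math.ceil(h / 2**k), math.ceil(w / 2**k)
        small = resize(
            level0.astype(float), (hk, wk, 3), order=1, anti_aliasing=True
        )
        levels.append(np.clip(np.floor(small + 0.5), 0, 255).astype(np.uint8))
    return levels


class Pyramid:
    """An in-memory multi-level slide raster (level 0 = full resolution)."""

    def __init__(self, levels: list[np.ndarray]):
        if not levels:
            raise InvalidInputError("pyramid needs at least one level")
        self.levels = [np.asarray(lv, dtype=np.uint8) for lv in levels]
        for lv in self.levels:
            if lv.ndim != 3 or lv.shape[2] != 3:
                raise InvalidInputError("pyramid levels must be HxWx3 uint8")

    @classmethod
    def from_level0(cls, level0: np.ndarray, n_levels: int = 4) -> "Pyramid":
        return cls(downsampled_levels(level0, n_levels))

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def level_dimensions(self) -> list[tuple[int, int]]:
        return [lv.shape[:2] for lv in self.levels]

    def downsample(self, level: int) -> int:
        return 2**level

    def read_region(
        self, origin: tuple[int, int], size: int, level: int = 0
    ) -> np.ndarray:
        """Read a ``size x size`` level-``level`` region.

        ``origin`` is the (row, col) of the region's top-left corner in
        level-0 pixels; regions extending past the slide edge are padded
        with white.
        """
        d = self.downsample(level)
        r0, c0 = origin[0] // d, origin[1] // d
        s = size // d
        lv = self.levels[level]
        out = np.full((s, s, 3), 255, dtype=np.uint8)
        r1, c1 = min(r0 + s, lv.shape[0]), min(c0 + s, lv.shape[1])
        if r1 > r0 and c1 > c0:
            out[: r1 - r0, : c1 - c0] = lv[r0:r1, c0:c1]
        return out

    def save(self, path) -> None:
        """Write as a multi-page TIFF, one page per level."""
        path = Path(path)
        with tifffile.TiffWriter(path) as tif:
            for lv in self.levels:
                tif.write(lv, photometric="rgb")

    @classmethod
    def open(cls, path) -> "Pyramid":
        """Open a multi-page TIFF pyramid or a flat PNG/TIFF image."""
        path = Path(path)
        if not path.exists():
            raise InvalidInputError(f"slide not found: {path}")
        if path.suffix.lower() in {".tif", ".tiff"}:
            with tifffile.TiffFile(path) as tif:
                levels = [page.asarray() for page in tif.pages]
            return cls(levels)
        arr = iio.imread(path)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        return cls([arr[..., :3]])
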