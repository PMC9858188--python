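"""Shared raster containers.

All coordinates in this package are 0-based, half-open ``[r, r+size) x
[c, c+size)`` ``(row, col)`` pairs expressed in level-0 pixels, regardless of
which pyramid level an array was computed on.  A level-``k`` raster covers the
same physical extent as level 0 at ``1/2**k`` the resolution.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RgbImage:
    """An 8-bit RGB raster taken from one pyramid level.

    ``downsample`` is the linear scale factor relative to level 0 and equals
    ``2**level`` for a standard dyadic pyramid.
    """

    pixels: np.ndarray
    level: int = 0
    downsample: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("RgbImage expects an HxWx3 array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class BinaryMask:
    """Boolean raster aligned to the image it was derived from."""

    pixels: np.ndarray
    level: int = 0
    downsample: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def tissue_fraction(self) -> float:
        return float(self.pixels.mean()) if self.pixels.size else 0.0


@dataclass
class TileGrid:
    """Non-overlapping, axis-aligned tiles admitted by a tissue mask.

    ``tiles`` holds ``(row0, col0, tissue_fraction)`` triples in row-major
    order; ``row0``/``col0`` are level-0 pixel offsets, multiples of
    ``tile_size``.
    """

    tile_size: int
    tiles: list[tuple[int, int, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tiles)

    def origins(self) -> list[tuple[int, int]]:
        return [(r, c) for r, c, _ in self.tiles]

    def index_shape(self) -> tuple[int, int]:
        """Shape of the smallest tile-index array covering all tiles."""
        if not self.tiles:
            return (0, 0)
        nr = max(r for r, _, _ in self.tiles) // self.tile_size + 1
        nc = max(c for _, c, _ in self.tiles) // self.tile_size + 1
        return (nr, nc)


@dataclass
class ProbMap:
    """Tumor probabilities on the tile grid; NaN marks non-tissue tiles."""

    values: np.ndarray
    tile_size: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")
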