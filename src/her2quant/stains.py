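"""Optical-density color model and stain separation.

Bright-field IHC obeys the Beer-Lambert law: each stain attenuates
transmitted light exponentially, so stain concentrations add linearly in
optical density, ``OD_c = -log10(I_c / I_0)`` per RGB channel ``c`` with
``I_0 = 255``.  A stain is characterised by its unit OD vector; unmixing an
image into per-stain concentration maps is a multiplication by the inverse of
the 3x3 stain matrix (color deconvolution).

Default stain vectors are the Ruifrok-Johnston hematoxylin/DAB pair with the
residual channel completing an orthogonal basis.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .errors import InvalidInputError

#: Ruifrok-Johnston optical-density vectors for the H-DAB stain combination.
RUIFROK_HEMATOXYLIN = (0.650, 0.704, 0.286)
RUIFROK_DAB = (0.268, 0.570, 0.776)

_LN10 = float(np.log(10.0))


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise InvalidInputError("stain vector must be nonzero")
    return v / n


@dataclass(frozen=True)
class StainVectors:
    """Unit OD vectors for hematoxylin, DAB and the residual channel."""

    od_hematoxylin: np.ndarray
    od_dab: np.ndarray
    od_residual: np.ndarray

    def __post_init__(self) -> None:
        for name in ("od_hematoxylin", "od_dab", "od_residual"):
            object.__setattr__(self, name, _unit(getattr(self, name)))
        if np.linalg.cond(self.matrix) >= 1e6:
            raise InvalidInputError("stain matrix is ill-conditioned")

    @classmethod
    def from_pair(cls, od_hematoxylin, od_dab) -> "StainVectors":
        """Complete a basis from two stain vectors via their cross product."""
        h = _unit(od_hematoxylin)
        d = _unit(od_dab)
        return cls(h, d, _unit(np.cross(h, d)))

    @classmethod
    def hdab(cls) -> "StainVectors":
        """The default Ruifrok-Johnston H-DAB basis."""
        return cls.from_pair(RUIFROK_HEMATOXYLIN, RUIFROK_DAB)

    @cached_property
    def matrix(self) -> np.ndarray:
        """3x3 matrix with stain OD vectors as rows (H, DAB, residual)."""
        return np.vstack([self.od_hematoxylin, self.od_dab, self.od_residual])

    @cached_property
    def inverse(self) -> np.ndarray:
        """The deconvolution matrix: inverse of the stain OD matrix."""
        return np.linalg.inv(self.matrix)


@dataclass
class StainMaps:
    """Per-stain concentration maps from color deconvolution (OD units)."""

    h_map: np.ndarray
    dab_map: np.ndarray
    residual_map: np.ndarray


def od_from_rgb(pixels: np.ndarray, base: str = "log10") -> np.ndarray:
    """Convert 8-bit RGB to optical density, flooring intensity at 1.

    The floor avoids infinite OD at fully absorbed pixels; with it, OD per
    channel is bounded by log10(255) ~ 2.41.
    """
    p = np.maximum(np.asarray(pixels, dtype=float), 1.0)
    od = -np.log10(p / 255.0)
    if base == "ln":
        od = od * _LN10
    elif base != "log10":
        raise InvalidInputError(f"unknown OD base {base!r}")
    return od


def rgb_from_od(od: np.ndarray, base: str = "log10") -> np.ndarray:
    """Invert :func:`od_from_rgb`: transmitted light, quantized round-half-up."""
    od = np.asarray(od, dtype=float)
    if base == "ln":
        od = od / _LN10
    elif base != "log10":
        raise InvalidInputError(f"unknown OD base {base!r}")
    t = np.power(10.0, -od)
    return np.clip(np.floor(255.0 * t + 0.5), 0, 255).astype(np.uint8)


def deconvolve(
    patch: np.ndarray, vectors: StainVectors | None = None, base: str = "log10"
) -> StainMaps:
    """Separate an RGB patch into H / DAB / residual concentration maps.

    Concentrations are the OD pixel vectors multiplied by the inverse stain
    matrix; physically meaningless negative outputs are floored at zero.
    """
    vectors = vectors or StainVectors.hdab()
    pixels = np.asarray(patch)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise InvalidInputError("deconvolve expects an HxWx3 RGB patch")
    od = od_from_rgb(pixels, base=base)
    conc = od.reshape(-1, 3) @ vectors.inverse
    conc = np.maximum(conc, 0.0).reshape(pixels.shape)
    return StainMaps(conc[..., 0], conc[..., 1], conc[..., 2])


def luma(pixels: np.ndarray) -> np.ndarray:
    """Rec. 601 luma of an 8-bit RGB array, in [0, 255]."""
    p = np.asarray(pixels, dtype=float)
    return p[..., 0] * 0.299 + p[..., 1] * 0.587 + p[..., 2] * 0.114
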