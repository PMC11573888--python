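"""Color-space machinery for H&E histology.

RGB <-> optical density conversion (Beer-Lambert), stain deconvolution with
a configurable stain matrix, and Reinhard-style color normalization of
tissue regions in CIELAB space.

Stain amounts are linear in optical density (OD): a pixel transmitting a
fraction T of incident light per channel has OD = -log10(T), and the OD of a
mix of stains is the density-weighted sum of the stains' unit OD vectors.
Deconvolution inverts that linear model per pixel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.color import lab2rgb, rgb2lab

# Ruifrok & Johnston style H&E OD vectors (columns: hematoxylin, eosin,
# residual), each normalized to unit length.
_RUIFROK_HE = np.array(
    [
        [0.650, 0.072, 0.268],
        [0.704, 0.990, 0.570],
        [0.286, 0.105, 0.776],
    ]
)


@dataclass(frozen=True)
class StainMatrix:
    """Columns are unit OD vectors for hematoxylin, eosin and residual."""

    columns: np.ndarray = field(default_factory=lambda: _RUIFROK_HE.copy())

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns, dtype=float)
        if cols.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        norms = np.linalg.norm(cols, axis=0)
        if np.any(norms <= 0):
            raise ValueError("stain vectors must be nonzero")
        object.__setattr__(self, "columns", cols / norms)
        if np.linalg.matrix_rank(self.columns[:, :2]) < 2:
            raise ValueError("hematoxylin and eosin vectors are collinear")

    @property
    def hematoxylin(self) -> np.ndarray:
        return self.columns[:, 0]

    @property
    def eosin(self) -> np.ndarray:
        return self.columns[:, 1]


@dataclass(frozen=True)
class ReferenceStats:
    """Per-channel mean/std of tissue pixels in CIELAB, from a reference image."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float).reshape(3)
        std = np.asarray(self.std, dtype=float).reshape(3)
        if np.any(std <= 0):
            raise ValueError("reference standard deviations must be > 0")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "std", std)

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean.tolist(), "std": self.std.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "ReferenceStats":
        d = json.loads(text)
        return cls(mean=np.asarray(d["mean"]), std=np.asarray(d["std"]))


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Beer-Lambert optical density: od = -log10((rgb + 1) / 256).

    Accepts uint8 or float arrays on the 0..255 scale; the +1 offset keeps
    pure black finite (OD ~ 2.408 per channel).
    """
    vals = np.asarray(rgb, dtype=float)
    od = -np.log10((vals + 1.0) / 256.0)
    return np.maximum(od, 0.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, rounded and clipped to uint8."""
    rgb = 256.0 * np.power(10.0, -np.asarray(od, dtype=float)) - 1.0
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def forward_render(densities: np.ndarray, matrix: StainMatrix | None = None) -> np.ndarray:
    """Render an RGB image from per-pixel stain densities (H, E, residual).

    The forward model underlying :func:`deconvolve`; used by the synthetic
    slide generator and as the oracle for deconvolution round-trip tests.

    Parameters
    ----------
    densities : (..., 3) array of nonnegative stain densities.
    """
    matrix = matrix or StainMatrix()
    dens = np.asarray(densities, dtype=float)
    od = dens @ matrix.columns.T
    return od_to_rgb(od)


def deconvolve(tile: np.ndarray, matrix: StainMatrix | None = None) -> np.ndarray:
    """Unmix an RGB tile into per-pixel stain density maps.

    Returns an array shaped like ``tile`` whose last axis holds
    (hematoxylin, eosin, residual) densities; negative solutions are clipped
    to zero.
    """
    matrix = matrix or StainMatrix()
    if abs(np.linalg.det(matrix.columns)) < 1e-10:
        raise ValueError("singular stain matrix")
    od = rgb_to_od(tile)
    inv = np.linalg.inv(matrix.columns)
    densities = od @ inv.T
    return np.maximum(densities, 0.0)


def compute_reference_stats(tile: np.ndarray, tissue_mask: np.ndarray) -> ReferenceStats:
    """LAB mean/std over the masked tissue pixels of a reference image."""
    mask = np.asarray(tissue_mask, dtype=bool)
    if not mask.any():
        raise ValueError("tissue mask is empty")
    lab = rgb2lab(np.asarray(tile, dtype=np.uint8))
    pix = lab[mask]
    std = pix.std(axis=0)
    std = np.where(std <= 1e-6, 1e-6, std)
    return ReferenceStats(mean=pix.mean(axis=0), std=std)


def reinhard_normalize(
    tile: np.ndarray, tissue_mask: np.ndarray, ref: ReferenceStats
) -> np.ndarray:
    """Match masked LAB mean/std of ``tile`` to ``ref``; glass left untouched.

    An empty mask returns the tile unchanged with a warning. Output is uint8
    RGB, clipped to the valid gamut.
    """
    tile = np.asarray(tile)
    mask = np.asarray(tissue_mask, dtype=bool)
    if tile.ndim != 3 or tile.shape[2] != 3:
        raise ValueError("expected an RGB tile")
    if not mask.any():
        warnings.warn("empty tissue mask; tile returned unchanged", stacklevel=2)
        return tile.copy()
    lab = rgb2lab(tile.astype(np.uint8))
    pix = lab[mask]
    mean = pix.mean(axis=0)
    std = pix.std(axis=0)
    std = np.where(std <= 1e-6, 1e-6, std)
    lab[mask] = (pix - mean) / std * ref.std + ref.mean
    out = lab2rgb(lab)
    out8 = np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)
    result = tile.astype(np.uint8).copy()
    result[mask] = out8[mask]
    return result
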