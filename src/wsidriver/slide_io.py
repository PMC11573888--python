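"""Pyramidal slide access: open tiled TIFF pyramids, resolve magnification
to a pyramid level, enumerate candidate tile coordinates and read regions.

Coordinates are 0-based, half-open and level-local, matching numpy slicing.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from skimage.transform import resize

DEFAULT_MAGNIFICATION = 20.0
TILE_SIZE = 512


@dataclass(frozen=True)
class SlideLevel:
    width: int
    height: int
    downsample: float


@dataclass(frozen=True)
class TileCoordinate:
    """A square tile at (x, y) top-left, level-local pixels, half-open."""

    level: int
    x: int
    y: int
    size: int = TILE_SIZE


class SlidePyramid:
    """Multi-resolution image with magnification metadata.

    Levels are ordered largest first; downsample factors strictly increase
    from 1. Backed either by in-memory arrays or by a multi-page TIFF read
    lazily through tifffile.
    """

    def __init__(
        self,
        levels: list[SlideLevel],
        base_magnification: float,
        arrays: list[np.ndarray] | None = None,
        tiff_path: str | Path | None = None,
    ):
        if not levels:
            raise ValueError("pyramid has no levels")
        downs = [lv.downsample for lv in levels]
        if downs[0] != 1 or any(b <= a for a, b in zip(downs, downs[1:])):
            raise ValueError("downsample factors must strictly increase from 1")
        self.levels = levels
        self.base_magnification = float(base_magnification)
        self._arrays: list[np.ndarray | None] = (
            list(arrays) if arrays is not None else [None] * len(levels)
        )
        self._tiff_path = Path(tiff_path) if tiff_path is not None else None

    @classmethod
    def from_arrays(
        cls, arrays: list[np.ndarray], base_magnification: float = DEFAULT_MAGNIFICATION
    ) -> "SlidePyramid":
        base_w = arrays[0].shape[1]
        levels = [
            SlideLevel(a.shape[1], a.shape[0], base_w / a.shape[1]) for a in arrays
        ]
        return cls(levels, base_magnification, arrays=arrays)

    def level_array(self, level: int) -> np.ndarray:
        """Full RGB array of one level (cached after first read)."""
        if not 0 <= level < len(self.levels):
            raise IndexError(f"level {level} out of range")
        if self._arrays[level] is None:
            with tifffile.TiffFile(self._tiff_path) as tf:
                self._arrays[level] = tf.pages[level].asarray()
        return self._arrays[level]

    def read_level_region(self, level: int, x: int, y: int, w: int, h: int) -> np.ndarray:
        lv = self.levels[level]
        if x < 0 or y < 0 or x + w > lv.width or y + h > lv.height:
            raise ValueError(
                f"region ({x},{y},{w},{h}) out of bounds for level {level} "
                f"({lv.width}x{lv.height})"
            )
        return self.level_array(level)[y : y + h, x : x + w]


def write_slide(
    arrays: list[np.ndarray],
    path: str | Path,
    base_magnification: float = DEFAULT_MAGNIFICATION,
) -> None:
    """Write a pyramid as a multi-page tiled TIFF with magnification metadata."""
    path = Path(path)
    base_w = arrays[0].shape[1]
    meta = {
        "base_magnification": base_magnification,
        "downsamples": [base_w / a.shape[1] for a in arrays],
    }
    with tifffile.TiffWriter(path) as tw:
        for i, arr in enumerate(arrays):
            tw.write(
                arr,
                tile=(256, 256),
                photometric="rgb",
                description=json.dumps(meta) if i == 0 else None,
            )


def open_slide(
    path: str | Path, default_magnification: float = DEFAULT_MAGNIFICATION
) -> SlidePyramid:
    """Open a tiled pyramidal TIFF.

    Magnification is read from the JSON ImageDescription tag; a missing tag
    falls back to ``default_magnification`` with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"slide not found: {path}")
    try:
        with tifffile.TiffFile(path) as tf:
            pages = tf.pages
            shapes = [(p.imagelength, p.imagewidth) for p in pages]
            desc = pages[0].description
    except Exception as exc:  # pragma: no cover - corrupt file path
        raise ValueError(f"unreadable slide: {path}: {exc}") from exc
    base_mag = None
    if desc:
        try:
            base_mag = float(json.loads(desc).get("base_magnification"))
        except (ValueError, TypeError, json.JSONDecodeError):
            base_mag = None
    if base_mag is None:
        warnings.warn(
            f"{path}: no magnification tag; assuming {default_magnification}x",
            stacklevel=2,
        )
        base_mag = default_magnification
    base_w = shapes[0][1]
    levels = [SlideLevel(w, h, base_w / w) for (h, w) in shapes]
    return SlidePyramid(levels, base_mag, tiff_path=path)


def magnification_to_level(
    slide: SlidePyramid, target_mag: float
) -> tuple[int, float]:
    """Pick the smallest pyramid level still at or above ``target_mag``.

    Returns (level index, residual_scale >= 1); residual_scale is the factor
    by which regions read at that level must be downscaled to reach the
    target magnification exactly.
    """
    if target_mag > slide.base_magnification:
        raise ValueError(
            f"upsampling refused: target {target_mag}x exceeds base "
            f"{slide.base_magnification}x"
        )
    best = None
    for i, lv in enumerate(slide.levels):
        eff = slide.base_magnification / lv.downsample
        if eff >= target_mag:
            best = (i, eff / target_mag)
    assert best is not None  # level 0 always qualifies
    return best


def enumerate_candidates(
    slide: SlidePyramid,
    tile_size: int = TILE_SIZE,
    stride: int | None = None,
    level: int = 0,
    residual_scale: float = 1.0,
):
    """Row-major grid of candidate tile coordinates at one level.

    ``tile_size`` is the output tile edge; at the pyramid level each tile
    occupies ``tile_size * residual_scale`` pixels. Partial edge tiles are
    dropped. The default stride equals the tile size (non-overlapping).
    """
    if stride is None:
        stride = tile_size
    if stride <= 0:
        raise ValueError("stride must be positive")
    lv = slide.levels[level]
    span = int(round(tile_size * residual_scale))
    stride_px = int(round(stride * residual_scale))
    if span > lv.width or span > lv.height:
        raise ValueError("tile larger than slide level")
    for y in range(0, lv.height - span + 1, stride_px):
        for x in range(0, lv.width - span + 1, stride_px):
            yield TileCoordinate(level=level, x=x, y=y, size=tile_size)


def read_region(
    slide: SlidePyramid, coord: TileCoordinate, residual_scale: float = 1.0
) -> np.ndarray:
    """Read one tile as uint8 RGB of shape (size, size, 3).

    With residual_scale > 1 a larger region is read and downscaled so the
    output is at the requested magnification.
    """
    span = int(round(coord.size * residual_scale))
    region = slide.read_level_region(coord.level, coord.x, coord.y, span, span)
    if region.ndim == 2:
        region = np.stack([region] * 3, axis=-1)
    if span != coord.size:
        region = resize(
            region, (coord.size, coord.size), anti_aliasing=True, preserve_range=True
        )
        region = np.clip(np.round(region), 0, 255)
    return region.astype(np.uint8)


def get_thumbnail(slide: SlidePyramid, downsample: float = 32.0) -> np.ndarray:
    """Whole-slide RGB thumbnail at approximately the requested downsample.

    Reads the smallest pyramid level not coarser than ``downsample`` and
    resizes the remainder.
    """
    src = 0
    for i, lv in enumerate(slide.levels):
        if lv.downsample <= downsample:
            src = i
    arr = slide.level_array(src)
    lv = slide.levels[src]
    out_w = max(1, int(round(lv.width * lv.downsample / downsample)))
    out_h = max(1, int(round(lv.height * lv.downsample / downsample)))
    if (out_h, out_w) != arr.shape[:2]:
        arr = resize(arr, (out_h, out_w), anti_aliasing=True, preserve_range=True)
        arr = np.clip(np.round(arr), 0, 255)
    return arr.astype(np.uint8)


def ceil_div(a: int, b: int) -> int:
    return math.ceil(a / b)
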