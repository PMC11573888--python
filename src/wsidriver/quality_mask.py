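"""Slide-level quality control: tissue detection on a thumbnail and masks
for the four artifact kinds excluded from tiling (blood, bubbles, blurred
regions, pen marks).

Tissue/pen/blood/bubble run on a coarse thumbnail (default 32x downsample);
blur is scale-sensitive, so it is measured on a finer rendering (default 4x)
and reduced onto the thumbnail grid. All thresholds are configuration with
stated defaults — they are this module's to own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_holes, remove_small_objects

from .slide_io import SlidePyramid, TileCoordinate, get_thumbnail


@dataclass(frozen=True)
class QcConfig:
    saturation_threshold: float = 0.08  # Otsu fallback floor
    white_value_threshold: float = 0.97  # above this luminance = glass
    blur_variance_threshold: float = 12.0  # Laplacian variance floor at blur_downsample
    blur_downsample: float = 4.0
    blur_window: int = 16
    pen_hue_ranges: tuple = ((0.25, 0.45), (0.5, 0.72))  # green, blue ink
    pen_saturation_min: float = 0.5
    blood_redness_threshold: float = 1.7  # R vs max(G, B) dominance ratio
    bubble_value_min: float = 0.93
    min_tissue_fraction_per_tile: float = 0.5
    thumbnail_downsample: float = 32.0
    speck_area_px: int = 16  # on the thumbnail grid

    def __post_init__(self) -> None:
        for name in ("saturation_threshold", "min_tissue_fraction_per_tile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.blur_variance_threshold < 0:
            raise ValueError("blur_variance_threshold must be >= 0")


@dataclass
class QualityMask:
    """Boolean masks on the thumbnail grid; usable = tissue minus artifacts."""

    tissue: np.ndarray
    artifact_masks: dict[str, np.ndarray]
    usable: np.ndarray
    thumbnail_downsample: float

    def __post_init__(self) -> None:
        union = np.zeros_like(self.tissue)
        for m in self.artifact_masks.values():
            union |= m
        assert self.usable.shape == self.tissue.shape
        assert not (self.usable & union).any()
        assert not (self.usable & ~self.tissue).any()


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image")
    return img


def compute_tissue_mask(thumbnail: np.ndarray, cfg: QcConfig | None = None) -> np.ndarray:
    """Tissue = saturated, non-white pixels; Otsu-refined with a fixed floor.

    Otsu on the saturation channel separates stained tissue from glass; when
    the histogram is effectively unimodal (blank or fully covered slides)
    the fixed ``saturation_threshold`` is used instead. Small holes are
    filled and specks removed.
    """
    cfg = cfg or QcConfig()
    thumbnail = _check_rgb(thumbnail)
    hsv = rgb2hsv(thumbnail.astype(np.uint8))
    sat, val = hsv[..., 1], hsv[..., 2]
    thr = cfg.saturation_threshold
    if sat.std() > 0.02:  # bimodal enough for Otsu to mean something
        try:
            thr = max(float(threshold_otsu(sat)), cfg.saturation_threshold)
        except ValueError:
            pass
    mask = (sat > thr) & (val < cfg.white_value_threshold)
    if mask.any():
        mask = remove_small_objects(mask, max_size=cfg.speck_area_px)
        mask = remove_small_holes(mask, max_size=4 * cfg.speck_area_px)
    return mask


def _block_any(mask: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Reduce a fine boolean mask onto a coarser grid: true if any pixel of
    the block is true (keeps thin strokes visible at thumbnail scale)."""
    fy = max(1, round(mask.shape[0] / out_shape[0]))
    fx = max(1, round(mask.shape[1] / out_shape[1]))
    py = (-mask.shape[0]) % fy
    px = (-mask.shape[1]) % fx
    if py or px:
        mask = np.pad(mask, ((0, py), (0, px)))
    r = mask.reshape(mask.shape[0] // fy, fy, mask.shape[1] // fx, fx)
    out = r.any(axis=(1, 3))
    out = out[: out_shape[0], : out_shape[1]]
    if out.shape != out_shape:
        out = np.pad(
            out, ((0, out_shape[0] - out.shape[0]), (0, out_shape[1] - out.shape[1]))
        )
    return out


def _block_frac(mask: np.ndarray, out_shape: tuple[int, int], frac: float) -> np.ndarray:
    """Coarse cell is true when at least ``frac`` of its block is true."""
    fy = max(1, round(mask.shape[0] / out_shape[0]))
    fx = max(1, round(mask.shape[1] / out_shape[1]))
    py = (-mask.shape[0]) % fy
    px = (-mask.shape[1]) % fx
    if py or px:
        mask = np.pad(mask, ((0, py), (0, px)))
    r = mask.reshape(mask.shape[0] // fy, fy, mask.shape[1] // fx, fx)
    out = r.mean(axis=(1, 3)) >= frac
    out = out[: out_shape[0], : out_shape[1]]
    if out.shape != out_shape:
        out = np.pad(
            out, ((0, out_shape[0] - out.shape[0]), (0, out_shape[1] - out.shape[1]))
        )
    return out


def _local_laplacian_variance(gray: np.ndarray, window: int) -> np.ndarray:
    lap = ndi.laplace(gray)
    mean = ndi.uniform_filter(lap, size=window)
    sq = ndi.uniform_filter(lap * lap, size=window)
    return np.maximum(sq - mean * mean, 0.0)


def detect_artifacts(
    thumbnail: np.ndarray,
    cfg: QcConfig | None = None,
    tissue: np.ndarray | None = None,
    fine_thumbnail: np.ndarray | None = None,
    fine_downsample: float | None = None,
) -> dict[str, np.ndarray]:
    """Per-kind boolean artifact masks on the thumbnail grid.

    Pen: saturated pixels whose hue falls in the configured ink windows.
    Blood: strong red-channel dominance. Bubble: bright low-texture blobs
    enclosed by tissue. Blur: local Laplacian variance below threshold
    within tissue, measured on ``fine_thumbnail`` when provided (blur is
    invisible at 32x) and reduced onto the thumbnail grid.
    """
    cfg = cfg or QcConfig()
    thumbnail = _check_rgb(thumbnail)
    if tissue is None:
        tissue = compute_tissue_mask(thumbnail, cfg)
    shape = thumbnail.shape[:2]
    val = rgb2hsv(thumbnail.astype(np.uint8))[..., 2]

    # chroma artifacts on the finest rendering available: thin pen strokes
    # average away at 32x
    chroma_src = fine_thumbnail if fine_thumbnail is not None else thumbnail
    chroma_src = _check_rgb(chroma_src)
    hsv_f = rgb2hsv(chroma_src.astype(np.uint8))
    hue_f, sat_f = hsv_f[..., 0], hsv_f[..., 1]
    rgbf = chroma_src.astype(float)

    # ink (green/blue marker) has G > R; hematoxylin nuclei and eosin tissue
    # have R >= G, which keeps dark nuclei out of the blue-ink hue window
    pen_f = np.zeros(chroma_src.shape[:2], dtype=bool)
    for lo, hi in cfg.pen_hue_ranges:
        pen_f |= (hue_f >= lo) & (hue_f <= hi) & (sat_f >= cfg.pen_saturation_min)
    pen_f &= rgbf[..., 1] > rgbf[..., 0] + 20
    pen = _block_any(pen_f, shape)

    other = np.maximum(rgbf[..., 1], rgbf[..., 2])
    blood_f = (rgbf[..., 0] > cfg.blood_redness_threshold * other) & (rgbf[..., 0] > 80)
    blood = _block_any(blood_f, shape)

    # bubble: bright, featureless blobs enclosed by tissue (brightness and
    # texture judged at the fine scale, enclosure at the thumbnail scale)
    val_f = hsv_f[..., 2]
    lowtex_f = _local_laplacian_variance(val_f * 255.0, 7) < 4.0
    cand = _block_frac((val_f > cfg.bubble_value_min) & lowtex_f, shape, 0.5)
    bubble = np.zeros(shape, dtype=bool)
    labels, n = ndi.label(cand)
    for i in range(1, n + 1):
        comp = labels == i
        if comp.sum() < cfg.speck_area_px:
            continue
        rows, cols = np.nonzero(comp)
        if rows.min() == 0 or cols.min() == 0 or rows.max() == shape[0] - 1 or cols.max() == shape[1] - 1:
            continue
        ring = ndi.binary_dilation(comp, iterations=2) & ~comp
        if ring.any() and (tissue[ring].mean() > 0.6):
            bubble |= ndi.binary_dilation(comp, iterations=1)

    # blur: Laplacian variance at a scale where sharp nuclei still register;
    # a dilation of half the variance window compensates boundary shrinkage
    if fine_thumbnail is not None:
        gray = chroma_src.astype(float).mean(axis=2)
        blur_f = _local_laplacian_variance(gray, cfg.blur_window) < cfg.blur_variance_threshold
        blur_f = ndi.binary_dilation(blur_f, iterations=cfg.blur_window // 4)
        blur = _block_frac(blur_f, shape, 0.4)
    else:
        gray = thumbnail.astype(float).mean(axis=2)
        lv_thumb = _local_laplacian_variance(gray, max(3, cfg.blur_window // 4))
        blur = lv_thumb < cfg.blur_variance_threshold
    blur &= tissue & ~pen & ~blood

    # drop isolated false-positive pixels only; thin pen strokes reduced to
    # the thumbnail grid can legitimately be small components
    masks = {"pen": pen, "blood": blood, "bubble": bubble, "blur": blur}
    for kind, m in masks.items():
        if m.any():
            masks[kind] = remove_small_objects(m, max_size=3)
    return masks


def build_quality_mask(slide: SlidePyramid, cfg: QcConfig | None = None) -> QualityMask:
    """Run the full QC stage for one slide."""
    cfg = cfg or QcConfig()
    thumb = get_thumbnail(slide, cfg.thumbnail_downsample)
    fine = get_thumbnail(slide, cfg.blur_downsample)
    tissue = compute_tissue_mask(thumb, cfg)
    artifacts = detect_artifacts(
        thumb, cfg, tissue=tissue, fine_thumbnail=fine, fine_downsample=cfg.blur_downsample
    )
    usable = tissue.copy()
    for m in artifacts.values():
        usable &= ~m
    return QualityMask(
        tissue=tissue,
        artifact_masks=artifacts,
        usable=usable,
        thumbnail_downsample=cfg.thumbnail_downsample,
    )


def tile_usable_fraction(mask: QualityMask, coord: TileCoordinate) -> float:
    """Fraction of a level-0 tile footprint that is usable tissue."""
    ds = mask.thumbnail_downsample
    h, w = mask.usable.shape
    r0 = coord.y / ds
    c0 = coord.x / ds
    r1 = (coord.y + coord.size) / ds
    c1 = (coord.x + coord.size) / ds
    if r0 < 0 or c0 < 0 or r1 > h + 1e-6 or c1 > w + 1e-6:
        raise ValueError("tile coordinate outside mask extent")
    ri0, ri1 = int(np.floor(r0)), min(h, int(np.ceil(r1)))
    ci0, ci1 = int(np.floor(c0)), min(w, int(np.ceil(c1)))
    window = mask.usable[ri0:ri1, ci0:ci1]
    if window.size == 0:
        return 0.0
    return float(window.mean())


def qc_summary(mask: QualityMask) -> dict:
    """Per-slide pixel fractions, serializable as JSON."""
    total = mask.tissue.size
    return {
        "tissue_fraction": float(mask.tissue.sum() / total),
        "usable_fraction": float(mask.usable.sum() / total),
        "artifact_fractions": {
            kind: float(m.sum() / total) for kind, m in mask.artifact_masks.items()
        },
    }
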