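"""Per-tile cellularity features and the patch accept/reject rule.

Nuclei are segmented on the deconvolved hematoxylin density map (Otsu
threshold with a fixed fallback, hole filling, distance-transform watershed
to split touching nuclei), characterized by ellipse moments, and summarized
into the patch-selection features: nucleus count, mean hematoxylin staining
density over nuclei, and major/minor axis ratios. A patch is accepted when
every feature clears its configured threshold (boundaries inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .stain_tools import StainMatrix, deconvolve


@dataclass(frozen=True)
class NucleusObject:
    centroid: tuple[float, float]  # (x, y) in tile pixels
    area_px: float
    major_axis_px: float
    minor_axis_px: float
    mean_h_density: float

    @property
    def axis_ratio(self) -> float:
        return self.major_axis_px / max(self.minor_axis_px, 1e-6)


@dataclass(frozen=True)
class PatchFeatureSet:
    nucleus_count: int
    staining_density: float  # mean of per-nucleus mean hematoxylin OD
    axis_ratio_mean: float
    axis_ratio_max: float
    tissue_fraction: float


@dataclass(frozen=True)
class PatchFilterConfig:
    """Accept thresholds; the defaults are this artifact's own, reasonable
    for 512 px tiles at 20x, and every one is overridable."""

    min_nucleus_count: int = 20
    h_density_range: tuple[float, float] = (0.15, 1.2)
    max_axis_ratio_mean: float = 4.0
    min_tissue_fraction: float = 0.5
    nucleus_area_range: tuple[float, float] = (40.0, 3000.0)
    h_threshold_fallback: float = 0.3
    watershed_min_distance: int = 5

    def __post_init__(self) -> None:
        lo, hi = self.h_density_range
        if lo >= hi:
            raise ValueError("h_density_range must satisfy lo < hi")
        amin, amax = self.nucleus_area_range
        if amin > amax:
            raise ValueError("nucleus_area_range must satisfy min <= max")


def segment_nuclei(
    h_density_map: np.ndarray, cfg: PatchFilterConfig | None = None
) -> list[NucleusObject]:
    """Segment nuclei on a hematoxylin density map.

    Threshold (Otsu, with a fixed fallback when the map is effectively
    flat), fill holes, split touching nuclei by watershed seeded from
    smoothed distance-transform peaks, then drop components outside the
    configured area range.
    """
    cfg = cfg or PatchFilterConfig()
    h = np.asarray(h_density_map, dtype=float)
    if h.max() - h.min() < 0.1:
        return []
    try:
        thr = float(threshold_otsu(h))
    except ValueError:
        thr = cfg.h_threshold_fallback
    thr = max(thr, cfg.h_threshold_fallback)
    mask = h >= thr
    if not mask.any():
        return []
    mask = ndi.binary_fill_holes(mask)

    dist = ndi.distance_transform_edt(mask)
    dist_s = ndi.gaussian_filter(dist, sigma=1.5)
    peaks = peak_local_max(
        dist_s,
        min_distance=cfg.watershed_min_distance,
        labels=ndi.label(mask)[0],
        exclude_border=False,
    )
    markers = np.zeros(mask.shape, dtype=int)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        labels = ndi.label(mask)[0]
    else:
        labels = watershed(-dist_s, markers, mask=mask)

    amin, amax = cfg.nucleus_area_range
    nuclei: list[NucleusObject] = []
    for prop in regionprops(labels, intensity_image=h):
        if not amin <= prop.area <= amax:
            continue
        cy, cx = prop.centroid
        minor = max(prop.axis_minor_length, 1.0)
        nuclei.append(
            NucleusObject(
                centroid=(cx, cy),
                area_px=float(prop.area),
                major_axis_px=float(max(prop.axis_major_length, minor)),
                minor_axis_px=float(minor),
                mean_h_density=float(prop.intensity_mean),
            )
        )
    return nuclei


def compute_patch_features(
    tile: np.ndarray,
    usable_fraction: float,
    cfg: PatchFilterConfig | None = None,
    stain_matrix: StainMatrix | None = None,
) -> PatchFeatureSet:
    """Deconvolve a tile, segment nuclei and aggregate their statistics.

    Deterministic for fixed tile bytes. With zero nuclei the density and
    ratio features are reported as 0.
    """
    cfg = cfg or PatchFilterConfig()
    densities = deconvolve(tile, stain_matrix)
    nuclei = segment_nuclei(densities[..., 0], cfg)
    if not nuclei:
        return PatchFeatureSet(0, 0.0, 0.0, 0.0, float(usable_fraction))
    ratios = np.array([n.axis_ratio for n in nuclei])
    return PatchFeatureSet(
        nucleus_count=len(nuclei),
        staining_density=float(np.mean([n.mean_h_density for n in nuclei])),
        axis_ratio_mean=float(ratios.mean()),
        axis_ratio_max=float(ratios.max()),
        tissue_fraction=float(usable_fraction),
    )


REJECT_REASONS = (
    "ok",
    "insufficient_tissue",
    "insufficient_nuclei",
    "staining_density_out_of_range",
    "axis_ratio_too_high",
)


def accept_patch(
    features: PatchFeatureSet, cfg: PatchFilterConfig | None = None
) -> tuple[bool, str]:
    """Conjunction of the cellularity criteria; boundaries inclusive.

    The reason names the first failed criterion in evaluation order
    (tissue, nuclei, density, axis ratio) or "ok".
    """
    cfg = cfg or PatchFilterConfig()
    if features.tissue_fraction < cfg.min_tissue_fraction:
        return False, "insufficient_tissue"
    if features.nucleus_count < cfg.min_nucleus_count:
        return False, "insufficient_nuclei"
    lo, hi = cfg.h_density_range
    if not lo <= features.staining_density <= hi:
        return False, "staining_density_out_of_range"
    if features.axis_ratio_mean > cfg.max_axis_ratio_mean:
        return False, "axis_ratio_too_high"
    return True, "ok"
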