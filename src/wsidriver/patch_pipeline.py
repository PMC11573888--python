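"""Per-slide patch extraction and training-set sampling.

Implements the extraction protocol: scan candidate 512 px tiles in
row-major order, keep the first 300 that pass QC and cellularity filters,
draw up to 200 accepted patches per sample for training, and expand each
training patch into 2 of its 8 dihedral (D4) variants. Validation and test
patches are never augmented.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .patch_features import (
    PatchFeatureSet,
    PatchFilterConfig,
    accept_patch,
    compute_patch_features,
)
from .quality_mask import QualityMask, tile_usable_fraction
from .slide_io import SlidePyramid, TileCoordinate, enumerate_candidates, read_region
from .stain_tools import StainMatrix

AUGMENTATION_TAGS = (
    "identity",
    "rot90",
    "rot180",
    "rot270",
    "flip_h",
    "flip_v",
    "transpose",
    "anti_transpose",
)


@dataclass(frozen=True)
class SamplerConfig:
    per_slide_cap: int = 300
    per_sample_train: int = 200
    augment_select: int = 2
    seed: int = 0
    cap_random: bool = False  # cap by seeded draw instead of scan order

    def __post_init__(self) -> None:
        if self.augment_select > len(AUGMENTATION_TAGS):
            raise ValueError("augment_select must be <= 8")
        if self.per_sample_train > self.per_slide_cap:
            raise ValueError("per_sample_train must be <= per_slide_cap")


@dataclass(frozen=True)
class PatchRecord:
    slide_id: str
    coord: TileCoordinate
    features: PatchFeatureSet
    accepted: bool
    reason: str = "ok"
    augmentation_tag: str | None = None  # only on training copies


def dihedral_variants(tile: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """The 8 symmetries of the square applied to a tile, in fixed tag order."""
    tile = np.asarray(tile)
    if tile.shape[0] != tile.shape[1]:
        raise ValueError("dihedral augmentation requires a square tile")
    return [
        ("identity", tile.copy()),
        ("rot90", np.rot90(tile, 1)),
        ("rot180", np.rot90(tile, 2)),
        ("rot270", np.rot90(tile, 3)),
        ("flip_h", tile[:, ::-1]),
        ("flip_v", tile[::-1, :]),
        ("transpose", tile.swapaxes(0, 1)),
        ("anti_transpose", np.rot90(tile, 2).swapaxes(0, 1)),
    ]


def apply_augmentation(tile: np.ndarray, tag: str) -> np.ndarray:
    for t, arr in dihedral_variants(tile):
        if t == tag:
            return arr
    raise ValueError(f"unknown augmentation tag: {tag}")


def _patch_rng(seed: int, slide_id: str, *extra: int) -> np.random.Generator:
    """Per-(slide, patch) RNG stream, order-independent across slides."""
    key = [seed & 0x7FFFFFFF, zlib.crc32(slide_id.encode()) & 0x7FFFFFFF]
    key.extend(int(e) & 0x7FFFFFFF for e in extra)
    return np.random.default_rng(np.random.SeedSequence(key))


def extract_patches(
    slide: SlidePyramid,
    slide_id: str,
    mask: QualityMask,
    filter_cfg: PatchFilterConfig | None = None,
    sampler_cfg: SamplerConfig | None = None,
    stain_matrix: StainMatrix | None = None,
    target_magnification: float = 20.0,
) -> list[PatchRecord]:
    """Accepted patches for one slide, capped at ``per_slide_cap``.

    Candidates are visited in row-major scan order at the target
    magnification; tiles failing the usable-tissue fraction are skipped
    without a full read. By default collection stops at the cap (first 300
    in scan order); with ``cap_random`` all qualifying tiles are collected
    and the cap is enforced by a seeded draw.
    """
    from .slide_io import magnification_to_level

    filter_cfg = filter_cfg or PatchFilterConfig()
    sampler_cfg = sampler_cfg or SamplerConfig()
    level, residual = magnification_to_level(slide, target_magnification)

    accepted: list[PatchRecord] = []
    for coord in enumerate_candidates(slide, level=level, residual_scale=residual):
        if not sampler_cfg.cap_random and len(accepted) >= sampler_cfg.per_slide_cap:
            break
        base_coord = TileCoordinate(
            level=0,
            x=int(round(coord.x * slide.levels[level].downsample)),
            y=int(round(coord.y * slide.levels[level].downsample)),
            size=int(round(coord.size * residual * slide.levels[level].downsample)),
        )
        frac = tile_usable_fraction(mask, base_coord)
        if frac < filter_cfg.min_tissue_fraction:
            continue
        tile = read_region(slide, coord, residual_scale=residual)
        features = compute_patch_features(tile, frac, filter_cfg, stain_matrix)
        ok, reason = accept_patch(features, filter_cfg)
        if ok:
            accepted.append(
                PatchRecord(
                    slide_id=slide_id,
                    coord=coord,
                    features=features,
                    accepted=True,
                    reason=reason,
                )
            )
    if sampler_cfg.cap_random and len(accepted) > sampler_cfg.per_slide_cap:
        rng = _patch_rng(sampler_cfg.seed, slide_id)
        idx = rng.choice(len(accepted), size=sampler_cfg.per_slide_cap, replace=False)
        accepted = [accepted[i] for i in sorted(idx)]
    if not accepted:
        warnings.warn(f"slide {slide_id}: no patches passed extraction", stacklevel=2)
    return accepted


def sample_for_split(
    patches: list[PatchRecord],
    role: str,
    cfg: SamplerConfig | None = None,
) -> list[PatchRecord]:
    """Seeded per-sample selection; training patches gain augmented copies.

    Draws min(per_sample_train, available) patches without replacement. For
    role "train" each selected patch yields ``augment_select`` records
    tagged with dihedral variants drawn without replacement from the 8 (the
    identity is eligible). Validation and test records carry no tag.
    """
    cfg = cfg or SamplerConfig()
    if role not in ("train", "validation", "test"):
        raise ValueError(f"unknown role: {role}")
    if not patches:
        return []
    slide_id = patches[0].slide_id
    rng = _patch_rng(cfg.seed, slide_id)
    k = min(cfg.per_sample_train, len(patches))
    idx = rng.choice(len(patches), size=k, replace=False)
    selected = [patches[i] for i in sorted(idx)]
    if role != "train":
        return [replace(p, augmentation_tag=None) for p in selected]
    out: list[PatchRecord] = []
    for p in selected:
        prng = _patch_rng(cfg.seed, p.slide_id, p.coord.x, p.coord.y)
        tags = prng.choice(len(AUGMENTATION_TAGS), size=cfg.augment_select, replace=False)
        for t in tags:
            out.append(replace(p, augmentation_tag=AUGMENTATION_TAGS[t]))
    return out


def patches_to_frame(patches: list[PatchRecord]) -> pd.DataFrame:
    """Flat manifest of patch records (TSV-friendly)."""
    rows = []
    for p in patches:
        rows.append(
            {
                "slide_id": p.slide_id,
                "level": p.coord.level,
                "x": p.coord.x,
                "y": p.coord.y,
                "size": p.coord.size,
                "nucleus_count": p.features.nucleus_count,
                "staining_density": p.features.staining_density,
                "axis_ratio_mean": p.features.axis_ratio_mean,
                "tissue_fraction": p.features.tissue_fraction,
                "accepted": p.accepted,
                "reason": p.reason,
                "augmentation_tag": p.augmentation_tag or "",
            }
        )
    return pd.DataFrame(rows)
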