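"""Seeded synthetic H&E-like pyramidal slides with ground truth.

Renders tissue polygons in eosin-pink with hematoxylin-dark elliptical
nuclei over near-white glass, through the same Beer-Lambert forward model
the stain tools invert, so stain deconvolution and nuclei segmentation are
meaningfully testable. Four artifact kinds (blur, pen, blood, bubble) are
painted with known masks, and synthetic cohorts carry BRAF-RAS-score (BRS)
values whose sign agreement with the class label is controlled by a
separability knob.

Everything is a pure function of (spec, seed): identical inputs give
bit-identical pixels and ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.draw import polygon as draw_polygon

from .cohort import SampleRecord
from .slide_io import DEFAULT_MAGNIFICATION, SlidePyramid, TILE_SIZE, write_slide
from .stain_tools import StainMatrix

ARTIFACT_KINDS = ("blur", "pen", "blood", "bubble")
ARRANGEMENTS = ("papillary_clusters", "follicular_rings")

# Stain densities used for rendering (dimensionless OD multipliers).
_TISSUE_EOSIN = 0.35
_TISSUE_HEMATOX = 0.06
_NUCLEUS_HEMATOX = 0.8
_NUCLEUS_EOSIN = 0.1

_PEN_COLORS = {"green": (30, 140, 60), "blue": (30, 110, 200)}
_BLOOD_COLOR = (150, 25, 35)


@dataclass(frozen=True)
class PhenotypeSpec:
    """Nuclear morphology and arrangement parameters for one mutation class.

    ``nucleus_density`` is the Poisson mean of nuclei per 512x512 patch of
    tissue; ``nucleus_axis_ratio`` the mean major/minor axis of the rendered
    ellipses. The two default presets differ in density, axis ratio and
    arrangement, standing in for the morphologic contrast between the
    classical type typical of BRAF-V600E tumors and the follicular variant
    typical of RAS tumors.
    """

    class_label: str
    nucleus_density: float
    nucleus_axis_ratio: float
    nucleus_radius_px: float
    arrangement: str
    stain_jitter: float = 0.05
    nucleus_h_density: float = _NUCLEUS_HEMATOX

    def __post_init__(self) -> None:
        if self.nucleus_density <= 0:
            raise ValueError("nucleus_density must be > 0")
        if self.nucleus_axis_ratio < 1:
            raise ValueError("nucleus_axis_ratio must be >= 1")
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(f"unknown arrangement: {self.arrangement}")


BRAF_PRESET = PhenotypeSpec(
    class_label="BRAF",
    nucleus_density=60.0,
    nucleus_axis_ratio=1.1,
    nucleus_radius_px=6.0,
    arrangement="papillary_clusters",
)
RAS_PRESET = PhenotypeSpec(
    class_label="RAS",
    nucleus_density=110.0,
    nucleus_axis_ratio=1.8,
    nucleus_radius_px=6.0,
    arrangement="follicular_rings",
)
# Guaranteed margin between rendered mean axis ratios of the two presets.
AXIS_RATIO_MARGIN = 0.4


@dataclass(frozen=True)
class SyntheticSlideSpec:
    width_px: int
    height_px: int
    phenotype: PhenotypeSpec
    seed: int
    base_magnification: float = DEFAULT_MAGNIFICATION
    tissue_polygons: tuple = ()
    artifacts: tuple = ()  # of (kind, (x, y, w, h))
    nucleus_grid_margin_px: float = 0.0

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px) < 1024:
            raise ValueError("slide too small for tiling")
        object.__setattr__(
            self,
            "tissue_polygons",
            tuple(np.asarray(p, dtype=float) for p in self.tissue_polygons),
        )
        arts = []
        for kind, box in self.artifacts:
            if kind not in ARTIFACT_KINDS:
                raise ValueError(f"unknown artifact kind: {kind}")
            x, y, w, h = (int(v) for v in box)
            if x < 0 or y < 0 or x + w > self.width_px or y + h > self.height_px:
                raise ValueError("artifact region outside image bounds")
            arts.append((kind, (x, y, w, h)))
        object.__setattr__(self, "artifacts", tuple(arts))


def full_tissue_polygon(width: int, height: int, margin: int = 32) -> np.ndarray:
    """A rectangle of tissue covering the slide up to a glass margin."""
    return np.array(
        [
            (margin, margin),
            (width - margin, margin),
            (width - margin, height - margin),
            (margin, height - margin),
        ],
        dtype=float,
    )


@dataclass
class GroundTruth:
    tissue_mask: np.ndarray
    artifact_masks: dict[str, np.ndarray]
    nuclei_centroids: np.ndarray  # (n, 2) of (x, y) at level 0
    nuclei_count_per_patch: np.ndarray  # grid of floor(H/512) x floor(W/512)
    nuclei_axis_ratios: np.ndarray = field(default_factory=lambda: np.empty(0))


def _rasterize_tissue(spec: SyntheticSlideSpec) -> np.ndarray:
    # strip-wise so the index arrays never cover the whole gigapixel plane
    mask = np.zeros((spec.height_px, spec.width_px), dtype=bool)
    strip = 1024
    for y0 in range(0, spec.height_px, strip):
        sh = min(strip, spec.height_px - y0)
        for poly in spec.tissue_polygons:
            rr, cc = draw_polygon(
                poly[:, 1] - y0, poly[:, 0], shape=(sh, spec.width_px)
            )
            mask[y0 + rr, cc] = True
    return mask


def _in_artifact(x: float, y: float, boxes: list[tuple[int, int, int, int]]) -> bool:
    return any(bx <= x < bx + bw and by <= y < by + bh for bx, by, bw, bh in boxes)


def _near_grid(v: float, margin: float) -> bool:
    r = v % TILE_SIZE
    return r < margin or r > TILE_SIZE - margin


def _place_nuclei(
    rng: np.random.Generator, spec: SyntheticSlideSpec, tissue: np.ndarray
) -> list[tuple[float, float, float, float, float]]:
    """Dart-throw nucleus centers with a minimum separation (spatial hash).

    Returns (x, y, semi_major, semi_minor, angle) per nucleus. Cluster and
    ring arrangements draw positions around seeded anchor points; rejected
    darts (outside tissue, inside artifacts, or too close to a neighbour)
    are retried so the achieved count tracks the Poisson target.
    """
    phen = spec.phenotype
    h, w = tissue.shape
    tissue_area = int(tissue.sum())
    if tissue_area == 0:
        return []
    target = int(rng.poisson(phen.nucleus_density * tissue_area / TILE_SIZE**2))
    if target == 0:
        return []

    a_mean = phen.nucleus_radius_px * np.sqrt(phen.nucleus_axis_ratio)
    min_sep = 2.2 * a_mean
    margin = spec.nucleus_grid_margin_px
    boxes = [box for _, box in spec.artifacts]

    # anchor points for the arrangement
    n_anchors = max(1, target // 9)
    anchors = []
    attempts = 0
    while len(anchors) < n_anchors and attempts < 50 * n_anchors:
        attempts += 1
        ax, ay = rng.uniform(0, w), rng.uniform(0, h)
        if tissue[int(ay), int(ax)]:
            anchors.append((ax, ay))
    if not anchors:
        return []
    anchors = np.asarray(anchors)
    ring_radii = rng.uniform(4 * a_mean, 8 * a_mean, size=len(anchors))

    cell = max(min_sep, 1.0)
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def clear(x: float, y: float) -> bool:
        ci, cj = int(x / cell), int(y / cell)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for px, py in grid.get((ci + di, cj + dj), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < min_sep**2:
                        return False
        return True

    nuclei: list[tuple[float, float, float, float, float]] = []
    attempts = 0
    max_attempts = 40 * target
    while len(nuclei) < target and attempts < max_attempts:
        attempts += 1
        k = rng.integers(len(anchors))
        ax, ay = anchors[k]
        if phen.arrangement == "papillary_clusters":
            x = ax + rng.normal(0, 5 * phen.nucleus_radius_px)
            y = ay + rng.normal(0, 5 * phen.nucleus_radius_px)
        else:  # follicular_rings
            theta = rng.uniform(0, 2 * np.pi)
            r = ring_radii[k] + rng.normal(0, 1.5)
            x, y = ax + r * np.cos(theta), ay + r * np.sin(theta)
        if not (0 <= x < w and 0 <= y < h):
            continue
        if not tissue[int(y), int(x)]:
            continue
        if boxes and _in_artifact(x, y, boxes):
            continue
        if margin > 0 and (_near_grid(x, margin) or _near_grid(y, margin)):
            continue
        if not clear(x, y):
            continue
        ratio = max(1.0, rng.normal(phen.nucleus_axis_ratio, 0.08 * phen.nucleus_axis_ratio))
        radius = max(2.5, rng.normal(phen.nucleus_radius_px, 0.1 * phen.nucleus_radius_px))
        angle = rng.uniform(0, np.pi)
        nuclei.append((x, y, radius * np.sqrt(ratio), radius / np.sqrt(ratio), angle))
        grid.setdefault((int(x / cell), int(y / cell)), []).append((x, y))
    return nuclei


def _paint_artifacts(
    rgb: np.ndarray, spec: SyntheticSlideSpec, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Paint artifact regions in place; return exact per-kind pixel masks."""
    masks = {
        kind: np.zeros(rgb.shape[:2], dtype=bool)
        for kind in {k for k, _ in spec.artifacts}
    }
    pen_cycle = list(_PEN_COLORS.values())
    pen_i = 0
    for kind, (x, y, w, h) in spec.artifacts:
        sub = rgb[y : y + h, x : x + w]
        if kind == "blur":
            for c in range(3):
                sub[..., c] = ndi.gaussian_filter(sub[..., c], sigma=6)
            masks[kind][y : y + h, x : x + w] = True
        elif kind == "pen":
            stroke = np.zeros((h, w), dtype=bool)
            n_seg = 4
            pts = np.column_stack(
                [rng.integers(0, h, n_seg + 1), rng.integers(0, w, n_seg + 1)]
            )
            for (r0, c0), (r1, c1) in zip(pts, pts[1:]):
                rr, cc = draw_line(r0, c0, r1, c1)
                stroke[rr, cc] = True
            stroke = ndi.binary_dilation(stroke, iterations=max(3, w // 60))
            color = np.array(pen_cycle[pen_i % len(pen_cycle)], dtype=float)
            pen_i += 1
            sub[stroke] = np.clip(
                0.12 * sub[stroke].astype(float) + 0.88 * color, 0, 255
            ).astype(np.uint8)
            masks[kind][y : y + h, x : x + w] |= stroke
        elif kind == "blood":
            blob = np.zeros((h, w), dtype=bool)
            for _ in range(6):
                rr, cc = draw_ellipse(
                    rng.uniform(0.2 * h, 0.8 * h),
                    rng.uniform(0.2 * w, 0.8 * w),
                    rng.uniform(0.08 * h, 0.25 * h),
                    rng.uniform(0.08 * w, 0.25 * w),
                    shape=(h, w),
                )
                blob[rr, cc] = True
            color = np.array(_BLOOD_COLOR, dtype=float)
            sub[blob] = np.clip(
                0.1 * sub[blob].astype(float) + 0.9 * color, 0, 255
            ).astype(np.uint8)
            masks[kind][y : y + h, x : x + w] |= blob
        elif kind == "bubble":
            rr, cc = draw_ellipse(h / 2, w / 2, 0.45 * h, 0.45 * w, shape=(h, w))
            bub = np.zeros((h, w), dtype=bool)
            bub[rr, cc] = True
            sub[bub] = np.clip(
                0.15 * sub[bub].astype(float) + 0.85 * 246.0, 0, 255
            ).astype(np.uint8)
            masks[kind][y : y + h, x : x + w] |= bub
        rgb[y : y + h, x : x + w] = sub
    return masks


def _downsample4(arr: np.ndarray) -> np.ndarray:
    """4x block mean via uint16 partial sums (no float copy of the plane)."""
    h4, w4 = arr.shape[0] // 4 * 4, arr.shape[1] // 4 * 4
    r = arr[:h4, :w4].reshape(h4 // 4, 4, w4 // 4, 4, 3)
    sums = r.sum(axis=(1, 3), dtype=np.uint16)
    return ((sums + 8) // 16).astype(np.uint8)


def _build_pyramid(base: np.ndarray) -> list[np.ndarray]:
    """Base plus 4x block-mean downsamples while levels stay >= 512 px."""
    levels = [base]
    cur = base
    while min(cur.shape[0], cur.shape[1]) // 4 >= 512:
        cur = _downsample4(cur)
        levels.append(cur)
    if len(levels) == 1:  # guarantee >= 2 levels
        levels.append(_downsample4(base))
    return levels


def generate_slide(spec: SyntheticSlideSpec) -> tuple[SlidePyramid, GroundTruth]:
    """Render a synthetic H&E slide and its exact ground truth.

    The returned pyramid is array-backed (use :func:`wsidriver.slide_io.write_slide`
    to materialize it as tiled TIFF); ground-truth nuclei bookkeeping refers
    to level-0 pixel coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    phen = spec.phenotype

    tissue = _rasterize_tissue(spec)
    nuclei = _place_nuclei(rng, spec, tissue)

    # per-slide stain jitter: intensity scales and a small vector perturbation
    h_scale = 1.0 + phen.stain_jitter * rng.normal()
    e_scale = 1.0 + phen.stain_jitter * rng.normal()
    cols = StainMatrix().columns.copy()
    cols[:, :2] += 0.05 * phen.stain_jitter * rng.normal(size=(3, 2))
    cols /= np.linalg.norm(cols, axis=0)

    h_map = np.zeros((h, w), dtype=np.float32)
    # glass: faint residue so the background is near-white, not pure white
    e_map = rng.standard_normal((h, w), dtype=np.float32)
    e_map *= 0.005
    e_map += 0.012
    if tissue.any():
        h_map[tissue] = _TISSUE_HEMATOX * h_scale
        e_map[tissue] = _TISSUE_EOSIN * e_scale
        noise = rng.standard_normal((h, w), dtype=np.float32)
        noise *= tissue
        noise *= 0.012
        h_map += noise
        noise = rng.standard_normal((h, w), dtype=np.float32)
        noise *= tissue
        noise *= 0.03
        e_map += noise
        del noise

    for x, y, a, b, ang in nuclei:
        rr, cc = draw_ellipse(y, x, b, a, shape=(h, w), rotation=ang)
        h_map[rr, cc] = (phen.nucleus_h_density + 0.05 * rng.normal()) * h_scale
        e_map[rr, cc] = _NUCLEUS_EOSIN * e_scale

    np.clip(h_map, 0.0, None, out=h_map)
    np.clip(e_map, 0.0, None, out=e_map)

    rgb = np.empty((h, w, 3), dtype=np.uint8)
    for c in range(3):
        od = h_map * np.float32(cols[c, 0])
        od += e_map * np.float32(cols[c, 1])
        od *= np.float32(-np.log(10.0))  # 10**-od == exp(-od ln 10)
        np.exp(od, out=od)
        od *= np.float32(256.0)
        od -= np.float32(1.0)
        np.clip(np.round(od, out=od), 0, 255, out=od)
        rgb[..., c] = od.astype(np.uint8)
    del h_map, e_map, od

    artifact_masks = _paint_artifacts(rgb, spec, rng)

    centroids = (
        np.array([(x, y) for x, y, *_ in nuclei], dtype=float)
        if nuclei
        else np.empty((0, 2))
    )
    ratios = (
        np.array([a / b for _, _, a, b, _ in nuclei]) if nuclei else np.empty(0)
    )
    counts = np.zeros((h // TILE_SIZE, w // TILE_SIZE), dtype=int)
    for x, y, *_ in nuclei:
        j, i = int(x // TILE_SIZE), int(y // TILE_SIZE)
        if i < counts.shape[0] and j < counts.shape[1]:
            counts[i, j] += 1

    pyramid = SlidePyramid.from_arrays(_build_pyramid(rgb), spec.base_magnification)
    gt = GroundTruth(
        tissue_mask=tissue,
        artifact_masks=artifact_masks,
        nuclei_centroids=centroids,
        nuclei_count_per_patch=counts,
        nuclei_axis_ratios=ratios,
    )
    return pyramid, gt


# ---------------------------------------------------------------------------
# cohorts

_BRAF_HISTOLOGY = (("classical", 0.765), ("tall_cell", 0.115), ("follicular_variant", 0.051), ("other", 0.069))
_RAS_HISTOLOGY = (("follicular_variant", 0.569), ("classical", 0.392), ("other", 0.039))


@dataclass(frozen=True)
class CohortMember:
    spec: SyntheticSlideSpec
    record: SampleRecord


def _interp_phenotype(label: str, separability: float) -> PhenotypeSpec:
    """Blend each class preset toward the midpoint as separability drops."""
    pre = BRAF_PRESET if label == "BRAF" else RAS_PRESET
    other = RAS_PRESET if label == "BRAF" else BRAF_PRESET

    def mix(a: float, b: float) -> float:
        mid = 0.5 * (a + b)
        return mid + separability * (a - mid)

    return PhenotypeSpec(
        class_label=pre.class_label,
        nucleus_density=mix(pre.nucleus_density, other.nucleus_density),
        nucleus_axis_ratio=max(1.0, mix(pre.nucleus_axis_ratio, other.nucleus_axis_ratio)),
        nucleus_radius_px=pre.nucleus_radius_px,
        arrangement=pre.arrangement,
        stain_jitter=pre.stain_jitter,
    )


def generate_cohort(
    n_braf: int,
    n_ras: int,
    separability: float,
    seed: int,
    slide_px: int = 4096,
) -> list[CohortMember]:
    """Synthetic cohort of slide specs with class-correlated BRS values.

    ``separability`` in [0, 1] controls both the phenotype contrast between
    the classes and the probability (1 + s) / 2 that a sample's BRS sign
    matches its class (BRAF negative, RAS positive). At 1 the classes are
    fully separable and every BRS sign agrees; at 0 BRS is label-independent.
    """
    if not 0.0 <= separability <= 1.0:
        raise ValueError("separability must be in [0, 1]")
    if n_braf < 1 or n_ras < 1:
        raise ValueError("need at least one sample per class")
    rng = np.random.default_rng(seed)
    members: list[CohortMember] = []
    labels = ["BRAF"] * n_braf + ["RAS"] * n_ras
    for i, label in enumerate(labels):
        hist_table = _BRAF_HISTOLOGY if label == "BRAF" else _RAS_HISTOLOGY
        names = [n for n, _ in hist_table]
        probs = np.array([p for _, p in hist_table])
        histology = rng.choice(names, p=probs / probs.sum())
        magnitude = rng.uniform(0.05, 0.95)
        class_sign = -1.0 if label == "BRAF" else 1.0
        sign = class_sign if rng.random() < (1.0 + separability) / 2.0 else -class_sign
        brs = float(np.clip(sign * magnitude, -1.0, 1.0))
        patient_id = f"SYN-{label}-{i:03d}"
        spec = SyntheticSlideSpec(
            width_px=slide_px,
            height_px=slide_px,
            phenotype=_interp_phenotype(label, separability),
            seed=int(rng.integers(0, 2**31 - 1)),
            tissue_polygons=(full_tissue_polygon(slide_px, slide_px),),
        )
        record = SampleRecord(
            patient_id=patient_id,
            mutation="BRAF_V600E" if label == "BRAF" else "RAS",
            histology=str(histology),
            brs=brs,
        )
        members.append(CohortMember(spec=spec, record=record))
    return members


def stable_slide_seed(base_seed: int, slide_id: str) -> int:
    """Deterministic per-slide child seed (crc32-mixed, below 2**31)."""
    return (base_seed * 1_000_003 + zlib.crc32(slide_id.encode())) % (2**31 - 1)


def write_ground_truth(gt: GroundTruth, outdir: str | Path) -> None:
    """Masks as PNG, centroids and per-patch counts as CSV."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(outdir / "tissue_mask.png", gt.tissue_mask.astype(np.uint8) * 255)
    for kind, mask in gt.artifact_masks.items():
        iio.imwrite(outdir / f"artifact_{kind}.png", mask.astype(np.uint8) * 255)
    np.savetxt(
        outdir / "nuclei_centroids.csv",
        gt.nuclei_centroids,
        delimiter=",",
        header="x,y",
        comments="",
        fmt="%.2f",
    )
    np.savetxt(
        outdir / "nuclei_count_per_patch.csv",
        gt.nuclei_count_per_patch,
        delimiter=",",
        fmt="%d",
    )


def write_cohort(
    members: list[CohortMember], outdir: str | Path, with_ground_truth: bool = True
) -> Path:
    """Materialize a cohort: TIFF slides, ground truth, and a manifest TSV.

    Returns the manifest path. Manifest columns: patient_id, label,
    histology, brs, slide.
    """
    import pandas as pd

    outdir = Path(outdir)
    slides_dir = outdir / "slides"
    slides_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for member in members:
        pyramid, gt = generate_slide(member.spec)
        slide_path = slides_dir / f"{member.record.patient_id}.tiff"
        write_slide(
            [pyramid.level_array(i) for i in range(len(pyramid.levels))],
            slide_path,
            member.spec.base_magnification,
        )
        if with_ground_truth:
            write_ground_truth(gt, outdir / "ground_truth" / member.record.patient_id)
        rows.append(
            {
                "patient_id": member.record.patient_id,
                "label": "BRAF" if member.record.mutation == "BRAF_V600E" else "RAS",
                "histology": member.record.histology,
                "brs": member.record.brs,
                "slide": str(slide_path),
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
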