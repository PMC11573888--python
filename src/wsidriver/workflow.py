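"""End-to-end pipeline: synth -> qc -> extract -> split -> train ->
predict -> aggregate -> evaluate, driven by one YAML config.

Each stage writes its artifacts under ``<workdir>/<stage>/`` and records a
content hash of (its config section + its upstream outputs) in a run
manifest; re-running with unchanged config and inputs skips the stage and
marks it cached. One global seed fans out to per-stage derived seeds so a
stage's randomness does not depend on which other stages ran.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregation_eval, classifier, cohort, patch_pipeline, quality_mask
from . import slide_io, stain_tools, synthetic_slide
from .aggregation_eval import AggregationConfig
from .classifier import ModelConfig
from .patch_features import PatchFeatureSet, PatchFilterConfig
from .patch_pipeline import PatchRecord, SamplerConfig
from .quality_mask import QcConfig
from .slide_io import TileCoordinate

log = logging.getLogger("wsidriver")

STAGES = ("synth", "qc", "extract", "split", "train", "predict", "aggregate", "evaluate")


class ConfigError(Exception):
    """Configuration schema violation; message carries the field path."""


class MissingArtifactError(Exception):
    def __init__(self, stage: str):
        self.stage = stage
        super().__init__(f"missing upstream artifact; run stage '{stage}' first")


@dataclass(frozen=True)
class SynthConfig:
    n_braf: int = 10
    n_ras: int = 10
    separability: float = 1.0
    slide_px: int = 2048


@dataclass
class PipelineConfig:
    workdir: Path
    seed: int = 0
    manifest: Path | None = None  # external cohort manifest; else synth output
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2)
    synth: SynthConfig = field(default_factory=SynthConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    filter: PatchFilterConfig = field(default_factory=PatchFilterConfig)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    aggregation: AggregationConfig = field(default_factory=AggregationConfig)


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in valid:
            raise ConfigError(f"{section}.{key}: unknown field")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{section}: {exc}") from exc


def config_from_dict(data: dict) -> PipelineConfig:
    if "workdir" not in data:
        raise ConfigError("workdir: required")
    sections = {
        "synth": SynthConfig,
        "qc": QcConfig,
        "filter": PatchFilterConfig,
        "sampler": SamplerConfig,
        "model": ModelConfig,
        "aggregation": AggregationConfig,
    }
    kwargs: dict = {
        "workdir": Path(data["workdir"]),
        "seed": int(data.get("seed", 0)),
        "manifest": Path(data["manifest"]) if data.get("manifest") else None,
    }
    if "ratios" in data:
        ratios = tuple(float(r) for r in data["ratios"])
        if len(ratios) != 3:
            raise ConfigError("ratios: expected three values")
        kwargs["ratios"] = ratios
    for name, cls in sections.items():
        sub = data.get(name, {})
        if not isinstance(sub, dict):
            raise ConfigError(f"{name}: expected a mapping")
        sub = dict(sub)
        for tup_field in ("h_density_range", "nucleus_area_range", "pen_hue_ranges"):
            if tup_field in sub and isinstance(sub[tup_field], list):
                v = sub[tup_field]
                sub[tup_field] = tuple(
                    tuple(x) if isinstance(x, list) else x for x in v
                )
        kwargs[name] = _build_section(cls, sub, name)
    return PipelineConfig(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(data)


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage derived seed (stage name hashed into the global seed)."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


# ---------------------------------------------------------------------------
# run manifest / caching


def _hash_bytes(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_section_dict(cfg: PipelineConfig, stage: str) -> dict:
    relevant = {
        "synth": ("synth", "seed"),
        "qc": ("qc",),
        "extract": ("qc", "filter", "sampler"),
        "split": ("ratios", "seed"),
        "train": ("sampler", "model", "seed"),
        "predict": ("sampler", "model"),
        "aggregate": ("aggregation",),
        "evaluate": ("aggregation", "seed"),
    }[stage]
    out = {}
    for name in relevant:
        val = getattr(cfg, name)
        out[name] = dataclasses.asdict(val) if dataclasses.is_dataclass(val) else val
    return out


class RunManifest:
    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {"stages": {}}
        if path.exists():
            self.data = json.loads(path.read_text())
            self.data.setdefault("stages", {})

    def stage_fresh(self, stage: str, input_hash: str) -> bool:
        rec = self.data["stages"].get(stage)
        if not rec or rec.get("input_hash") != input_hash:
            return False
        for f, digest in rec.get("outputs", {}).items():
            p = Path(f)
            if not p.exists() or _hash_file(p) != digest:
                return False
        return True

    def record(self, stage: str, input_hash: str, outputs: list[Path], cached: bool) -> None:
        self.data["stages"][stage] = {
            "input_hash": input_hash,
            "outputs": {str(p): _hash_file(p) for p in outputs},
            "cached": cached,
            "timestamp": time.time(),
        }

    def save(self, config_hash: str) -> None:
        self.data["config_hash"] = config_hash
        self.path.write_text(json.dumps(self.data, indent=2))

    def stage_outputs(self, stage: str) -> list[str]:
        return list(self.data["stages"].get(stage, {}).get("outputs", {}))


# ---------------------------------------------------------------------------
# stage implementations


def _manifest_path(cfg: PipelineConfig) -> Path:
    return cfg.manifest or (cfg.workdir / "synth" / "manifest.tsv")


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(stage)
    return path


def _stage_synth(cfg: PipelineConfig) -> list[Path]:
    outdir = cfg.workdir / "synth"
    members = synthetic_slide.generate_cohort(
        cfg.synth.n_braf,
        cfg.synth.n_ras,
        cfg.synth.separability,
        seed=stage_seed(cfg.seed, "synth"),
        slide_px=cfg.synth.slide_px,
    )
    manifest = synthetic_slide.write_cohort(members, outdir, with_ground_truth=False)
    return [manifest]


def _read_manifest_df(cfg: PipelineConfig, stage: str) -> pd.DataFrame:
    path = _require(_manifest_path(cfg), "synth")
    df = pd.read_csv(path, sep="\t")
    if "slide" not in df.columns:
        raise ConfigError("manifest: missing 'slide' column with slide paths")
    return df


def _stage_qc(cfg: PipelineConfig) -> list[Path]:
    df = _read_manifest_df(cfg, "qc")
    outdir = cfg.workdir / "qc"
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for _, row in df.iterrows():
        slide = slide_io.open_slide(row["slide"])
        mask = quality_mask.build_quality_mask(slide, cfg.qc)
        pid = str(row["patient_id"])
        npz = outdir / f"{pid}.npz"
        np.savez_compressed(
            npz,
            tissue=mask.tissue,
            usable=mask.usable,
            downsample=mask.thumbnail_downsample,
            **{f"artifact_{k}": v for k, v in mask.artifact_masks.items()},
        )
        summary = outdir / f"{pid}.json"
        summary.write_text(json.dumps(quality_mask.qc_summary(mask), indent=2))
        outputs.extend([npz, summary])
        log.info(json.dumps({"stage": "qc", "slide": pid}))
    return outputs


def _load_qc(cfg: PipelineConfig, pid: str) -> quality_mask.QualityMask:
    npz_path = _require(cfg.workdir / "qc" / f"{pid}.npz", "qc")
    with np.load(npz_path) as data:
        artifacts = {
            k[len("artifact_"):]: data[k] for k in data.files if k.startswith("artifact_")
        }
        return quality_mask.QualityMask(
            tissue=data["tissue"],
            artifact_masks=artifacts,
            usable=data["usable"],
            thumbnail_downsample=float(data["downsample"]),
        )


def _stage_extract(cfg: PipelineConfig) -> list[Path]:
    df = _read_manifest_df(cfg, "extract")
    outdir = cfg.workdir / "extract"
    outdir.mkdir(parents=True, exist_ok=True)
    frames = []
    outputs = []
    sampler = dataclasses.replace(cfg.sampler, seed=stage_seed(cfg.seed, "extract"))
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        slide = slide_io.open_slide(row["slide"])
        mask = _load_qc(cfg, pid)
        records = patch_pipeline.extract_patches(
            slide, pid, mask, cfg.filter, sampler
        )
        tiles = np.stack(
            [slide_io.read_region(slide, r.coord) for r in records]
        ) if records else np.empty((0, 512, 512, 3), dtype=np.uint8)
        tile_path = outdir / f"{pid}.npy"
        np.save(tile_path, tiles)
        outputs.append(tile_path)
        frames.append(patch_pipeline.patches_to_frame(records))
        log.info(json.dumps({"stage": "extract", "slide": pid, "accepted": len(records)}))
    patches_tsv = outdir / "patches.tsv"
    pd.concat([f for f in frames if len(f)], ignore_index=True).to_csv(
        patches_tsv, sep="\t", index=False
    )
    outputs.append(patches_tsv)
    return outputs


def _stage_split(cfg: PipelineConfig) -> list[Path]:
    df = _read_manifest_df(cfg, "split")
    records = cohort.read_manifest(_manifest_path(cfg))
    included, _ = cohort.filter_cohort(records)
    split = cohort.split_patients(
        included, cfg.ratios, seed=stage_seed(cfg.seed, "split")
    )
    outdir = cfg.workdir / "split"
    outdir.mkdir(parents=True, exist_ok=True)
    split_path = outdir / "split.tsv"
    cohort.write_split(split, split_path)
    plan = cohort.compute_training_plan(
        split,
        per_sample_train=cfg.sampler.per_sample_train,
        augment_select=cfg.sampler.augment_select,
        batch_size=cfg.model.batch_size,
        epochs=cfg.model.epochs,
    )
    plan_path = outdir / "training_plan.json"
    plan_path.write_text(json.dumps(dataclasses.asdict(plan), indent=2))
    return [split_path, plan_path]


def _load_patches(cfg: PipelineConfig, pid: str) -> tuple[list[PatchRecord], np.ndarray]:
    patches_tsv = _require(cfg.workdir / "extract" / "patches.tsv", "extract")
    tiles = np.load(_require(cfg.workdir / "extract" / f"{pid}.npy", "extract"))
    df = pd.read_csv(patches_tsv, sep="\t")
    df = df[df["slide_id"] == pid]
    records = []
    for _, row in df.iterrows():
        records.append(
            PatchRecord(
                slide_id=pid,
                coord=TileCoordinate(
                    level=int(row["level"]), x=int(row["x"]), y=int(row["y"]), size=int(row["size"])
                ),
                features=PatchFeatureSet(
                    nucleus_count=int(row["nucleus_count"]),
                    staining_density=float(row["staining_density"]),
                    axis_ratio_mean=float(row["axis_ratio_mean"]),
                    axis_ratio_max=0.0,
                    tissue_fraction=float(row["tissue_fraction"]),
                ),
                accepted=bool(row["accepted"]),
                reason=str(row["reason"]),
            )
        )
    return records, tiles


def _labels(cfg: PipelineConfig) -> dict[str, str]:
    df = _read_manifest_df(cfg, "split")
    label_map = {"BRAF": "BRAF_V600E", "BRAF_V600E": "BRAF_V600E", "RAS": "RAS"}
    return {
        str(r["patient_id"]): label_map[str(r["label"])] for _, r in df.iterrows()
    }


def _assemble_role(
    cfg: PipelineConfig,
    split: cohort.SplitAssignment,
    role: str,
    sampler: SamplerConfig,
    reference: stain_tools.ReferenceStats | None,
) -> tuple[np.ndarray, np.ndarray, list[str], stain_tools.ReferenceStats | None]:
    """Tiles and labels for one role; training tiles are augmented copies.

    The color-normalization reference defaults to the first accepted patch
    of the first training slide when none is supplied.
    """
    labels = _labels(cfg)
    xs, ys, ids = [], [], []
    for pid in sorted(split.patients(role)):
        records, tiles = _load_patches(cfg, pid)
        if not records:
            continue
        index = {(r.coord.x, r.coord.y): i for i, r in enumerate(records)}
        selected = patch_pipeline.sample_for_split(records, role, sampler)
        for rec in selected:
            tile = tiles[index[(rec.coord.x, rec.coord.y)]]
            if reference is None:
                t_mask = quality_mask.compute_tissue_mask(tile, cfg.qc)
                if t_mask.any():
                    reference = stain_tools.compute_reference_stats(tile, t_mask)
            if reference is not None:
                t_mask = quality_mask.compute_tissue_mask(tile, cfg.qc)
                if t_mask.any():
                    tile = stain_tools.reinhard_normalize(tile, t_mask, reference)
            if rec.augmentation_tag:
                tile = patch_pipeline.apply_augmentation(tile, rec.augmentation_tag)
            xs.append(np.ascontiguousarray(tile))
            ys.append(1 if labels[pid] == "RAS" else 0)
            ids.append(pid)
    x = np.stack(xs) if xs else np.empty((0, 512, 512, 3), dtype=np.uint8)
    return x, np.array(ys, dtype=int), ids, reference


def _stage_train(cfg: PipelineConfig) -> list[Path]:
    split = cohort.read_split(_require(cfg.workdir / "split" / "split.tsv", "split"))
    sampler = dataclasses.replace(cfg.sampler, seed=stage_seed(cfg.seed, "train"))
    x_train, y_train, _, reference = _assemble_role(cfg, split, "train", sampler, None)
    x_val, y_val, _, _ = _assemble_role(cfg, split, "validation", sampler, reference)
    model_cfg = dataclasses.replace(cfg.model, seed=stage_seed(cfg.seed, "train"))
    model = classifier.build_model(model_cfg)
    best, train_log = classifier.train(model, (x_train, y_train), (x_val, y_val), model_cfg)
    outdir = cfg.workdir / "train"
    outdir.mkdir(parents=True, exist_ok=True)
    model_path = outdir / "model.npz"
    classifier.save_model(best, train_log, model_path)
    ref_path = outdir / "reference.json"
    ref_path.write_text(reference.to_json() if reference else "{}")
    log.info(json.dumps({"stage": "train", "best_epoch": train_log.best_epoch}))
    return [model_path, model_path.with_suffix(".json"), ref_path]


def _stage_predict(cfg: PipelineConfig) -> list[Path]:
    split = cohort.read_split(_require(cfg.workdir / "split" / "split.tsv", "split"))
    model = classifier.load_model(_require(cfg.workdir / "train" / "model.npz", "train"))
    ref_text = _require(cfg.workdir / "train" / "reference.json", "train").read_text()
    reference = (
        stain_tools.ReferenceStats.from_json(ref_text) if ref_text.strip() != "{}" else None
    )
    sampler = dataclasses.replace(cfg.sampler, seed=stage_seed(cfg.seed, "train"))
    rows = []
    for role in ("validation", "test"):
        x, y, ids, _ = _assemble_role(cfg, split, role, sampler, reference)
        if not len(x):
            continue
        preds = classifier.predict_tiles(
            model, x, ids, [f"{pid}:{i}" for i, pid in enumerate(ids)]
        )
        for p in preds:
            rows.append(
                {"slide_id": p.slide_id, "key": p.key, "p_ras": p.p_ras, "role": role}
            )
    outdir = cfg.workdir / "predict"
    outdir.mkdir(parents=True, exist_ok=True)
    out = outdir / "tiles.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return [out]


def _stage_aggregate(cfg: PipelineConfig) -> list[Path]:
    tiles = pd.read_csv(
        _require(cfg.workdir / "predict" / "tiles.tsv", "predict"), sep="\t"
    )
    rows = []
    for (pid, role), grp in tiles.groupby(["slide_id", "role"]):
        t = aggregation_eval.perc_ras(
            grp["p_ras"].to_numpy(), cfg.aggregation, patient_id=str(pid)
        )
        rows.append(
            {
                "patient_id": pid,
                "role": role,
                "n_tiles": t.n_tiles,
                "perc_ras": t.perc_ras,
                "call": t.call,
            }
        )
    outdir = cfg.workdir / "aggregate"
    outdir.mkdir(parents=True, exist_ok=True)
    out = outdir / "tumors.tsv"
    pd.DataFrame(rows).to_csv(out, sep="\t", index=False)
    return [out]


def _stage_evaluate(cfg: PipelineConfig) -> list[Path]:
    tumors = pd.read_csv(
        _require(cfg.workdir / "aggregate" / "tumors.tsv", "aggregate"), sep="\t"
    )
    tiles = pd.read_csv(
        _require(cfg.workdir / "predict" / "tiles.tsv", "predict"), sep="\t"
    )
    labels = _labels(cfg)
    manifest = pd.read_csv(_manifest_path(cfg), sep="\t")
    brs_records = [
        aggregation_eval.BrsRecord(str(r["patient_id"]), float(r["brs"]))
        for _, r in manifest.iterrows()
        if "brs" in manifest.columns and pd.notna(r.get("brs"))
    ]
    outdir = cfg.workdir / "evaluate"
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = []
    for role in sorted(tumors["role"].unique()):
        sub = tumors[tumors["role"] == role]
        tumor_preds = [
            aggregation_eval.TumorPrediction(
                patient_id=str(r["patient_id"]),
                n_tiles=int(r["n_tiles"]),
                perc_ras=float(r["perc_ras"]),
                call=str(r["call"]),
            )
            for _, r in sub.iterrows()
        ]
        tile_preds = [
            classifier.TilePrediction(str(r["slide_id"]), str(r["key"]), float(r["p_ras"]))
            for _, r in tiles[tiles["role"] == role].iterrows()
        ]
        report = aggregation_eval.evaluate(
            tumor_preds,
            {pid: labels[pid] for pid in sub["patient_id"].astype(str)},
            brs_records=brs_records,
            tile_predictions=tile_preds,
            cfg=cfg.aggregation,
            seed=stage_seed(cfg.seed, "evaluate"),
        )
        jpath = outdir / f"report_{role}.json"
        jpath.write_text(report.to_json())
        tpath = outdir / f"report_{role}.txt"
        tpath.write_text(report.to_text())
        outputs.extend([jpath, tpath])
    return outputs


_STAGE_FUNCS = {
    "synth": _stage_synth,
    "qc": _stage_qc,
    "extract": _stage_extract,
    "split": _stage_split,
    "train": _stage_train,
    "predict": _stage_predict,
    "aggregate": _stage_aggregate,
    "evaluate": _stage_evaluate,
}

_UPSTREAM = {
    "synth": (),
    "qc": ("synth",),
    "extract": ("qc",),
    "split": ("synth",),
    "train": ("extract", "split"),
    "predict": ("train",),
    "aggregate": ("predict",),
    "evaluate": ("aggregate",),
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in canonical order; returns the manifest
    data including per-stage cached flags."""
    requested = list(stages) if stages else list(STAGES)
    for s in requested:
        if s not in STAGES:
            raise ConfigError(f"stages: unknown stage '{s}'")
    if cfg.manifest is not None:
        requested = [s for s in requested if s != "synth"]
    cfg.workdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(cfg.workdir / "run_manifest.json")
    config_hash = _hash_bytes(
        json.dumps(
            {s: _config_section_dict(cfg, s) for s in STAGES}, sort_keys=True, default=str
        ).encode()
    )
    for stage in STAGES:
        if stage not in requested:
            continue
        upstream_state = []
        for up in _UPSTREAM[stage]:
            if up == "synth" and cfg.manifest is not None:
                upstream_state.append(_hash_file(cfg.manifest))
                continue
            rec = manifest.data["stages"].get(up)
            if rec is None:
                raise MissingArtifactError(up)
            upstream_state.append(json.dumps(rec.get("outputs", {}), sort_keys=True))
        input_hash = _hash_bytes(
            json.dumps(
                {
                    "config": _config_section_dict(cfg, stage),
                    "upstream": upstream_state,
                    "seed": cfg.seed,
                },
                sort_keys=True,
                default=str,
            ).encode()
        )
        if manifest.stage_fresh(stage, input_hash):
            rec = manifest.data["stages"][stage]
            manifest.record(
                stage, input_hash, [Path(p) for p in rec["outputs"]], cached=True
            )
            log.info(json.dumps({"stage": stage, "cached": True}))
            continue
        t0 = time.time()
        outputs = _STAGE_FUNCS[stage](cfg)
        manifest.record(stage, input_hash, outputs, cached=False)
        log.info(
            json.dumps({"stage": stage, "cached": False, "seconds": round(time.time() - t0, 2)})
        )
    manifest.save(config_hash)
    return manifest.data
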