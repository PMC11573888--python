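"""Cohort assembly: dual-mutant exclusion, histology-matched BRAF
subsampling, leakage-free patient-level 60/20/20 splitting, and the
training-plan patch/iteration arithmetic.

The reference cohort this reproduces: 235 BRAF-V600E and 52 RAS samples,
one dual-mutant excluded, all 51 remaining RAS kept, 52 BRAF drawn to match
the RAS histology distribution, and the 103 patients split 61/21/21.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MUTATIONS = ("BRAF_V600E", "RAS", "both")
ROLES = ("train", "validation", "test")


@dataclass(frozen=True)
class SampleRecord:
    patient_id: str
    mutation: str
    histology: str = "unknown"
    brs: float | None = None

    def __post_init__(self) -> None:
        if self.mutation not in MUTATIONS:
            raise ValueError(f"unknown mutation label: {self.mutation}")
        if self.brs is not None and not -1.0 <= self.brs <= 1.0:
            raise ValueError("brs must lie in [-1, 1]")


@dataclass(frozen=True)
class SplitAssignment:
    """patient_id -> role; a partition with both classes in every role."""

    roles: dict[str, str]

    def patients(self, role: str) -> list[str]:
        return [p for p, r in self.roles.items() if r == role]

    def counts(self) -> dict[str, int]:
        return {role: len(self.patients(role)) for role in ROLES}


@dataclass(frozen=True)
class TrainingPlan:
    n_train_patches: int
    n_val_patches: int
    n_test_patches: int
    batch_size: int = 8
    epochs: int = 200
    iterations: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "iterations",
            (self.n_train_patches // self.batch_size) * self.epochs,
        )


def read_manifest(path: str | Path) -> list[SampleRecord]:
    """Cohort manifest TSV with columns patient_id, label, histology, brs."""
    df = pd.read_csv(path, sep="\t")
    label_map = {"BRAF": "BRAF_V600E", "BRAF_V600E": "BRAF_V600E", "RAS": "RAS", "both": "both"}
    records = []
    for _, row in df.iterrows():
        brs = row.get("brs")
        records.append(
            SampleRecord(
                patient_id=str(row["patient_id"]),
                mutation=label_map[str(row["label"])],
                histology=str(row.get("histology", "unknown")),
                brs=None if brs is None or (isinstance(brs, float) and math.isnan(brs)) else float(brs),
            )
        )
    return records


def filter_cohort(
    samples: list[SampleRecord],
) -> tuple[list[SampleRecord], list[SampleRecord]]:
    """Drop dual-mutant samples; keep every RAS sample.

    Returns (included, exclusions). The BRAF pool in the result is the full
    pool; pair with :func:`match_braf_subsample` to draw the matched subset.
    """
    excluded = [s for s in samples if s.mutation == "both"]
    included = [s for s in samples if s.mutation != "both"]
    n_ras = sum(1 for s in included if s.mutation == "RAS")
    n_braf = sum(1 for s in included if s.mutation == "BRAF_V600E")
    if n_ras == 0 or n_braf == 0:
        raise ValueError("a mutation class is empty after dual-mutant exclusion")
    return included, excluded


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing to ``total`` by largest fractional remainder."""
    floors = np.floor(targets).astype(int)
    short = total - floors.sum()
    order = np.argsort(-(targets - floors))
    out = floors.copy()
    for i in range(short):
        out[order[i % len(order)]] += 1
    return out


def match_braf_subsample(
    braf_pool: list[SampleRecord],
    ras_samples: list[SampleRecord],
    seed: int,
) -> list[SampleRecord]:
    """Seeded stratified draw of |RAS| + 1 BRAF samples matched on histology.

    Per-histology counts follow the RAS histology distribution with
    largest-remainder rounding; an under-filled stratum borrows from the
    remaining pool with a warning.
    """
    n_target = len(ras_samples) + 1
    if len(braf_pool) < n_target:
        raise ValueError("BRAF pool smaller than the matched target size")
    rng = np.random.default_rng(seed)
    strata = sorted({s.histology for s in ras_samples})
    ras_counts = np.array(
        [sum(1 for s in ras_samples if s.histology == h) for h in strata], dtype=float
    )
    quotas = _largest_remainder(ras_counts / ras_counts.sum() * n_target, n_target)

    chosen: list[SampleRecord] = []
    remaining = list(braf_pool)
    deficit = 0
    for h, q in zip(strata, quotas):
        pool_h = [s for s in remaining if s.histology == h]
        take = min(int(q), len(pool_h))
        if take < q:
            deficit += int(q) - take
            warnings.warn(
                f"histology stratum '{h}' has only {take} BRAF samples of "
                f"{int(q)} requested; borrowing from other strata",
                stacklevel=2,
            )
        idx = rng.choice(len(pool_h), size=take, replace=False)
        picked = [pool_h[i] for i in sorted(idx)]
        chosen.extend(picked)
        for s in picked:
            remaining.remove(s)
    if deficit:
        idx = rng.choice(len(remaining), size=deficit, replace=False)
        chosen.extend(remaining[i] for i in sorted(idx))
    return chosen


def split_patients(
    samples: list[SampleRecord],
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Class-stratified 60/20/20 patient split.

    Global role totals are fixed first — train gets floor(0.6 N), the
    remainder is split as evenly as possible with validation taking the odd
    extra — then per-class seats are allocated by largest fractional
    remainder under those totals, so a 52 + 51 cohort lands on 61/21/21
    with both classes present in every role.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    classes = sorted({s.mutation for s in samples})
    by_class = {c: [s for s in samples if s.mutation == c] for c in classes}
    if any(len(v) < 5 for v in by_class.values()):
        raise ValueError("need at least 5 samples per class to split")

    n = len(samples)
    n_train = math.floor(ratios[0] * n)
    rem = n - n_train
    n_val = math.ceil(rem * ratios[1] / (ratios[1] + ratios[2]))
    n_test = rem - n_val
    class_sizes = np.array([len(by_class[c]) for c in classes], dtype=float)

    train_per_class = _largest_remainder(class_sizes * ratios[0], n_train)
    left = class_sizes - train_per_class
    val_target = left * ratios[1] / (ratios[1] + ratios[2])
    val_per_class = _largest_remainder(val_target, n_val)
    val_per_class = np.minimum(val_per_class, left.astype(int))
    # top up if the minimum clipped a class below its quota
    while val_per_class.sum() < n_val:
        room = left.astype(int) - val_per_class
        val_per_class[np.argmax(room)] += 1
    test_per_class = left.astype(int) - val_per_class

    rng = np.random.default_rng(seed)
    roles: dict[str, str] = {}
    for ci, c in enumerate(classes):
        members = sorted(by_class[c], key=lambda s: s.patient_id)
        order = rng.permutation(len(members))
        shuffled = [members[i] for i in order]
        a, b = int(train_per_class[ci]), int(val_per_class[ci])
        for s in shuffled[:a]:
            roles[s.patient_id] = "train"
        for s in shuffled[a : a + b]:
            roles[s.patient_id] = "validation"
        for s in shuffled[a + b :]:
            roles[s.patient_id] = "test"
    assert len(roles) == n and n_test == sum(1 for r in roles.values() if r == "test")
    return SplitAssignment(roles=roles)


def compute_training_plan(
    split: SplitAssignment,
    per_sample_train: int = 200,
    augment_select: int = 2,
    batch_size: int = 8,
    epochs: int = 200,
) -> TrainingPlan:
    """Patch and iteration bookkeeping implied by the split and sampler.

    Training patches = train patients x per-sample quota x augmented
    variants; validation/test patches are unaugmented.
    """
    counts = split.counts()
    return TrainingPlan(
        n_train_patches=counts["train"] * per_sample_train * augment_select,
        n_val_patches=counts["validation"] * per_sample_train,
        n_test_patches=counts["test"] * per_sample_train,
        batch_size=batch_size,
        epochs=epochs,
    )


def write_split(split: SplitAssignment, path: str | Path) -> None:
    pd.DataFrame(
        [{"patient_id": p, "role": r} for p, r in sorted(split.roles.items())]
    ).to_csv(path, sep="\t", index=False)


def read_split(path: str | Path) -> SplitAssignment:
    df = pd.read_csv(path, sep="\t")
    return SplitAssignment(roles=dict(zip(df["patient_id"].astype(str), df["role"])))
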