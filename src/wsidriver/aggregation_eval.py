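"""Tumor-level aggregation and the evaluation suite.

A tile is called RAS when its predicted p(RAS) is at least 0.5 (inclusive).
A tumor's percRAS score is the fraction of its tiles called RAS; the tumor
is called RAS when percRAS strictly exceeds 0.75, BRAF-V600E when it is
strictly below 0.25, and left not-predicted in between. Those cutoffs are
the single place to change the decision rule.

Evaluation covers tile- and tumor-level ROC/AUC (Mann-Whitney rank form
with ties counted half, bootstrap percentile CIs), confusion matrices with
an explicit not-predicted row, Fisher's exact test on the called tumors,
and Spearman correlation of percRAS against the continuous BRAF-RAS score
(BRS), including the sign-based BRAF-like / RAS-like cross-tabulation.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .classifier import TilePrediction

CLASSES = ("BRAF_V600E", "RAS")
NOT_PREDICTED = "not_predicted"


@dataclass(frozen=True)
class AggregationConfig:
    tile_ras_cutoff: float = 0.5  # inclusive
    ras_band_hi: float = 0.75  # strict: call RAS only above this
    braf_band_lo: float = 0.25  # strict: call BRAF only below this

    def __post_init__(self) -> None:
        if not 0.0 < self.braf_band_lo < self.ras_band_hi < 1.0:
            raise ValueError("bands must satisfy 0 < braf_band_lo < ras_band_hi < 1")


@dataclass(frozen=True)
class TumorPrediction:
    patient_id: str
    n_tiles: int
    perc_ras: float
    call: str


@dataclass(frozen=True)
class BrsRecord:
    patient_id: str
    brs: float

    @property
    def brs_class(self) -> str:
        if self.brs < 0:
            return "BRAF_like"
        if self.brs > 0:
            return "RAS_like"
        return "undefined"


@dataclass
class EvalReport:
    tile_auc: tuple[float, float, float] | None
    tumor_auc: tuple[float, float, float] | None
    tile_confusion: dict
    tumor_confusion: dict
    fisher_p: float | None
    accuracy_called: float | None
    accuracy_overall: float
    per_class_accuracy: dict
    n_not_predicted: int
    spearman_rho_vs_brs: float | None = None
    spearman_p_vs_brs: float | None = None
    brs_crosstab: dict = field(default_factory=dict)
    n_brs_zero_excluded: int = 0

    def to_json(self) -> str:
        return json.dumps(vars(self), indent=2, default=str)

    def to_text(self) -> str:
        lines = []
        if self.tile_auc:
            lines.append(
                "tile AUC %.3f (95%% CI %.3f-%.3f)" % self.tile_auc
            )
        if self.tumor_auc:
            lines.append("tumor AUC %.3f (95%% CI %.3f-%.3f)" % self.tumor_auc)
        lines.append(f"tumor accuracy (called only): {self.accuracy_called}")
        lines.append(f"tumor accuracy (all tumors): {self.accuracy_overall}")
        lines.append(f"not predicted: {self.n_not_predicted}")
        if self.fisher_p is not None:
            lines.append(f"Fisher exact p: {self.fisher_p:.4g}")
        if self.spearman_rho_vs_brs is not None:
            lines.append(
                f"Spearman vs BRS: rho={self.spearman_rho_vs_brs:.3f} "
                f"p={self.spearman_p_vs_brs:.3g}"
            )
        return "\n".join(lines)


def perc_ras(
    tile_predictions: list[TilePrediction] | np.ndarray,
    cfg: AggregationConfig | None = None,
    patient_id: str = "",
) -> TumorPrediction:
    """percRAS = fraction of tiles with p(RAS) >= the inclusive 0.5 cutoff."""
    cfg = cfg or AggregationConfig()
    if isinstance(tile_predictions, (list, tuple)) and tile_predictions and isinstance(
        tile_predictions[0], TilePrediction
    ):
        probs = np.array([t.p_ras for t in tile_predictions])
        patient_id = patient_id or tile_predictions[0].slide_id
    else:
        probs = np.asarray(tile_predictions, dtype=float)
    if probs.size == 0:
        raise ValueError(f"no tiles for patient {patient_id!r}")
    score = float(np.count_nonzero(probs >= cfg.tile_ras_cutoff) / probs.size)
    return TumorPrediction(
        patient_id=patient_id,
        n_tiles=int(probs.size),
        perc_ras=score,
        call=classify_tumor(score, cfg),
    )


def classify_tumor(perc_ras_score: float, cfg: AggregationConfig | None = None) -> str:
    """Band rule: RAS above 0.75 (strict), BRAF below 0.25 (strict),
    otherwise not predicted."""
    cfg = cfg or AggregationConfig()
    if not 0.0 <= perc_ras_score <= 1.0:
        raise ValueError("percRAS score must be in [0, 1]")
    if perc_ras_score > cfg.ras_band_hi:
        return "RAS"
    if perc_ras_score < cfg.braf_band_lo:
        return "BRAF_V600E"
    return NOT_PREDICTED


def roc_auc(
    scores: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """AUC by the Mann-Whitney rank formulation (ties counted half) with a
    seeded bootstrap percentile 95% CI over units."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both labels present")

    def _auc(s, y):
        ranks = stats.rankdata(s)
        n_pos = int(y.sum())
        n_neg = len(y) - n_pos
        return (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    point = float(_auc(scores, labels))
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(labels), size=len(labels))
        y = labels[idx]
        if y.min() == y.max():
            continue
        boots.append(_auc(scores[idx], y))
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (point, point))
    return point, float(lo), float(hi)


def fisher_exact(table: np.ndarray) -> float:
    """Two-sided Fisher's exact p for a 2x2 table of nonnegative integers
    (sum of hypergeometric probabilities not exceeding the observed one)."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if np.any(table != np.floor(table)) or np.any(table < 0):
            raise ValueError("cells must be nonnegative integers")
        table = table.astype(int)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with mid-ranks; exact permutation p for n <= 9
    (tie-free), t-approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman undefined for a constant vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    tie_free = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= 9 and tie_free:
        n_perm = math.factorial(n)
        perms = np.fromiter(
            itertools.chain.from_iterable(itertools.permutations(range(n))),
            dtype=np.int8,
            count=n * n_perm,
        ).reshape(n_perm, n)
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        rhos = (rx_c[perms] @ ry_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho * rho))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def _confusion(calls: dict[str, str], truth: dict[str, str], rows) -> dict:
    table = {r: {c: 0 for c in CLASSES} for r in rows}
    for pid, call in calls.items():
        table[call][truth[pid]] += 1
    return table


def evaluate(
    tumor_predictions: list[TumorPrediction],
    truth: dict[str, str],
    brs_records: list[BrsRecord] | None = None,
    tile_predictions: list[TilePrediction] | None = None,
    cfg: AggregationConfig | None = None,
    seed: int = 0,
) -> EvalReport:
    """Assemble the full evaluation report.

    ``truth`` maps patient id to "BRAF_V600E" or "RAS". Tumor accuracy over
    called tumors is reported next to the all-tumor accuracy (not-predicted
    counted as wrong), since the headline figure's denominator is a
    reporting choice. The BRS cross-tab excludes exact zeros and logs them.
    """
    cfg = cfg or AggregationConfig()
    preds = {t.patient_id: t for t in tumor_predictions if t.patient_id in truth}
    if not preds:
        raise ValueError("no overlapping patient ids between predictions and truth")

    calls = {pid: t.call for pid, t in preds.items()}
    scores = np.array([preds[pid].perc_ras for pid in preds])
    y = np.array([1 if truth[pid] == "RAS" else 0 for pid in preds])
    tumor_auc = roc_auc(scores, y, seed=seed) if len(np.unique(y)) == 2 else None

    tile_auc = None
    tile_confusion = {}
    if tile_predictions:
        tp = [t for t in tile_predictions if t.slide_id in truth]
        ts = np.array([t.p_ras for t in tp])
        ty = np.array([1 if truth[t.slide_id] == "RAS" else 0 for t in tp])
        if len(np.unique(ty)) == 2:
            tile_auc = roc_auc(ts, ty, seed=seed + 1)
        tile_calls = {
            str(i): ("RAS" if t.p_ras >= cfg.tile_ras_cutoff else "BRAF_V600E")
            for i, t in enumerate(tp)
        }
        tile_truth = {str(i): truth[t.slide_id] for i, t in enumerate(tp)}
        tile_confusion = _confusion(tile_calls, tile_truth, CLASSES)

    tumor_confusion = _confusion(calls, truth, CLASSES + (NOT_PREDICTED,))

    called = {pid: c for pid, c in calls.items() if c != NOT_PREDICTED}
    n_not = len(calls) - len(called)
    correct_called = sum(1 for pid, c in called.items() if c == truth[pid])
    accuracy_called = correct_called / len(called) if called else None
    accuracy_overall = correct_called / len(calls)
    per_class = {}
    for cls in CLASSES:
        members = [pid for pid in called if truth[pid] == cls]
        per_class[cls] = (
            sum(1 for pid in members if called[pid] == cls) / len(members)
            if members
            else None
        )

    fisher_p = None
    if called:
        table = np.array(
            [[sum(1 for pid in called if called[pid] == p and truth[pid] == t) for t in CLASSES] for p in CLASSES],
            dtype=int,
        )
        fisher_p = fisher_exact(table)

    rho = p_rho = None
    crosstab: dict = {}
    n_zero = 0
    if brs_records:
        joined = [(r, preds[r.patient_id]) for r in brs_records if r.patient_id in preds]
        if len(joined) >= 3:
            brs_vals = np.array([r.brs for r, _ in joined])
            pr = np.array([t.perc_ras for _, t in joined])
            if np.ptp(brs_vals) > 0 and np.ptp(pr) > 0:
                rho, p_rho = spearman(pr, brs_vals)
        crosstab = {
            bc: {c: 0 for c in CLASSES + (NOT_PREDICTED,)}
            for bc in ("BRAF_like", "RAS_like")
        }
        for r, t in joined:
            if r.brs_class == "undefined":
                n_zero += 1
                continue
            crosstab[r.brs_class][t.call] += 1

    return EvalReport(
        tile_auc=tile_auc,
        tumor_auc=tumor_auc,
        tile_confusion=tile_confusion,
        tumor_confusion=tumor_confusion,
        fisher_p=fisher_p,
        accuracy_called=accuracy_called,
        accuracy_overall=accuracy_overall,
        per_class_accuracy=per_class,
        n_not_predicted=n_not,
        spearman_rho_vs_brs=rho,
        spearman_p_vs_brs=p_rho,
        brs_crosstab=crosstab,
        n_brs_zero_excluded=n_zero,
    )
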