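"""percRAS aggregation, decision bands, and the evaluation statistics
checked against independent brute-force oracles (all-pairs concordance,
hypergeometric enumeration, rank closed form)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wsidriver as w
from wsidriver.aggregation_eval import (
    AggregationConfig,
    BrsRecord,
    NOT_PREDICTED,
    TumorPrediction,
)


class TestPercRas:
    def test_all_above_cutoff(self):
        assert w.perc_ras(np.array([0.9, 0.8, 0.6])).perc_ras == 1.0

    def test_cutoff_inclusive(self):
        assert w.perc_ras(np.array([0.5])).perc_ras == 1.0

    def test_direct_count(self):
        assert w.perc_ras(np.array([0.6, 0.4, 0.9])).perc_ras == pytest.approx(2 / 3)

    def test_zero_tiles_errors(self):
        with pytest.raises(ValueError, match="no tiles"):
            w.perc_ras(np.array([]), patient_id="P1")

    def test_matches_bruteforce_tile_count(self):
        rng = np.random.default_rng(0)
        cfg = AggregationConfig()
        for _ in range(50):
            probs = np.round(rng.uniform(0, 1, size=rng.integers(1, 40)), 2)
            expected = sum(1 for p in probs if p >= 0.5) / len(probs)
            assert w.perc_ras(probs, cfg).perc_ras == pytest.approx(expected, abs=1e-12)


class TestBands:
    def test_examples(self):
        assert w.classify_tumor(0.8) == "RAS"
        assert w.classify_tumor(0.1) == "BRAF_V600E"
        assert w.classify_tumor(0.75) == NOT_PREDICTED  # "exceeded" is strict
        assert w.classify_tumor(0.25) == NOT_PREDICTED  # "below" is strict
        assert w.classify_tumor(0.5) == NOT_PREDICTED

    @settings(deadline=None, max_examples=300)
    @given(score=st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_band_predicate_property(self, score):
        call = w.classify_tumor(score)
        if score > 0.75:
            assert call == "RAS"
        elif score < 0.25:
            assert call == "BRAF_V600E"
        else:
            assert call == NOT_PREDICTED

    def test_exhaustive_grid_against_independent_predicate(self):
        rng = np.random.default_rng(1)
        scores = np.concatenate(
            [rng.uniform(0, 1, 9000), np.array([0.0, 0.25, 0.5, 0.75, 1.0]), rng.integers(0, 41, 995) / 40]
        )
        for s in scores:
            expected = "RAS" if s > 0.75 else ("BRAF_V600E" if s < 0.25 else NOT_PREDICTED)
            assert w.classify_tumor(float(s)) == expected

    def test_invalid_band_config(self):
        with pytest.raises(ValueError):
            AggregationConfig(braf_band_lo=0.8, ras_band_hi=0.75)


def _auc_allpairs(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, lo, hi = w.roc_auc(np.array([0.9, 0.8, 0.3, 0.4]), np.array([1, 1, 0, 0]), seed=0)
        assert auc == 1.0
        assert 0 <= lo <= auc <= hi <= 1

    def test_known_value(self):
        auc, _, _ = w.roc_auc(np.array([0.9, 0.8, 0.4, 0.3]), np.array([1, 0, 1, 0]), n_boot=0)
        assert auc == pytest.approx(0.75, abs=1e-12)

    def test_all_tied_scores(self):
        auc, _, _ = w.roc_auc(np.full(10, 0.5), np.array([1, 0] * 5), n_boot=0)
        assert auc == pytest.approx(0.5, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both labels"):
            w.roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_matches_allpairs_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        for n in (10, 50, 200):
            scores = rng.integers(0, 12, size=n) / 11.0  # coarse grid forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            auc, _, _ = w.roc_auc(scores, labels, n_boot=0)
            assert auc == pytest.approx(_auc_allpairs(scores, labels), abs=1e-9)

    def test_matches_sklearn_cross_check(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        scores = rng.uniform(size=80)
        labels = rng.integers(0, 2, size=80)
        auc, _, _ = w.roc_auc(scores, labels, n_boot=0)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)


def _fisher_enumeration(table):
    """Two-sided Fisher p by exact hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs + 1e-12)


class TestFisher:
    def test_enumerated_examples(self):
        assert w.fisher_exact(np.array([[3, 1], [1, 3]])) == pytest.approx(34 / 70, abs=1e-9)
        assert w.fisher_exact(np.array([[5, 0], [0, 5]])) == pytest.approx(2 / 252, abs=1e-9)

    def test_zero_margin_degenerate(self):
        assert w.fisher_exact(np.array([[0, 0], [2, 3]])) == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            w.fisher_exact(np.array([[1, -1], [2, 3]]))

    def test_matches_enumeration_all_small_tables(self):
        rng = np.random.default_rng(5)
        tables = [rng.integers(0, 9, size=(2, 2)) for _ in range(200)]
        tables = [t for t in tables if t.sum() <= 30]
        assert len(tables) > 100
        for t in tables:
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            assert w.fisher_exact(t) == pytest.approx(_fisher_enumeration(t), abs=1e-9)


class TestSpearman:
    def test_closed_form_small_example(self):
        rho, p = w.spearman(np.array([1, 2, 3]), np.array([3, 1, 2]))
        assert rho == pytest.approx(-0.5, abs=1e-12)
        assert 0 <= p <= 1

    def test_monotone_identity(self):
        x = np.array([3.0, 1.0, 7.0, 5.0])
        assert w.spearman(x, x)[0] == pytest.approx(1.0)
        assert w.spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="constant"):
            w.spearman(np.ones(5), np.arange(5.0))

    def test_matches_sum_d2_closed_form(self):
        rng = np.random.default_rng(6)
        for n in (5, 9, 30, 100):
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            rho, _ = w.spearman(x, y)
            d2 = ((np.argsort(np.argsort(x)) - np.argsort(np.argsort(y))) ** 2).sum()
            assert rho == pytest.approx(1 - 6 * d2 / (n * (n**2 - 1)), abs=1e-9)

    def test_p_against_scipy_t_approximation(self):
        from scipy import stats

        rng = np.random.default_rng(7)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        rho, p = w.spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestEvaluate:
    @staticmethod
    def _tumors(calls_scores, truth):
        return [
            TumorPrediction(pid, 10, s, w.classify_tumor(s)) for pid, s in calls_scores
        ], truth

    def test_perfect_predictions(self):
        preds, truth = self._tumors(
            [("a", 0.0), ("b", 0.05), ("c", 1.0), ("d", 0.95)],
            {"a": "BRAF_V600E", "b": "BRAF_V600E", "c": "RAS", "d": "RAS"},
        )
        report = w.evaluate(preds, truth)
        assert report.accuracy_called == 1.0
        assert report.accuracy_overall == 1.0
        assert report.tumor_confusion["BRAF_V600E"]["RAS"] == 0
        assert report.tumor_confusion["RAS"]["BRAF_V600E"] == 0
        assert report.n_not_predicted == 0

    def test_label_independent_predictions_give_null_auc(self):
        rng = np.random.default_rng(11)
        scores = rng.uniform(0, 1, size=40)
        labels = ["BRAF_V600E"] * 20 + ["RAS"] * 20
        preds, truth = self._tumors(
            [(f"p{i}", float(scores[i])) for i in range(40)],
            {f"p{i}": labels[i] for i in range(40)},
        )
        report = w.evaluate(preds, truth)
        assert 0.3 <= report.tumor_auc[0] <= 0.7

    def test_brs_zero_excluded_from_crosstab(self):
        preds, truth = self._tumors(
            [("a", 0.0), ("b", 1.0), ("c", 0.9)],
            {"a": "BRAF_V600E", "b": "RAS", "c": "RAS"},
        )
        brs = [BrsRecord("a", -0.5), BrsRecord("b", 0.4), BrsRecord("c", 0.0)]
        report = w.evaluate(preds, truth, brs_records=brs)
        assert report.n_brs_zero_excluded == 1
        total = sum(v for row in report.brs_crosstab.values() for v in row.values())
        assert total == 2

    def test_not_predicted_reported_separately(self):
        preds, truth = self._tumors(
            [("a", 0.1), ("b", 0.5), ("c", 0.9), ("d", 0.95)],
            {"a": "BRAF_V600E", "b": "BRAF_V600E", "c": "RAS", "d": "RAS"},
        )
        report = w.evaluate(preds, truth)
        assert report.n_not_predicted == 1
        assert report.accuracy_called == 1.0
        assert report.accuracy_overall == pytest.approx(3 / 4)
        assert report.tumor_confusion[NOT_PREDICTED]["BRAF_V600E"] == 1

    def test_no_overlap_errors(self):
        preds, _ = self._tumors([("a", 0.5)], {})
        with pytest.raises(ValueError, match="overlap"):
            w.evaluate(preds, {"zz": "RAS"})

    def test_confusion_cells_sum_to_units(self):
        rng = np.random.default_rng(12)
        n = 30
        scores = rng.uniform(0, 1, size=n)
        labels = ["BRAF_V600E" if i % 2 else "RAS" for i in range(n)]
        preds, truth = self._tumors(
            [(f"p{i}", float(scores[i])) for i in range(n)],
            {f"p{i}": labels[i] for i in range(n)},
        )
        report = w.evaluate(preds, truth)
        total = sum(v for row in report.tumor_confusion.values() for v in row.values())
        assert total == n
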