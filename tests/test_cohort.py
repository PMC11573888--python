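"""Cohort filtering, histology-matched subsampling, patient splitting and
training-plan arithmetic."""

import pytest

import wsidriver as w
from wsidriver.cohort import SampleRecord, read_manifest, read_split, write_split


def _records(n_braf=234, n_ras=51, n_both=1):
    braf_hist = ["classical"] * 179 + ["tall_cell"] * 27 + ["follicular_variant"] * 12 + ["other"] * 16
    recs = [
        SampleRecord(f"B{i:03d}", "BRAF_V600E", braf_hist[i % len(braf_hist)])
        for i in range(n_braf)
    ]
    ras_hist = ["follicular_variant"] * 29 + ["classical"] * 20 + ["other"] * 2
    recs += [SampleRecord(f"R{i:03d}", "RAS", ras_hist[i % len(ras_hist)]) for i in range(n_ras)]
    recs += [SampleRecord(f"D{i:03d}", "both", "classical") for i in range(n_both)]
    return recs


class TestFilter:
    def test_dual_mutant_excluded_ras_retained(self):
        included, excluded = w.filter_cohort(_records())
        assert len(excluded) == 1
        assert sum(1 for s in included if s.mutation == "RAS") == 51
        assert sum(1 for s in included if s.mutation == "BRAF_V600E") == 234

    def test_no_dual_mutants_empty_log(self):
        _, excluded = w.filter_cohort(_records(n_both=0))
        assert excluded == []

    def test_all_dual_mutants_errors(self):
        with pytest.raises(ValueError):
            w.filter_cohort([SampleRecord("D1", "both"), SampleRecord("D2", "both")])


class TestMatchedSubsample:
    def test_target_size_is_ras_plus_one(self):
        included, _ = w.filter_cohort(_records())
        braf = [s for s in included if s.mutation == "BRAF_V600E"]
        ras = [s for s in included if s.mutation == "RAS"]
        subset = w.match_braf_subsample(braf, ras, seed=0)
        assert len(subset) == 52
        assert all(s.mutation == "BRAF_V600E" for s in subset)

    def test_histology_proportions_match_within_one(self):
        # pool sharing the RAS histology mix, large enough per stratum
        braf = (
            [SampleRecord(f"Bf{i}", "BRAF_V600E", "follicular_variant") for i in range(87)]
            + [SampleRecord(f"Bc{i}", "BRAF_V600E", "classical") for i in range(60)]
            + [SampleRecord(f"Bo{i}", "BRAF_V600E", "other") for i in range(6)]
        )
        ras = [s for s in _records()[234:285] if s.mutation == "RAS"]
        assert len(ras) == 51
        subset = w.match_braf_subsample(braf, ras, seed=1)
        for h in {s.histology for s in ras}:
            target = sum(1 for s in ras if s.histology == h) / len(ras) * 52
            got = sum(1 for s in subset if s.histology == h)
            assert abs(got - target) <= 1.0

    def test_seeded_repeatability(self):
        included, _ = w.filter_cohort(_records())
        braf = [s for s in included if s.mutation == "BRAF_V600E"]
        ras = [s for s in included if s.mutation == "RAS"]
        a = w.match_braf_subsample(braf, ras, seed=7)
        b = w.match_braf_subsample(braf, ras, seed=7)
        assert [s.patient_id for s in a] == [s.patient_id for s in b]

    def test_missing_stratum_borrows_with_warning(self):
        braf = [SampleRecord(f"B{i}", "BRAF_V600E", "classical") for i in range(30)]
        ras = [SampleRecord(f"R{i}", "RAS", "follicular_variant") for i in range(10)]
        with pytest.warns(UserWarning, match="borrowing"):
            subset = w.match_braf_subsample(braf, ras, seed=0)
        assert len(subset) == 11


class TestSplit:
    @staticmethod
    def _cohort_103():
        included, _ = w.filter_cohort(_records())
        braf = [s for s in included if s.mutation == "BRAF_V600E"]
        ras = [s for s in included if s.mutation == "RAS"]
        return w.match_braf_subsample(braf, ras, seed=0) + ras

    def test_103_patients_split_61_21_21(self):
        split = w.split_patients(self._cohort_103(), seed=0)
        assert split.counts() == {"train": 61, "validation": 21, "test": 21}

    def test_both_classes_in_every_role(self):
        samples = self._cohort_103()
        split = w.split_patients(samples, seed=0)
        mut = {s.patient_id: s.mutation for s in samples}
        for role in ("train", "validation", "test"):
            classes = {mut[p] for p in split.patients(role)}
            assert classes == {"BRAF_V600E", "RAS"}

    def test_exact_division(self):
        samples = [SampleRecord(f"B{i}", "BRAF_V600E") for i in range(5)] + [
            SampleRecord(f"R{i}", "RAS") for i in range(5)
        ]
        split = w.split_patients(samples, seed=3)
        assert split.counts() == {"train": 6, "validation": 2, "test": 2}

    def test_is_partition(self):
        samples = self._cohort_103()
        split = w.split_patients(samples, seed=5)
        assert sorted(split.roles) == sorted(s.patient_id for s in samples)

    def test_seeded_repeatability(self):
        samples = self._cohort_103()
        assert w.split_patients(samples, seed=2).roles == w.split_patients(samples, seed=2).roles

    def test_bad_ratios(self):
        with pytest.raises(ValueError, match="sum to 1"):
            w.split_patients(self._cohort_103(), ratios=(0.5, 0.2, 0.2))


class TestTrainingPlan:
    def test_printed_counts(self):
        split = w.split_patients(TestSplit._cohort_103(), seed=0)
        plan = w.compute_training_plan(split)
        assert plan.n_train_patches == 24_400
        assert plan.n_val_patches == 4_200
        assert plan.n_test_patches == 4_200
        assert plan.iterations == 610_000

    def test_plan_matches_bruteforce_manifest_counts(self):
        """Plan arithmetic equals counting the records the sampler emits."""
        from wsidriver.patch_features import PatchFeatureSet
        from wsidriver.patch_pipeline import PatchRecord, SamplerConfig, sample_for_split
        from wsidriver.slide_io import TileCoordinate

        def _fake_records(n, pid):
            feats = PatchFeatureSet(30, 0.5, 1.2, 2.0, 1.0)
            return [
                PatchRecord(pid, TileCoordinate(0, 512 * (i % 40), 512 * (i // 40), 512), feats, True)
                for i in range(n)
            ]

        samples = [SampleRecord(f"B{i}", "BRAF_V600E") for i in range(6)] + [
            SampleRecord(f"R{i}", "RAS") for i in range(6)
        ]
        split = w.split_patients(samples, seed=1)
        cfg = SamplerConfig(per_sample_train=20, per_slide_cap=40, augment_select=2, seed=0)
        plan = w.compute_training_plan(split, per_sample_train=20, augment_select=2)
        emitted = {"train": 0, "validation": 0, "test": 0}
        for pid, role in split.roles.items():
            emitted[role] += len(sample_for_split(_fake_records(40, pid), role, cfg))
        assert emitted["train"] == plan.n_train_patches
        assert emitted["validation"] == plan.n_val_patches
        assert emitted["test"] == plan.n_test_patches


def test_manifest_and_split_round_trip(tmp_path):
    import pandas as pd

    members = w.generate_cohort(3, 3, 0.5, seed=0)
    df = pd.DataFrame(
        [
            {
                "patient_id": m.record.patient_id,
                "label": "BRAF" if m.record.mutation == "BRAF_V600E" else "RAS",
                "histology": m.record.histology,
                "brs": m.record.brs,
            }
            for m in members
        ]
    )
    path = tmp_path / "manifest.tsv"
    df.to_csv(path, sep="\t", index=False)
    records = read_manifest(path)
    assert [r.patient_id for r in records] == [m.record.patient_id for m in members]
    assert records[0].mutation == "BRAF_V600E"

    split = w.split_patients(
        [SampleRecord(f"B{i}", "BRAF_V600E") for i in range(5)]
        + [SampleRecord(f"R{i}", "RAS") for i in range(5)],
        seed=0,
    )
    spath = tmp_path / "split.tsv"
    write_split(split, spath)
    assert read_split(spath).roles == split.roles
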