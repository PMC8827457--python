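"""Cross-validation harness: folds, leakage, selection, hold-out evaluation."""

import numpy as np
import pytest

from fetalsweep.harness import (SELECTION_METRICS, FoldSpec, audit_leakage,
                                evaluate_holdout, make_folds, run_loocv,
                                select_best)
from fetalsweep.phantom import PhantomConfig, make_phantom
from fetalsweep.preprocess import TrainingSet
from fetalsweep.segmentation import OracleSegmenter, UNetConfig


def make_record(fold_index, **overrides):
    rec = {"fold_index": fold_index, "sensitivity": 0.9, "specificity": 0.9,
           "ppv": 0.9, "npv": 0.9, "jaccard": 0.8, "pixel_accuracy": 0.95,
           "area_error_pct": 10.0}
    rec.update(overrides)
    return rec


def tiny_dataset(n_patients=3, frames_each=8, size=16, seed=0):
    rng = np.random.default_rng(seed)
    n = n_patients * frames_each
    frames = rng.uniform(0, 0.3, (n, size, size)).astype(np.float32)
    masks = np.zeros((n, size, size), bool)
    present = np.zeros(n, bool)
    for i in range(n):
        if i % 2 == 0:
            frames[i, 4:9, 4:9] = 0.9
            masks[i, 4:9, 4:9] = True
            present[i] = True
    return TrainingSet(frames=frames, masks={"head": masks},
                       present={"head": present},
                       patient_ids=np.repeat(np.arange(n_patients), frames_each))


class TestFolds:
    def test_one_fold_per_patient_with_exclusion(self):
        folds = make_folds([10, 11, 12])
        assert len(folds) == 3
        for fold in folds:
            assert fold.test_patient_id not in fold.training_patient_ids
            assert len(fold.training_patient_ids) == 2

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            make_folds([1, 1, 2])

    def test_single_patient_rejected(self):
        with pytest.raises(ValueError):
            make_folds([1])

    def test_foldspec_leakage_rejected(self):
        with pytest.raises(ValueError):
            FoldSpec(0, 1, (1, 2))

    def test_audit_leakage_zero_on_valid_folds(self):
        ds = tiny_dataset()
        assert audit_leakage(ds, make_folds([0, 1, 2])) == 0


class TestSelectBest:
    def test_uniform_records_tie_break_lowest_fold(self):
        records = [make_record(2), make_record(0), make_record(1)]
        assert select_best(records) == 0

    def test_dominant_fold_wins(self):
        records = [make_record(0),
                   make_record(1, sensitivity=0.99, jaccard=0.95,
                               area_error_pct=1.0),
                   make_record(2, sensitivity=0.5, jaccard=0.4)]
        assert select_best(records) == 1

    def test_area_error_ranks_ascending(self):
        records = [make_record(0, area_error_pct=50.0),
                   make_record(1, area_error_pct=2.0)]
        assert select_best(records) == 1

    def test_nan_gets_worst_rank(self):
        records = [make_record(0, jaccard=float("nan")),
                   make_record(1, jaccard=0.1)]
        assert select_best(records) == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])

    def test_seven_selection_metrics(self):
        assert len(SELECTION_METRICS) == 7
        directions = dict(SELECTION_METRICS)
        assert directions["area_error_pct"] == "asc"
        assert all(d == "desc" for m, d in SELECTION_METRICS
                   if m != "area_error_pct")


@pytest.fixture(scope="module")
def loocv_result():
    ds = tiny_dataset()
    cfg = UNetConfig(input_size=(16, 16), depth=2, base_filters=2,
                     batch_size=8, epochs=2, seed=0)
    return ds, run_loocv(ds, "head", cfg, master_seed=100)


class TestRunLoocv:
    def test_one_record_per_patient(self, loocv_result):
        ds, result = loocv_result
        assert len(result.records) == 3
        assert sorted(r["test_patient_id"] for r in result.records) == [0, 1, 2]

    def test_selected_model_available(self, loocv_result):
        _, result = loocv_result
        assert result.selected_fold in {0, 1, 2}
        assert result.selected_model is result.models[result.selected_fold]

    def test_per_fold_seed_offsets(self, loocv_result):
        _, result = loocv_result
        for fold_index, model in result.models.items():
            assert model.config.seed == 100 + fold_index

    def test_reproducible(self, loocv_result):
        ds, result = loocv_result
        cfg = UNetConfig(input_size=(16, 16), depth=2, base_filters=2,
                         batch_size=8, epochs=2, seed=0)
        again = run_loocv(ds, "head", cfg, master_seed=100, keep_models=False)
        for a, b in zip(result.records, again.records):
            assert a.keys() == b.keys()
            for key in a:
                va, vb = a[key], b[key]
                if isinstance(va, float) and np.isnan(va):
                    assert np.isnan(vb)
                else:
                    assert va == vb
        assert again.selected_fold == result.selected_fold

    def test_fold_without_positives_skipped(self):
        ds = tiny_dataset(n_patients=2)
        # strip positives from patient 1's complement: make patient 0 hold
        # every positive, so the fold testing patient 1 trains fine but the
        # fold testing patient 0 has no positive training frame
        ds.present["head"][ds.patient_ids == 1] = False
        ds.masks["head"][ds.patient_ids == 1] = False
        cfg = UNetConfig(input_size=(16, 16), depth=2, base_filters=2,
                         batch_size=8, epochs=1, seed=0)
        result = run_loocv(ds, "head", cfg, master_seed=0)
        assert len(result.skipped) == 1
        assert result.skipped[0][0] == 0


@pytest.fixture(scope="module")
def holdout():
    configs = [
        PhantomConfig(frames_per_sweep=12, seed=31),
        PhantomConfig(head_center=(0.7, 0.5, 0.5),
                      presentation_label="non-cephalic",
                      placenta_location_label="posterior",
                      frames_per_sweep=12, seed=32),
        PhantomConfig(placenta_location_label="fundal",
                      frames_per_sweep=12, seed=33),
    ]
    exams, truths = [], []
    for config in configs:
        exam, truth = make_phantom(config)
        exams.append(exam)
        truths.append(truth)
    return exams, truths


class TestEvaluateHoldout:
    @staticmethod
    def run(exams, truths, references):
        by_id = {id(e): t for e, t in zip(exams, truths)}
        return evaluate_holdout(
            lambda e: OracleSegmenter(by_id[id(e)], "head"),
            lambda e: OracleSegmenter(by_id[id(e)], "placenta"),
            exams, references)

    def test_perfect_references_agree(self, holdout):
        exams, truths = holdout
        references = [{"presentation": t.true_presentation,
                       "placenta_location": t.true_placenta_location,
                       "bpd_mm": t.true_bpd_mm, "hc_mm": t.true_hc_mm}
                      for t in truths]
        report = self.run(exams, truths, references)
        assert report["presentation"]["percent_agreement"] == 100.0
        assert report["placenta_location"]["percent_agreement"] == 100.0
        assert report["bpd_mm"]["relative_error_pct"] < 5.0
        assert report["excluded"]["presentation"] == 0

    def test_unable_references_excluded_and_counted(self, holdout):
        exams, truths = holdout
        references = [{"presentation": t.true_presentation,
                       "placenta_location": t.true_placenta_location,
                       "bpd_mm": t.true_bpd_mm, "hc_mm": t.true_hc_mm}
                      for t in truths]
        references[0]["presentation"] = "unable"
        references[1]["bpd_mm"] = None
        report = self.run(exams, truths, references)
        assert report["excluded"]["presentation"] == 1
        assert report["excluded"]["bpd_mm"] == 1

    def test_fundal_exclusion_report_present(self, holdout):
        exams, truths = holdout
        references = [{"presentation": t.true_presentation,
                       "placenta_location": t.true_placenta_location,
                       "bpd_mm": t.true_bpd_mm, "hc_mm": t.true_hc_mm}
                      for t in truths]
        report = self.run(exams, truths, references)
        assert "placenta_location_excl_fundal" in report
        # one of the three phantoms is fundal; the restricted table keeps the
        # remaining two concordant cases
        restricted = report["placenta_location_excl_fundal"]
        assert restricted["percent_agreement"] == 100.0

    def test_empty_exam_list_rejected(self):
        with pytest.raises(ValueError):
            evaluate_holdout(lambda e: None, lambda e: None, [], [])

    def test_mismatched_lengths_rejected(self, holdout):
        exams, truths = holdout
        with pytest.raises(ValueError):
            evaluate_holdout(lambda e: None, lambda e: None, exams, [{}])
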