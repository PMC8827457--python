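"""Leave-one-out cross-validation, model selection, and hold-out evaluation.

Each patient takes one turn as the single test case while the remaining
patients train the segmenter; the fold whose held-out metrics rank best on
average across seven criteria (sensitivity, specificity, PPV, NPV, Jaccard,
pixel accuracy, and area error) supplies the weights used on novel
patients.  Rank aggregation is used because the seven metrics live on
different scales; area error ranks ascending, everything else descending.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .agreement import AgreementReport, categorical_report, continuous_report
from .preprocess import TrainingSet
from .segmentation import SegModel, UNetConfig, segmentation_metrics, train_segmenter

#: Metrics entering model selection, with ranking direction.
SELECTION_METRICS = (
    ("sensitivity", "desc"),
    ("specificity", "desc"),
    ("ppv", "desc"),
    ("npv", "desc"),
    ("jaccard", "desc"),
    ("pixel_accuracy", "desc"),
    ("area_error_pct", "asc"),
)


@dataclass(frozen=True)
class FoldSpec:
    fold_index: int
    test_patient_id: int
    training_patient_ids: tuple

    def __post_init__(self) -> None:
        if self.test_patient_id in self.training_patient_ids:
            raise ValueError("test patient must be excluded from training")


def make_folds(patient_ids: Sequence) -> list[FoldSpec]:
    """One fold per patient: fold i tests patient i, trains on the rest."""
    ids = list(patient_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate patient ids")
    if len(ids) < 2:
        raise ValueError("need at least 2 patients")
    folds = []
    for i, pid in enumerate(ids):
        train = tuple(p for p in ids if p != pid)
        folds.append(FoldSpec(fold_index=i, test_patient_id=pid,
                              training_patient_ids=train))
    return folds


@dataclass
class ModelSelectionRecord:
    """Per-fold metrics, trained models, and the selected fold."""

    records: list = field(default_factory=list)   # dicts with fold_index + metrics
    models: dict = field(default_factory=dict)    # fold_index -> SegModel
    skipped: list = field(default_factory=list)   # (fold_index, reason)
    selected_fold: int | None = None

    @property
    def selected_model(self) -> SegModel | None:
        if self.selected_fold is None:
            return None
        return self.models.get(self.selected_fold)


def select_best(records: Sequence[Mapping]) -> int:
    """Fold with the lowest mean rank across the seven selection metrics.

    Ties break toward the lowest fold_index; NaN metric values get the
    worst rank for that metric.
    """
    if not records:
        raise ValueError("no records to select from")
    n = len(records)
    mean_ranks = np.zeros(n)
    for metric, direction in SELECTION_METRICS:
        values = np.array([float(r[metric]) for r in records])
        signed = values if direction == "asc" else -values
        signed = np.where(np.isnan(signed), np.inf, signed)
        mean_ranks += rankdata(signed, method="average")
    mean_ranks /= len(SELECTION_METRICS)
    order = np.lexsort((np.array([r["fold_index"] for r in records]), mean_ranks))
    return int(records[order[0]]["fold_index"])


def run_loocv(dataset: TrainingSet, structure: str, config: UNetConfig,
              master_seed: int = 0, *, keep_models: bool = True
              ) -> ModelSelectionRecord:
    """Train and evaluate one fold per patient.

    Per-fold training seeds derive from ``master_seed`` plus the fold index
    so folds are independent but the whole run is reproducible.  Folds
    whose training pool has no structure-present frame are skipped with a
    recorded warning.  The leakage audit (`audit_leakage`) re-checks that
    no test-patient frame index ever enters the fold's training indices.
    """
    patient_ids = sorted(set(dataset.patient_ids.tolist()))
    folds = make_folds(patient_ids)
    result = ModelSelectionRecord()
    present = dataset.present[structure]
    for fold in folds:
        train_idx = np.flatnonzero(np.isin(dataset.patient_ids,
                                           fold.training_patient_ids))
        test_idx = np.flatnonzero(dataset.patient_ids == fold.test_patient_id)
        assert not np.intersect1d(train_idx, test_idx).size, "fold leakage"
        if not present[train_idx].any():
            result.skipped.append((fold.fold_index,
                                   "no structure-present frames in training pool"))
            continue
        fold_seed = int(master_seed) + fold.fold_index
        fold_config = UNetConfig(
            input_size=config.input_size, depth=config.depth,
            base_filters=config.base_filters, batch_size=config.batch_size,
            epochs=config.epochs, learning_rate=config.learning_rate,
            seed=fold_seed)
        model = train_segmenter(dataset.subset(train_idx), fold_config, structure)
        prob = model.predict_proba(dataset.frames[test_idx])
        pred = prob >= 0.5
        metrics = segmentation_metrics(pred, dataset.masks[structure][test_idx])
        record = {"fold_index": fold.fold_index,
                  "test_patient_id": fold.test_patient_id, **metrics}
        result.records.append(record)
        if keep_models:
            result.models[fold.fold_index] = model
    if result.records:
        result.selected_fold = select_best(result.records)
    return result


def audit_leakage(dataset: TrainingSet, folds: Sequence[FoldSpec]) -> int:
    """Count frame indices appearing in both a fold's train and test sets."""
    leaks = 0
    for fold in folds:
        train_idx = set(np.flatnonzero(
            np.isin(dataset.patient_ids, fold.training_patient_ids)).tolist())
        test_idx = set(np.flatnonzero(
            dataset.patient_ids == fold.test_patient_id).tolist())
        leaks += len(train_idx & test_idx)
    return leaks


# ---------------------------------------------------------------------------
# Hold-out evaluation
# ---------------------------------------------------------------------------

UNREPORTABLE = "unable"


def evaluate_holdout(head_segmenter_for: Callable, placenta_segmenter_for: Callable,
                     exams: Sequence, references: Sequence[Mapping], *,
                     registry=None, params=None, diagnose_kwargs: dict | None = None
                     ) -> dict:
    """Diagnose each hold-out exam and compare against reference readings.

    ``head_segmenter_for(exam)`` / ``placenta_segmenter_for(exam)`` return
    the segmenter to use (a constant trained model, or a per-exam oracle).
    ``references`` holds per-exam dicts with keys ``presentation``,
    ``placenta_location``, ``bpd_mm``, ``hc_mm``; a value equal to
    ``"unable"`` (or None) excludes that exam from the corresponding
    comparison and is counted.
    """
    from .diagnosis import diagnose_exam

    if not exams:
        raise ValueError("empty hold-out set")
    if len(exams) != len(references):
        raise ValueError("need one reference per exam")
    kwargs = dict(diagnose_kwargs or {})
    diagnoses = [diagnose_exam(exam, head_segmenter_for(exam),
                               placenta_segmenter_for(exam),
                               registry=registry, params=params, **kwargs)
                 for exam in exams]

    report: dict = {"diagnoses": [d.to_dict() for d in diagnoses], "excluded": {}}

    def _paired(key, pred_values):
        refs, preds, excluded = [], [], 0
        for ref, pred in zip(references, pred_values):
            value = ref.get(key)
            if value is None or value == UNREPORTABLE or pred is None:
                excluded += 1
                continue
            refs.append(value)
            preds.append(pred)
        return refs, preds, excluded

    refs, preds, excl = _paired("presentation", [d.presentation for d in diagnoses])
    report["excluded"]["presentation"] = excl
    if refs:
        report["presentation"] = categorical_report(
            refs, preds, positive_label="cephalic").to_dict()

    refs, preds, excl = _paired("placenta_location",
                                [d.placenta_location for d in diagnoses])
    report["excluded"]["placenta_location"] = excl
    if refs:
        report["placenta_location"] = categorical_report(
            refs, preds, positive_label="anterior").to_dict()
        report["placenta_location_excl_fundal"] = categorical_report(
            refs, preds, positive_label="anterior", exclude_label="fundal").to_dict()

    for key, attr in (("bpd_mm", "bpd_mm"), ("hc_mm", "hc_mm")):
        values = [getattr(d.biometry, attr) if d.biometry else None for d in diagnoses]
        refs, preds, excl = _paired(key, values)
        report["excluded"][key] = excl
        if len(refs) >= 3:
            report[key] = continuous_report(preds, refs).to_dict()
    return report
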