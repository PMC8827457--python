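"""Score-based diagnosis: fetal presentation and placental location.

The likelihood maps live on the axial x lateral plane, so presentation
(head toward pelvis vs not) reads directly off the head map's mass-weighted
axial centroid.  The anterior/posterior distinction needs the third axis:
the within-frame depth centroid of the placenta masks (near field =
anterior wall) supplies it.  Fundal placentas straddle both walls at the
top of the uterus, so the fundal decision (map centroid near the fundus)
takes precedence over the depth rule.  A placenta mapped to the very bottom
of the matrix raises a low-placenta flag — the previa-suspect referral
signal — without claiming a previa diagnosis.

All thresholds are plain parameters: the decision rule is deliberately
simple and declared, not learned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .biometry import BiometryResult, GaEstimate, NoHeadError, ga_from_biometry, measure_head
from .localization import LikelihoodMap, SweepGeometry, build_likelihood_map, default_registry
from .preprocess import DEFAULT_OUT_SIZE, CropBox, crop_and_resize, backproject
from .segmentation import DetectionSeries, detect_series, predict_mask

CEPHALIC = "cephalic"
NON_CEPHALIC = "non-cephalic"
INDETERMINATE = "indeterminate"
ANTERIOR = "anterior"
POSTERIOR = "posterior"
FUNDAL = "fundal"


class ExamValidationError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the score-based decision rule (normalized coordinates)."""

    presentation_threshold: float = 0.5
    fundal_axial_threshold: float = 0.75
    depth_anterior_max: float = 0.45
    depth_posterior_min: float = 0.55
    low_axial_threshold: float = 0.10
    min_total_mass: float = 1e-9

    def __post_init__(self) -> None:
        for name in ("presentation_threshold", "fundal_axial_threshold",
                     "depth_anterior_max", "depth_posterior_min",
                     "low_axial_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
        if self.depth_anterior_max > self.depth_posterior_min:
            raise ValueError("depth_anterior_max must be <= depth_posterior_min")
        if self.min_total_mass <= 0:
            raise ValueError("min_total_mass must be > 0")


@dataclass
class Diagnosis:
    """Labels and scores for one examination."""

    presentation: str
    presentation_score: float | None
    placenta_location: str
    placenta_depth_score: float | None
    placenta_axial_score: float | None
    low_placenta_flag: bool
    biometry: BiometryResult | None = None
    ga: GaEstimate | None = None
    head_map: LikelihoodMap | None = None
    placenta_map: LikelihoodMap | None = None

    def to_dict(self) -> dict:
        out = {
            "presentation": self.presentation,
            "presentation_score": self.presentation_score,
            "placenta_location": self.placenta_location,
            "placenta_depth_score": self.placenta_depth_score,
            "placenta_axial_score": self.placenta_axial_score,
            "low_placenta_flag": self.low_placenta_flag,
        }
        if self.biometry is not None:
            out["bpd_mm"] = self.biometry.bpd_mm
            out["hc_mm"] = self.biometry.hc_mm
            out["biometry_source"] = list(self.biometry.source)
        if self.ga is not None:
            out["ga_days_bpd"] = self.ga.ga_days_bpd
            out["ga_days_hc"] = self.ga.ga_days_hc
            out["ga_formula"] = self.ga.formula_id
        return out


def classify_presentation(head_map: LikelihoodMap,
                          params: ClassifierParams | None = None
                          ) -> tuple[str, float | None]:
    """Cephalic when the head map's axial centroid is in the pelvic half."""
    if params is None:
        params = ClassifierParams()
    if head_map.total_mass < params.min_total_mass:
        return INDETERMINATE, None
    axial, _ = head_map.centroid()
    label = CEPHALIC if axial < params.presentation_threshold else NON_CEPHALIC
    return label, axial


def classify_placenta(placenta_map: LikelihoodMap,
                      depth_stat: float | None,
                      params: ClassifierParams | None = None
                      ) -> tuple[str, dict]:
    """Rule order: indeterminate -> fundal -> anterior -> posterior -> fundal.

    ``depth_stat`` is the area-weighted mean within-frame depth centroid over
    all placenta-detected frames (0 = near field / anterior wall).  The final
    fundal fallback covers straddling placentas whose depth is ambiguous.
    """
    if params is None:
        params = ClassifierParams()
    scores: dict = {"axial": None, "depth": depth_stat, "low_placenta_flag": False}
    if placenta_map.total_mass < params.min_total_mass:
        return INDETERMINATE, scores
    axial, _ = placenta_map.centroid()
    scores["axial"] = axial
    scores["low_placenta_flag"] = bool(axial <= params.low_axial_threshold)
    if axial >= params.fundal_axial_threshold:
        return FUNDAL, scores
    if depth_stat is not None and depth_stat <= params.depth_anterior_max:
        return ANTERIOR, scores
    if depth_stat is not None and depth_stat >= params.depth_posterior_min:
        return POSTERIOR, scores
    return FUNDAL, scores


def placenta_depth_stat(series_by_sweep: Mapping[int, DetectionSeries]) -> float | None:
    """Area-weighted mean depth centroid across all detected frames."""
    num, den = 0.0, 0.0
    for series in series_by_sweep.values():
        for i in np.flatnonzero(series.present):
            num += series.area_px[i] * series.depth_centroid[i]
            den += series.area_px[i]
    return (num / den) if den > 0 else None


def predict_exam_masks(exam, segmenter, *, out_size=DEFAULT_OUT_SIZE,
                       crop_box: CropBox | None = None, threshold: float = 0.5):
    """Segment every frame of an exam.

    Returns (masks at network resolution per sweep, masks at native frame
    resolution per sweep, native spacing lookup dict).  Trained models
    predict on the preprocessed frame and are back-projected through the
    recorded transform; a ground-truth oracle is evaluated at both
    resolutions directly.
    """
    small_masks: dict[int, np.ndarray] = {}
    native_masks: dict[int, np.ndarray] = {}
    spacing: dict[tuple[int, int], tuple[float, float]] = {}
    is_oracle = hasattr(segmenter, "truth")
    for sid, frames in exam.sweeps.items():
        smalls, natives = [], []
        for frame in frames:
            spacing[(sid, frame.frame_index)] = frame.pixel_spacing_mm
            small, transform = crop_and_resize(frame, crop_box, out_size)
            prob, binary = predict_mask(segmenter, small, threshold)
            smalls.append(binary)
            if is_oracle:
                _, native = predict_mask(segmenter, frame, threshold)
            else:
                native = backproject(prob, transform, threshold)
            natives.append(native)
        small_masks[sid] = np.stack(smalls)
        native_masks[sid] = np.stack(natives)
    return small_masks, native_masks, spacing


def diagnose_exam(exam, head_segmenter, placenta_segmenter,
                  registry: Mapping[int, SweepGeometry] | None = None,
                  params: ClassifierParams | None = None, *,
                  min_area_px: int = 30, min_run: int = 3,
                  sigma: float | None = None,
                  crop_box: CropBox | None = None,
                  out_size=DEFAULT_OUT_SIZE,
                  with_biometry: bool = True,
                  ga_formula: str | None = "hadlock1984") -> Diagnosis:
    """Full pipeline: preprocess -> segment -> detect -> maps -> classify.

    Deterministic given the exam and the segmenters.  Raises
    :class:`ExamValidationError` if the exam lacks sweeps the registry
    expects.
    """
    if registry is None:
        registry = default_registry()
    if params is None:
        params = ClassifierParams()
    missing = sorted(set(registry) - set(exam.sweeps))
    if missing:
        raise ExamValidationError(f"exam is missing sweeps {missing}")

    head_small, head_native, spacing = predict_exam_masks(
        exam, head_segmenter, out_size=out_size, crop_box=crop_box)
    plac_small, _, _ = predict_exam_masks(
        exam, placenta_segmenter, out_size=out_size, crop_box=crop_box)

    head_series = {sid: detect_series(stack, min_area_px, min_run)
                   for sid, stack in head_small.items()}
    plac_series = {sid: detect_series(stack, min_area_px, min_run)
                   for sid, stack in plac_small.items()}

    counts = exam.frame_counts
    head_map = build_likelihood_map(
        counts, {sid: s.present for sid, s in head_series.items()},
        registry, sigma=sigma, structure="head")
    plac_map = build_likelihood_map(
        counts, {sid: s.present for sid, s in plac_series.items()},
        registry, sigma=sigma, structure="placenta")

    presentation, pres_score = classify_presentation(head_map, params)
    depth_stat = placenta_depth_stat(plac_series)
    plac_label, plac_scores = classify_placenta(plac_map, depth_stat, params)

    biometry = None
    ga = None
    if with_biometry:
        try:
            biometry = measure_head(head_native, lambda s, f: spacing[(s, f)])
        except NoHeadError:
            biometry = None
        if biometry is not None and ga_formula is not None:
            ga = ga_from_biometry(biometry.bpd_mm, biometry.hc_mm,
                                  formula_id=ga_formula)

    return Diagnosis(
        presentation=presentation,
        presentation_score=pres_score,
        placenta_location=plac_label,
        placenta_depth_score=plac_scores["depth"],
        placenta_axial_score=plac_scores["axial"],
        low_placenta_flag=plac_scores["low_placenta_flag"],
        biometry=biometry,
        ga=ga,
        head_map=head_map,
        placenta_map=plac_map,
    )
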