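"""Fetal head biometry from segmentation masks.

The biparietal diameter (BPD) and head circumference (HC) are read off the
single largest head mask in the examination: an equivalent ellipse is fitted
to the mask from its second central moments, BPD is the full minor axis of
that ellipse in millimetres, and HC is the arc length of the mask's outer
contour (a sub-pixel marching-squares contour of the lightly smoothed mask;
the fitted-ellipse perimeter is available as an alternative for sensitivity
analysis).  Gestational age comes from published polynomial regressions on
BPD or HC, shipped as editable data rather than code.

All measurements accept anisotropic pixel spacing (row, col) in mm/px, as
produced by the crop/resize preprocessing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
from scipy import ndimage
from skimage import measure


class FitError(ValueError):
    """Mask too small or degenerate for an ellipse fit."""


class NoHeadError(ValueError):
    """No non-empty head mask anywhere in the examination."""


def _as_spacing(spacing) -> tuple[float, float]:
    if np.isscalar(spacing):
        spacing = (float(spacing), float(spacing))
    return float(spacing[0]), float(spacing[1])


@dataclass(frozen=True)
class EllipseFit:
    """Moment-equivalent ellipse of a binary mask (pixel units)."""

    center: tuple[float, float]
    semi_major_px: float
    semi_minor_px: float
    angle: float  # radians, major axis vs row axis

    def __post_init__(self) -> None:
        if not (self.semi_major_px >= self.semi_minor_px > 0):
            raise FitError(
                f"need semi_major >= semi_minor > 0, got "
                f"({self.semi_major_px}, {self.semi_minor_px})")


@dataclass
class BiometryResult:
    bpd_mm: float
    hc_mm: float
    source: tuple[int, int]  # (sweep_id, frame_index)
    ellipse: EllipseFit
    pixel_spacing_mm: tuple[float, float]
    multiple_components: bool = False

    def __post_init__(self) -> None:
        if self.bpd_mm <= 0:
            raise ValueError("bpd_mm must be positive")


@dataclass
class GaEstimate:
    ga_days_bpd: float
    ga_days_hc: float
    formula_id: str
    warnings: list = field(default_factory=list)


def select_largest_mask(mask_stacks: Mapping[int, np.ndarray]
                        ) -> tuple[int, int, np.ndarray]:
    """Pick the largest-area mask across all sweeps.

    Ties break toward the lowest sweep_id, then the lowest frame index.
    """
    best = None
    for sid in sorted(mask_stacks):
        stack = np.asarray(mask_stacks[sid]).astype(bool)
        areas = stack.sum(axis=(1, 2))
        fi = int(np.argmax(areas))  # argmax returns the first maximum
        if areas[fi] > 0 and (best is None or areas[fi] > best[0]):
            best = (int(areas[fi]), sid, fi, stack[fi])
    if best is None:
        raise NoHeadError("all head masks are empty")
    _, sid, fi, mask = best
    return sid, fi, mask


def fit_ellipse(mask: np.ndarray, spacing=(1.0, 1.0)) -> EllipseFit:
    """Equivalent ellipse from the second central moments of a filled mask.

    ``spacing`` scales pixel coordinates per axis, so the returned semi-axes
    are in units of spacing (pixels when spacing is 1).  A uniform filled
    ellipse with semi-axis a has coordinate variance a^2/4 along that axis,
    so semi-axes are 2*sqrt(eigenvalues of the coordinate covariance).
    """
    mask = np.asarray(mask).astype(bool)
    sr, sc = _as_spacing(spacing)
    rows, cols = np.nonzero(mask)
    if rows.size < 5:
        raise FitError(f"need >= 5 foreground pixels, got {rows.size}")
    pts = np.stack([rows * sr, cols * sc], axis=1).astype(float)
    center = pts.mean(axis=0)
    cov = np.cov(pts.T, bias=True)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 1e-12:
        raise FitError("degenerate (collinear) mask")
    semi_minor = 2.0 * math.sqrt(evals[0])
    semi_major = 2.0 * math.sqrt(evals[1])
    major_vec = evecs[:, 1]
    angle = math.atan2(major_vec[1], major_vec[0])
    if angle < 0:
        angle += math.pi
    return EllipseFit(center=(center[0], center[1]),
                      semi_major_px=semi_major, semi_minor_px=semi_minor,
                      angle=angle)


def bpd_from_fit(fit: EllipseFit, spacing: float = 1.0) -> float:
    """BPD = full minor axis: 2 x semi-minor x spacing (mm)."""
    return 2.0 * fit.semi_minor_px * float(spacing)


def ellipse_perimeter(semi_a: float, semi_b: float) -> float:
    """Ramanujan's second ellipse-perimeter approximation."""
    h = ((semi_a - semi_b) / (semi_a + semi_b)) ** 2
    return math.pi * (semi_a + semi_b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


def hc_from_mask(mask: np.ndarray, spacing=(1.0, 1.0), *,
                 method: str = "contour", smooth_sigma: float = 1.5
                 ) -> tuple[float, bool]:
    """Head circumference in mm, with a multiple-components flag.

    ``method="contour"`` (default): arc length of the marching-squares
    contour of the largest connected component, extracted at the 0.5 level
    of the Gaussian-smoothed mask (the smoothing removes the rasterization
    staircase, giving a sub-pixel boundary).  ``method="ellipse"``: the
    Ramanujan perimeter of the moment-fitted ellipse.
    """
    mask = np.asarray(mask).astype(bool)
    sr, sc = _as_spacing(spacing)
    labels, n_comp = ndimage.label(mask)
    if n_comp == 0:
        raise FitError("empty mask")
    flagged = n_comp > 1
    if flagged:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    if method == "ellipse":
        fit = fit_ellipse(mask, spacing=(sr, sc))
        return ellipse_perimeter(fit.semi_major_px, fit.semi_minor_px), flagged
    if method != "contour":
        raise ValueError(f"unknown HC method {method!r}")
    pad = int(math.ceil(3 * smooth_sigma)) + 2
    padded = np.pad(mask.astype(np.float32), pad)
    smoothed = ndimage.gaussian_filter(padded, sigma=smooth_sigma)
    contours = measure.find_contours(smoothed, 0.5)
    if not contours:
        raise FitError("mask vanished under contour smoothing")
    best_len = -1.0
    for contour in contours:
        scaled = contour * np.array([sr, sc])
        seg = np.diff(np.vstack([scaled, scaled[:1]]), axis=0)
        length = float(np.sqrt((seg ** 2).sum(axis=1)).sum())
        best_len = max(best_len, length)
    return best_len, flagged


def measure_head(mask_stacks: Mapping[int, np.ndarray],
                 spacing_lookup, *, hc_method: str = "contour") -> BiometryResult:
    """Full biometry from an exam's head mask stacks.

    ``spacing_lookup`` maps (sweep_id, frame_index) -> (row, col) spacing in
    mm/px (or is a constant tuple applied to every frame).
    """
    sid, fi, mask = select_largest_mask(mask_stacks)
    if callable(spacing_lookup):
        spacing = _as_spacing(spacing_lookup(sid, fi))
    else:
        spacing = _as_spacing(spacing_lookup)
    fit_px = fit_ellipse(mask)  # pixel-unit fit, reported for provenance
    fit_mm = fit_ellipse(mask, spacing=spacing)
    bpd = bpd_from_fit(fit_mm, 1.0)
    hc, flagged = hc_from_mask(mask, spacing, method=hc_method)
    return BiometryResult(bpd_mm=bpd, hc_mm=hc, source=(sid, fi), ellipse=fit_px,
                          pixel_spacing_mm=spacing, multiple_components=flagged)


# ---------------------------------------------------------------------------
# Gestational age
# ---------------------------------------------------------------------------

def load_formula_table(path=None) -> dict:
    """Published GA regression tables (coefficients in weeks on cm inputs)."""
    if path is not None:
        with open(path) as fh:
            return json.load(fh)
    ref = resources.files("fetalsweep").joinpath("data/ga_formulas.json")
    return json.loads(ref.read_text())


def _eval_formula(spec: dict, value_mm: float, warnings: list, name: str) -> float:
    lo, hi = spec.get("valid_range_mm", (0.0, math.inf))
    if not (lo <= value_mm <= hi):
        warnings.append(f"{name} {value_mm:.1f} mm outside validity range "
                        f"[{lo}, {hi}] mm")
    x = value_mm / 10.0 if spec.get("unit_in", "cm") == "cm" else value_mm
    weeks = sum(c * x ** p for c, p in zip(spec["coefficients"], spec["powers"]))
    return weeks * 7.0


def ga_from_biometry(bpd_mm: float, hc_mm: float,
                     formula_table: dict | None = None,
                     formula_id: str = "hadlock1984") -> GaEstimate:
    """Gestational age in days from BPD and HC via a configured regression.

    Out-of-range inputs still return an estimate but carry a warning.
    """
    if formula_table is None:
        formula_table = load_formula_table()
    spec = formula_table[formula_id]
    warnings: list = []
    ga_bpd = _eval_formula(spec["bpd"], bpd_mm, warnings, "BPD")
    ga_hc = _eval_formula(spec["hc"], hc_mm, warnings, "HC")
    return GaEstimate(ga_days_bpd=ga_bpd, ga_days_hc=ga_hc,
                      formula_id=formula_id, warnings=warnings)


def ga_within(deltas_days, window_days: float) -> float:
    """Fraction of |signed day differences| within the window."""
    deltas = np.asarray(deltas_days, dtype=float)
    if deltas.size == 0:
        raise ValueError("ga_within undefined for empty input")
    return float(np.mean(np.abs(deltas) <= window_days))
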