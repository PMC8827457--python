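"""Synthetic volume-sweep-imaging phantoms with known ground truth.

A phantom is a 3D pregnant-abdomen scene — a homogeneous mid-gray block
containing an ellipsoidal fetal head (bright skull rim, dark interior) and
a textured placental slab on the anterior wall, posterior wall, or fundus —
scanned by the eight standardized probe sweeps of the imaging protocol.
Each sweep yields an ordered stack of planar grayscale frames with
multiplicative speckle, plus per-frame binary ground-truth masks for both
structures, so every downstream stage (segmentation, likelihood mapping,
classification, biometry) can be tested without clinical scans.

Coordinates follow the shared convention (see :mod:`fetalsweep.localization`):
axial 0 = pelvis / 1 = fundus, lateral 0 = maternal right / 1 = left,
depth 0 = anterior (probe side) / 1 = posterior.  The generator's label
convention is geometric and unambiguous: cephalic phantoms place the head's
axial centre in [0.1, 0.4], non-cephalic in [0.6, 0.9].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np

from .localization import (HORIZONTAL, VERTICAL, SweepGeometry,
                           default_registry)
from .preprocess import (DEFAULT_OUT_SIZE, CropBox, Frame, TrainingSet,
                         crop_and_resize)

# Noiseless scene intensities.  Kept well below 1 so that unit-mean
# multiplicative speckle rarely clips against the [0, 1] range.
ABDOMEN_LEVEL = 0.35
RIM_LEVEL = 0.75
INTERIOR_LEVEL = 0.12
PLACENTA_LEVEL = 0.60
PLACENTA_TEXTURE_AMPLITUDE = 0.08
RIM_FRACTION = 0.80  # normalized ellipsoid radius where the skull rim starts

CEPHALIC = "cephalic"
NON_CEPHALIC = "non-cephalic"
ANTERIOR = "anterior"
POSTERIOR = "posterior"
FUNDAL = "fundal"


class PhantomConfigError(ValueError):
    """Invalid phantom configuration; the message names the offending field."""


class EmptyFrameError(ValueError):
    """Requested slice plane does not intersect the abdomen volume."""


def ellipse_perimeter_mm(semi_a: float, semi_b: float) -> float:
    """Ramanujan's second approximation to the ellipse perimeter."""
    a, b = float(semi_a), float(semi_b)
    h = ((a - b) / (a + b)) ** 2
    return math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))


@dataclass(frozen=True)
class PhantomConfig:
    """Full specification of one synthetic examination.

    ``abdomen_size_mm`` is (axial, lateral, depth) physical extents;
    ``head_center`` is in normalized abdomen coordinates; ``head_axes_mm``
    are the three ellipsoid semi-axes in (axial, lateral, depth) order.
    ``frames_per_sweep`` may be a single integer or a mapping sweep_id ->
    count; every sweep needs at least 8 frames.  ``noise_level`` is the
    variance of the unit-mean multiplicative speckle.
    """

    abdomen_size_mm: tuple[float, float, float] = (240.0, 200.0, 160.0)
    head_center: tuple[float, float, float] = (0.25, 0.5, 0.5)
    head_axes_mm: tuple[float, float, float] = (50.0, 42.0, 42.0)
    presentation_label: str = CEPHALIC
    placenta_location_label: str = ANTERIOR
    placenta_thickness_mm: float = 35.0
    pixel_spacing_mm: float = 1.0
    frames_per_sweep: int | Mapping[int, int] = 24
    noise_level: float = 0.05
    seed: int = 0

    def frames_for(self, sweep_id: int) -> int:
        if isinstance(self.frames_per_sweep, Mapping):
            return int(self.frames_per_sweep[sweep_id])
        return int(self.frames_per_sweep)

    def validate(self, registry: Mapping[int, SweepGeometry]) -> None:
        if any(e <= 0 for e in self.abdomen_size_mm):
            raise PhantomConfigError("abdomen_size_mm: extents must be strictly positive")
        if any(a <= 0 for a in self.head_axes_mm):
            raise PhantomConfigError("head_axes_mm: semi-axes must be strictly positive")
        if self.pixel_spacing_mm <= 0:
            raise PhantomConfigError("pixel_spacing_mm: must be strictly positive")
        if self.placenta_thickness_mm <= 0:
            raise PhantomConfigError("placenta_thickness_mm: must be strictly positive")
        if self.noise_level < 0:
            raise PhantomConfigError("noise_level: speckle variance must be >= 0")
        if self.presentation_label not in (CEPHALIC, NON_CEPHALIC):
            raise PhantomConfigError(
                f"presentation_label: unknown label {self.presentation_label!r}")
        if self.placenta_location_label not in (ANTERIOR, POSTERIOR, FUNDAL):
            raise PhantomConfigError(
                f"placenta_location_label: unknown label {self.placenta_location_label!r}")
        for i, name in enumerate(("axial", "lateral", "depth")):
            c = self.head_center[i] * self.abdomen_size_mm[i]
            if c - self.head_axes_mm[i] < 0 or c + self.head_axes_mm[i] > self.abdomen_size_mm[i]:
                raise PhantomConfigError(
                    f"head_center/head_axes_mm: head ellipsoid exceeds abdomen "
                    f"along the {name} axis")
        axial = self.head_center[0]
        if self.presentation_label == CEPHALIC and not axial < 0.5:
            raise PhantomConfigError(
                "presentation_label: cephalic requires head axial centre < 0.5")
        if self.presentation_label == NON_CEPHALIC and not axial >= 0.5:
            raise PhantomConfigError(
                "presentation_label: non-cephalic requires head axial centre >= 0.5")
        for sid in registry:
            if self.frames_for(sid) < 8:
                raise PhantomConfigError(
                    f"frames_per_sweep: sweep {sid} needs >= 8 frames")

    # -- derived ground-truth biometry ------------------------------------
    @property
    def true_bpd_mm(self) -> float:
        """Biparietal-diameter analogue: full second-largest ellipsoid axis."""
        return 2.0 * sorted(self.head_axes_mm)[-2]

    @property
    def true_hc_mm(self) -> float:
        """Perimeter of the maximal head cross-section ellipse."""
        a, b = sorted(self.head_axes_mm)[-2:]
        return ellipse_perimeter_mm(a, b)


@dataclass
class VsiExam:
    """One examination: ordered sweeps of frames plus acquisition metadata."""

    sweeps: dict[int, list[Frame]]
    pixel_spacing_mm: float
    exam_id: str = "phantom"
    labels: dict = field(default_factory=dict)

    @property
    def frame_counts(self) -> dict[int, int]:
        return {sid: len(frames) for sid, frames in self.sweeps.items()}


@dataclass
class PhantomTruth:
    """Ground-truth masks and labels for a generated phantom."""

    masks: dict[int, dict[str, np.ndarray]]  # sweep_id -> structure -> (n, H, W) bool
    true_presentation: str
    true_placenta_location: str
    true_bpd_mm: float
    true_hc_mm: float

    def mask_stack(self, sweep_id: int, structure: str) -> np.ndarray:
        return self.masks[sweep_id][structure]


# ---------------------------------------------------------------------------
# Scene evaluation
# ---------------------------------------------------------------------------

def _placenta_region(config: PhantomConfig, A, L, D) -> np.ndarray:
    ax_mm, lat_mm, dep_mm = config.abdomen_size_mm
    loc = config.placenta_location_label
    if loc == ANTERIOR:
        return D <= config.placenta_thickness_mm / dep_mm
    if loc == POSTERIOR:
        return D >= 1.0 - config.placenta_thickness_mm / dep_mm
    return A >= 1.0 - config.placenta_thickness_mm / ax_mm


def _evaluate_scene(config: PhantomConfig, A, L, D):
    """Noiseless intensities + masks at normalized coordinate grids A, L, D."""
    ax_mm, lat_mm, dep_mm = config.abdomen_size_mm
    ca, cl, cd = config.head_center
    sa, sl, sd = config.head_axes_mm
    rho2 = (((A - ca) * ax_mm / sa) ** 2
            + ((L - cl) * lat_mm / sl) ** 2
            + ((D - cd) * dep_mm / sd) ** 2)
    head = rho2 <= 1.0
    rim = head & (rho2 > RIM_FRACTION ** 2)
    placenta = _placenta_region(config, A, L, D) & ~head
    img = np.full(A.shape, ABDOMEN_LEVEL, dtype=np.float32)
    texture = (PLACENTA_TEXTURE_AMPLITUDE
               * np.sin(2 * np.pi * A * ax_mm / 17.0)
               * np.sin(2 * np.pi * L * lat_mm / 13.0)
               * np.sin(2 * np.pi * D * dep_mm / 11.0))
    img[placenta] = PLACENTA_LEVEL + texture[placenta]
    img[head] = INTERIOR_LEVEL
    img[rim] = RIM_LEVEL
    return img, head, placenta


def _frame_grid(config: PhantomConfig, geom: SweepGeometry, position: float):
    """Normalized (A, L, D) coordinate grids for one frame of a sweep.

    ``position`` is the probe position along the sweep direction in [0, 1].
    Rows sample the depth axis; columns sample a field-of-view window of the
    orthogonal in-plane axis centred on the sweep's band.
    """
    if not (0.0 <= position <= 1.0):
        raise EmptyFrameError(f"slice position {position} outside the abdomen")
    ax_mm, lat_mm, dep_mm = config.abdomen_size_mm
    sp = config.pixel_spacing_mm
    n_rows = max(2, int(round(dep_mm / sp)))
    half = geom.fov / 2.0
    lo = min(max(geom.band_center - half, 0.0), 1.0 - geom.fov)
    lo = max(lo, 0.0)
    hi = min(lo + geom.fov, 1.0)
    in_plane_mm = lat_mm if geom.orientation == VERTICAL else ax_mm
    n_cols = max(2, int(round((hi - lo) * in_plane_mm / sp)))
    d = (np.arange(n_rows) + 0.5) / n_rows
    w = lo + (np.arange(n_cols) + 0.5) / n_cols * (hi - lo)
    D, W = np.meshgrid(d, w, indexing="ij")
    if geom.orientation == VERTICAL:
        A = np.full_like(D, position)
        L = W
    else:
        L = np.full_like(D, position)
        A = W
    return A, L, D, (hi - lo) * in_plane_mm


def render_frame(config: PhantomConfig, geom: SweepGeometry, position: float,
                 noise_level: float | None = None,
                 rng: np.random.Generator | None = None):
    """Render one frame: (pixels, head_mask, placenta_mask).

    Intensities are in [0, 1].  Speckle is a unit-mean gamma-distributed
    multiplicative field with variance ``noise_level`` applied after the
    noiseless rasterization, so ``noise_level=0`` returns the rasterization
    exactly.
    """
    if noise_level is None:
        noise_level = config.noise_level
    A, L, D, width_mm = _frame_grid(config, geom, position)
    img, head, placenta = _evaluate_scene(config, A, L, D)
    if noise_level > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        mult = rng.gamma(shape=1.0 / noise_level, scale=noise_level, size=img.shape)
        img = np.clip(img * mult, 0.0, 1.0).astype(np.float32)
    spacing = (config.abdomen_size_mm[2] / img.shape[0], width_mm / img.shape[1])
    return img.astype(np.float32), head, placenta, spacing


def make_phantom(config: PhantomConfig,
                 registry: Mapping[int, SweepGeometry] | None = None
                 ) -> tuple[VsiExam, PhantomTruth]:
    """Generate the full eight-sweep examination and its ground truth.

    Deterministic for a fixed (config, registry): each frame's speckle is
    seeded from (config.seed, sweep_id, frame_index).
    """
    if registry is None:
        registry = default_registry()
    config.validate(registry)
    sweeps: dict[int, list[Frame]] = {}
    masks: dict[int, dict[str, np.ndarray]] = {}
    for sid in sorted(registry):
        geom = registry[sid]
        n = config.frames_for(sid)
        frames, head_stack, plac_stack = [], [], []
        for i in range(n):
            pos = i / (n - 1)
            rng = np.random.default_rng([max(config.seed, 0), sid, i])
            img, head, plac, spacing = render_frame(config, geom, pos, rng=rng)
            frames.append(Frame(img, spacing, sweep_id=sid, frame_index=i))
            head_stack.append(head)
            plac_stack.append(plac)
        sweeps[sid] = frames
        masks[sid] = {"head": np.stack(head_stack), "placenta": np.stack(plac_stack)}
    exam = VsiExam(sweeps=sweeps, pixel_spacing_mm=config.pixel_spacing_mm,
                   labels={"presentation": config.presentation_label,
                           "placenta_location": config.placenta_location_label})
    truth = PhantomTruth(masks=masks,
                         true_presentation=config.presentation_label,
                         true_placenta_location=config.placenta_location_label,
                         true_bpd_mm=config.true_bpd_mm,
                         true_hc_mm=config.true_hc_mm)
    return exam, truth


# ---------------------------------------------------------------------------
# Random configuration sampling and training-set generation
# ---------------------------------------------------------------------------

def sample_config(rng: np.random.Generator, *,
                  presentation: str | None = None,
                  placenta_location: str | None = None,
                  frames_per_sweep: int = 12,
                  noise_level: float = 0.05) -> PhantomConfig:
    """Draw a realistic third-trimester phantom configuration.

    Head semi-axes are prolate (two equal transverse axes) around a 32-week
    biometry: axial semi-axis 45-55 mm, transverse 38-44 mm.  Cephalic heads
    sit at axial centre 0.24-0.35, non-cephalic at 0.65-0.76 (the ranges
    keep the whole ellipsoid inside the abdomen at the largest sampled
    semi-axis).
    """
    if presentation is None:
        presentation = CEPHALIC if rng.random() < 0.5 else NON_CEPHALIC
    if placenta_location is None:
        placenta_location = (ANTERIOR, POSTERIOR, FUNDAL)[rng.integers(3)]
    if presentation == CEPHALIC:
        axial = rng.uniform(0.24, 0.35)
    else:
        axial = rng.uniform(0.65, 0.76)
    a_ax = rng.uniform(45.0, 55.0)
    a_tr = rng.uniform(38.0, 44.0)
    return PhantomConfig(
        head_center=(axial, rng.uniform(0.45, 0.55), rng.uniform(0.45, 0.55)),
        head_axes_mm=(a_ax, a_tr, a_tr),
        presentation_label=presentation,
        placenta_location_label=placenta_location,
        placenta_thickness_mm=rng.uniform(30.0, 40.0),
        frames_per_sweep=frames_per_sweep,
        noise_level=noise_level,
        seed=int(rng.integers(2**31 - 1)),
    )


def gen_training_set(n_patients: int,
                     config_sampler: Callable[[np.random.Generator], PhantomConfig]
                     | None = None,
                     seed: int = 0,
                     out_size: tuple[int, int] = DEFAULT_OUT_SIZE,
                     registry: Mapping[int, SweepGeometry] | None = None
                     ) -> TrainingSet:
    """Render phantoms and flatten them into a preprocessed training set.

    Frames are full-frame cropped and resized to ``out_size`` (bilinear),
    masks resized with nearest-neighbour; per-frame structure-present flags
    come from the resized masks.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if config_sampler is None:
        config_sampler = sample_config
    if registry is None:
        registry = default_registry()
    rng = np.random.default_rng(seed)
    frames, head_masks, plac_masks, patient_ids = [], [], [], []
    for pid in range(n_patients):
        config = config_sampler(rng)
        exam, truth = make_phantom(config, registry)
        for sid in sorted(exam.sweeps):
            for i, frame in enumerate(exam.sweeps[sid]):
                small, _ = crop_and_resize(frame, out_size=out_size)
                hm = _resize_mask(truth.masks[sid]["head"][i], out_size)
                pm = _resize_mask(truth.masks[sid]["placenta"][i], out_size)
                frames.append(small.pixels)
                head_masks.append(hm)
                plac_masks.append(pm)
                patient_ids.append(pid)
    head = np.stack(head_masks)
    plac = np.stack(plac_masks)
    return TrainingSet(
        frames=np.stack(frames),
        masks={"head": head, "placenta": plac},
        present={"head": head.any(axis=(1, 2)), "placenta": plac.any(axis=(1, 2))},
        patient_ids=np.asarray(patient_ids),
    )


def _resize_mask(mask: np.ndarray, out_size) -> np.ndarray:
    from skimage.transform import resize as _sk_resize
    if mask.shape == tuple(out_size):
        return mask.astype(bool)
    return _sk_resize(mask.astype(np.float32), out_size, order=0,
                      preserve_range=True, anti_aliasing=False) >= 0.5


# ---------------------------------------------------------------------------
# On-disk format: per-sweep multipage TIFF + PNG masks + JSON sidecar
# ---------------------------------------------------------------------------

def write_exam(exam: VsiExam, truth: PhantomTruth | None, outdir) -> None:
    """Write an exam as per-sweep multipage TIFFs, PNG masks, JSON sidecar."""
    import imageio.v3 as iio
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sidecar = {"exam_id": exam.exam_id, "labels": exam.labels, "sweeps": []}
    for sid in sorted(exam.sweeps):
        frames = exam.sweeps[sid]
        stack = np.stack([f.pixels for f in frames])
        tifffile.imwrite(outdir / f"sweep_{sid:02d}.tif",
                         (stack * 255).astype(np.uint8))
        sidecar["sweeps"].append({
            "sweep_id": sid,
            "n_frames": len(frames),
            "pixel_spacing_mm": list(frames[0].pixel_spacing_mm),
        })
        if truth is not None:
            for structure in ("head", "placenta"):
                mdir = outdir / f"masks_{structure}"
                mdir.mkdir(exist_ok=True)
                for i, m in enumerate(truth.masks[sid][structure]):
                    iio.imwrite(mdir / f"sweep_{sid:02d}_frame_{i:03d}.png",
                                (m.astype(np.uint8) * 255))
    if truth is not None:
        sidecar["truth"] = {
            "presentation": truth.true_presentation,
            "placenta_location": truth.true_placenta_location,
            "bpd_mm": truth.true_bpd_mm,
            "hc_mm": truth.true_hc_mm,
        }
    with open(outdir / "exam.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_exam(path) -> VsiExam:
    """Read an exam previously written by :func:`write_exam`."""
    import tifffile

    path = Path(path)
    with open(path / "exam.json") as fh:
        sidecar = json.load(fh)
    sweeps: dict[int, list[Frame]] = {}
    for rec in sidecar["sweeps"]:
        sid = rec["sweep_id"]
        stack = tifffile.imread(path / f"sweep_{sid:02d}.tif").astype(np.float32) / 255.0
        spacing = tuple(rec["pixel_spacing_mm"])
        sweeps[sid] = [Frame(stack[i], spacing, sweep_id=sid, frame_index=i)
                       for i in range(stack.shape[0])]
    return VsiExam(sweeps=sweeps,
                   pixel_spacing_mm=sidecar["sweeps"][0]["pixel_spacing_mm"][0],
                   exam_id=sidecar.get("exam_id", "exam"),
                   labels=sidecar.get("labels", {}))
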