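"""Spatial-location likelihood maps from per-sweep detections.

The scanning protocol covers the pregnant abdomen with eight standardized
probe sweeps: vertical sweeps run from the maternal pelvis toward the fundus
at fixed lateral stations, horizontal sweeps run from the maternal right
flank to the left flank at fixed axial stations.  Every frame in which a
structure (fetal head or placenta) is detected casts a vote into a 2D
accumulation matrix over normalized abdomen coordinates (rows = axial,
pelvis -> fundus; columns = lateral, right -> left).  Where sweeps overlap,
votes add up, so the matrix becomes a likelihood map of where the structure
sits in the abdomen.  A Gaussian blur turns the blocky vote matrix into a
smooth heatmap; the classifier downstream reads centroids off it.

All modules share one normalized coordinate frame:

* axial   0 = pelvis,   1 = fundus
* lateral 0 = maternal right, 1 = maternal left
* depth   0 = anterior (probe side), 1 = posterior
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

VERTICAL = "vertical"
HORIZONTAL = "horizontal"

#: Default blur width as a fraction of the larger map dimension.
DEFAULT_SIGMA_FRACTION = 0.03


class GeometryError(ValueError):
    """Raised when a sweep registry cannot support map construction."""


@dataclass(frozen=True)
class SweepGeometry:
    """Geometry of one standardized probe sweep.

    Parameters
    ----------
    sweep_id:
        Identifier, 1-based in the clinical protocol.
    orientation:
        ``"vertical"`` (frames ordered along the axial axis) or
        ``"horizontal"`` (frames ordered along the lateral axis).
    band:
        Normalized interval on the axis orthogonal to the sweep direction
        that the probe path covers (lateral interval for vertical sweeps,
        axial interval for horizontal ones).
    direction:
        Human-readable start -> end landmark description.
    fov:
        Fraction of the orthogonal axis imaged by each frame.  Frames see a
        window centred on the band centre that is wider than the band
        itself, as a real convex-probe frame does; only the band is painted
        into the likelihood map.
    """

    sweep_id: int
    orientation: str
    band: tuple[float, float]
    direction: str = ""
    fov: float = 0.6

    def __post_init__(self) -> None:
        if self.orientation not in (VERTICAL, HORIZONTAL):
            raise GeometryError(f"unknown orientation {self.orientation!r}")
        lo, hi = self.band
        if not (0.0 <= lo < hi <= 1.0):
            raise GeometryError(f"band {self.band} not a non-empty subinterval of [0, 1]")
        if not (0.0 < self.fov <= 1.0):
            raise GeometryError(f"fov {self.fov} outside (0, 1]")

    @property
    def band_center(self) -> float:
        return 0.5 * (self.band[0] + self.band[1])


def default_registry(fov: float = 0.6) -> dict[int, SweepGeometry]:
    """Eight-sweep registry: four vertical stations then four horizontal.

    The clinical protocol fixes the sweep anatomy on a poster; here the
    stations are spread evenly (band centres 0.2/0.4/0.6/0.8, band width
    0.25) and kept configurable so a measured protocol can be substituted
    via :func:`load_registry`.
    """
    centers = (0.2, 0.4, 0.6, 0.8)
    half = 0.125
    registry: dict[int, SweepGeometry] = {}
    for i, c in enumerate(centers):
        registry[i + 1] = SweepGeometry(
            sweep_id=i + 1,
            orientation=VERTICAL,
            band=(max(0.0, c - half), min(1.0, c + half)),
            direction="pelvis to fundus",
            fov=fov,
        )
    for i, c in enumerate(centers):
        registry[i + 5] = SweepGeometry(
            sweep_id=i + 5,
            orientation=HORIZONTAL,
            band=(max(0.0, c - half), min(1.0, c + half)),
            direction="maternal right to left flank",
            fov=fov,
        )
    return registry


def load_registry(path) -> dict[int, SweepGeometry]:
    """Read a sweep registry from a JSON file (list of geometry records)."""
    with open(path) as fh:
        records = json.load(fh)
    registry = {}
    for rec in records:
        geom = SweepGeometry(
            sweep_id=int(rec["sweep_id"]),
            orientation=rec["orientation"],
            band=tuple(rec["band"]),
            direction=rec.get("direction", ""),
            fov=rec.get("fov", 0.6),
        )
        registry[geom.sweep_id] = geom
    _check_registry(registry)
    return registry


def save_registry(registry: Mapping[int, SweepGeometry], path) -> None:
    records = [
        {
            "sweep_id": g.sweep_id,
            "orientation": g.orientation,
            "band": list(g.band),
            "direction": g.direction,
            "fov": g.fov,
        }
        for g in registry.values()
    ]
    with open(path, "w") as fh:
        json.dump(records, fh, indent=2)


def _check_registry(registry: Mapping[int, SweepGeometry]) -> None:
    orientations = {g.orientation for g in registry.values()}
    if VERTICAL not in orientations or HORIZONTAL not in orientations:
        raise GeometryError("registry needs at least one vertical and one horizontal sweep")


@dataclass
class LikelihoodMap:
    """2D non-negative accumulation matrix over the normalized abdomen.

    Rows sample the axial axis (0 = pelvis at row 0), columns the lateral
    axis.  Before smoothing every entry is the integer number of sweeps
    voting for that cell.
    """

    values: np.ndarray
    structure: str = ""
    axial_axis: np.ndarray = field(default=None)  # type: ignore[assignment]
    lateral_axis: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("likelihood map must be 2D")
        if (self.values < 0).any():
            raise ValueError("likelihood map values must be non-negative")
        n_r, n_c = self.values.shape
        if self.axial_axis is None:
            self.axial_axis = _axis_coords(n_r)
        if self.lateral_axis is None:
            self.lateral_axis = _axis_coords(n_c)

    @property
    def total_mass(self) -> float:
        return float(self.values.sum())

    def centroid(self) -> tuple[float, float]:
        """Mass-weighted (axial, lateral) centroid in normalized coords.

        Raises ``ValueError`` on an all-zero map.
        """
        mass = self.values.sum()
        if mass <= 0:
            raise ValueError("centroid undefined for an all-zero map")
        axial = float((self.values.sum(axis=1) * self.axial_axis).sum() / mass)
        lateral = float((self.values.sum(axis=0) * self.lateral_axis).sum() / mass)
        return axial, lateral


def _axis_coords(n: int) -> np.ndarray:
    """Normalized [0, 1] sample positions for n cells (cell centres of a unit axis)."""
    if n == 1:
        return np.array([0.5])
    return np.arange(n) / (n - 1)


def _sweep_lengths(frame_counts: Mapping[int, int], registry: Mapping[int, SweepGeometry]):
    vertical = [n for sid, n in frame_counts.items() if registry[sid].orientation == VERTICAL]
    horizontal = [n for sid, n in frame_counts.items() if registry[sid].orientation == HORIZONTAL]
    return vertical, horizontal


def init_map(frame_counts: Mapping[int, int], registry: Mapping[int, SweepGeometry],
             structure: str = "") -> LikelihoodMap:
    """All-zero matrix sized by the largest vertical and horizontal sweeps.

    ``frame_counts`` maps sweep_id -> number of frames.  Rows = largest
    vertical sweep length (axial samples), columns = largest horizontal
    sweep length (lateral samples).
    """
    missing = set(frame_counts) - set(registry)
    if missing:
        raise GeometryError(f"registry does not cover sweeps {sorted(missing)}")
    vertical, horizontal = _sweep_lengths(frame_counts, registry)
    if not vertical or not horizontal:
        raise GeometryError("need at least one vertical and one horizontal sweep")
    shape = (max(vertical), max(horizontal))
    return LikelihoodMap(np.zeros(shape), structure=structure)


def rescale_detections(present: Sequence[bool], target_len: int) -> np.ndarray:
    """Nearest-index resampling of a present/absent vector to ``target_len``.

    Up-scaling only: output cell j copies input cell floor(j * len / target).
    Identity when lengths match.
    """
    present = np.asarray(present, dtype=bool)
    n = present.shape[0]
    if n < 1:
        raise ValueError("empty detection series")
    if target_len < n:
        raise ValueError(f"cannot down-scale detections from {n} to {target_len}")
    if target_len == n:
        return present.copy()
    src = (np.arange(target_len) * n) // target_len
    return present[src]


def _band_slice(band: tuple[float, float], n: int) -> slice:
    lo = int(np.floor(band[0] * n))
    hi = int(np.ceil(band[1] * n))
    return slice(max(lo, 0), min(max(hi, lo + 1), n))


def accumulate_sweep(map_: LikelihoodMap, geometry: SweepGeometry,
                     detections: Sequence[bool]) -> LikelihoodMap:
    """Add one sweep's detection votes to the map, in place.

    A vertical sweep paints detected frame positions as rows within its
    lateral band; a horizontal sweep paints columns within its axial band.
    ``detections`` must already be rescaled to the matching map dimension.
    """
    det = np.asarray(detections, dtype=bool)
    n_rows, n_cols = map_.values.shape
    if geometry.orientation == VERTICAL:
        if det.shape[0] != n_rows:
            raise ValueError(
                f"vertical sweep detections length {det.shape[0]} != map rows {n_rows}")
        cols = _band_slice(geometry.band, n_cols)
        map_.values[det, cols] += 1.0
    else:
        if det.shape[0] != n_cols:
            raise ValueError(
                f"horizontal sweep detections length {det.shape[0]} != map cols {n_cols}")
        rows = _band_slice(geometry.band, n_rows)
        map_.values[rows, det] += 1.0
    return map_


def smooth_map(map_: LikelihoodMap, sigma: float) -> LikelihoodMap:
    """Gaussian blur with reflective boundary; sigma = 0 is the identity.

    The reflective boundary together with the symmetric normalized kernel
    preserves total mass exactly.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        values = map_.values.copy()
    else:
        values = gaussian_filter(map_.values, sigma=sigma, mode="reflect")
    return LikelihoodMap(values, structure=map_.structure,
                         axial_axis=map_.axial_axis.copy(),
                         lateral_axis=map_.lateral_axis.copy())


def build_likelihood_map(frame_counts: Mapping[int, int],
                         detections_by_sweep: Mapping[int, Sequence[bool]],
                         registry: Mapping[int, SweepGeometry],
                         sigma: float | None = None,
                         structure: str = "") -> LikelihoodMap:
    """Full pipeline: init -> rescale each sweep -> accumulate -> smooth.

    ``sigma=None`` uses the default fraction of the larger map dimension;
    pass ``sigma=0`` for the raw vote matrix.
    """
    map_ = init_map(frame_counts, registry, structure=structure)
    n_rows, n_cols = map_.values.shape
    for sid, series in detections_by_sweep.items():
        geom = registry[sid]
        target = n_rows if geom.orientation == VERTICAL else n_cols
        det = rescale_detections(series, target)
        accumulate_sweep(map_, geom, det)
    if sigma is None:
        sigma = DEFAULT_SIGMA_FRACTION * max(n_rows, n_cols)
    return smooth_map(map_, sigma)
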