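"""Frame preparation: grayscale, crop, resize, class rebalancing, augmentation.

Raw sweep cine frames arrive as RGB screen grabs with device set-up text
around the fan; training and inference use 128x128 grayscale crops.  The
physical pixel spacing is carried (per axis, since resizing a non-square
crop makes it anisotropic) so biometric measurements stay in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

#: Network input size used throughout the pipeline.
DEFAULT_OUT_SIZE = (128, 128)

#: ITU-R BT.601 luminance weights for RGB -> grayscale.
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)


class FormatError(ValueError):
    pass


def _as_spacing(value) -> tuple[float, float]:
    if np.isscalar(value):
        value = (float(value), float(value))
    row, col = float(value[0]), float(value[1])
    if row <= 0 or col <= 0:
        raise ValueError(f"pixel spacing must be positive, got {(row, col)}")
    return (row, col)


@dataclass
class Frame:
    """One 2D grayscale ultrasound frame with physical pixel spacing.

    ``pixel_spacing_mm`` is (row, col) mm per pixel; a scalar is accepted
    and broadcast to both axes.
    """

    pixels: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    sweep_id: int = 0
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise FormatError(f"frame pixels must be 2D, got shape {self.pixels.shape}")
        self.pixel_spacing_mm = _as_spacing(self.pixel_spacing_mm)
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class CropBox:
    """Half-open pixel crop window (top, left, height, width), 0-based."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("crop box height and width must be positive")
        if self.top < 0 or self.left < 0:
            raise ValueError("crop box origin must be non-negative")

    def check_within(self, shape: tuple[int, int]) -> None:
        if self.top + self.height > shape[0] or self.left + self.width > shape[1]:
            raise ValueError(f"crop box {self} exceeds frame shape {shape}")

    @classmethod
    def full(cls, shape: tuple[int, int]) -> "CropBox":
        return cls(0, 0, shape[0], shape[1])


@dataclass(frozen=True)
class FrameTransform:
    """Record of the crop/resize applied to a frame, for back-projection."""

    crop: CropBox
    in_shape: tuple[int, int]
    out_size: tuple[int, int]
    in_spacing: tuple[float, float]

    @property
    def out_spacing(self) -> tuple[float, float]:
        return (
            self.in_spacing[0] * self.crop.height / self.out_size[0],
            self.in_spacing[1] * self.crop.width / self.out_size[1],
        )


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """RGB (H, W, 3) -> luminance (H, W); single-channel input passes through."""
    pixels = np.asarray(pixels, dtype=np.float32)
    if pixels.ndim == 2:
        return pixels
    if pixels.ndim == 3 and pixels.shape[2] == 1:
        return pixels[:, :, 0]
    if pixels.ndim == 3 and pixels.shape[2] == 3:
        w = np.asarray(LUMINANCE_WEIGHTS, dtype=np.float32)
        return pixels @ w
    raise FormatError(f"expected 1 or 3 channels, got shape {pixels.shape}")


def crop_and_resize(frame: Frame, crop_box: CropBox | None = None,
                    out_size: tuple[int, int] = DEFAULT_OUT_SIZE,
                    *, is_mask: bool = False) -> tuple[Frame, FrameTransform]:
    """Crop a frame and resize to the network input size.

    Frames are interpolated bilinearly (with anti-aliasing when shrinking);
    masks use nearest-neighbour so they stay binary.  Pixel spacing is
    rescaled per axis so that physical extent is preserved exactly:
    ``out_size * new_spacing == crop extent * old_spacing``.
    """
    if out_size[0] <= 0 or out_size[1] <= 0:
        raise ValueError("out_size must be positive")
    if crop_box is None:
        crop_box = CropBox.full(frame.shape)
    crop_box.check_within(frame.shape)
    window = frame.pixels[crop_box.top:crop_box.top + crop_box.height,
                          crop_box.left:crop_box.left + crop_box.width]
    if window.shape == tuple(out_size):
        out = window.astype(np.float32).copy()
    elif is_mask:
        out = _sk_resize(window, out_size, order=0, preserve_range=True,
                         anti_aliasing=False).astype(np.float32)
    else:
        shrink = out_size[0] < window.shape[0] or out_size[1] < window.shape[1]
        out = _sk_resize(window, out_size, order=1, preserve_range=True,
                         anti_aliasing=shrink).astype(np.float32)
    transform = FrameTransform(crop=crop_box, in_shape=frame.shape,
                               out_size=tuple(out_size),
                               in_spacing=frame.pixel_spacing_mm)
    new = Frame(out, transform.out_spacing, sweep_id=frame.sweep_id,
                frame_index=frame.frame_index)
    return new, transform


def backproject(prob_map: np.ndarray, transform: FrameTransform,
                threshold: float = 0.5) -> np.ndarray:
    """Map a network-resolution probability map back to original frame pixels.

    The probability map is bilinearly interpolated up to the crop window
    (recovering sub-pixel boundary position), thresholded, and pasted into
    a full-frame boolean canvas.
    """
    prob = np.asarray(prob_map, dtype=np.float32)
    if prob.shape != transform.out_size:
        raise ValueError(f"probability map shape {prob.shape} != {transform.out_size}")
    crop = transform.crop
    up = _sk_resize(prob, (crop.height, crop.width), order=1,
                    preserve_range=True, anti_aliasing=False)
    canvas = np.zeros(transform.in_shape, dtype=bool)
    canvas[crop.top:crop.top + crop.height,
           crop.left:crop.left + crop.width] = up >= threshold
    return canvas


# ---------------------------------------------------------------------------
# Training-set container and class rebalancing
# ---------------------------------------------------------------------------

@dataclass
class TrainingSet:
    """Preprocessed frames with aligned masks and structure-present flags."""

    frames: np.ndarray                  # (N, H, W) float32 in [0, 1]
    masks: dict                         # structure -> (N, H, W) bool
    present: dict                       # structure -> (N,) bool
    patient_ids: np.ndarray             # (N,) int
    warning: str | None = None

    def __len__(self) -> int:
        return self.frames.shape[0]

    def class_ratio(self, structure: str) -> float:
        """Fraction of frames containing the structure."""
        flags = self.present[structure]
        return float(flags.mean()) if flags.size else 0.0

    def subset(self, idx: np.ndarray) -> "TrainingSet":
        return TrainingSet(
            frames=self.frames[idx],
            masks={k: v[idx] for k, v in self.masks.items()},
            present={k: v[idx] for k, v in self.present.items()},
            patient_ids=self.patient_ids[idx],
        )


def rebalance_frames(dataset: TrainingSet, structure: str,
                     target_ratio: tuple[int, int] = (1, 2),
                     seed: int = 0) -> TrainingSet:
    """Randomly drop structure-absent frames toward a positives:negatives ratio.

    The cine clips contain roughly ten background frames per head frame; the
    training recipe deletes background frames to 1:2 for the head and 1:1
    for the placenta.  Structure-present frames are never removed.  If fewer
    negatives exist than the target asks for, everything is kept and a
    warning is recorded on the returned set.
    """
    pos_part, neg_part = target_ratio
    if pos_part <= 0 or neg_part < 0:
        raise ValueError("target_ratio parts must be positive")
    flags = dataset.present[structure]
    pos_idx = np.flatnonzero(flags)
    neg_idx = np.flatnonzero(~flags)
    n_neg_target = int(round(len(pos_idx) * neg_part / pos_part))
    warning = None
    if n_neg_target >= len(neg_idx):
        keep_neg = neg_idx
        if n_neg_target > len(neg_idx):
            warning = (f"target ratio {pos_part}:{neg_part} needs {n_neg_target} "
                       f"negatives but only {len(neg_idx)} available; kept all")
    else:
        rng = np.random.default_rng(seed)
        keep_neg = rng.choice(neg_idx, size=n_neg_target, replace=False)
    keep = np.sort(np.concatenate([pos_idx, keep_neg]))
    out = dataset.subset(keep)
    out.warning = warning
    return out


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

_AUGMENT_OPS = ("brightness", "reflect_lr", "blur", "contrast")


def augment(frame: np.ndarray, mask: np.ndarray,
            ops: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Apply intensity/geometry augmentations to a frame and its mask.

    ``ops`` is a sequence of op names or ``(name, parameter)`` pairs drawn
    from brightness (additive delta), reflect_lr (left-right mirror), blur
    (Gaussian sigma), contrast (gain about the mean).  Only ``reflect_lr``
    is geometric, so it is the only op that touches the mask.  Rotation is
    deliberately not offered: the convex-probe fan has a fixed orientation.
    """
    from scipy.ndimage import gaussian_filter

    frame = np.asarray(frame, dtype=np.float32).copy()
    mask = np.asarray(mask).copy()
    defaults = {"brightness": 0.1, "blur": 1.0, "contrast": 1.2}
    for op in ops:
        if isinstance(op, str):
            name, param = op, defaults.get(op)
        else:
            name, param = op
        if name not in _AUGMENT_OPS:
            raise ValueError(f"unknown augmentation op {name!r}; "
                             f"choose from {_AUGMENT_OPS}")
        if name == "brightness":
            frame = np.clip(frame + float(param), 0.0, 1.0)
        elif name == "reflect_lr":
            frame = frame[:, ::-1].copy()
            mask = mask[:, ::-1].copy()
        elif name == "blur":
            if param > 0:
                frame = gaussian_filter(frame, sigma=float(param))
        elif name == "contrast":
            m = frame.mean()
            frame = np.clip((frame - m) * float(param) + m, 0.0, 1.0)
    return frame, mask
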