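"""Per-frame binary segmentation of fetal head and placenta.

The segmenter is the classic U-shaped encoder–decoder: a contracting path
(two 3x3 convolutions per level, each followed by batch normalization and
ReLU, then 2x2 max-pooling, filter count doubling per level), a two-
convolution bottleneck, an expansive path (2x upsampling followed by a 2x2
up-convolution that halves the filters, concatenation with the matching
encoder feature map, then two 3x3 convolutions), and a final 1x1 sigmoid
output convolution.  At the default depth of 4 the network has exactly 23
convolutional layers.  Weights use He initialization; training minimizes
binary cross-entropy with Adam while Dice and Jaccard monitor convergence.

One model is trained per structure (head and placenta get different epoch
budgets).  A ground-truth oracle segmenter satisfies the same prediction
contract so the downstream pipeline can be exercised without training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .preprocess import Frame, TrainingSet

DEFAULT_EPOCHS = {"head": 20, "placenta": 40}


class ConfigurationError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


class DivergenceError(TrainingError):
    def __init__(self, epoch: int):
        super().__init__(f"loss became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class UNetConfig:
    """Architecture and training hyper-parameters.

    ``depth`` is the number of down-sampling levels; ``input_size`` must be
    divisible by ``2**depth``.  Defaults follow the training recipe: 128x128
    inputs, batches of 16, 20 epochs for the head and 40 for the placenta.
    """

    input_size: tuple[int, int] = (128, 128)
    depth: int = 4
    base_filters: int = 64
    batch_size: int = 16
    epochs: int = 20
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.input_size
        if h % (2 ** self.depth) or w % (2 ** self.depth):
            raise ConfigurationError(
                f"input_size {self.input_size} not divisible by 2^depth = {2 ** self.depth}")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.base_filters < 1:
            raise ConfigurationError("base_filters must be >= 1")


class _ConvBlock:
    """(3x3 conv -> BN -> ReLU) twice."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.layers = [nn.Conv2D(c_in, c_out, 3, rng), nn.BatchNorm2D(c_out), nn.ReLU(),
                       nn.Conv2D(c_out, c_out, 3, rng), nn.BatchNorm2D(c_out), nn.ReLU()]

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, d):
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d


class _UpBlock:
    """2x nearest upsampling then a 2x2 up-convolution halving the filters."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.layers = [nn.UpsampleNearest2x(), nn.Conv2D(c_in, c_out, 2, rng),
                       nn.BatchNorm2D(c_out), nn.ReLU()]

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x, train):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, d):
        for layer in reversed(self.layers):
            d = layer.backward(d)
        return d


class UNet:
    """Encoder–decoder with skip connections; see module docstring."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f, depth = config.base_filters, config.depth
        self.down = []
        c_in = 1
        for d in range(depth):
            self.down.append(_ConvBlock(c_in, f * 2 ** d, rng))
            c_in = f * 2 ** d
        self.pools = [nn.MaxPool2x2() for _ in range(depth)]
        self.bottleneck = _ConvBlock(c_in, f * 2 ** depth, rng)
        self.ups, self.decoders = [], []
        for d in reversed(range(depth)):
            c_hi = f * 2 ** (d + 1)
            c_lo = f * 2 ** d
            self.ups.append(_UpBlock(c_hi, c_lo, rng))
            self.decoders.append(_ConvBlock(2 * c_lo, c_lo, rng))
        self.final = nn.Conv2D(f, 1, 1, rng)

    # -- introspection ----------------------------------------------------
    def conv_layers(self) -> list[nn.Conv2D]:
        """Enumerate every convolutional layer in forward order."""
        convs = []
        for block in self.down:
            convs += [l for l in block.layers if isinstance(l, nn.Conv2D)]
        convs += [l for l in self.bottleneck.layers if isinstance(l, nn.Conv2D)]
        for up, dec in zip(self.ups, self.decoders):
            convs += [l for l in up.layers if isinstance(l, nn.Conv2D)]
            convs += [l for l in dec.layers if isinstance(l, nn.Conv2D)]
        convs.append(self.final)
        return convs

    @property
    def conv_layer_count(self) -> int:
        return len(self.conv_layers())

    @property
    def params(self):
        out = []
        for block in self.down:
            out += block.params
        out += self.bottleneck.params
        for up, dec in zip(self.ups, self.decoders):
            out += up.params + dec.params
        out += self.final.params
        return out

    def batchnorms(self) -> list[nn.BatchNorm2D]:
        bns = []
        for block in self.down:
            bns += [l for l in block.layers if isinstance(l, nn.BatchNorm2D)]
        bns += [l for l in self.bottleneck.layers if isinstance(l, nn.BatchNorm2D)]
        for up, dec in zip(self.ups, self.decoders):
            bns += [l for l in up.layers if isinstance(l, nn.BatchNorm2D)]
            bns += [l for l in dec.layers if isinstance(l, nn.BatchNorm2D)]
        return bns

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, 1, H, W) -> sigmoid probabilities (N, 1, H, W)."""
        skips = []
        h = x.astype(np.float32)
        for block, pool in zip(self.down, self.pools):
            h = block.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.decoders, reversed(skips)):
            h = up.forward(h, train)
            self._skip_channels.append(skip.shape[1])
            h = dec.forward(np.concatenate([skip, h], axis=1), train)
        z = self.final.forward(h, train)
        return nn.sigmoid(z)

    def backward(self, dlogit: np.ndarray) -> None:
        d = self.final.backward(dlogit)
        dskips = []
        for dec, up, c_skip in zip(reversed(self.decoders), reversed(self.ups),
                                   reversed(self._skip_channels)):
            dcat = dec.backward(d)
            dskips.append(dcat[:, :c_skip])
            d = up.backward(dcat[:, c_skip:])
        d = self.bottleneck.backward(d)
        # dskips[0] pairs with the shallowest level; reverse to walk the
        # contracting path from deepest to shallowest
        for block, pool, dskip in zip(reversed(self.down), reversed(self.pools),
                                      reversed(dskips)):
            d = pool.backward(d) + dskip
            d = block.backward(d)


@dataclass
class SegModel:
    """A (possibly trained) segmenter: network, config, training history."""

    net: UNet
    config: UNetConfig
    structure: str = ""
    history: dict = field(default_factory=dict)

    def predict_proba(self, frames: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """(N, H, W) frames -> (N, H, W) probabilities in [0, 1]."""
        frames = np.asarray(frames, dtype=np.float32)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.shape[1:] != tuple(self.config.input_size):
            raise ValueError(f"frames shape {frames.shape[1:]} != "
                             f"input_size {self.config.input_size}")
        out = np.empty_like(frames)
        for start in range(0, frames.shape[0], batch_size):
            batch = frames[start:start + batch_size, None]
            out[start:start + batch.shape[0]] = self.net.forward(batch, train=False)[:, 0]
        return out

    def predict_frame(self, frame: Frame) -> np.ndarray:
        return self.predict_proba(frame.pixels[None])[0]

    @property
    def conv_layer_count(self) -> int:
        return self.net.conv_layer_count


def build_unet(config: UNetConfig, structure: str = "") -> SegModel:
    """Construct an untrained segmenter for the given configuration."""
    return SegModel(net=UNet(config), config=config, structure=structure)


# ---------------------------------------------------------------------------
# Overlap coefficients
# ---------------------------------------------------------------------------

def dice_coefficient(pred: np.ndarray, truth: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    denom = pred.sum() + truth.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, truth).sum() / denom)


def jaccard_index(pred: np.ndarray, truth: np.ndarray) -> float:
    """|A∩B| / |A∪B|; 1.0 when both masks are empty."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    union = np.logical_or(pred, truth).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pred, truth).sum() / union)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_val_split(present: np.ndarray, seed: int,
                    val_fraction: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    """Seeded 80/20 split of structure-present frame indices.

    Structure-absent frames all stay in the training pool as background;
    validation uses held-out structure-present frames only.
    """
    pos = np.flatnonzero(present)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(pos)
    n_val = int(round(val_fraction * len(pos)))
    val_idx = np.sort(perm[:n_val])
    train_idx = np.sort(np.concatenate([perm[n_val:], np.flatnonzero(~present)]))
    return train_idx, val_idx


def train_segmenter(dataset: TrainingSet, config: UNetConfig,
                    structure: str) -> SegModel:
    """Train one structure's segmenter and return it with its history.

    Frames are shuffled each epoch with a seeded generator; the history
    records per-epoch training loss/Dice/Jaccard and validation
    Dice/Jaccard (thresholded at 0.5).
    """
    frames = np.asarray(dataset.frames, dtype=np.float32)
    masks = np.asarray(dataset.masks[structure], dtype=np.float32)
    if frames.shape[0] == 0:
        raise TrainingError("empty dataset")
    if frames.shape[1:] != tuple(config.input_size):
        raise TrainingError(f"frames shape {frames.shape[1:]} != "
                            f"input_size {config.input_size}")
    present = np.asarray(dataset.present[structure], dtype=bool)
    warning = None
    if not present.any():
        # Degenerate all-background dataset: train on everything; the
        # constant-zero target is learnable, validation tracks the training
        # pool instead of held-out positives.
        warning = "no structure-present frames; validating on training frames"
        train_idx = np.arange(frames.shape[0])
        val_idx = train_idx
    else:
        train_idx, val_idx = train_val_split(present, seed=config.seed)

    model = build_unet(config, structure=structure)
    optimizer = nn.Adam(model.net.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    history = {"epoch": [], "train_loss": [], "train_dice": [], "train_jaccard": [],
               "val_dice": [], "val_jaccard": []}
    if warning:
        history["warning"] = warning

    for epoch in range(config.epochs):
        order = rng.permutation(train_idx)
        losses, dices, jaccards = [], [], []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            x = frames[idx][:, None]
            y = masks[idx][:, None]
            prob = model.net.forward(x, train=True)
            loss, dlogit = nn.bce_loss_and_grad(prob, y)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            optimizer.zero_grad()
            model.net.backward(dlogit)
            optimizer.step()
            losses.append(loss)
            pred = prob >= 0.5
            dices.append(np.mean([dice_coefficient(pred[i, 0], y[i, 0] > 0.5)
                                  for i in range(len(idx))]))
            jaccards.append(np.mean([jaccard_index(pred[i, 0], y[i, 0] > 0.5)
                                     for i in range(len(idx))]))
        val_d, val_j = _evaluate_split(model, frames, masks, val_idx)
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["train_dice"].append(float(np.mean(dices)))
        history["train_jaccard"].append(float(np.mean(jaccards)))
        history["val_dice"].append(val_d)
        history["val_jaccard"].append(val_j)
    model.history = history
    return model


def _evaluate_split(model: SegModel, frames, masks, idx) -> tuple[float, float]:
    if len(idx) == 0:
        return float("nan"), float("nan")
    prob = model.predict_proba(frames[idx])
    pred = prob >= 0.5
    d = np.mean([dice_coefficient(pred[i], masks[idx[i]] > 0.5) for i in range(len(idx))])
    j = np.mean([jaccard_index(pred[i], masks[idx[i]] > 0.5) for i in range(len(idx))])
    return float(d), float(j)


# ---------------------------------------------------------------------------
# Prediction and the oracle segmenter
# ---------------------------------------------------------------------------

def predict_mask(model, frame: Frame, threshold: float = 0.5
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Probability map and thresholded binary mask for one frame.

    ``model`` is anything with a ``predict_frame(frame)`` method returning a
    probability map the shape of the frame (a trained :class:`SegModel` or
    a ground-truth :class:`OracleSegmenter`).
    """
    prob = np.asarray(model.predict_frame(frame), dtype=np.float32)
    if prob.shape != frame.pixels.shape:
        raise ValueError(f"prediction shape {prob.shape} != frame {frame.pixels.shape}")
    return prob, prob >= threshold


class OracleSegmenter:
    """Ground-truth-backed segmenter satisfying the prediction contract.

    Bound to one phantom's truth masks; returns the exact mask for the
    frame's (sweep_id, frame_index), resampled (nearest) if the frame has
    been resized.  Used to test the pipeline downstream of segmentation in
    isolation from training quality.
    """

    def __init__(self, truth, structure: str):
        self.truth = truth
        self.structure = structure

    def predict_frame(self, frame: Frame) -> np.ndarray:
        mask = self.truth.masks[frame.sweep_id][self.structure][frame.frame_index]
        if mask.shape != frame.pixels.shape:
            from .phantom import _resize_mask
            mask = _resize_mask(mask, frame.pixels.shape)
        return mask.astype(np.float32)


# ---------------------------------------------------------------------------
# Detection series and evaluation metrics
# ---------------------------------------------------------------------------

@dataclass
class DetectionSeries:
    """Frame-by-frame structure detection along one sweep.

    ``depth_centroid`` is the mask's mean row position normalized to [0, 1]
    within the frame (0 = near field / anterior), NaN where absent.
    """

    present: np.ndarray
    area_px: np.ndarray
    depth_centroid: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.present) == len(self.area_px) == len(self.depth_centroid)):
            raise ValueError("detection series fields must have equal length")

    def __len__(self) -> int:
        return len(self.present)


def _clear_short_runs(present: np.ndarray, min_run: int) -> np.ndarray:
    if min_run <= 1:
        return present
    out = present.copy()
    n = len(out)
    i = 0
    while i < n:
        if out[i]:
            j = i
            while j < n and out[j]:
                j += 1
            if j - i < min_run:
                out[i:j] = False
            i = j
        else:
            i += 1
    return out


def detect_series(mask_stack: np.ndarray, min_area_px: int = 30,
                  min_run: int = 3) -> DetectionSeries:
    """Turn a sweep's mask stack into presence flags with false-hit filtering.

    A frame counts as containing the structure when its mask area reaches
    ``min_area_px``; runs of consecutive detections shorter than ``min_run``
    are discarded (a real structure stays in view across several frames of
    a sweep, an isolated hit is noise).
    """
    stack = np.asarray(mask_stack).astype(bool)
    areas = stack.sum(axis=(1, 2))
    present = _clear_short_runs(areas >= min_area_px, min_run)
    n_rows = stack.shape[1]
    centroids = np.full(len(stack), np.nan)
    for i in np.flatnonzero(present):
        rows = np.nonzero(stack[i])[0]
        centroids[i] = rows.mean() / max(n_rows - 1, 1)
    return DetectionSeries(present=present,
                           area_px=np.where(present, areas, 0),
                           depth_centroid=centroids)


def segmentation_metrics(pred_masks: np.ndarray, truth_masks: np.ndarray) -> dict:
    """Frame-level detection confusion and pixel-level overlap metrics.

    Detection: a frame is positive when its mask is non-empty; sensitivity,
    specificity, accuracy, PPV, NPV come from the per-frame confusion.
    Segmentation: Jaccard, Dice, and pixel accuracy averaged over frames
    whose truth mask is non-empty; area error (%) is the mean of
    |pred area - true area| / true area * 100 over those frames.
    """
    pred = np.asarray(pred_masks).astype(bool)
    truth = np.asarray(truth_masks).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth stacks must be aligned")
    p_flag = pred.any(axis=(1, 2))
    t_flag = truth.any(axis=(1, 2))
    tp = int(np.sum(p_flag & t_flag))
    tn = int(np.sum(~p_flag & ~t_flag))
    fp = int(np.sum(p_flag & ~t_flag))
    fn = int(np.sum(~p_flag & t_flag))

    def _rate(num, den):
        return num / den if den else float("nan")

    metrics = {
        "sensitivity": _rate(tp, tp + fn),
        "specificity": _rate(tn, tn + fp),
        "accuracy": _rate(tp + tn, len(p_flag)),
        "ppv": _rate(tp, tp + fp),
        "npv": _rate(tn, tn + fn),
    }
    pos = np.flatnonzero(t_flag)
    if len(pos) == 0:
        metrics.update(jaccard=float("nan"), dice=float("nan"),
                       pixel_accuracy=float("nan"), area_error_pct=float("nan"),
                       pixel_metrics_defined=False)
        return metrics
    jac = [jaccard_index(pred[i], truth[i]) for i in pos]
    dic = [dice_coefficient(pred[i], truth[i]) for i in pos]
    pix = [float(np.mean(pred[i] == truth[i])) for i in pos]
    area = [abs(int(pred[i].sum()) - int(truth[i].sum())) / int(truth[i].sum()) * 100.0
            for i in pos]
    metrics.update(jaccard=float(np.mean(jac)), dice=float(np.mean(dic)),
                   pixel_accuracy=float(np.mean(pix)),
                   area_error_pct=float(np.mean(area)), pixel_metrics_defined=True)
    return metrics


# ---------------------------------------------------------------------------
# Persistence: weights as npz + JSON config sidecar
# ---------------------------------------------------------------------------

def save_model(model: SegModel, path) -> None:
    path = Path(path)
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.net.params)}
    for i, bn in enumerate(model.net.batchnorms()):
        arrays[f"bn_{i}_mean"] = bn.running_mean
        arrays[f"bn_{i}_var"] = bn.running_var
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"config": {"input_size": list(model.config.input_size),
                          "depth": model.config.depth,
                          "base_filters": model.config.base_filters,
                          "batch_size": model.config.batch_size,
                          "epochs": model.config.epochs,
                          "learning_rate": model.config.learning_rate,
                          "seed": model.config.seed},
               "structure": model.structure,
               "history": model.history}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_model(path) -> SegModel:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    cfg = sidecar["config"]
    config = UNetConfig(input_size=tuple(cfg["input_size"]), depth=cfg["depth"],
                        base_filters=cfg["base_filters"], batch_size=cfg["batch_size"],
                        epochs=cfg["epochs"], learning_rate=cfg["learning_rate"],
                        seed=cfg["seed"])
    model = build_unet(config, structure=sidecar.get("structure", ""))
    data = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(model.net.params):
        p.value[...] = data[f"param_{i}"]
    for i, bn in enumerate(model.net.batchnorms()):
        bn.running_mean[...] = data[f"bn_{i}_mean"]
        bn.running_var[...] = data[f"bn_{i}_var"]
    model.history = sidecar.get("history", {})
    return model
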