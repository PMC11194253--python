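"""Stage classifiers: a lightweight 3-conv/2-FC CNN and residual variants.

The designed network is
``[conv -> batch-norm -> ReLU -> 2x2 max-pool] x3 -> flatten -> dense ->
ReLU -> dropout -> dense(3) -> softmax`` on single-channel 64x64 input.
The residual alternative is the standard 18-weighted-layer basic-block
topology adapted to one input channel, trained from random initial values
with no frozen layers; ``residual_small`` is a reduced-depth variant for
desk-scale experiments.

Training uses seeded mini-batch Adam with a decreasing (step-decay)
learning-rate schedule and on-the-fly augmentation: rotation up to 20
degrees, row/column shifts up to 10% of the image size, and zoom within
10%, with reflected edges.  The weights of the best validation-accuracy
epoch are retained.
"""

from __future__ import annotations

import copy
import json
import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .nn.layers import (
    Adam, BasicBlock, BatchNorm2d, Conv2d, Dense, Dropout, Flatten,
    GlobalAvgPool, Layer, MaxPool2d, ReLU, Sequential, cross_entropy, softmax,
)
from .types import STAGES, RoiImage, StageLabel

ARCHITECTURES = ("designed_cnn", "residual18", "residual_small")


class ConfigurationError(ValueError):
    pass


class DivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    architecture: str = "designed_cnn"
    conv_channels: Tuple[int, int, int] = (16, 32, 64)
    kernel_size: int = 3
    dense_units: int = 128
    dropout_rate: float = 0.5
    use_batch_norm: bool = True
    n_classes: int = 3
    input_size: int = 64

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        if not (0 <= self.dropout_rate < 1):
            raise ConfigurationError("dropout_rate must lie in [0, 1)")


@dataclass(frozen=True)
class AugmentParams:
    max_rotation_deg: float = 20.0
    shift_frac: float = 0.10
    zoom_frac: float = 0.10

    def __post_init__(self) -> None:
        if min(self.max_rotation_deg, self.shift_frac, self.zoom_frac) < 0:
            raise ValueError("augmentation magnitudes must be nonnegative")

    @property
    def is_identity(self) -> bool:
        return self.max_rotation_deg == 0 and self.shift_frac == 0 and self.zoom_frac == 0


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 32
    initial_lr: float = 1e-3
    lr_schedule: str = "decreasing"  # or "constant"
    lr_decay_factor: float = 0.5
    lr_decay_every: int = 50
    augmentation: AugmentParams = field(default_factory=AugmentParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_schedule not in ("constant", "decreasing"):
            raise ValueError("lr_schedule must be 'constant' or 'decreasing'")

    def lr_at(self, epoch: int) -> float:
        """Learning rate for a 0-based epoch index."""
        if self.lr_schedule == "constant":
            return self.initial_lr
        return self.initial_lr * self.lr_decay_factor ** (epoch // self.lr_decay_every)


@dataclass
class TrainedModel:
    net: Sequential
    config: ModelConfig
    history: List[Dict[str, float]] = field(default_factory=list)

    def state(self) -> List[np.ndarray]:
        return [p.value.copy() for p in self.net.params()]

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        for p, v in zip(self.net.params(), state):
            p.value[...] = v


def _designed_cnn(config: ModelConfig, rng: np.random.Generator) -> Sequential:
    layers: List[Layer] = []
    in_ch = 1
    size = config.input_size
    for ch in config.conv_channels:
        layers.append(Conv2d(in_ch, ch, config.kernel_size, rng=rng))
        if config.use_batch_norm:
            layers.append(BatchNorm2d(ch))
        layers.append(ReLU())
        layers.append(MaxPool2d())
        in_ch = ch
        size //= 2
    layers.append(Flatten())
    layers.append(Dense(in_ch * size * size, config.dense_units, rng=rng))
    layers.append(ReLU())
    layers.append(Dropout(config.dropout_rate, rng=np.random.default_rng(rng.integers(2**31))))
    layers.append(Dense(config.dense_units, config.n_classes, rng=rng))
    return Sequential(layers)


def _residual(config: ModelConfig, rng: np.random.Generator, small: bool) -> Sequential:
    if small:
        stem_ch, plan = 16, [(16, 1, 1), (32, 2, 1)]  # (channels, stride, blocks)
    else:
        stem_ch, plan = 64, [(64, 1, 2), (128, 2, 2), (256, 2, 2), (512, 2, 2)]
    layers: List[Layer] = [Conv2d(1, stem_ch, 3, rng=rng), BatchNorm2d(stem_ch), ReLU()]
    in_ch = stem_ch
    for ch, stride, blocks in plan:
        for b in range(blocks):
            layers.append(BasicBlock(in_ch, ch, stride=stride if b == 0 else 1, rng=rng))
            in_ch = ch
    layers.append(GlobalAvgPool())
    layers.append(Dense(in_ch, config.n_classes, rng=rng))
    return Sequential(layers)


def build_model(config: ModelConfig, seed: int = 0) -> TrainedModel:
    """Deterministically initialized, untrained model."""
    rng = np.random.default_rng(seed)
    if config.architecture == "designed_cnn":
        net = _designed_cnn(config, rng)
    elif config.architecture == "residual18":
        net = _residual(config, rng, small=False)
    else:
        net = _residual(config, rng, small=True)
    return TrainedModel(net=net, config=config)


def parameter_count(model: TrainedModel) -> int:
    return sum(p.value.size for p in model.net.params())


# ---------------------------------------------------------------------------
# augmentation


def apply_affine(
    image: np.ndarray,
    rotation_deg: float = 0.0,
    shift_rows: float = 0.0,
    shift_cols: float = 0.0,
    zoom: float = 1.0,
) -> np.ndarray:
    """Rotate about the center, zoom, then shift; reflected edges.

    Identity parameters return the input unchanged (exactly).
    """
    if rotation_deg == 0 and shift_rows == 0 and shift_cols == 0 and zoom == 1.0:
        return image.copy()
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    theta = np.deg2rad(rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    matrix = rot.T / zoom  # output -> input mapping
    shift = np.array([shift_rows, shift_cols])
    offset = center - matrix @ (center + shift)
    out = ndimage.affine_transform(img, matrix, offset=offset, order=1, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def augment(
    image: np.ndarray, params: AugmentParams, rng: np.random.Generator
) -> np.ndarray:
    """One random training-time augmentation draw."""
    if params.is_identity:
        return image.copy()
    h, w = image.shape
    rot = rng.uniform(-params.max_rotation_deg, params.max_rotation_deg)
    dr = rng.uniform(-params.shift_frac, params.shift_frac) * h
    dc = rng.uniform(-params.shift_frac, params.shift_frac) * w
    zoom = rng.uniform(1.0 - params.zoom_frac, 1.0 + params.zoom_frac)
    return apply_affine(image, rotation_deg=rot, shift_rows=dr, shift_cols=dc, zoom=zoom)


# ---------------------------------------------------------------------------
# training / prediction


def _to_batch(images: Sequence[np.ndarray]) -> np.ndarray:
    from .nn.layers import DTYPE

    arr = np.stack([np.asarray(im, dtype=DTYPE) for im in images])
    return arr[:, None, :, :]  # NCHW


def _labels_to_int(labels: Sequence[StageLabel]) -> np.ndarray:
    return np.array([STAGES.index(lab) for lab in labels], dtype=np.int64)


def _eval_split(model: TrainedModel, x: np.ndarray, y: np.ndarray,
                batch_size: int) -> Tuple[float, float]:
    losses, correct = [], 0
    for i in range(0, len(x), batch_size):
        logits = model.net.forward(x[i : i + batch_size], train=False)
        loss, _ = cross_entropy(logits, y[i : i + batch_size])
        losses.append(loss * len(logits))
        correct += int((logits.argmax(axis=1) == y[i : i + batch_size]).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(
    model: TrainedModel,
    train_images: Sequence[np.ndarray],
    train_labels: Sequence[StageLabel],
    val_images: Sequence[np.ndarray],
    val_labels: Sequence[StageLabel],
    config: TrainConfig,
    verbose: bool = False,
) -> TrainedModel:
    """Seeded mini-batch training; keeps the best-validation-accuracy weights."""
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("train and validation partitions must be non-empty")
    rng = np.random.default_rng(config.seed)
    xtr = _to_batch(train_images)
    ytr = _labels_to_int(train_labels)
    xva = _to_batch(val_images)
    yva = _labels_to_int(val_labels)
    opt = Adam(model.net.params(), lr=config.initial_lr)
    best_acc, best_state = -1.0, model.state()
    model.history = []
    for epoch in range(config.epochs):
        opt.lr = config.lr_at(epoch)
        order = rng.permutation(len(xtr))
        ep_loss, ep_correct = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            batch = xtr[idx]
            if not config.augmentation.is_identity:
                from .nn.layers import DTYPE

                batch = np.stack(
                    [augment(im[0], config.augmentation, rng)[None] for im in batch]
                ).astype(DTYPE)
            logits = model.net.forward(batch, train=True)
            loss, grad = cross_entropy(logits, ytr[idx])
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            model.net.backward(grad)
            opt.step()
            ep_loss += loss * len(idx)
            ep_correct += int((logits.argmax(axis=1) == ytr[idx]).sum())
        val_loss, val_acc = _eval_split(model, xva, yva, config.batch_size)
        rec = {
            "epoch": epoch + 1,
            "train_loss": ep_loss / len(xtr),
            "train_accuracy": ep_correct / len(xtr),
            "val_loss": val_loss,
            "val_accuracy": val_acc,
            "lr": opt.lr,
        }
        model.history.append(rec)
        if verbose:
            print(
                f"epoch {rec['epoch']:3d}  loss {rec['train_loss']:.4f}  "
                f"acc {rec['train_accuracy']:.3f}  val_acc {val_acc:.3f}"
            )
        if val_acc > best_acc:
            best_acc, best_state = val_acc, model.state()
    model.load_state(best_state)
    return model


def predict(
    model: TrainedModel, images: Sequence[np.ndarray], batch_size: int = 64
) -> Tuple[np.ndarray, List[StageLabel]]:
    """Per-image class probabilities and argmax labels (ties break toward
    the earlier stage)."""
    x = _to_batch(images)
    if x.shape[2] != model.config.input_size or x.shape[3] != model.config.input_size:
        raise ValueError(
            f"expected {model.config.input_size}x{model.config.input_size} inputs, "
            f"got {x.shape[2]}x{x.shape[3]}"
        )
    probs = []
    for i in range(0, len(x), batch_size):
        logits = model.net.forward(x[i : i + batch_size], train=False)
        probs.append(softmax(logits))
    p = np.concatenate(probs)
    labels = [STAGES[int(j)] for j in p.argmax(axis=1)]
    return p, labels


# ---------------------------------------------------------------------------
# class-activation heat maps


class UnsupportedArchitectureError(ValueError):
    pass


def _last_feature_index(net: Sequential) -> int:
    """Index of the last activation layer emitting a 4-D feature map."""
    idx = -1
    for i, (layer, out) in enumerate(zip(net.layers, net.outputs)):
        if isinstance(layer, (ReLU, BasicBlock)) and out.ndim == 4:
            idx = i
    if idx < 0:
        raise UnsupportedArchitectureError("no convolutional stage found")
    return idx


def class_activation_map(model: TrainedModel, image: np.ndarray) -> np.ndarray:
    """Gradient-weighted activation map for the predicted class.

    Last convolutional stage activations are weighted by the spatial mean
    of the predicted-class score gradient, rectified, max-normalized to 1
    and upsampled to the input extent.  An all-zero map is returned when
    nothing activates.
    """
    from skimage.transform import resize

    x = _to_batch([image])
    logits = model.net.forward(x, train=False)
    k = _last_feature_index(model.net)
    activations = model.net.outputs[k]  # (1, C, h, w)
    pred = int(logits.argmax(axis=1)[0])
    grad_logits = np.zeros_like(logits)
    grad_logits[0, pred] = 1.0
    grad_act = model.net.backward(grad_logits, stop_after=k)
    weights = grad_act.mean(axis=(2, 3))  # (1, C)
    cam = np.maximum((weights[:, :, None, None] * activations).sum(axis=1)[0], 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return resize(cam, image.shape, order=1, mode="edge",
                  anti_aliasing=False, preserve_range=True)


# ---------------------------------------------------------------------------
# serialization


def save_model(model: TrainedModel, path: Path | str) -> None:
    """Single-file weights + config + history."""
    payload = {
        "config": asdict(model.config),
        "history": model.history,
        "state": model.state(),
        "bn_running": [
            (layer.running_mean.copy(), layer.running_var.copy())
            for layer in _iter_bn(model.net)
        ],
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: Path | str, seed: int = 0) -> TrainedModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    cfg_dict = dict(payload["config"])
    cfg_dict["conv_channels"] = tuple(cfg_dict["conv_channels"])
    config = ModelConfig(**cfg_dict)
    model = build_model(config, seed=seed)
    model.load_state(payload["state"])
    for layer, (mean, var) in zip(_iter_bn(model.net), payload["bn_running"]):
        layer.running_mean[...] = mean
        layer.running_var[...] = var
    model.history = payload["history"]
    return model


def _iter_bn(net: Sequential):
    for layer in net.layers:
        if isinstance(layer, BatchNorm2d):
            yield layer
        elif isinstance(layer, BasicBlock):
            yield layer.bn1
            yield layer.bn2
            if layer.proj_bn is not None:
                yield layer.proj_bn


def history_table(model: TrainedModel):
    import pandas as pd

    return pd.DataFrame(model.history)
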