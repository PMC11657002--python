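"""Stage 1: the binary tumor-presence classifier.

A backbone CNN (VGG-16 with batch norm at paper scale; a narrow VGG-style
net for CPU work) maps a 4-channel slice to one logit; the sigmoid of that
logit is the probability that the slice contains tumor.  Inputs are
bilinearly upsampled by a factor of 2 before entering the network (the
classifier is the only model that sees upsampled inputs).  Training
minimises binary cross-entropy with Adam, decaying the learning rate by a
configurable factor whenever the validation loss stops improving.

The trained classifier serves two later roles: its occlusion-saliency maps
become localization seeds, and its predictions gate the healthy-image
overrides (all-negative seeds at training time, empty masks at inference).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .data import MultimodalSlice

_LOG_EPS = 1e-7


@dataclass
class ClassifierConfig:
    backbone: str = "vgg16-bn"
    input_upsample_factor: int = 2
    epochs: int = 100
    batch_size: int = 32
    lr_init: float = 5e-4
    lr_decay_factor: float = 10.0
    plateau_tol: float = 1e-4
    max_lr_decays: int = 3
    weight_decay: float = 0.1
    adam_betas: tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8
    decision_threshold: float = 0.5
    rng_seed: int = 0

    def __post_init__(self):
        if self.lr_init <= 0:
            raise ValueError("lr_init must be positive")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")


@dataclass
class TrainedClassifier:
    net: nn.Module
    config: ClassifierConfig
    history: dict[str, list[float]] = field(default_factory=dict)
    input_shape: tuple[int, int] | None = None  # (H, W) seen during training

    def save(self, path: str | Path) -> None:
        path = Path(path)
        state = self.net.state_dict()
        meta = {"config": asdict(self.config), "history": self.history,
                "input_shape": self.input_shape}
        np.savez_compressed(path, __meta__=json.dumps(meta), **state)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            state = {k: data[k] for k in data.files if k != "__meta__"}
        cfg_dict = meta["config"]
        cfg_dict["adam_betas"] = tuple(cfg_dict["adam_betas"])
        config = ClassifierConfig(**cfg_dict)
        nn.seed(config.rng_seed)
        net = nn.build_backbone(config.backbone, in_channels=4, num_outputs=1)
        net.load_state_dict(state)
        return cls(net=net, config=config, history=meta["history"],
                   input_shape=tuple(meta["input_shape"]) if meta.get("input_shape") else None)


def _upsample2x_bilinear(batch: np.ndarray) -> np.ndarray:
    """Fast exact ×2 bilinear upsample (half-pixel centers, edges clamped)."""

    def axis_up(x, axis):
        x = np.moveaxis(x, axis, -1)
        lo = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)  # left neighbours
        hi = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)  # right neighbours
        out = np.empty(x.shape[:-1] + (2 * x.shape[-1],), dtype=x.dtype)
        out[..., 0::2] = 0.75 * x + 0.25 * lo
        out[..., 1::2] = 0.75 * x + 0.25 * hi
        return np.moveaxis(out, -1, axis)

    return axis_up(axis_up(batch, -2), -1)


def bilinear_resize(batch: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Vectorised bilinear resize of the two trailing axes (half-pixel centers)."""
    h, w = batch.shape[-2:]
    if (h, w) == (out_h, out_w):
        return batch
    if (out_h, out_w) == (2 * h, 2 * w):
        return _upsample2x_bilinear(batch)

    def _axis(coords_out: int, size_in: int):
        x = (np.arange(coords_out) + 0.5) * size_in / coords_out - 0.5
        x0 = np.clip(np.floor(x).astype(int), 0, size_in - 1)
        x1 = np.clip(x0 + 1, 0, size_in - 1)
        frac = np.clip(x - x0, 0.0, 1.0)
        return x0, x1, frac.astype(batch.dtype)

    y0, y1, fy = _axis(out_h, h)
    x0, x1, fx = _axis(out_w, w)
    rows0 = batch[..., y0, :]
    rows1 = batch[..., y1, :]
    rows = rows0 + fy[:, None] * (rows1 - rows0)
    cols0 = rows[..., :, x0]
    cols1 = rows[..., :, x1]
    return cols0 + fx * (cols1 - cols0)


def _pixels(item) -> np.ndarray:
    return item.pixels if isinstance(item, MultimodalSlice) else np.asarray(item)


def prepare_batch(items, upsample_factor: int) -> np.ndarray:
    batch = np.stack([_pixels(i) for i in items]).astype(np.float32)
    if upsample_factor > 1:
        h, w = batch.shape[-2:]
        batch = bilinear_resize(batch, h * upsample_factor, w * upsample_factor)
    return batch


def _bce(probs: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    y = labels.astype(np.float32)
    p = probs
    return -(
        nn.Tensor(y) * (p + _LOG_EPS).log()
        + nn.Tensor(1.0 - y) * (1.0 - p + _LOG_EPS).log()
    ).mean()


def _forward_probs(net: nn.Module, batch: np.ndarray) -> nn.Tensor:
    return net(nn.Tensor(batch)).reshape(len(batch)).sigmoid()


def train_classifier(
    train_slices: list[MultimodalSlice],
    val_slices: list[MultimodalSlice],
    config: ClassifierConfig | None = None,
) -> TrainedClassifier:
    """Train the tumor-presence classifier; records per-epoch loss/accuracy."""
    config = config or ClassifierConfig()
    for name, cohort in (("train", train_slices), ("val", val_slices)):
        labels = {s.label for s in cohort}
        if labels != {0, 1}:
            raise ValueError(f"{name} cohort must contain both labels, has {labels}")
    rng = np.random.default_rng(config.rng_seed)
    nn.seed(config.rng_seed)
    net = nn.build_backbone(config.backbone, in_channels=4, num_outputs=1)
    opt = nn.Adam(net.parameters(), lr=config.lr_init, betas=config.adam_betas,
                  eps=config.adam_eps, weight_decay=config.weight_decay)
    plateau = nn.ReduceOnPlateau(opt, factor=config.lr_decay_factor,
                                 tol=config.plateau_tol,
                                 max_decays=config.max_lr_decays)
    x_train = prepare_batch(train_slices, config.input_upsample_factor)
    y_train = np.array([s.label for s in train_slices], dtype=np.float32)
    x_val = prepare_batch(val_slices, config.input_upsample_factor)
    y_val = np.array([s.label for s in val_slices], dtype=np.float32)
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [], "lr": []
    }
    n = len(train_slices)
    for epoch in range(config.epochs):
        net.train()
        order = rng.permutation(n)
        losses, hits = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            probs = _forward_probs(net, x_train[idx])
            loss = _bce(probs, y_train[idx])
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch "
                    f"{start // config.batch_size} (lr={opt.lr:g})"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item() * len(idx))
            hits += int(((probs.data >= config.decision_threshold) == y_train[idx]).sum())
        net.eval()
        with nn.no_grad():
            val_probs = _eval_probs(net, x_val, config.batch_size)
        val_loss = float(
            -np.mean(
                y_val * np.log(val_probs + _LOG_EPS)
                + (1 - y_val) * np.log(1 - val_probs + _LOG_EPS)
            )
        )
        history["train_loss"].append(sum(losses) / n)
        history["train_acc"].append(hits / n)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(
            float(((val_probs >= config.decision_threshold) == y_val).mean())
        )
        history["lr"].append(opt.lr)
        plateau.update(val_loss)
    net.eval()
    return TrainedClassifier(net=net, config=config, history=history,
                             input_shape=train_slices[0].shape)


def _eval_probs(net: nn.Module, batch: np.ndarray, batch_size: int) -> np.ndarray:
    out = np.empty(len(batch), dtype=np.float64)
    for start in range(0, len(batch), batch_size):
        chunk = batch[start : start + batch_size]
        out[start : start + len(chunk)] = _forward_probs(net, chunk).data
    return out


def predict_tumor_probability(
    model: TrainedClassifier, image: MultimodalSlice | np.ndarray
) -> float:
    """Probability in [0, 1] that the slice contains tumor (eval mode)."""
    return float(predict_batch(model, [image])[0])


def predict_batch(model: TrainedClassifier, items) -> np.ndarray:
    model.net.eval()
    if model.input_shape is not None:
        for item in items:
            shape = tuple(_pixels(item).shape[-2:])
            if shape != tuple(model.input_shape):
                raise ValueError(
                    f"slice shape {shape} does not match training shape "
                    f"{tuple(model.input_shape)}"
                )
    batch = prepare_batch(items, model.config.input_upsample_factor)
    with nn.no_grad():
        return _eval_probs(model.net, batch, model.config.batch_size)


def classify(
    model: TrainedClassifier, image: MultimodalSlice | np.ndarray,
    threshold: float | None = None,
) -> int:
    """Binary decision: 1 iff probability >= threshold (ties count positive)."""
    threshold = model.config.decision_threshold if threshold is None else threshold
    return int(predict_tumor_probability(model, image) >= threshold)
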