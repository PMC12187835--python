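"""Transfer-learning style training harness for patch classification.

The protocol: a staged convolutional backbone whose first ``frozen_depth``
stages stay fixed while the remaining stages and the 2-class head are
fine-tuned with cross-entropy loss, SGD with momentum, L2 weight decay
1e-4, batch size 128, 18 epochs, and a cosine-annealed learning rate from a
maximum of 2e-2 down to ``min_lr`` (default 0).

The bundled ``tiny-cnn`` backbone is a four-stage strided CNN sized for
synthetic 90 x 90 patches; freezing its first three stages mirrors the
freeze-the-early-layers protocol structurally while training in minutes on a
single CPU. The harness is backbone-agnostic: any :class:`~slnpatch._nn.StagedNet`
with ordered stages plugs in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nn import SGD, Conv2d, Dense, GlobalAvgPool, ReLU, StagedNet, cross_entropy_grad, softmax
from .augment import AugmentationConfig, ChannelStats, apply_augmentations, compute_channel_stats
from .metrics import ConfusionCounts, MetricsReport, UndefinedMetricError, compute_metrics, roc_auc
from .patches import DatasetManifest, patch_pixels

__all__ = [
    "TrainConfig",
    "BackboneSpec",
    "PatchClassifier",
    "MaskOracle",
    "build_model",
    "lr_at",
    "train",
    "predict_proba",
    "evaluate_patches",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    epochs: int = 18
    weight_decay: float = 1e-4
    max_lr: float = 2e-2
    min_lr: float = 0.0
    momentum: float = 0.9
    frozen_depth: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("batch_size and epochs must be positive")
        if self.max_lr <= 0 or self.min_lr < 0 or self.min_lr > self.max_lr:
            raise ValueError("need 0 <= min_lr <= max_lr and max_lr > 0")
        if self.frozen_depth < 0:
            raise ValueError("frozen_depth must be non-negative")


@dataclass(frozen=True)
class BackboneSpec:
    name: str = "tiny-cnn"
    pretrained: bool = False


def lr_at(t: float, total: float, config: TrainConfig) -> float:
    """Cosine annealing: lr(t) = min + (max - min) * (1 + cos(pi * t / T)) / 2."""
    if total <= 0:
        raise ValueError("total steps must be positive")
    if not (0 <= t <= total):
        raise ValueError(f"step {t} outside [0, {total}]")
    return config.min_lr + (config.max_lr - config.min_lr) * (
        1.0 + float(np.cos(np.pi * t / total))
    ) / 2.0


class PatchClassifier:
    """A staged CNN plus normalization statistics and freezing bookkeeping."""

    def __init__(self, net: StagedNet, config: TrainConfig, backbone: BackboneSpec) -> None:
        self.net = net
        self.config = config
        self.backbone = backbone
        self.channel_stats: ChannelStats | None = None

    def _normalize(self, tiles: np.ndarray) -> np.ndarray:
        x = np.asarray(tiles, dtype=np.float32) / 255.0
        if self.channel_stats is not None:
            mean = np.asarray(self.channel_stats.mean, dtype=np.float32)
            sd = np.maximum(np.asarray(self.channel_stats.sd, dtype=np.float32), 1e-6)
            x = (x - mean) / sd
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def logits(self, tiles: np.ndarray) -> np.ndarray:
        tiles = np.asarray(tiles)
        if tiles.ndim == 3:
            tiles = tiles[None]
        if tiles.ndim != 4 or tiles.shape[3] != 3:
            raise ValueError(f"expected (N, H, W, 3) RGB tiles, got shape {tiles.shape}")
        return self.net.forward(self._normalize(tiles))

    def predict_proba(self, tiles: np.ndarray, meta=None) -> np.ndarray:
        """Positive-class probability per tile, order preserved."""
        return softmax(self.logits(tiles))[:, 1]

    def frozen_checksums(self) -> list[str]:
        return self.net.stage_checksums()[: self.config.frozen_depth]


def _tiny_cnn(rng: np.random.Generator) -> StagedNet:
    stages = [
        [Conv2d(3, 8, k=3, stride=2, rng=rng), ReLU()],
        [Conv2d(8, 16, k=3, stride=2, rng=rng), ReLU()],
        [Conv2d(16, 32, k=3, stride=2, rng=rng), ReLU()],
        [Conv2d(32, 32, k=3, stride=2, rng=rng), ReLU()],
    ]
    head = [GlobalAvgPool(), Dense(32, 2, rng=rng)]
    return StagedNet(stages, head)


_BACKBONES = {"tiny-cnn": _tiny_cnn}


def build_model(backbone: BackboneSpec, config: TrainConfig | None = None) -> PatchClassifier:
    """Instantiate a backbone with a fresh 2-class head and freezing metadata.

    Raises on unknown backbone names. ``frozen_depth`` must not exceed the
    backbone's stage count.
    """
    config = config or TrainConfig()
    factory = _BACKBONES.get(backbone.name)
    if factory is None:
        raise ValueError(
            f"unknown backbone {backbone.name!r}; available: {sorted(_BACKBONES)}"
        )
    net = factory(np.random.default_rng(config.seed))
    if config.frozen_depth > net.n_stages:
        raise ValueError(
            f"frozen_depth {config.frozen_depth} exceeds the backbone's "
            f"{net.n_stages} stages"
        )
    return PatchClassifier(net, config, backbone)


def train(
    model: PatchClassifier,
    manifest: DatasetManifest,
    slides: dict,
    augmentation: AugmentationConfig | None = None,
) -> pd.DataFrame:
    """Fine-tune on the manifest's train split.

    Frozen-stage parameters are bitwise unchanged afterwards. Augmentation
    (when given) is applied on the fly per patch per epoch. Returns the
    per-epoch history (epoch, loss, lr, train_acc). Deterministic given the
    model seed and a fixed thread policy.
    """
    cfg = model.config
    records = manifest.subset("train")
    if not records:
        raise ValueError("manifest has no train split (run split_manifest first)")
    labels = np.array([1 if r.label == "positive" else 0 for r in records], dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("train split must contain both classes")
    tiles = patch_pixels(records, slides)
    if model.channel_stats is None:
        model.channel_stats = compute_channel_stats(tiles)

    n = len(records)
    steps_per_epoch = int(np.ceil(n / cfg.batch_size))
    total_steps = cfg.epochs * steps_per_epoch
    rng = np.random.default_rng(cfg.seed)
    optimizer = SGD(momentum=cfg.momentum, weight_decay=cfg.weight_decay)

    history = []
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        lr = cfg.max_lr
        for b in range(steps_per_epoch):
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            batch = tiles[idx]
            if augmentation is not None:
                batch = np.stack(
                    [apply_augmentations(tile, augmentation, rng) for tile in batch]
                )
            logits = model.net.forward(model._normalize(batch))
            loss, dlogits = cross_entropy_grad(logits, labels[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}, step {b}")
            model.net.backward(dlogits, stop_stage=cfg.frozen_depth)
            lr = lr_at(step, total_steps, cfg)
            optimizer.step(model.net, cfg.frozen_depth, lr)
            step += 1
            epoch_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == labels[idx]).sum())
        history.append(
            {
                "epoch": epoch,
                "loss": epoch_loss / n,
                "lr": lr,
                "train_acc": correct / n,
            }
        )
    return pd.DataFrame(history)


def predict_proba(model, tiles: np.ndarray, meta=None) -> np.ndarray:
    """Module-level convenience dispatching to the model's ``predict_proba``."""
    return model.predict_proba(tiles, meta=meta)


def evaluate_patches(
    model, manifest: DatasetManifest, slides: dict, threshold: float = 0.5
) -> MetricsReport:
    """Confusion metrics (threshold 0.5, ties negative) plus AUC on the test split."""
    records = manifest.subset("test")
    if not records:
        raise ValueError("manifest has no test split")
    tiles = patch_pixels(records, slides)
    meta = [(r.slide_id, r.x0, r.y0) for r in records]
    probs = model.predict_proba(tiles, meta=meta)
    truth = np.array([r.label == "positive" for r in records])
    pred = probs > threshold
    counts = ConfusionCounts(
        tp=int((pred & truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fp=int((pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )
    try:
        auc = roc_auc(probs, truth)[0]
    except UndefinedMetricError:
        auc = None
    return compute_metrics(counts, auc=auc)


class MaskOracle:
    """Test double that reads tumor content straight from ground-truth masks.

    ``masks`` maps slide_id to a binary mask; prediction for a tile anchored
    at (x0, y0) is 1.0 iff its tumor content exceeds ``theta``, else 0.0.
    Requires per-tile metadata ``(slide_id, x0, y0)``.
    """

    def __init__(self, masks: dict, theta: float = 0.20, patch_size: int = 90) -> None:
        self.masks = {k: np.asarray(v) for k, v in masks.items()}
        self.theta = theta
        self.patch_size = patch_size

    def predict_proba(self, tiles: np.ndarray, meta=None) -> np.ndarray:
        if meta is None:
            raise ValueError("MaskOracle needs (slide_id, x0, y0) metadata per tile")
        s = self.patch_size
        probs = np.empty(len(meta))
        for i, (slide_id, x0, y0) in enumerate(meta):
            tile = self.masks[slide_id][y0 : y0 + s, x0 : x0 + s]
            probs[i] = 1.0 if tile.sum() / (s * s) > self.theta else 0.0
        return probs
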