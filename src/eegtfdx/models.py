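"""Classifier architectures and the training/prediction contract.

Four architectures sit behind one interface: a bespoke deep CNN (repeated
convolution -> ReLU -> 2x2 max-pool blocks followed by a two-way fully
connected softmax head) and the three standard backbones AlexNet, ResNet50
and SqueezeNet, each rebuilt at its published topology with a two-class
final classifier.  Backbones are randomly initialised; the training
defaults are Adam with learning rate 1e-4, 12 epochs and mini-batches of
64.  Class index 0 is HC, index 1 is MD; an exact 0.5/0.5 probability tie
resolves to HC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import (
    AdaptiveAvgPool2D,
    Bottleneck,
    Conv2D,
    Dense,
    Dropout,
    Fire,
    Flatten,
    MaxPool2D,
    ReLU,
    Sequential,
    SoftmaxCrossEntropy,
    softmax,
)

__all__ = [
    "CLASSES",
    "TrainConfig",
    "ModelHandle",
    "TrainedModel",
    "build_dcnn",
    "build_backbone",
    "train",
    "predict",
    "hard_labels_from_probs",
]

CLASSES = ("HC", "MD")  # index 0 / index 1; ties resolve to index 0 (HC)

BACKBONE_SIDES = {"alexnet": 227, "resnet50": 224, "squeezenet": 227}


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    max_epochs: int = 12
    batch_size: int = 64
    optimizer: str = "adam"
    weight_decay: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.max_epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning rate, epochs and batch size must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be non-negative")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")


@dataclass
class ModelHandle:
    """An architecture instance: the network plus its input-side contract."""

    architecture: str
    network: Sequential
    input_side: int
    seed: int


@dataclass
class TrainedModel:
    handle: ModelHandle
    history: list[dict] = field(default_factory=list)  # per-epoch loss/accuracy

    @property
    def input_side(self) -> int:
        return self.handle.input_side


def build_dcnn(
    side: int = 256,
    n_blocks: int = 3,
    filters: tuple[int, ...] = (8, 16, 32),
    seed: int = 0,
) -> ModelHandle:
    """The bespoke DCNN: [conv3x3 -> ReLU -> maxpool2x2] blocks + FC(2).

    Pooling uses floor semantics, so any side with ``side // 2**n_blocks
    >= 1`` is accepted.
    """
    if len(filters) != n_blocks:
        raise ValueError(f"need {n_blocks} filter counts, got {len(filters)}")
    rng = np.random.default_rng(seed)
    layers: list = []
    in_ch, s = 3, side
    for f in filters:
        layers += [Conv2D(in_ch, f, 3, pad=1, rng=rng), ReLU(), MaxPool2D(2)]
        in_ch, s = f, s // 2
        if s < 1:
            raise ValueError(
                f"{n_blocks} pooling blocks collapse a {side}-pixel input to nothing"
            )
    layers += [Flatten(), Dense(in_ch * s * s, 2, rng=rng)]
    return ModelHandle("dcnn", Sequential(*layers), input_side=side, seed=seed)


def _alexnet(rng) -> Sequential:
    return Sequential(
        Conv2D(3, 64, 11, stride=4, pad=2, rng=rng), ReLU(), MaxPool2D(3, 2),
        Conv2D(64, 192, 5, pad=2, rng=rng), ReLU(), MaxPool2D(3, 2),
        Conv2D(192, 384, 3, pad=1, rng=rng), ReLU(),
        Conv2D(384, 256, 3, pad=1, rng=rng), ReLU(),
        Conv2D(256, 256, 3, pad=1, rng=rng), ReLU(), MaxPool2D(3, 2),
        AdaptiveAvgPool2D(6), Flatten(),
        Dropout(0.5, rng=np.random.default_rng(rng.integers(2**31))),
        Dense(256 * 36, 4096, rng=rng), ReLU(),
        Dropout(0.5, rng=np.random.default_rng(rng.integers(2**31))),
        Dense(4096, 4096, rng=rng), ReLU(),
        Dense(4096, 2, rng=rng),
    )


def _resnet50(rng) -> Sequential:
    layers: list = [
        Conv2D(3, 64, 7, stride=2, pad=3, rng=rng, bias=False),
        _nn.BatchNorm2D(64), ReLU(),
        MaxPool2D(3, 2),
    ]
    in_ch = 64
    for mid, out_ch, blocks, stride in (
        (64, 256, 3, 1), (128, 512, 4, 2), (256, 1024, 6, 2), (512, 2048, 3, 2)
    ):
        for b in range(blocks):
            layers.append(Bottleneck(in_ch, mid, out_ch, stride if b == 0 else 1, rng))
            in_ch = out_ch
    layers += [AdaptiveAvgPool2D(1), Flatten(), Dense(2048, 2, rng=rng)]
    return Sequential(*layers)


def _squeezenet(rng) -> Sequential:
    return Sequential(
        Conv2D(3, 96, 7, stride=2, rng=rng), ReLU(), MaxPool2D(3, 2),
        Fire(96, 16, 64, 64, rng), Fire(128, 16, 64, 64, rng),
        Fire(128, 32, 128, 128, rng), MaxPool2D(3, 2),
        Fire(256, 32, 128, 128, rng), Fire(256, 48, 192, 192, rng),
        Fire(384, 48, 192, 192, rng), Fire(384, 64, 256, 256, rng),
        MaxPool2D(3, 2), Fire(512, 64, 256, 256, rng),
        Dropout(0.5, rng=np.random.default_rng(rng.integers(2**31))),
        Conv2D(512, 2, 1, rng=rng), ReLU(),
        AdaptiveAvgPool2D(1), Flatten(),
    )


def build_backbone(name: str, pretrained: bool = False, seed: int = 0) -> ModelHandle:
    """One of the standard backbones with a two-way classifier head."""
    if name not in BACKBONE_SIDES:
        raise ValueError(
            f"unknown backbone {name!r}; valid names: {sorted(BACKBONE_SIDES)}"
        )
    if pretrained:
        raise ValueError(
            "pretrained weights are not bundled; build with pretrained=False "
            "for random initialisation"
        )
    rng = np.random.default_rng(seed)
    net = {"alexnet": _alexnet, "resnet50": _resnet50, "squeezenet": _squeezenet}[name](rng)
    return ModelHandle(name, net, input_side=BACKBONE_SIDES[name], seed=seed)


def _as_batch(images: np.ndarray, side: int) -> np.ndarray:
    """uint8 (n, side, side, 3) -> float32 NCHW in [0, 1]."""
    images = np.asarray(images)
    if images.ndim != 4 or images.shape[1:] != (side, side, 3):
        raise ValueError(
            f"expected images of shape (n, {side}, {side}, 3), got {images.shape}"
        )
    return (images.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)


def _label_indices(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    idx = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab not in CLASSES:
            raise ValueError(f"unknown label {lab!r}; expected one of {CLASSES}")
        idx[i] = CLASSES.index(lab)
    return idx


def train(
    model: ModelHandle, images: np.ndarray, labels: np.ndarray, config: TrainConfig
) -> TrainedModel:
    """Seeded mini-batch Adam training for exactly ``max_epochs`` epochs."""
    x = _as_batch(images, model.input_side)
    y = _label_indices(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(config.seed)
    loss_fn = SoftmaxCrossEntropy()
    opt = _nn.Adam(
        model.network.params(),
        lr=config.learning_rate,
        weight_decay=config.weight_decay,
    )
    n = len(y)
    history = []
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            logits = model.network.forward(x[sel], train=True)
            losses.append(loss_fn.forward(logits, y[sel]) * len(sel))
            correct += int((logits.argmax(axis=1) == y[sel]).sum())
            model.network.backward(loss_fn.backward())
            opt.step(model.network.grads())
        history.append(
            {"loss": float(np.sum(losses) / n), "accuracy": 100.0 * correct / n}
        )
    return TrainedModel(handle=model, history=history)


def hard_labels_from_probs(probs: np.ndarray) -> np.ndarray:
    """MD iff p(MD) strictly exceeds p(HC); an exact tie resolves to HC."""
    probs = np.asarray(probs)
    return np.where(probs[:, 1] > probs[:, 0], "MD", "HC")


def predict(
    model: TrainedModel, images: np.ndarray, batch_size: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Per-image (HC, MD) probability pairs and hard labels."""
    x = _as_batch(images, model.input_side)
    probs = np.concatenate(
        [
            softmax(model.handle.network.forward(x[i : i + batch_size], train=False))
            for i in range(0, len(x), batch_size)
        ]
    )
    return probs, hard_labels_from_probs(probs)
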