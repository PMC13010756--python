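"""The per-image condition decoder: build, train, and apply a 2-class CNN.

Two architecture families:

* ``alexnet`` — the canonical 5-convolution + 3-fully-connected layout at
  227x227 input, with the final layer resized to the number of conditions.
  Single-channel fixation maps are replicated across the three input
  channels.
* ``small`` — a two-convolution-block + one-hidden-dense surrogate at
  64x64, sized so the full pipeline runs on one CPU in minutes. It is an
  explicit desk-scale extension of the method, not a study-scale model.

Training uses stochastic gradient descent with momentum 0.9, mini-batches
of 32, at most 8 epochs, initial learning rate 6e-4 dropping by 10x every
4 epochs, L2 regularisation 1e-4, data reshuffled each epoch, and
validation accuracy monitored every 50 iterations; the checkpoint with the
best validation accuracy (earliest on ties) is returned.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import nn
from .render import FixationMap
from .sampling import AugmentationSpec, augment


class ConfigError(ValueError):
    pass


class DegenerateDataError(ValueError):
    """Training data contain fewer than n_classes distinct labels."""


@dataclass(frozen=True)
class ArchitectureSpec:
    family: str = "small"
    input_size_px: tuple[int, int] | None = None  # (width, height)
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.family not in {"alexnet", "small"}:
            raise ConfigError(f"unknown architecture family {self.family!r}")
        if self.n_classes < 2:
            raise ConfigError("n_classes must be >= 2")
        if self.input_size_px is None:
            default = (227, 227) if self.family == "alexnet" else (64, 64)
            object.__setattr__(self, "input_size_px", default)

    @property
    def in_channels(self) -> int:
        return 3 if self.family == "alexnet" else 1


@dataclass(frozen=True)
class TrainConfig:
    """SGDM optimisation settings (defaults follow the decoding protocol)."""

    momentum: float = 0.9
    initial_lr: float = 6e-4
    lr_drop_factor: float = 0.1
    lr_drop_period_epochs: int = 4
    batch_size: int = 32
    max_epochs: int = 8
    l2: float = 1e-4
    shuffle_each_epoch: bool = True
    validation_frequency_iters: int = 50
    checkpoint: str = "final"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.initial_lr, self.lr_drop_factor, self.momentum + 1e-9,
               self.l2 + 1e-12) <= 0:
            raise ConfigError("rates must be positive")
        if self.max_epochs < 1:
            raise ConfigError("max_epochs must be >= 1")
        if self.checkpoint not in {"final", "best"}:
            raise ConfigError("checkpoint must be 'final' or 'best'")


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Effective learning rate during a given 1-based epoch under the
    piecewise schedule (drop by ``lr_drop_factor`` every
    ``lr_drop_period_epochs`` epochs)."""
    drops = (epoch - 1) // config.lr_drop_period_epochs
    return config.initial_lr * config.lr_drop_factor ** drops


@dataclass
class TrainedDecoder:
    """A condition classifier with its architecture, weights, and history."""

    architecture: ArchitectureSpec
    net: nn.Sequential
    class_labels: list[str] = field(default_factory=list)
    history: list[dict] = field(default_factory=list)
    fingerprint: str = ""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train=train)


def config_fingerprint(*specs) -> str:
    blob = json.dumps([asdict(s) if hasattr(s, "__dataclass_fields__") else s
                       for s in specs], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build_small(spec: ArchitectureSpec, rng) -> nn.Sequential:
    w, h = spec.input_size_px
    layers = [
        nn.Conv2d(1, 8, 5, stride=2, pad=2, rng=rng),
        nn.ReLU(),
        nn.MaxPool2d(2),
        nn.Conv2d(8, 16, 3, stride=1, pad=1, rng=rng),
        nn.ReLU(),
        nn.MaxPool2d(2),
        nn.Flatten(),
    ]
    fh, fw = h, w
    fh = (fh + 2 * 2 - 5) // 2 + 1
    fw = (fw + 2 * 2 - 5) // 2 + 1
    fh, fw = fh // 2, fw // 2  # pool 1
    fh, fw = fh, fw            # conv2 same-pad
    fh, fw = fh // 2, fw // 2  # pool 2
    layers += [
        nn.Dense(16 * fh * fw, 64, rng=rng),
        nn.ReLU(),
        nn.Dense(64, spec.n_classes, rng=rng),
    ]
    return nn.Sequential(layers)


def _build_alexnet(spec: ArchitectureSpec, rng) -> nn.Sequential:
    w, h = spec.input_size_px
    if (w, h) != (227, 227):
        raise ConfigError("alexnet family expects 227x227 input")
    drop_rng = np.random.default_rng(rng.integers(2**31))
    return nn.Sequential([
        nn.Conv2d(3, 96, 11, stride=4, rng=rng),
        nn.ReLU(),
        nn.MaxPool2d(3, 2),
        nn.Conv2d(96, 256, 5, stride=1, pad=2, rng=rng),
        nn.ReLU(),
        nn.MaxPool2d(3, 2),
        nn.Conv2d(256, 384, 3, stride=1, pad=1, rng=rng),
        nn.ReLU(),
        nn.Conv2d(384, 384, 3, stride=1, pad=1, rng=rng),
        nn.ReLU(),
        nn.Conv2d(384, 256, 3, stride=1, pad=1, rng=rng),
        nn.ReLU(),
        nn.MaxPool2d(3, 2),
        nn.Flatten(),
        nn.Dropout(0.5, drop_rng),
        nn.Dense(256 * 6 * 6, 4096, rng=rng),
        nn.ReLU(),
        nn.Dropout(0.5, drop_rng),
        nn.Dense(4096, 4096, rng=rng),
        nn.ReLU(),
        nn.Dense(4096, spec.n_classes, rng=rng),
    ])


def build_decoder(spec: ArchitectureSpec, seed: int = 0) -> TrainedDecoder:
    """Construct an untrained decoder with seed-deterministic weights."""
    rng = np.random.default_rng(seed)
    net = (_build_alexnet if spec.family == "alexnet" else _build_small)(
        spec, rng)
    return TrainedDecoder(
        architecture=spec, net=net,
        fingerprint=config_fingerprint(spec, {"seed": seed}),
    )


def maps_to_batch(maps: Sequence[FixationMap] | np.ndarray,
                  spec: ArchitectureSpec) -> np.ndarray:
    """Stack maps into an NCHW float32 batch, replicating channels for
    architectures that expect more than one."""
    if isinstance(maps, np.ndarray):
        arr = maps.astype(np.float32, copy=False)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim == 3:
            arr = arr[:, None]
    else:
        arr = np.stack([m.values for m in maps])[:, None]
    h, w = arr.shape[2:]
    ew, eh = spec.input_size_px
    if (w, h) != (ew, eh):
        raise ConfigError(
            f"map size {(w, h)} does not match architecture input "
            f"{spec.input_size_px}"
        )
    if arr.shape[1] != spec.in_channels:
        arr = np.repeat(arr, spec.in_channels, axis=1)
    return arr


def collect_stream(
    stream: Iterable[FixationMap], spec: ArchitectureSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Materialise a labelled map stream into (batch, label-index) arrays;
    the returned labels index into the sorted label set."""
    maps = list(stream)
    labels = sorted({m.label for m in maps})
    idx = np.array([labels.index(m.label) for m in maps], dtype=np.int64)
    return maps_to_batch(maps, spec), idx, labels


def evaluate_accuracy(decoder: TrainedDecoder, x: np.ndarray,
                      y: np.ndarray, batch_size: int = 256) -> float:
    correct = 0
    for i in range(0, len(x), batch_size):
        logits = decoder.forward(x[i:i + batch_size])
        correct += int((logits.argmax(axis=1) == y[i:i + batch_size]).sum())
    return correct / len(x)


def train_decoder(
    decoder: TrainedDecoder,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    config: TrainConfig,
    class_labels: Sequence[str] | None = None,
    augmentation: AugmentationSpec | None = None,
) -> TrainedDecoder:
    """Train in place and return the decoder at its best checkpoint.

    ``train_x``/``val_x`` are NCHW batches (see :func:`maps_to_batch`),
    ``train_y``/``val_y`` integer class indices. Validation accuracy is
    logged every ``config.validation_frequency_iters`` iterations and at
    the end of each epoch. With ``config.checkpoint == "final"`` (default)
    the network after the last iteration is returned — the unbiased choice
    for chance-level estimation, since selecting the best of many noisy
    checkpoints inflates accuracy under the null; ``"best"`` instead
    restores the parameters with the highest validation accuracy (ties
    broken toward the earliest checkpoint).
    """
    n_classes = decoder.architecture.n_classes
    if len(np.unique(train_y)) < n_classes:
        raise DegenerateDataError(
            f"training stream has {len(np.unique(train_y))} classes, "
            f"decoder expects {n_classes}"
        )
    rng = np.random.default_rng(config.seed)
    aug_rng = np.random.default_rng(rng.integers(2**31))
    opt = nn.SGDM(momentum=config.momentum, l2=config.l2)
    params = decoder.net.params()
    n = len(train_x)
    best = (-1.0, None)  # (val accuracy, state)
    iteration = 0

    def checkpoint(epoch: int, lr: float, loss: float) -> None:
        nonlocal best
        acc = evaluate_accuracy(decoder, val_x, val_y)
        decoder.history.append(
            {"iteration": iteration, "epoch": epoch, "lr": lr,
             "train_loss": loss, "val_accuracy": acc}
        )
        if config.checkpoint == "best" and acc > best[0]:
            best = (acc, decoder.net.state())

    for epoch in range(1, config.max_epochs + 1):
        lr = lr_at_epoch(config, epoch)
        order = rng.permutation(n) if config.shuffle_each_epoch else np.arange(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = train_x[idx]
            if augmentation is not None:
                xb = np.stack([
                    augment(FixationMap(im[0]), augmentation, aug_rng).values
                    for im in xb
                ])[:, None]
                if xb.shape[1] != decoder.architecture.in_channels:
                    xb = np.repeat(xb, decoder.architecture.in_channels, 1)
            logits = decoder.net.forward(xb, train=True)
            loss, grad = nn.softmax_cross_entropy(logits, train_y[idx])
            decoder.net.backward(grad)
            opt.step(params, lr)
            iteration += 1
            if iteration % config.validation_frequency_iters == 0:
                checkpoint(epoch, lr, loss)
        checkpoint(epoch, lr, loss)

    if best[1] is not None:
        decoder.net.load_state(best[1])
    if class_labels is not None:
        decoder.class_labels = list(class_labels)
    decoder.fingerprint = config_fingerprint(
        decoder.architecture, config, {"n_train": int(n)})
    return decoder


def predict(
    decoder: TrainedDecoder,
    maps: Sequence[FixationMap] | np.ndarray,
    batch_size: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Classify maps; returns (predicted label indices, softmax scores).

    Deterministic given the weights; the argmax resolves exact ties toward
    the first class.
    """
    x = maps_to_batch(maps, decoder.architecture)
    scores = []
    for i in range(0, len(x), batch_size):
        scores.append(nn.softmax(decoder.forward(x[i:i + batch_size])))
    scores = np.concatenate(scores, axis=0)
    return scores.argmax(axis=1), scores
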