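"""Classifier architecture and inference contract.

The network is a seven-block convolutional stack over 100x100 single-cell
grayscale crops: each block is convolution -> batch normalization -> ReLU,
with 2x2/stride-2 max-pooling interleaved, followed by one fully connected
layer and a softmax over the six cell-state classes. Early blocks use 64
filters (coarse patterns), later blocks 128 (finer detail).

Input crops are 16-bit intensities; they are scaled by 1/65535 into [0, 1]
before the first convolution so training is invariant to camera bit scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .labels import LABEL_ORDER, CellStateLabel
from .nn import SequentialCNN, softmax

INTENSITY_SCALE = 65535.0

DEFAULT_CONV_PLAN: tuple[tuple[int, int], ...] = (
    (64, 3),
    (64, 3),
    (64, 3),
    (128, 3),
    (128, 3),
    (128, 3),
    (128, 3),
)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    conv_plan: seven (filter_count, kernel_size) pairs; filter counts are 64
        or 128 with every 64 preceding every 128. Each conv block carries
        batch normalization and a ReLU.
    pool_positions: 1-based conv-block indices followed by a 2x2/stride-2
        max-pool. The default (1, 2, 3, 4) takes 100 -> 50 -> 25 -> 12 -> 6;
        pooling early keeps the wide 64-filter convolutions cheap without
        changing the final feature-map size.
    """

    conv_plan: tuple[tuple[int, int], ...] = DEFAULT_CONV_PLAN
    pool_positions: tuple[int, ...] = (1, 2, 3, 4)
    pool_size: int = 2
    pool_stride: int = 2
    n_classes: int = 6
    input_shape: tuple[int, int, int] = (100, 100, 1)

    def __post_init__(self):
        plan = tuple((int(f), int(k)) for f, k in self.conv_plan)
        object.__setattr__(self, "conv_plan", plan)
        object.__setattr__(self, "pool_positions", tuple(int(p) for p in self.pool_positions))
        object.__setattr__(self, "input_shape", tuple(int(s) for s in self.input_shape))
        if len(plan) != 7:
            raise ValueError(f"conv_plan must have exactly 7 entries, got {len(plan)}")
        filters = [f for f, _ in plan]
        if not set(filters) <= {64, 128}:
            raise ValueError("filter counts must be drawn from {64, 128}")
        if sorted(filters) != filters:
            raise ValueError("64-filter blocks must precede 128-filter blocks")
        if self.pool_size != 2 or self.pool_stride != 2:
            raise ValueError("pooling is fixed at 2x2 windows with stride 2")
        if not set(self.pool_positions) <= set(range(1, len(plan) + 1)):
            raise ValueError("pool_positions must index conv blocks 1..7")

    def to_dict(self) -> dict:
        return {
            "conv_plan": [list(p) for p in self.conv_plan],
            "pool_positions": list(self.pool_positions),
            "pool_size": self.pool_size,
            "pool_stride": self.pool_stride,
            "n_classes": self.n_classes,
            "input_shape": list(self.input_shape),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(
            conv_plan=tuple(tuple(p) for p in d["conv_plan"]),
            pool_positions=tuple(d["pool_positions"]),
            pool_size=d.get("pool_size", 2),
            pool_stride=d.get("pool_stride", 2),
            n_classes=d.get("n_classes", 6),
            input_shape=tuple(d.get("input_shape", (100, 100, 1))),
        )


@dataclass(frozen=True)
class ClassProbabilities:
    """Six-way posterior for one crop; predicted label is the argmax
    (ties broken toward the lowest class index, for determinism)."""

    probabilities: np.ndarray
    predicted_label: CellStateLabel = field(init=False)

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.shape != (len(LABEL_ORDER),):
            raise ValueError(f"expected {len(LABEL_ORDER)} probabilities, got {p.shape}")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "probabilities", p)
        object.__setattr__(self, "predicted_label", LABEL_ORDER[int(np.argmax(p))])


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> SequentialCNN:
    """Instantiate the CNN with seeded variance-scaling initialisation."""
    config = config or NetworkConfig()
    net = SequentialCNN(
        conv_plan=list(config.conv_plan),
        pool_positions=config.pool_positions,
        input_shape=config.input_shape,
        n_classes=config.n_classes,
        seed=seed,
    )
    net.config = config
    return net


def _as_batch(crops: np.ndarray, input_shape: tuple[int, int, int]) -> np.ndarray:
    x = np.asarray(crops)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[..., None]
    if x.ndim != 4 or x.shape[1:] != tuple(input_shape):
        raise ValueError(
            f"expected crops of shape {tuple(input_shape[:2])} "
            f"(got array of shape {np.asarray(crops).shape})"
        )
    return x.astype(np.float32) / np.float32(INTENSITY_SCALE)


def predict_proba(net: SequentialCNN, crops: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Inference-mode probabilities, one row per crop, in input order."""
    x = _as_batch(crops, net.input_shape)
    return net.predict_proba(x, batch_size=batch_size)


def predict(net: SequentialCNN, crop: np.ndarray) -> ClassProbabilities:
    """Classify one crop_size x crop_size crop."""
    probs = predict_proba(net, crop)
    return ClassProbabilities(probs[0])


def predict_labels(net: SequentialCNN, crops: np.ndarray, batch_size: int = 64) -> list[CellStateLabel]:
    probs = predict_proba(net, crops, batch_size=batch_size)
    return [LABEL_ORDER[i] for i in probs.argmax(axis=1)]


def save_model(net: SequentialCNN, path: str | Path) -> None:
    """Serialize weights + architecture + label mapping to one .npz file."""
    path = Path(path)
    config: NetworkConfig = getattr(net, "config", None) or NetworkConfig()
    manifest = {
        "network_config": config.to_dict(),
        "label_order": [l.value for l in LABEL_ORDER],
    }
    arrays = net.state_arrays()
    np.savez(path, __manifest__=np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> SequentialCNN:
    with np.load(path) as data:
        manifest = json.loads(bytes(data["__manifest__"]).decode())
        config = NetworkConfig.from_dict(manifest["network_config"])
        saved_order = manifest["label_order"]
        if saved_order != [l.value for l in LABEL_ORDER]:
            raise ValueError("model file was saved with an incompatible label order")
        net = build_network(config)
        net.load_state_arrays({k: data[k] for k in data.files if k != "__manifest__"})
    return net
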