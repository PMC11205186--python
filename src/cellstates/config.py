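"""Run configuration: one serializable object that replays a whole run.

A RunConfig bundles the phantom-generator, segmentation, network and
training parameters plus a master seed. Each pipeline stage derives its own
child seed from the master seed, so adding or reordering stages cannot
perturb another stage's random stream.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .model import NetworkConfig
from .segmentation import SegmentationParams
from .training import TrainingConfig


@dataclass(frozen=True)
class PhantomConfig:
    n_fields: int = 10
    cells_per_field: int = 20
    field_rows: int = 1000
    field_cols: int = 1000
    noise_sigma: float = 350.0
    background_level: float = 28000.0
    n_per_class: int = 200
    include_multiplets: bool = False


@dataclass(frozen=True)
class RunConfig:
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    seed: int = 0

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31, forked from the master
        seed; independent of the order stages run in."""
        import zlib

        ss = np.random.SeedSequence(
            self.seed, spawn_key=(zlib.crc32(stage.encode()),)
        )
        return int(ss.generate_state(1)[0] % 2**31)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "segmentation": asdict(self.segmentation),
            "network": self.network.to_dict(),
            "training": asdict(self.training),
            "phantom": asdict(self.phantom),
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            seed=int(d.get("seed", 0)),
            segmentation=SegmentationParams(**d.get("segmentation", {})),
            network=NetworkConfig.from_dict(d["network"])
            if "network" in d
            else NetworkConfig(),
            training=TrainingConfig(**d.get("training", {})),
            phantom=PhantomConfig(**d.get("phantom", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
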