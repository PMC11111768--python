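"""Single-file YAML configuration tying the pipeline stages together.

Defaults reproduce the published operating point: clip percentiles 1/99,
normalisation floor/ceiling 10/90, 128-voxel input patches (88 output),
leaky-ReLU slope 0.20, loss weights alpha = (1, 10), Adam learning rate
0.001, and a 15% subject-level validation split.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .losses import LossConfig
from .network import ModelConfig
from .preprocess import NormalizationParams
from .training import TrainConfig


@dataclass(frozen=True)
class PipelineConfig:
    normalization: NormalizationParams = field(default_factory=NormalizationParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    bias_order: int = 2
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "normalization": asdict(self.normalization),
            "model": {**asdict(self.model), "heads": [list(h) for h in self.model.heads]},
            "train": asdict(self.train),
            "loss": {
                "alpha_tissue": self.loss.alpha_tissue,
                "alpha_structural": self.loss.alpha_structural,
                "dice_eps": self.loss.dice_eps,
            },
            "bias_order": self.bias_order,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        model = dict(doc.get("model", {}))
        if "heads" in model:
            model["heads"] = tuple(tuple(h) for h in model["heads"])
        return cls(
            normalization=NormalizationParams(**doc.get("normalization", {})),
            model=ModelConfig(**model),
            train=TrainConfig(**doc.get("train", {})),
            loss=LossConfig(**doc.get("loss", {})),
            bias_order=int(doc.get("bias_order", 2)),
            seed=int(doc.get("seed", 0)),
        )
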