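"""Configuration objects shared across the pipeline.

Every tunable the pipeline exposes lives in one of the dataclasses below so a
run can be serialized, echoed into its output directory, and replayed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Any


@dataclass
class ModelConfig:
    """Architecture constants of the dual-branch fusion network.

    The environment branch consumes RGB scene images downsampled by the
    resolution factor ``beta`` (224 * 6/7 = 192 px).  The motion branch
    consumes GADF pseudo-images and is thinned by the width factor ``alpha``
    (channel counts scaled by 0.75, rounded to a multiple of 8).
    """

    alpha: float = 0.75
    beta: float = float(Fraction(6, 7))
    base_resolution: int = 224
    num_classes: int = 9
    se_ratio: int = 16
    stat_dim_in: int = 63
    stat_dim_out: int = 256
    gadf_input_side: int = 224
    use_env: bool = True
    use_gadf: bool = True
    use_stats: bool = True
    seed: int = 0

    @property
    def env_input_side(self) -> int:
        return round(self.base_resolution * self.beta)

    def validate(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.env_input_side % 32 != 0:
            raise ValueError(
                f"environment input side {self.env_input_side} not divisible "
                "by 32 (the backbone downsamples x32)"
            )
        if self.use_gadf and self.gadf_input_side % 32 != 0:
            raise ValueError(
                f"GADF input side {self.gadf_input_side} not divisible by 32"
            )
        if not (self.use_env or self.use_gadf or self.use_stats):
            raise ValueError("at least one input modality must be enabled")


@dataclass
class TrainConfig:
    """SGD-with-momentum training hyperparameters."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 32
    epochs: int = 30
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")


@dataclass
class SyntheticDatasetSpec:
    """Size and sampling parameters of the synthetic paired dataset.

    Defaults mirror the collection protocol the generator emulates:
    30 subjects x 300 pairs of (6 s, 50 Hz) acceleration windows with one
    keyframe image each, balanced over the nine hazard classes.
    """

    n_subjects: int = 30
    pairs_per_subject: int = 300
    sample_rate: float = 50.0
    window_s: float = 6.0
    image_side: int = 224
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1 or self.pairs_per_subject < 1:
            raise ValueError("n_subjects and pairs_per_subject must be >= 1")
        if self.sample_rate <= 0 or self.window_s <= 0:
            raise ValueError("sample_rate and window_s must be > 0")
        if self.image_side < 32:
            raise ValueError("image_side must be >= 32")


@dataclass
class GateConfig:
    """Decision-tree hyperparameters for the camera-activation gate."""

    criterion: str = "gini"
    max_depth: int = 8
    min_samples_leaf: int = 5
    seed: int = 0


@dataclass
class RunConfig:
    """Top-level config tying all sections together for a CLI run."""

    generator: SyntheticDatasetSpec = field(default_factory=SyntheticDatasetSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    gate: GateConfig = field(default_factory=GateConfig)
    seed: int = 0
    output_dir: str = "runs"

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        sections = {
            "generator": SyntheticDatasetSpec,
            "model": ModelConfig,
            "training": TrainConfig,
            "gate": GateConfig,
        }
        for key, value in d.items():
            if key in sections:
                kwargs[key] = sections[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)
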