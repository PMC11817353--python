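"""Pipeline configuration: one nested, strictly validated document.

Every block mirrors the parameter object of one pipeline stage, with
identical defaults, so an empty config file reproduces the package
defaults exactly.  Unknown keys are rejected.  A single master seed derives
per-stage seeds by CRC-hashing the stage name, so stages are individually
reproducible.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .convmixer import ModelConfig, TrainOptions
from .relieff import ReliefFParams
from .spectrogram import SpectrogramParams
from .synthetic import DEFAULT_CLASS_COUNTS, GeneratorConfig
from .wsse import SVMOptions


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeneratorBlock(_Block):
    fs: float = 500.0
    duration: float = 10.0
    heart_rate_bpm: tuple[float, float] = (55.0, 95.0)
    st_shift_mv: float = 0.15
    t_inversion_prob: float = 0.5
    noise_sd_mv: float = 0.02
    baseline_wander_mv: float = 0.05
    per_class_counts: tuple[int, ...] = DEFAULT_CLASS_COUNTS

    def build(self, seed: int) -> GeneratorConfig:
        return GeneratorConfig(seed=seed, **self.model_dump())


class SpectrogramBlock(_Block):
    window: int = 10
    hop: int = 5
    nfft: int = 512
    fs: float = 500.0
    colormap: str = "viridis"
    out_size: int = 64
    dynamic_range_db: float = 80.0

    def build(self) -> SpectrogramParams:
        return SpectrogramParams(**self.model_dump())


class ModelBlock(_Block):
    input_size: int = 64
    patch_sizes: tuple[int, ...] = (16, 8)
    hidden: int = 32
    kernel: int = 3
    depth: int = 4
    embed_dim: int = 1000

    def build(self) -> ModelConfig:
        return ModelConfig(**self.model_dump())


class TrainBlock(_Block):
    epochs: int = 100
    minibatch: int = 128
    initial_lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 1e-4
    validation_fraction: float = 0.1
    validation_frequency: int = 30

    def build(self, seed: int) -> TrainOptions:
        return TrainOptions(seed=seed, **self.model_dump())


class ReliefFBlock(_Block):
    k_neighbors: int = 10
    sigma: float = 20.0

    def build(self) -> ReliefFParams:
        return ReliefFParams(**self.model_dump())


class WSSEBlock(_Block):
    k: int = 10
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    standardize: bool = True
    vote_mode: str = "mass"

    def svm_options(self) -> SVMOptions:
        return SVMOptions(
            kernel=self.kernel, C=self.C, gamma=self.gamma,
            standardize=self.standardize,
        )


class EvaluationBlock(_Block):
    folds: int = 10
    top_q: int = 500
    arms: tuple[str, ...] = ("a", "b", "c", "d")

    @field_validator("folds")
    @classmethod
    def _folds_ge_2(cls, v: int) -> int:
        if v < 2:
            raise ValueError("folds must be >= 2")
        return v

    @field_validator("arms")
    @classmethod
    def _known_arms(cls, v):
        bad = set(v) - {"a", "b", "c", "d"}
        if bad:
            raise ValueError(f"unknown arms {sorted(bad)}")
        return v


class PipelineConfig(_Block):
    seed: int = 17
    out_dir: str = "coromix_out"
    self_check: bool = False
    generator: GeneratorBlock = Field(default_factory=GeneratorBlock)
    spectrogram: SpectrogramBlock = Field(default_factory=SpectrogramBlock)
    model: ModelBlock = Field(default_factory=ModelBlock)
    train: TrainBlock = Field(default_factory=TrainBlock)
    relieff: ReliefFBlock = Field(default_factory=ReliefFBlock)
    wsse: WSSEBlock = Field(default_factory=WSSEBlock)
    evaluation: EvaluationBlock = Field(default_factory=EvaluationBlock)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2^31."""
        return (self.seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            json.loads(self.model_dump_json()), sort_keys=False
        )


def desk_scale_config(seed: int = 17, out_dir: str = "coromix_out") -> PipelineConfig:
    """The reduced configuration used for end-to-end runs on one CPU.

    35 records per class, a 16-channel depth-2 model, 10 epochs in
    minibatches of 8, and 3 folds.  With ~150-sample training folds the
    batch of 8 yields a few hundred SGD updates inside the 10-epoch budget;
    the reference batch of 128 would yield only ~20, far too few to train
    from scratch.  Everything else keeps the package defaults.
    """
    return PipelineConfig(
        seed=seed,
        out_dir=out_dir,
        generator=GeneratorBlock(per_class_counts=(35,) * 7),
        model=ModelBlock(hidden=16, depth=2),
        train=TrainBlock(epochs=10, minibatch=8),
        evaluation=EvaluationBlock(folds=3),
    )


def load_config(path: str | Path | None = None, text: str | None = None) -> PipelineConfig:
    """Load a YAML or JSON config; missing keys take their defaults.

    An empty (or absent) document yields all defaults; unknown keys raise a
    validation error naming the key.
    """
    if text is None:
        if path is None:
            return PipelineConfig()
        text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return PipelineConfig()
    if not isinstance(data, dict):
        raise ValueError("config document must be a mapping")
    return PipelineConfig(**data)
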