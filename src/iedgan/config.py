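"""Run configuration: one nested, strictly validated document, one global seed.

All stage seeds derive deterministically from the single global seed, so a run
is reproducible from its config file alone.  Unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .detector import DetectorConfig
from .synthesis import SynthesisConfig
from .translator import TranslatorConfig

__all__ = ["RunConfig", "load_config", "save_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SynthesisSection(_Strict):
    n_subjects: int = 6
    duration_s: float = 300.0
    sampling_rate: float = 200.0
    n_ieds_per_subject: int | None = 200
    visibility_fraction: float = 0.15
    ieeg_snr_db: float = 26.0
    seeg_attenuation: float = 0.45
    noise_color_exponent: float = 1.0
    artifact_rate: float = 3.0
    noise_scale: float = 1.0


class TranslatorSection(_Strict):
    base_feature_channels: int = 16
    n_levels: int = 3
    kernel_time: int = 5
    lambda_l2: float = 100.0
    squared_l2: bool = False
    dropout_rate: float = 0.25
    learning_rate: float = 1e-3
    adam_beta1: float = 0.5
    batch_size: int = 32
    n_epochs: int = 30
    adversarial_mode: str = "non_saturating"


class DetectorSection(_Strict):
    temporal_filters: int = 8
    depth_multiplier: int = 2
    separable_filters: int = 16
    temporal_kernel: int = 32
    separable_kernel: int = 16
    dropout_rate: float = 0.25
    learning_rate: float = 1e-3
    batch_size: int = 32
    n_epochs: int = 30


class EvaluationSection(_Strict):
    threshold: float = 0.70
    fractions: list[float] = Field(default_factory=lambda: [0.7, 0.1, 0.2])


class PathsSection(_Strict):
    cohort_dir: str = "cohort"
    out_dir: str = "runs"


class RunConfig(_Strict):
    seed: int = 0
    synthesis: SynthesisSection = Field(default_factory=SynthesisSection)
    translator: TranslatorSection = Field(default_factory=TranslatorSection)
    detector: DetectorSection = Field(default_factory=DetectorSection)
    evaluation: EvaluationSection = Field(default_factory=EvaluationSection)
    paths: PathsSection = Field(default_factory=PathsSection)

    # stage seeds derive from the global seed by fixed offsets
    def synthesis_config(self, seed: int | None = None) -> SynthesisConfig:
        base = self.seed if seed is None else seed
        return SynthesisConfig(**self.synthesis.model_dump(), seed=base + 1)

    def translator_config(self, seed: int | None = None) -> TranslatorConfig:
        base = self.seed if seed is None else seed
        return TranslatorConfig(**self.translator.model_dump(), seed=base + 2)

    def detector_config(self, seed: int | None = None) -> DetectorConfig:
        base = self.seed if seed is None else seed
        return DetectorConfig(**self.detector.model_dump(), seed=base + 3)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    doc = yaml.safe_load(Path(path).read_text())
    return RunConfig.model_validate(doc or {})


def save_config(cfg: RunConfig, path: str | Path):
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
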