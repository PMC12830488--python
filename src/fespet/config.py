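"""Run configuration: a single human-readable YAML file drives the pipeline.

Unknown keys are rejected (pydantic ``extra="forbid"``), so typos fail fast.
The config plus the seed fully determine every artifact; a SHA-256 hash of
the canonical serialized config is embedded in the run manifest.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .schedule import DEFAULT_FRAME_DURATIONS_S

__all__ = ["RunConfig", "CohortConfig", "SelectionConfig", "load_config"]


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_pre: int = 18
    n_peri: int = 18
    n_post: int = 19
    post_vs_pre_ratio: float = 1.36
    noise_scale: float = 0.1
    late_noise_slope: float = 0.0
    binding_correlation: float = 0.6


class SelectionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    entry_p: float = 0.05
    removal_p: float = 0.10
    entry_adjust: str = "bonferroni"
    lasso_cv_folds: int = 10
    lambda_rule: str = "min"


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    outdir: str = "fespet_run"
    frame_durations_s: list[int] = Field(
        default_factory=lambda: list(DEFAULT_FRAME_DURATIONS_S)
    )
    windows_min: list[tuple[float, float]] = Field(
        default_factory=lambda: [(30, 50), (40, 60), (50, 70), (60, 80), (70, 90)]
    )
    t_star_min: float = 30.0
    k2prime: float | None = None
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    selection: SelectionConfig = Field(default_factory=SelectionConfig)
    make_plots: bool = True

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        data = self.model_dump(mode="json")
        data.pop("outdir", None)
        text = yaml.safe_dump(data, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def load_config(path=None, **overrides) -> RunConfig:
    cfg = RunConfig.from_yaml(path) if path else RunConfig()
    if overrides:
        cfg = cfg.model_copy(update=overrides)
    return cfg
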