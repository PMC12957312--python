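"""Structured run configuration shared by the CLI subcommands.

All pipeline defaults live here: 10 ms bins, 50 ms smoothing, p = 20
demixed components, 16 latent dimensions, 10 label shuffles, the 90% /
15-trial behavioral criterion, and the seeds.  Unknown keys are
rejected so a typo in a YAML file fails loudly.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bin_ms: float = Field(10.0, gt=0)
    sigma_ms: float = Field(50.0, gt=0)
    epoch_bins: int = Field(100, ge=1)
    p: int = Field(20, ge=1)
    latent_dim: int = Field(16, ge=1)
    n_shuffles: int = Field(10, ge=1)
    criterion_threshold: float = Field(0.9, ge=0.0, le=1.0)
    criterion_window: int = Field(15, ge=1)
    ridge: float | None = Field(None, ge=0.0)
    seed: int = 0

    # simulator conditions
    n_units: int = Field(60, ge=1)
    n_stimuli_per_task: int = Field(2, ge=1)
    tasks: list[str] = ["A", "B", "Revisit-A", "Reverse-A"]
    trials_per_condition: int = Field(50, ge=1)
    baseline_rate: float = Field(12.0, gt=0)
    signal_gain: float = 1.0
    target_angle_deg: float = Field(80.0, ge=0.0, le=90.0)
    reuse_rho: float = Field(0.9, ge=-1.0, le=1.0)


def load_config(path=None, **overrides) -> RunConfig:
    """Load a YAML/JSON config file (missing path = all defaults) and
    apply keyword overrides."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=False))
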