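"""Run configuration: a validated, fully-defaulted parameter set.

Configs are plain YAML key-value files. Unknown keys are rejected, types
are checked, and every random stage carries an explicit seed, so a run is
fully reproducible from its config alone.
"""

from __future__ import annotations

from pathlib import Path
from typing import List

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PIRConfig(_Strict):
    rho_grid: List[float] = Field(default=[0.1, 0.3, 0.5, 0.9])
    depth: float = Field(default=50_000.0, gt=0)
    read_length: int = Field(default=100, ge=20)
    min_anchor: int = Field(default=8, ge=1)
    min_total: int = Field(default=15, ge=1)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    n_replicates: int = Field(default=25, ge=1)

    @field_validator("rho_grid")
    @classmethod
    def _rho_range(cls, v):
        if not v or any(not (0 <= r <= 1) for r in v):
            raise ValueError("rho_grid values must lie in [0, 1]")
        return v


class FishConfig(_Strict):
    n_fields: int = Field(default=4, ge=1)
    n_signals: int = Field(default=50, ge=0)
    n_cells: int = Field(default=4, ge=1)
    snr: float = Field(default=10.0, gt=0)
    radius: float = Field(default=3.0, ge=0)
    sigma: float = Field(default=1.3, gt=0)


class RunConfig(_Strict):
    """Top-level benchmark configuration."""

    seed: int = Field(default=0, ge=0)
    stages: List[str] = Field(default=["pir", "fish", "stats"])
    outdir: str = Field(default="pirfish_run")
    pir: PIRConfig = Field(default_factory=PIRConfig)
    fish: FishConfig = Field(default_factory=FishConfig)

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v):
        known = {"pir", "fish", "stats"}
        bad = [s for s in v if s not in known]
        if bad:
            raise ValueError(f"unknown stages {bad}; known: {sorted(known)}")
        return v


def validate_config(path_or_mapping) -> RunConfig:
    """Load, type-check and default-fill a run config.

    Accepts a YAML file path or an already-parsed mapping. An empty file
    yields the full defaults; unknown keys or wrong types raise a
    validation error naming the offending key. Idempotent: validating a
    normalized config reproduces it.
    """
    if isinstance(path_or_mapping, (str, Path)):
        text = Path(path_or_mapping).read_text()
        data = yaml.safe_load(text) or {}
    elif path_or_mapping is None:
        data = {}
    else:
        data = dict(path_or_mapping)
    return RunConfig.model_validate(data)


def config_hash(config: RunConfig) -> str:
    import hashlib

    payload = config.model_dump_json().encode()
    return hashlib.sha256(payload).hexdigest()[:16]
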