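"""Run configuration: JSON loading, validation, and output writing.

A :class:`RunConfig` gathers everything a study run needs — scenario name,
modes, model choices, session geometry, difficulty bounds, heart-rate
ceiling and the rule-model constants.  Unknown keys are rejected and every
numeric field is range-checked; validation errors carry the field path.
Outputs are a per-game trace CSV, a metrics JSON, and a manifest with
content hashes so identical runs are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigError
from .study import StudyResult


class StepConfig(BaseModel):
    """Rule-model step constants (dimensionless difficulty units)."""

    model_config = ConfigDict(extra="forbid")

    constant_step: float = Field(0.01, gt=0, le=0.5)
    slope_gain: float = Field(0.5, gt=0)
    max_step: float = Field(0.08, gt=0, le=0.5)
    hr_over_step: float = Field(0.05, gt=0, le=0.5)
    realtime_step: float = Field(0.02, gt=0, le=0.5)
    rising_threshold: float = Field(1.0, ge=0)


class RunConfig(BaseModel):
    """Validated study-run configuration with documented defaults."""

    model_config = ConfigDict(extra="forbid")

    scenario: str = "fig10_rising"
    modes: list[Literal["offline", "realtime"]] = ["offline", "realtime"]
    offline_model: str = "offline_score_hr"
    realtime_model: str = "realtime_score_hr"
    out_dir: str = "out"

    session_length: int = Field(60, ge=1)
    d_start: float = Field(0.8, gt=0)
    d_min: float = Field(0.2, gt=0)
    d_max: float = Field(1.6, gt=0)
    hr_max: float = Field(180.0, gt=0)
    t_eval: int = Field(5, ge=1)
    ewma_alpha: float = Field(0.3, gt=0, le=1)
    window: int = Field(5, ge=2)
    dead_band: float = Field(0.05, ge=0)
    steps: StepConfig = StepConfig()

    @model_validator(mode="after")
    def _check_bounds(self) -> "RunConfig":
        if not self.d_min < self.d_max:
            raise ValueError(f"d_min ({self.d_min}) must be < d_max ({self.d_max})")
        if not self.d_min <= self.d_start <= self.d_max:
            raise ValueError(
                f"d_start ({self.d_start}) must lie in [{self.d_min}, {self.d_max}]"
            )
        return self

    def rule_params(self):
        from .personalizer import RuleParams

        return RuleParams(
            constant_step=self.steps.constant_step,
            slope_gain=self.steps.slope_gain,
            max_step=self.steps.max_step,
            hr_over_step=self.steps.hr_over_step,
            realtime_step=self.steps.realtime_step,
            t_eval=self.t_eval,
            ewma_alpha=self.ewma_alpha,
            rising_threshold=self.steps.rising_threshold,
            trend_window=self.window,
            dead_band=self.dead_band,
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}") from None
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path}: not valid JSON: {exc}") from None
    return parse_config(raw)


def parse_config(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        details = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration: {details}") from None


def dump_config(cfg: RunConfig) -> dict:
    return cfg.model_dump()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(result: StudyResult, out_dir: str | Path) -> dict:
    """Write trace CSV + metrics JSON + hash manifest for one study result.

    Re-running on identical inputs yields identical hashes (the loop is
    deterministic and the CSV dialect fixed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mode = result.mode.value
    trace_path = out / f"trace_{mode}.csv"
    result.trace_frame().to_csv(trace_path, index=False, float_format="%.17g")
    metrics_path = out / f"metrics_{mode}.json"
    metrics_path.write_text(json.dumps(result.metrics, indent=2, sort_keys=True) + "\n")
    manifest = {
        "scenario": result.scenario,
        "mode": mode,
        "files": {
            p.name: _sha256(p) for p in (trace_path, metrics_path)
        },
    }
    manifest_path = out / f"manifest_{mode}.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
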