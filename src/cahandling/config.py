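"""Versioned, schema-validated analysis configuration.

Every report embeds the resolved configuration, so a run is reproducible
from config + seed alone.  Unknown keys are rejected (fail-fast) rather
than silently ignored.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .calibration import CalibrationCurve

__all__ = ["CalibrationConfig", "AnalysisConfig"]


class CalibrationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    r_min: float = 1.0
    r_max: float = 3.0
    kd_um: float = 0.4
    sat_ratio: float = 2.4
    name: str = "furared-default"


class AnalysisConfig(BaseModel):
    """All tunables of the analysis pipeline, with units in field names."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    beta: float = 100.0  # cytoplasmic buffering capacity, dimensionless
    mode: Literal["ncx-subtracted", "lumped"] = "ncx-subtracted"
    discard_first_n: int = 2  # pre-steady-state beats dropped before averaging
    pre_window_s: float = 0.05  # segment lead-in before each stimulus
    diastolic_window_s: float = 0.05  # pre-stimulus window for diastolic Ca
    resting_window_s: Tuple[float, float] = (2.0, 0.5)  # (start, end) before caffeine onset
    peak_search_s: float = 2.0  # caffeine peak search window after onset
    fit_window: Tuple[float, float] = (0.9, 0.1)  # amplitude fractions for flux fits
    smooth_window_cat: int = 21  # Savitzky-Golay samples, paced-transient flux
    smooth_window_caff: int = 101  # Savitzky-Golay samples, caffeine flux
    prominence_factor: float = 4.0  # detection threshold, robust noise s.d. units
    min_peak_separation_s: float = 0.2
    recovery_fraction: float = 0.9  # fraction for the CaT recovery-time metric
    seed: int = 0

    @field_validator("beta")
    @classmethod
    def _beta_ge_1(cls, v: float) -> float:
        if v < 1:
            raise ValueError("beta must be >= 1")
        return v

    @field_validator("smooth_window_cat", "smooth_window_caff")
    @classmethod
    def _odd_window(cls, v: int) -> int:
        if v < 5 or v % 2 == 0:
            raise ValueError("smoothing windows must be odd and >= 5")
        return v

    def curve(self) -> CalibrationCurve:
        c = self.calibration
        return CalibrationCurve(
            r_min=c.r_min, r_max=c.r_max, kd=c.kd_um, sat_ratio=c.sat_ratio, name=c.name
        )

    @classmethod
    def with_curve(cls, curve: CalibrationCurve, beta: float = 100.0, **kwargs) -> "AnalysisConfig":
        return cls(
            calibration=CalibrationConfig(
                r_min=curve.r_min,
                r_max=curve.r_max,
                kd_um=curve.kd,
                sat_ratio=curve.sat_ratio,
                name=curve.name,
            ),
            beta=beta,
            **kwargs,
        )

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.model_validate(data or {})

    def to_file(self, path) -> None:
        path = Path(path)
        data = self.model_dump()
        if path.suffix.lower() in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(data, sort_keys=True))
        else:
            path.write_text(json.dumps(data, indent=2, sort_keys=True))
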