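"""File formats: trace CSV + JSON sidecar, TIFF stacks, report output.

Traces are stored as plain CSV (columns ``time_s`` and either
``ch_num``/``ch_den`` or ``ratio``) with a JSON sidecar of the same stem
carrying protocol metadata (stimulus times, caffeine onset, dye,
calibration id, backgrounds).  Full ``%.17g`` precision makes the round
trip lossless and byte-reproducible.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .calibration import FluorescenceTrace

__all__ = ["TraceSchemaError", "write_trace", "read_trace", "write_stack", "read_stack"]

_SIDECAR_SCHEMA = "cahandling-trace-v1"


class TraceSchemaError(ValueError):
    """A trace file is missing required columns or metadata."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace(trace: FluorescenceTrace, path) -> Path:
    """Write a trace as CSV plus JSON sidecar; returns the CSV path."""
    path = Path(path)
    cols = {"time_s": trace.time}
    if trace.has_channels:
        cols["ch_num"] = trace.ch_num
        cols["ch_den"] = trace.ch_den
    else:
        cols["ratio"] = trace.ratio
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    meta = {
        "schema": _SIDECAR_SCHEMA,
        "stimulus_times_s": [float(s) for s in trace.stimulus_times],
        "caffeine_onset_s": trace.caffeine_onset,
        "dye": trace.dye,
        "calibration_id": trace.calibration_id,
        "bg_num": trace.bg_num,
        "bg_den": trace.bg_den,
        "meta": trace.meta,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_trace(path) -> FluorescenceTrace:
    """Read a trace CSV (+ sidecar if present); schema errors name the columns."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "time_s" not in df.columns:
        raise TraceSchemaError(f"{path.name}: missing required column 'time_s'")
    has_channels = {"ch_num", "ch_den"}.issubset(df.columns)
    has_ratio = "ratio" in df.columns
    if not has_channels and not has_ratio:
        raise TraceSchemaError(
            f"{path.name}: need columns 'ch_num'+'ch_den' or 'ratio'"
        )
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    inner = meta.get("meta", {})
    return FluorescenceTrace(
        time=df["time_s"].to_numpy(),
        ch_num=df["ch_num"].to_numpy() if has_channels else None,
        ch_den=df["ch_den"].to_numpy() if has_channels else None,
        ratio=df["ratio"].to_numpy() if (has_ratio and not has_channels) else None,
        bg_num=float(meta.get("bg_num", 0.0)),
        bg_den=float(meta.get("bg_den", 0.0)),
        stimulus_times=np.asarray(meta.get("stimulus_times_s", []), dtype=float),
        caffeine_onset=meta.get("caffeine_onset_s"),
        dye=meta.get("dye", "unknown"),
        calibration_id=meta.get("calibration_id"),
        meta=inner,
    )


def write_stack(stack: np.ndarray, path) -> Path:
    """Write an image stack as multi-page TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))
    return path


def read_stack(path) -> np.ndarray:
    return tifffile.imread(Path(path))
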