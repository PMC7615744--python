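"""Ratiometric dye calibration: channel ratios and the hyperbolic ratio<->Ca map.

Dual-excitation Ca2+ dyes such as FuraRed report free cytosolic [Ca2+]
through the ratio ``R`` of two background-subtracted emission intensities.
For a 1:1 Ca-dye complex the calibration is the hyperbola

    ca = Kd * (R - Rmin) / (Rmax - R)

where ``Rmin``/``Rmax`` are the ratios of the Ca-free and Ca-saturated dye
and ``Kd`` is the apparent dissociation constant (uM).  A ratiometric
readout cancels dye loading and pathlength, which is what makes per-cell
comparisons between experimental groups meaningful.  The flip side of a
low-Kd red-shifted dye is poor resolving power at high Ca2+: above a
saturation ratio (2.4 for FuraRed) calibrated values are no longer
trustworthy, so every sample above it carries an explicit ``saturated``
flag that downstream metrics must propagate.

Units are fixed package-wide: seconds for time, uM for Ca2+.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CalibrationError",
    "EmptySignalError",
    "CalibrationCurve",
    "DEFAULT_CURVE",
    "FluorescenceTrace",
    "compute_ratio",
    "ratio_to_ca",
    "ca_to_ratio",
]


class CalibrationError(ValueError):
    """Invalid calibration constants or uncalibratable input."""


class EmptySignalError(CalibrationError):
    """Every sample of a ratio computation was masked."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Hyperbolic ratio<->Ca2+ map with an explicit saturation threshold.

    Parameters
    ----------
    r_min, r_max : float
        Ratios of the Ca-free and Ca-saturated dye.
    kd : float
        Apparent dissociation constant, uM.  ``ratio_to_ca`` returns ``kd``
        at the midpoint ratio ``(r_min + r_max) / 2``.
    sat_ratio : float
        Ratios above this are flagged saturated.  The default of 2.4 is the
        published FuraRed bound; ``r_min``/``r_max``/``kd`` defaults are
        plain placeholders and should be overridden with the constants of
        the actual calibration — every report records the curve it used.
    """

    r_min: float = 1.0
    r_max: float = 3.0
    kd: float = 0.4
    sat_ratio: float = 2.4
    name: str = "furared-default"

    def __post_init__(self) -> None:
        if not self.kd > 0:
            raise CalibrationError(f"kd must be > 0, got {self.kd}")
        if not (self.r_min < self.sat_ratio <= self.r_max):
            raise CalibrationError(
                f"need r_min < sat_ratio <= r_max, got "
                f"r_min={self.r_min}, sat_ratio={self.sat_ratio}, r_max={self.r_max}"
            )

    @property
    def ca_at_saturation(self) -> float:
        """Free [Ca2+] (uM) at the saturation ratio; the cap for r >= r_max."""
        return self.kd * (self.sat_ratio - self.r_min) / (self.r_max - self.sat_ratio)

    def to_dict(self) -> dict:
        return {
            "r_min": self.r_min,
            "r_max": self.r_max,
            "kd_um": self.kd,
            "sat_ratio": self.sat_ratio,
            "name": self.name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationCurve":
        return cls(
            r_min=float(d["r_min"]),
            r_max=float(d["r_max"]),
            kd=float(d.get("kd_um", d.get("kd"))),
            sat_ratio=float(d["sat_ratio"]),
            name=str(d.get("name", "custom")),
        )


DEFAULT_CURVE = CalibrationCurve()


def compute_ratio(ch_num, ch_den, bg_num: float = 0.0, bg_den: float = 0.0):
    """Background-subtracted ratio of two emission channels.

    ``(ch_num - bg_num) / (ch_den - bg_den)`` per sample.  Samples whose
    denominator is <= 0 after background subtraction are masked (NaN), not
    raised; an all-masked result raises :class:`EmptySignalError`.
    """
    num = np.asarray(ch_num, dtype=float) - float(bg_num)
    den = np.asarray(ch_den, dtype=float) - float(bg_den)
    if num.shape != den.shape:
        raise CalibrationError(
            f"channel length mismatch: {num.shape} vs {den.shape}"
        )
    if bg_num < 0 or bg_den < 0:
        raise CalibrationError("background levels must be >= 0")
    good = den > 0
    ratio = np.full(num.shape, np.nan)
    np.divide(num, den, out=ratio, where=good)
    if not np.any(np.isfinite(ratio)):
        raise EmptySignalError("all samples masked: denominator <= 0 everywhere")
    return ratio


def ratio_to_ca(r, curve: CalibrationCurve = DEFAULT_CURVE):
    """Convert ratio(s) to free [Ca2+] (uM) with saturation flags.

    Returns ``(ca, saturated)``.  ``ca = kd*(r - r_min)/(r_max - r)``,
    clipped to >= 0.  Ratios above ``sat_ratio`` are flagged; ratios at or
    above ``r_max`` are additionally capped at the value at ``sat_ratio``
    (never infinity) so that peak *timing* stays usable while peak *values*
    are marked unreliable.  NaN passes through as NaN, unflagged.
    """
    arr = np.asarray(r, dtype=float)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    saturated = arr > curve.sat_ratio
    with np.errstate(divide="ignore", invalid="ignore"):
        ca = curve.kd * (arr - curve.r_min) / (curve.r_max - arr)
    ca = np.clip(ca, 0.0, None)
    ca = np.where(arr >= curve.r_max, curve.ca_at_saturation, ca)
    ca = np.where(np.isnan(arr), np.nan, ca)
    if scalar:
        return float(ca[0]), bool(saturated[0])
    return ca, saturated


def ca_to_ratio(ca, curve: CalibrationCurve = DEFAULT_CURVE):
    """Inverse calibration map: free [Ca2+] (uM) -> ratio.

    ``r = (r_min*kd + r_max*ca) / (kd + ca)``; exact inverse of
    :func:`ratio_to_ca` below saturation, with ``r -> r_max`` as
    ``ca -> inf``.
    """
    arr = np.asarray(ca, dtype=float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise CalibrationError("ca must be >= 0")
    r = (curve.r_min * curve.kd + curve.r_max * arr) / (curve.kd + arr)
    if arr.ndim == 0:
        return float(r)
    return r


@dataclass
class FluorescenceTrace:
    """A sampled recording (two channels or a precomputed ratio) plus protocol metadata.

    ``stimulus_times`` and ``caffeine_onset`` (seconds, same clock as
    ``time``) anchor segmentation downstream; either channel pair or ratio
    must be present.  Background levels travel with the trace so that
    subtraction happens exactly once.
    """

    time: np.ndarray
    ch_num: Optional[np.ndarray] = None
    ch_den: Optional[np.ndarray] = None
    ratio: Optional[np.ndarray] = None
    bg_num: float = 0.0
    bg_den: float = 0.0
    stimulus_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    caffeine_onset: Optional[float] = None
    dye: str = "FuraRed"
    calibration_id: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in ("ch_num", "ch_den", "ratio"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.time.shape:
                    raise CalibrationError(f"{name} length differs from time")
                setattr(self, name, v)
        self.stimulus_times = np.asarray(self.stimulus_times, dtype=float)
        if self.time.size < 2 or not np.all(np.diff(self.time) > 0):
            raise CalibrationError("time must be strictly increasing with >= 2 samples")
        if self.ratio is None and (self.ch_num is None or self.ch_den is None):
            raise CalibrationError("need either both channels or a ratio")

    @property
    def has_channels(self) -> bool:
        return self.ch_num is not None and self.ch_den is not None

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))

    def get_ratio(self) -> np.ndarray:
        """Ratio series; computed from channels (with background removal) if needed."""
        if self.ratio is not None:
            return self.ratio
        return compute_ratio(self.ch_num, self.ch_den, self.bg_num, self.bg_den)

    def calibrate(self, curve: CalibrationCurve = DEFAULT_CURVE):
        """Return ``(ca_um, saturated)`` for the whole trace."""
        return ratio_to_ca(self.get_ratio(), curve)
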