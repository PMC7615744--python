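"""Buffering-scaled flux curves and the SERCA/NCX/backflux/leak decomposition.

The core inference: during the recovery phase of a Ca2+ event the total
removal flux is ``-beta * dc/dt`` (uM total / s), where ``beta`` is the
constant cytoplasmic buffering capacity.  Plotting that flux against the
concurrent free [Ca2+] and fitting a line gives a rate constant (s^-1) —
the slope — for the removal pathway that dominates the event:

* paced-transient recovery: SERCA + NCX (``ncx-subtracted`` mode removes
  the caffeine-derived NCX slope to isolate SERCA; ``lumped`` reports the
  raw slope);
* caffeine-transient recovery (SR emptied, SERCA futile): NCX alone.

Two constant balancing fluxes complete the decomposition: SR backflux,
the rate required to balance SERCA at diastolic [Ca2+]
(``k_serca * diastolic``), and sarcolemmal leak, the rate required to
balance NCX at resting [Ca2+] (``k_ncx * resting``).  Differentiation is
by Savitzky-Golay local-quadratic smoothing rather than raw finite
differences; the fit window, smoothing width and buffering capacity are
recorded in every report's provenance.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import stats
from scipy.signal import savgol_filter

from ._version import __version__
from .calibration import DEFAULT_CURVE, CalibrationCurve, FluorescenceTrace, ratio_to_ca
from .transients import (
    CaffeineTransient,
    CaTransient,
    EmptyResultError,
    TransientError,
    average_transients,
    detect_caffeine_transient,
    detect_transients,
    fractional_release,
)

__all__ = [
    "FluxError",
    "InsufficientDataError",
    "DegenerateFitError",
    "StageError",
    "BufferingModel",
    "FluxFit",
    "NcxResult",
    "SercaResult",
    "CaHandlingReport",
    "recovery_flux_curve",
    "fit_rate_constant",
    "ncx_analysis",
    "serca_analysis",
    "full_report",
]


class FluxError(ValueError):
    pass


class InsufficientDataError(FluxError):
    """Fewer than three usable points in the fit window."""


class DegenerateFitError(FluxError):
    """Zero variance in [Ca2+]; no slope is defined."""


class StageError(RuntimeError):
    """Wraps a pipeline-stage failure with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class BufferingModel:
    """Constant cytoplasmic buffering capacity (dimensionless, >= 1)."""

    beta: float = 100.0

    def __post_init__(self) -> None:
        if not self.beta >= 1:
            raise FluxError("beta must be >= 1")


def _beta(buffering: Union[BufferingModel, float]) -> float:
    if isinstance(buffering, BufferingModel):
        return buffering.beta
    b = float(buffering)
    if not b >= 1:
        raise FluxError("beta must be >= 1")
    return b


@dataclass(frozen=True)
class FluxFit:
    """OLS line through (ca, flux) points; the rate constant is the slope."""

    rate_constant: float  # s^-1
    intercept: float  # uM/s
    r_squared: float
    n_points: int
    ca_window: tuple  # (min, max) uM actually used

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise FluxError("a flux fit needs >= 3 points")
        if not np.isfinite(self.rate_constant):
            raise FluxError("non-finite rate constant")

    def to_dict(self) -> dict:
        return {
            "rate_constant_s": self.rate_constant,
            "intercept_um_s": self.intercept,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "ca_window_um": list(self.ca_window),
        }


def recovery_flux_curve(
    time: np.ndarray,
    ca: np.ndarray,
    buffering: Union[BufferingModel, float] = BufferingModel(),
    window: tuple = (0.9, 0.1),
    baseline: Optional[float] = None,
    smooth_window: int = 11,
):
    """Buffering-scaled removal flux paired with concurrent [Ca2+].

    ``flux = -beta * dc/dt`` by Savitzky-Golay local-quadratic
    differentiation (``smooth_window`` samples), paired with the equally
    smoothed ``c``.  Points are restricted to the post-peak decay between
    ``window[0]`` and ``window[1]`` of the amplitude above ``baseline``
    (default: the series minimum), avoiding peak rounding and baseline
    noise.  Returns ``(ca_points, flux_points)`` in uM and uM total / s.
    """
    beta = _beta(buffering)
    time = np.asarray(time, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if time.size != ca.size or time.size < 3:
        raise InsufficientDataError("need >= 3 samples of (t, ca)")
    dts = np.diff(time)
    dt = float(np.median(dts))
    if not np.allclose(dts, dt, rtol=1e-6, atol=1e-12):
        raise FluxError("recovery series must be uniformly sampled")
    w = min(smooth_window, time.size)
    if w % 2 == 0:
        w -= 1
    if w < 5:
        raise InsufficientDataError(f"series too short for smoothing window ({time.size} samples)")
    c_s = savgol_filter(ca, w, 2)
    flux = -beta * savgol_filter(ca, w, 2, deriv=1, delta=dt)

    if baseline is None:
        baseline = float(np.min(c_s))
    pk = int(np.argmax(c_s))
    amp = float(c_s[pk]) - baseline
    if amp <= 1e-12 * max(float(np.max(np.abs(c_s))), 1e-30):
        # constant series: no excursion, flux is identically ~0
        return c_s[pk:], flux[pk:]
    hi, lo = max(window), min(window)
    post_c = c_s[pk:]
    sel = (post_c <= baseline + hi * amp) & (post_c >= baseline + lo * amp)
    if int(np.sum(sel)) < 3:
        raise InsufficientDataError(
            f"only {int(np.sum(sel))} usable points in the [{hi}, {lo}] amplitude window"
        )
    return post_c[sel], flux[pk:][sel]


def fit_rate_constant(ca_points: np.ndarray, flux_points: np.ndarray) -> FluxFit:
    """Ordinary least squares with a free intercept; slope = rate constant.

    The intercept is deliberately free: the constant backflux/leak terms
    imply a nonzero flux at the baseline [Ca2+].
    """
    ca_points = np.asarray(ca_points, dtype=float)
    flux_points = np.asarray(flux_points, dtype=float)
    if ca_points.size < 3:
        raise InsufficientDataError("need >= 3 points to fit a rate constant")
    if np.ptp(ca_points) <= 0 or np.var(ca_points) == 0:
        raise DegenerateFitError("zero variance in [Ca2+]; slope undefined")
    res = stats.linregress(ca_points, flux_points)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    return FluxFit(
        rate_constant=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        n_points=int(ca_points.size),
        ca_window=(float(np.min(ca_points)), float(np.max(ca_points))),
    )


@dataclass(frozen=True)
class NcxResult:
    k_ncx: float  # s^-1
    leak: float  # uM/s, = k_ncx * resting
    fit: FluxFit


@dataclass(frozen=True)
class SercaResult:
    k_serca: float  # s^-1
    backflux: float  # uM/s, = k_serca * diastolic
    fit: FluxFit
    mode: str
    negative_flagged: bool = False


def ncx_analysis(
    cafft: CaffeineTransient,
    buffering: Union[BufferingModel, float] = BufferingModel(),
    window: tuple = (0.9, 0.1),
    smooth_window: int = 101,
) -> NcxResult:
    """NCX rate constant from the caffeine-transient recovery.

    With the SR held empty by caffeine, removal is via NCX alone, so the
    slope of the recovery flux curve is ``k_ncx``; sarcolemmal leak is the
    balancing rate ``k_ncx * resting``.  The default smoothing window is
    wider than for the paced transient because the caffeine decay is an
    order of magnitude slower.
    """
    if cafft.amplitude <= 0 or cafft.recovery_time.size < 3:
        raise InsufficientDataError("no caffeine recovery available")
    ca_pts, flux_pts = recovery_flux_curve(
        cafft.recovery_time,
        cafft.recovery_ca,
        buffering,
        window=window,
        baseline=cafft.resting,
        smooth_window=smooth_window,
    )
    fit = fit_rate_constant(ca_pts, flux_pts)
    return NcxResult(k_ncx=fit.rate_constant, leak=fit.rate_constant * cafft.resting, fit=fit)


def serca_analysis(
    cat: CaTransient,
    ncx_fit: Optional[FluxFit] = None,
    buffering: Union[BufferingModel, float] = BufferingModel(),
    window: tuple = (0.9, 0.1),
    mode: str = "ncx-subtracted",
    smooth_window: int = 21,
) -> SercaResult:
    """SERCA rate constant from the averaged paced-transient recovery.

    The raw slope reflects SERCA + NCX.  In ``ncx-subtracted`` mode
    (default) the caffeine-derived NCX slope is removed; ``lumped``
    reports the raw slope.  A negative subtracted rate is flagged, not
    raised.  SR backflux is the balancing rate ``k_serca * diastolic``.
    """
    if mode not in ("ncx-subtracted", "lumped"):
        raise FluxError(f"unknown mode {mode!r}")
    pk = int(np.argmax(cat.ca))
    ca_pts, flux_pts = recovery_flux_curve(
        cat.time[pk:],
        cat.ca[pk:],
        buffering,
        window=window,
        baseline=cat.diastolic,
        smooth_window=smooth_window,
    )
    fit = fit_rate_constant(ca_pts, flux_pts)
    if mode == "ncx-subtracted":
        if ncx_fit is None:
            raise FluxError("ncx-subtracted mode requires an NCX fit")
        k = fit.rate_constant - ncx_fit.rate_constant
    else:
        k = fit.rate_constant
    flagged = k < 0
    if flagged:
        warnings.warn("negative SERCA rate constant after NCX subtraction", UserWarning)
    return SercaResult(
        k_serca=float(k),
        backflux=float(k * cat.diastolic),
        fit=fit,
        mode=mode,
        negative_flagged=bool(flagged),
    )


@dataclass
class CaHandlingReport:
    """Full per-cell metric panel with provenance.

    Missing stages leave fields as None (partial reports are legitimate —
    e.g. a trace without caffeine metadata has no k_ncx/leak/sr_load and
    only a lumped SERCA slope).  The balancing identities
    ``backflux = k_serca * diastolic`` and ``leak = k_ncx * resting`` hold
    exactly by construction.
    """

    diastolic: Optional[float] = None
    systolic: Optional[float] = None
    amplitude: Optional[float] = None
    cat90: Optional[float] = None
    resting: Optional[float] = None
    sr_load: Optional[float] = None
    fractional_release: Optional[float] = None
    k_serca: Optional[float] = None
    backflux: Optional[float] = None
    k_ncx: Optional[float] = None
    leak: Optional[float] = None
    mode: Optional[str] = None
    serca_fit: Optional[FluxFit] = None
    ncx_fit: Optional[FluxFit] = None
    n_beats_averaged: Optional[int] = None
    saturated_fraction: float = 0.0
    peak_unreliable: bool = False
    notes: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "diastolic_um": self.diastolic,
            "systolic_um": self.systolic,
            "amplitude_um": self.amplitude,
            "cat90_s": self.cat90,
            "resting_um": self.resting,
            "sr_load_um": self.sr_load,
            "fractional_release": self.fractional_release,
            "k_serca_s": self.k_serca,
            "backflux_um_s": self.backflux,
            "k_ncx_s": self.k_ncx,
            "leak_um_s": self.leak,
            "mode": self.mode,
            "n_beats_averaged": self.n_beats_averaged,
            "saturated_fraction": self.saturated_fraction,
            "peak_unreliable": self.peak_unreliable,
            "notes": list(self.notes),
            "serca_fit": self.serca_fit.to_dict() if self.serca_fit else None,
            "ncx_fit": self.ncx_fit.to_dict() if self.ncx_fit else None,
            "provenance": self.provenance,
        }
        return d

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    def to_row(self) -> dict:
        """Flat scalar row for batch CSV output."""
        d = self.to_dict()
        d.pop("serca_fit")
        d.pop("ncx_fit")
        d.pop("provenance")
        d["notes"] = "; ".join(self.notes)
        return d


def full_report(
    trace: FluorescenceTrace,
    curve: CalibrationCurve = DEFAULT_CURVE,
    buffering: Union[BufferingModel, float] = BufferingModel(),
    config=None,
) -> CaHandlingReport:
    """Run calibrate -> segment -> average -> caffeine -> fluxes on one trace.

    Deterministic for a fixed config; any stage failure is re-raised as
    :class:`StageError` naming the stage, except for legitimately missing
    inputs (no beats, no caffeine metadata), which produce a partial
    report with a note.
    """
    from .config import AnalysisConfig  # local import: config depends on calibration

    if config is not None:
        cfg = config
        curve = cfg.curve()
        buffering = cfg.beta
    else:
        cfg = AnalysisConfig.with_curve(curve, beta=_beta(buffering))
    beta = _beta(buffering)
    report = CaHandlingReport(mode=cfg.mode)
    report.provenance = {
        "calibration": curve.to_dict(),
        "beta": beta,
        "config": cfg.model_dump(),
        "software": f"cahandling {__version__}",
        "dye": trace.dye,
    }

    try:
        ratio = trace.get_ratio()
        ca, sat = ratio_to_ca(ratio, curve)
    except Exception as e:  # noqa: BLE001 - wrapped with stage name
        raise StageError("calibration", e) from e

    cat = None
    try:
        stims = trace.stimulus_times if trace.stimulus_times.size else None
        segments = detect_transients(
            trace.time,
            ca,
            stimulus_times=stims,
            caffeine_onset=trace.caffeine_onset,
            pre_window=cfg.pre_window_s,
            prominence_factor=cfg.prominence_factor,
            min_separation=cfg.min_peak_separation_s,
            sat=sat,
        )
        cat = average_transients(
            segments,
            discard_first_n=cfg.discard_first_n,
            diastolic_window=cfg.diastolic_window_s,
            recovery_fraction=cfg.recovery_fraction,
        )
    except EmptyResultError as e:
        report.notes.append(f"segmentation: {e}")
    except Exception as e:  # noqa: BLE001
        raise StageError("segmentation", e) from e

    if cat is not None:
        report.diastolic = cat.diastolic
        report.systolic = cat.systolic
        report.amplitude = cat.amplitude
        report.cat90 = cat.t_recovery_90
        report.n_beats_averaged = cat.n_averaged
        report.saturated_fraction = cat.saturated_fraction

    cafft = None
    if trace.caffeine_onset is not None:
        try:
            cafft = detect_caffeine_transient(
                trace.time,
                ca,
                trace.caffeine_onset,
                resting_window=tuple(cfg.resting_window_s),
                peak_search=cfg.peak_search_s,
                noise_factor=cfg.prominence_factor,
                sat=sat,
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("caffeine", e) from e
        report.resting = cafft.resting
        report.sr_load = beta * cafft.amplitude
        report.saturated_fraction = max(report.saturated_fraction, cafft.saturated_fraction)
    else:
        report.notes.append("no caffeine metadata: k_ncx/leak/sr_load unavailable")

    ncx = None
    if cafft is not None and cafft.amplitude > 0:
        try:
            ncx = ncx_analysis(
                cafft,
                beta,
                window=tuple(cfg.fit_window),
                smooth_window=cfg.smooth_window_caff,
            )
        except InsufficientDataError as e:
            report.notes.append(f"ncx: {e}")
        except Exception as e:  # noqa: BLE001
            raise StageError("ncx", e) from e
    if ncx is not None:
        report.k_ncx = ncx.k_ncx
        report.leak = ncx.leak
        report.ncx_fit = ncx.fit

    if cat is not None:
        mode = cfg.mode
        if mode == "ncx-subtracted" and ncx is None:
            mode = "lumped"
            report.notes.append("fell back to lumped mode: no NCX fit available")
        try:
            serca = serca_analysis(
                cat,
                ncx_fit=ncx.fit if ncx is not None else None,
                buffering=beta,
                window=tuple(cfg.fit_window),
                mode=mode,
                smooth_window=cfg.smooth_window_cat,
            )
        except InsufficientDataError as e:
            serca = None
            report.notes.append(f"serca: {e}")
        except Exception as e:  # noqa: BLE001
            raise StageError("serca", e) from e
        if serca is not None:
            report.k_serca = serca.k_serca
            report.backflux = serca.backflux
            report.serca_fit = serca.fit
            report.mode = serca.mode
            if serca.negative_flagged:
                report.notes.append("negative k_serca after NCX subtraction")

    if cat is not None and cafft is not None and cafft.amplitude > 0:
        try:
            report.fractional_release = fractional_release(cat, cafft)
        except Exception as e:  # noqa: BLE001
            raise StageError("fractional-release", e) from e

    report.peak_unreliable = report.saturated_fraction > 0
    return report
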