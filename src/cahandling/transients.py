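"""Segmentation and descriptive metrics of paced and caffeine-evoked Ca2+ events.

Works on a calibrated (time, ca) pair.  The paced train is cut into
per-beat segments (anchored to stimulus metadata when available, otherwise
by prominence-based peak detection), averaged onto a common post-stimulus
time base after discarding the first pre-steady-state beats, and reduced
to diastolic / systolic / amplitude / recovery-time metrics.  The caffeine
transient yields resting Ca2+, the peak (an SR-load proxy once scaled by
the buffering capacity) and the recovery timecourse that the NCX analysis
consumes.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks, savgol_filter

__all__ = [
    "TransientError",
    "EmptyResultError",
    "UndefinedResultError",
    "NoReleaseWarning",
    "Segment",
    "CaTransient",
    "CaffeineTransient",
    "ShorteningResult",
    "detect_transients",
    "average_transients",
    "detect_caffeine_transient",
    "fractional_release",
    "recovery_fraction_time",
    "cell_area_shortening",
]

logger = logging.getLogger("cahandling.transients")


class TransientError(ValueError):
    pass


class EmptyResultError(TransientError):
    """No beats detected; message carries detection diagnostics."""


class UndefinedResultError(TransientError):
    """A ratio metric with a zero denominator (e.g. zero CaffT amplitude)."""


class NoReleaseWarning(UserWarning):
    """Caffeine produced no rise above resting noise; amplitude reported 0."""


@dataclass
class Segment:
    """One beat: time relative to its (actual or estimated) stimulus."""

    time: np.ndarray
    ca: np.ndarray
    stim_time: float
    sat: Optional[np.ndarray] = None

    @property
    def peak_time(self) -> float:
        """Absolute time of the segment's Ca2+ peak."""
        post = self.time >= 0
        return self.stim_time + float(self.time[post][np.argmax(self.ca[post])])


@dataclass
class CaTransient:
    """Averaged paced transient with its per-cell descriptive metrics (uM, s)."""

    time: np.ndarray
    ca: np.ndarray
    diastolic: float
    systolic: float
    amplitude: float
    t_recovery_90: float
    n_averaged: int
    saturated_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.systolic < self.diastolic:
            raise TransientError("systolic must be >= diastolic")


@dataclass
class CaffeineTransient:
    """Caffeine-evoked release: resting/peak levels and the recovery timecourse."""

    resting: float
    peak: float
    amplitude: float
    peak_time: float
    recovery_time: np.ndarray  # seconds from the caffeine peak
    recovery_ca: np.ndarray
    saturated_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.peak < self.resting:
            raise TransientError("peak must be >= resting")


def _robust_sd(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    if x.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def _odd_window(n: int, upper: int) -> int:
    w = min(n, upper)
    return w if w % 2 == 1 else w - 1


def detect_transients(
    time: np.ndarray,
    ca: np.ndarray,
    stimulus_times: Optional[Sequence[float]] = None,
    caffeine_onset: Optional[float] = None,
    pre_window: float = 0.05,
    prominence_factor: float = 4.0,
    min_separation: float = 0.2,
    sat: Optional[np.ndarray] = None,
) -> list:
    """Cut a calibrated trace into per-beat segments.

    With stimulus metadata, segmentation anchors to the stimulus times
    (each segment runs from ``stimulus - pre_window`` to the next
    stimulus).  Without it, peaks are found by prominence on a lightly
    smoothed trace; the threshold is ``prominence_factor`` times a robust
    noise s.d. (MAD of the high-pass residual), floored at 10% of the
    signal span.  Beats overlapping the caffeine window are excluded.
    Raises :class:`EmptyResultError` with diagnostics when nothing is found.
    """
    time = np.asarray(time, dtype=float)
    ca = np.asarray(ca, dtype=float)
    dt = float(np.median(np.diff(time)))
    guard = caffeine_onset - 0.25 if caffeine_onset is not None else np.inf

    if stimulus_times is not None and len(stimulus_times) > 0:
        stims = np.asarray(stimulus_times, dtype=float)
        period = float(np.median(np.diff(stims))) if stims.size > 1 else 0.5
        bounds = np.append(stims[1:], stims[-1] + period)
    else:
        w = _odd_window(ca.size, 11)
        smooth = savgol_filter(ca, w, 2) if w >= 5 else ca
        resid = ca - smooth
        sigma = _robust_sd(resid)
        span = float(np.ptp(smooth))
        prominence = max(prominence_factor * sigma, 0.1 * span)
        scale = float(np.max(np.abs(smooth))) if smooth.size else 0.0
        if span <= 1e-9 * max(scale, 1e-30) or prominence <= 0:
            raise EmptyResultError(
                f"flat trace: signal span {span:.3g}, threshold {prominence:.3g}"
            )
        peaks, props = find_peaks(
            smooth, prominence=prominence, distance=max(1, int(round(min_separation / dt)))
        )
        peaks = peaks[time[peaks] < guard]
        if peaks.size == 0:
            max_prom = float(np.max(props["prominences"])) if len(props.get("prominences", [])) else 0.0
            raise EmptyResultError(
                f"no beats detected: threshold {prominence:.3g}, "
                f"max prominence seen {max_prom:.3g}"
            )
        # refine each smoothed peak to the raw maximum nearby, then treat the
        # peak as the stimulus estimate (the upstroke is fast on this scale)
        half = w // 2
        peaks = np.array(
            [p - half + int(np.argmax(ca[max(p - half, 0):p + half + 1])) for p in peaks]
        )
        stims = time[peaks]
        period = float(np.median(np.diff(stims))) if stims.size > 1 else 0.5
        bounds = np.append(stims[1:], stims[-1] + period)

    segments = []
    for st, end in zip(stims, bounds):
        if end > guard:
            continue
        i0 = int(np.searchsorted(time, st - pre_window - 1e-12))
        i1 = int(np.searchsorted(time, end - 1e-12))
        if i1 - i0 < 3:
            continue
        segments.append(
            Segment(
                time=time[i0:i1] - st,
                ca=ca[i0:i1],
                stim_time=float(st),
                sat=None if sat is None else np.asarray(sat[i0:i1]),
            )
        )
    if not segments:
        raise EmptyResultError("all candidate beats overlapped the caffeine window")
    return segments


def average_transients(
    segments: Sequence[Segment],
    discard_first_n: int = 2,
    diastolic_window: float = 0.05,
    recovery_fraction: float = 0.9,
) -> CaTransient:
    """Average beats onto a common post-stimulus base and compute metrics.

    The first ``discard_first_n`` beats (approach to the SR steady state)
    are dropped.  Diastolic Ca2+ is the mean over the pre-stimulus window,
    systolic the maximum of the average, and ``t_recovery_90`` the first
    time the decay falls below ``diastolic + (1 - recovery_fraction) *
    amplitude``, measured from the peak.
    """
    kept = list(segments)[discard_first_n:]
    if not kept:
        raise TransientError(
            f"no beats left after discarding {discard_first_n} of {len(segments)}"
        )
    dts = [float(np.median(np.diff(s.time))) for s in kept]
    dt = dts[0]
    if not np.allclose(dts, dt, rtol=1e-3):
        logger.info("segments have inconsistent sampling; resampling to dt=%g s", dt)
    t0 = max(float(s.time[0]) for s in kept)
    t1 = min(float(s.time[-1]) for s in kept)
    base = np.arange(int(np.ceil(t0 / dt - 1e-9)), int(np.floor(t1 / dt + 1e-9)) + 1) * dt
    avg = np.mean([np.interp(base, s.time, s.ca) for s in kept], axis=0)

    pre = (base < 0) & (base >= -diastolic_window - 1e-12)
    diastolic = float(np.nanmean(avg[pre])) if np.any(pre) else float(avg[0])
    post = base >= 0
    pk_rel = int(np.argmax(avg[post]))
    pk = np.nonzero(post)[0][0] + pk_rel
    systolic = float(avg[pk])
    amplitude = systolic - diastolic

    t90 = recovery_fraction_time(
        base[pk:], avg[pk:], fraction=recovery_fraction, baseline=diastolic, peak=systolic
    )
    sat_frac = 0.0
    flagged = [s.sat for s in kept if s.sat is not None]
    if flagged:
        sat_frac = float(np.mean(np.concatenate(flagged)))
    return CaTransient(
        time=base,
        ca=avg,
        diastolic=diastolic,
        systolic=max(systolic, diastolic),
        amplitude=max(amplitude, 0.0),
        t_recovery_90=t90,
        n_averaged=len(kept),
        saturated_fraction=sat_frac,
    )


def recovery_fraction_time(
    time: np.ndarray,
    y: np.ndarray,
    fraction: float = 0.9,
    baseline: Optional[float] = None,
    peak: Optional[float] = None,
) -> float:
    """Time (from the start of the series) to recover a fraction of an excursion.

    The threshold is ``baseline + (1 - fraction) * (peak - baseline)``;
    the first downward crossing after the maximum is located by linear
    interpolation between bracketing samples (ties broken by earliest
    time).  Returns NaN (not-recovered sentinel) when the series never
    crosses.  Defaults: ``baseline = min(y)``, ``peak = max(y)``.
    """
    time = np.asarray(time, dtype=float)
    y = np.asarray(y, dtype=float)
    if baseline is None:
        baseline = float(np.nanmin(y))
    if peak is None:
        peak = float(np.nanmax(y))
    if peak <= baseline:
        return float("nan")
    thr = baseline + (1.0 - fraction) * (peak - baseline)
    start = int(np.nanargmax(y))
    for i in range(start + 1, y.size):
        if y[i] <= thr < y[i - 1]:
            frac = (y[i - 1] - thr) / (y[i - 1] - y[i])
            return float(time[i - 1] + frac * (time[i] - time[i - 1]) - time[0])
    return float("nan")


def detect_caffeine_transient(
    time: np.ndarray,
    ca: np.ndarray,
    caffeine_onset: float,
    resting_window: tuple = (2.0, 0.5),
    peak_search: float = 2.0,
    smooth_window: int = 25,
    noise_factor: float = 4.0,
    sat: Optional[np.ndarray] = None,
) -> CaffeineTransient:
    """Identify the caffeine transient around a known onset time.

    Resting Ca2+ is the mean over a window ending ``resting_window[1]`` s
    before the onset and spanning ``resting_window[0] - resting_window[1]``
    s; the peak is the maximum of a lightly smoothed trace within
    ``peak_search`` s after onset (smoothing keeps the extreme-value bias
    of noisy maxima in check).  If the rise does not exceed
    ``noise_factor`` robust noise s.d., a :class:`NoReleaseWarning` is
    issued and the amplitude reported as 0.
    """
    time = np.asarray(time, dtype=float)
    ca = np.asarray(ca, dtype=float)
    if not time[0] <= caffeine_onset <= time[-1]:
        raise TransientError("caffeine_onset outside the trace")
    lo, hi = caffeine_onset - resting_window[0], caffeine_onset - resting_window[1]
    rest_mask = (time >= lo) & (time <= hi)
    if not np.any(rest_mask):
        raise TransientError("no samples in the resting window before caffeine onset")
    resting = float(np.nanmean(ca[rest_mask]))
    sigma = _robust_sd(ca[rest_mask] - resting)

    post = (time >= caffeine_onset) & (time <= caffeine_onset + peak_search)
    idx_post = np.nonzero(post)[0]
    seg = ca[idx_post]
    w = _odd_window(seg.size, smooth_window)
    smooth = savgol_filter(seg, w, 2) if w >= 5 else seg
    pk_rel = int(np.argmax(smooth))
    peak = float(smooth[pk_rel])
    pk = int(idx_post[pk_rel])
    amplitude = peak - resting

    if amplitude <= max(noise_factor * sigma, 0.0) or amplitude <= 0:
        warnings.warn(
            f"no caffeine-evoked release above resting + {noise_factor} s.d.; "
            "amplitude set to 0",
            NoReleaseWarning,
        )
        return CaffeineTransient(
            resting=resting,
            peak=resting,
            amplitude=0.0,
            peak_time=float(caffeine_onset),
            recovery_time=np.empty(0),
            recovery_ca=np.empty(0),
            saturated_fraction=0.0,
        )

    sat_frac = 0.0
    if sat is not None:
        after = time >= caffeine_onset
        sat_frac = float(np.mean(np.asarray(sat)[after]))
    return CaffeineTransient(
        resting=resting,
        peak=peak,
        amplitude=amplitude,
        peak_time=float(time[pk]),
        recovery_time=time[pk:] - time[pk],
        recovery_ca=ca[pk:],
        saturated_fraction=sat_frac,
    )


def fractional_release(cat: CaTransient, cafft: CaffeineTransient) -> float:
    """SR fraction released per beat: CaT amplitude / CaffT amplitude.

    Typically in (0, 1]; values above 1 are allowed but flagged with a
    warning.  A zero caffeine amplitude raises
    :class:`UndefinedResultError`.
    """
    if cafft.amplitude <= 0:
        raise UndefinedResultError("caffeine amplitude is zero; fractional release undefined")
    value = cat.amplitude / cafft.amplitude
    if value > 1:
        warnings.warn(f"fractional release {value:.3g} > 1; check segmentation", UserWarning)
    return float(value)


@dataclass
class ShorteningResult:
    """Per-frame myocyte area, normalised to diastolic area."""

    areas: np.ndarray
    normalised: np.ndarray
    shortening: float
    threshold: float


def cell_area_shortening(stack: np.ndarray, threshold: Optional[float] = None) -> ShorteningResult:
    """Cell shortening from a fluorescence image stack by area thresholding.

    Each frame is binarised (auto threshold: midpoint between the dark and
    bright intensity levels, estimated from the 1st/99th percentiles of
    the stack) and the largest connected component taken as the myocyte.
    Areas are normalised to the mean over diastolic frames (the top
    quartile of areas); ``shortening = 1 - min(normalised area)``.  Frames
    with an empty mask contribute NaN with a warning.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, h, w)")
    if threshold is None:
        lo = float(np.percentile(stack, 1))
        hi = float(np.percentile(stack, 99))
        threshold = 0.5 * (lo + hi)
    areas = np.empty(stack.shape[0])
    for k, frame in enumerate(stack):
        labels, n = ndimage.label(frame > threshold)
        if n == 0:
            warnings.warn(f"empty mask in frame {k}; area set to NaN", UserWarning)
            areas[k] = np.nan
            continue
        counts = np.bincount(labels.ravel())[1:]
        areas[k] = float(np.max(counts))
    good = areas[np.isfinite(areas)]
    if good.size == 0:
        raise TransientError("no frame produced a non-empty mask")
    rest = float(np.mean(good[good >= np.percentile(good, 75)]))
    normalised = areas / rest
    return ShorteningResult(
        areas=areas,
        normalised=normalised,
        shortening=float(1.0 - np.nanmin(normalised)),
        threshold=float(threshold),
    )
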