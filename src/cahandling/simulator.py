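"""Forward model of a paced ventricular myocyte rendered into noisy fluorescence.

The model is the minimal two-compartment scheme that the downstream flux
analysis inverts: free cytosolic Ca2+ ``c`` (uM) buffered with constant
capacity ``beta`` (d[Ca]total/d[Ca]free), and SR content ``s`` expressed in
cytosol-volume-equivalent total Ca (uM).  Removal fluxes are linear in
``c`` (SERCA ``k_serca*c`` into the SR, NCX ``k_ncx*c`` out of the cell)
and are balanced at rest by two constant fluxes — SR backflux
``k_serca*c_rest`` and sarcolemmal leak ``k_ncx*c_rest`` — so that the
quiescent cell is self-consistently at ``c = c_rest``.

Each electrical stimulus instantaneously releases the fraction ``fr`` of
SR content into the cytosol (free ``c`` jumps by ``fr*s/beta``), which
makes fractional release exactly recoverable by the analysis.  During the
paced phase a constant sarcolemmal Ca entry (``ca_entry_per_beat`` uM of
total Ca per cycle, the trigger/L-type component) replaces what NCX
extrudes over each transient; a per-period integral balance shows the SR
then has the exact periodic steady state

    s_ss = ca_entry_per_beat * k_serca / (fr * k_ncx)

independent of pacing rate, and the default entry is chosen so that
``s_ss = sr_init``.  Caffeine application holds SR release channels open:
the SR empties at rate ``k_caff`` and SERCA cycling becomes futile (uptake
instantly re-released), so net cytosolic removal during the caffeine
transient is via NCX alone and the tail decays at exactly ``k_ncx/beta``.

Integration is fixed-step RK4 (default dt = 1 ms) with stimulus release
applied as a state jump between steps.  All randomness (emission noise,
cohort sampling) is seeded and reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._version import __version__
from .calibration import DEFAULT_CURVE, CalibrationCurve, FluorescenceTrace, ca_to_ratio

__all__ = [
    "SimulationError",
    "CohortError",
    "MyocyteParams",
    "Protocol",
    "NoiseSpec",
    "CohortSpec",
    "SimulationResult",
    "CohortResult",
    "simulate_myocyte",
    "render_fluorescence",
    "make_cohort",
    "make_shortening_stack",
]

#: fields of MyocyteParams that vary between animals/cells in a cohort
COHORT_VARIED_FIELDS = ("k_serca", "k_ncx", "fr", "sr_init")


class SimulationError(RuntimeError):
    """Integration produced a non-finite or negative state."""


class CohortError(ValueError):
    """Degenerate cohort specification."""


@dataclass(frozen=True)
class MyocyteParams:
    """Ground-truth cell parameters.  Units: s^-1, uM; beta dimensionless.

    ``ca_entry_per_beat`` (uM total Ca per pacing cycle) defaults to
    ``fr * sr_init * k_ncx / k_serca``, the unique value for which the SR
    periodic steady state equals ``sr_init``.
    """

    k_serca: float = 430.0
    k_ncx: float = 70.0
    c_rest: float = 0.1
    beta: float = 100.0
    fr: float = 0.6
    k_caff: float = 50.0
    sr_init: float = 80.0
    ca_entry_per_beat: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("k_serca", "k_ncx", "k_caff", "c_rest"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.beta >= 1:
            raise ValueError("beta must be >= 1")
        if not 0 < self.fr < 1:
            raise ValueError("fr must be in (0, 1)")
        if self.sr_init < 0:
            raise ValueError("sr_init must be >= 0")
        if self.ca_entry_per_beat is not None and self.ca_entry_per_beat < 0:
            raise ValueError("ca_entry_per_beat must be >= 0")

    @property
    def q_beat(self) -> float:
        """Sarcolemmal Ca entry per pacing cycle (uM total)."""
        if self.ca_entry_per_beat is not None:
            return self.ca_entry_per_beat
        return self.fr * self.sr_init * self.k_ncx / self.k_serca

    def to_dict(self) -> dict:
        return {
            "k_serca_s": self.k_serca,
            "k_ncx_s": self.k_ncx,
            "c_rest_um": self.c_rest,
            "beta": self.beta,
            "fr": self.fr,
            "k_caff_s": self.k_caff,
            "sr_init_um": self.sr_init,
            "ca_entry_per_beat_um": self.q_beat,
        }


@dataclass(frozen=True)
class Protocol:
    """Pacing/caffeine protocol: a 2 Hz train then a caffeine pulse.

    ``caffeine_mm`` is metadata only (the solution's nominal caffeine
    concentration); the model treats caffeine as all-or-none.
    Set ``n_beats=0`` and/or ``caffeine_onset=None`` to drop either phase.
    """

    pacing_hz: float = 2.0
    n_beats: int = 60
    stim_start: float = 1.0
    caffeine_onset: Optional[float] = 36.0
    duration: float = 46.0
    dt: float = 1e-3
    caffeine_mm: float = 10.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not self.duration > 0:
            raise ValueError("duration must be > 0")
        if self.n_beats < 0:
            raise ValueError("n_beats must be >= 0")
        if self.n_beats > 0:
            if not self.pacing_hz > 0:
                raise ValueError("pacing_hz must be > 0")
            last = self.stim_start + (self.n_beats - 1) / self.pacing_hz
            if last >= self.duration:
                raise ValueError("stimulus train exceeds duration")
            if self.caffeine_onset is not None and self.caffeine_onset <= last + 1 / self.pacing_hz:
                raise ValueError(
                    "caffeine_onset must come after the pacing train "
                    "(last stimulus + one pacing period)"
                )
        if self.caffeine_onset is not None and self.caffeine_onset >= self.duration:
            raise ValueError("duration must exceed caffeine_onset")

    @property
    def stimulus_times(self) -> np.ndarray:
        if self.n_beats == 0:
            return np.empty(0)
        return self.stim_start + np.arange(self.n_beats) / self.pacing_hz

    def to_dict(self) -> dict:
        return {
            "pacing_hz": self.pacing_hz,
            "n_beats": self.n_beats,
            "stim_start_s": self.stim_start,
            "caffeine_onset_s": self.caffeine_onset,
            "duration_s": self.duration,
            "dt_s": self.dt,
            "caffeine_mm": self.caffeine_mm,
        }


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise per emission channel (arbitrary units).

    Noise is applied to the channels, not to the ratio, so ratio noise is
    realistically heteroscedastic.  Default s.d. is 1% of the baseline
    channel intensity used by :func:`render_fluorescence`.
    """

    channel_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.channel_sd < 0:
            raise ValueError("channel_sd must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic two-group, cells-within-animals study design.

    Per-animal parameters are drawn lognormally around the base cell
    (median multiplier 1, fractional s.d. ``animal_sd``), per-cell
    parameters lognormally around their animal.  ``group_effects`` maps
    MyocyteParams field names to multiplicative shifts applied to the
    second group.
    """

    n_animals_per_group: int = 8
    cells_per_animal: int = 30
    animal_sd: float = 0.10
    cell_sd: float = 0.20
    group_effects: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals_per_group < 1 or self.cells_per_animal < 1:
            raise CohortError("cohort needs >= 1 animal per group and >= 1 cell per animal")
        if self.animal_sd < 0 or self.cell_sd < 0:
            raise CohortError("s.d. values must be >= 0")
        for k in self.group_effects:
            if k not in COHORT_VARIED_FIELDS:
                raise CohortError(f"group effect on unknown/unsupported field {k!r}")


@dataclass
class SimulationResult:
    """Ground-truth trajectories and per-term fluxes (uM total / s)."""

    time: np.ndarray
    c: np.ndarray
    s: np.ndarray
    flux_serca: np.ndarray
    flux_ncx: np.ndarray
    flux_backflux: np.ndarray
    flux_leak: np.ndarray
    flux_release: np.ndarray
    flux_entry: np.ndarray
    entered: np.ndarray  # cumulative leak + entry, uM total
    extruded: np.ndarray  # cumulative NCX, uM total
    params: MyocyteParams
    protocol: Protocol

    def mass_balance_residual(self) -> float:
        """max |beta*c + s + extruded - entered - const| over the run."""
        total = self.params.beta * self.c + self.s + self.extruded - self.entered
        return float(np.max(np.abs(total - total[0])))

    @property
    def total_ca_scale(self) -> float:
        """Natural scale for conservation tolerances: beta*c_rest + sr_init."""
        return self.params.beta * self.params.c_rest + self.params.sr_init


def simulate_myocyte(params: MyocyteParams, protocol: Protocol) -> SimulationResult:
    """Integrate the myocyte model with fixed-step RK4.

    Stimulus release is applied as an instantaneous state jump between
    steps; stimulus times and the caffeine onset are snapped to the
    integration grid.  Raises :class:`SimulationError` naming the offending
    time if the state becomes non-finite or negative.
    """
    dt = protocol.dt
    n = int(round(protocol.duration / dt)) + 1
    t = np.arange(n) * dt

    stim_idx = {int(round(st / dt)) for st in protocol.stimulus_times}
    onset = protocol.caffeine_onset
    t_caff = math.inf if onset is None else round(onset / dt) * dt

    # pacing-phase sarcolemmal entry window [first stim, last stim + period)
    if protocol.n_beats > 0:
        period = 1.0 / protocol.pacing_hz
        t_on = round(protocol.stim_start / dt) * dt
        t_off = round((protocol.stimulus_times[-1] + period) / dt) * dt
        j_in = params.q_beat * protocol.pacing_hz
    else:
        t_on, t_off, j_in = math.inf, -math.inf, 0.0

    ks, kn, kcaff = params.k_serca, params.k_ncx, params.k_caff
    beta, c_rest, fr = params.beta, params.c_rest, params.fr
    back_rest = ks * c_rest
    leak = kn * c_rest
    eps = 1e-9 * dt

    def rhs(tt: float, c: float, s: float):
        caff = tt >= t_caff - eps
        j_rel = kcaff * s if caff else 0.0
        j_serca = 0.0 if caff else ks * c
        j_back = 0.0 if caff else back_rest
        jin = j_in if (t_on - eps <= tt < t_off - eps) else 0.0
        dc = (j_rel + j_back + leak + jin - j_serca - kn * c) / beta
        ds = j_serca - j_back - j_rel
        return dc, ds, leak + jin, kn * c

    c_arr = np.empty(n)
    s_arr = np.empty(n)
    ein_arr = np.empty(n)
    eout_arr = np.empty(n)

    c, s, ein, eout = params.c_rest, params.sr_init, 0.0, 0.0
    if 0 in stim_idx:
        c, s = c + fr * s / beta, (1.0 - fr) * s
    c_arr[0], s_arr[0], ein_arr[0], eout_arr[0] = c, s, ein, eout

    half = dt / 2.0
    for i in range(1, n):
        t0 = (i - 1) * dt
        k1 = rhs(t0, c, s)
        k2 = rhs(t0 + half, c + half * k1[0], s + half * k1[1])
        k3 = rhs(t0 + half, c + half * k2[0], s + half * k2[1])
        k4 = rhs(t0 + dt, c + dt * k3[0], s + dt * k3[1])
        c += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        s += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        ein += dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        eout += dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        if i in stim_idx:
            c, s = c + fr * s / beta, (1.0 - fr) * s
        if not (math.isfinite(c) and math.isfinite(s)) or c <= 0 or s < -1e-9:
            raise SimulationError(
                f"integration failure at t={i * dt:.6g} s: c={c!r}, s={s!r}"
            )
        c_arr[i], s_arr[i], ein_arr[i], eout_arr[i] = c, s, ein, eout

    caff_mask = t >= t_caff - eps
    entry_mask = (t >= t_on - eps) & (t < t_off - eps)
    return SimulationResult(
        time=t,
        c=c_arr,
        s=s_arr,
        flux_serca=np.where(caff_mask, 0.0, ks * c_arr),
        flux_ncx=kn * c_arr,
        flux_backflux=np.where(caff_mask, 0.0, back_rest),
        flux_leak=np.full(n, leak),
        flux_release=np.where(caff_mask, kcaff * s_arr, 0.0),
        flux_entry=np.where(entry_mask, j_in, 0.0),
        entered=ein_arr,
        extruded=eout_arr,
        params=params,
        protocol=protocol,
    )


def render_fluorescence(
    sim: SimulationResult,
    curve: CalibrationCurve = DEFAULT_CURVE,
    noise: Optional[NoiseSpec] = None,
    i0: float = 1000.0,
) -> FluorescenceTrace:
    """Render a simulation into a two-channel ratiometric recording.

    The denominator channel is a constant baseline intensity ``i0``; the
    numerator is ``ratio * i0`` with ``ratio = ca_to_ratio(c)``, so the
    noiseless ratio reproduces the calibration map exactly.  Independent
    Gaussian noise (``noise.channel_sd``) is added per channel; the same
    seed gives bit-identical traces.
    """
    if noise is None:
        noise = NoiseSpec()
    r = ca_to_ratio(sim.c, curve)
    ch_den = np.full(sim.time.shape, i0)
    ch_num = r * i0
    if noise.channel_sd > 0:
        rng = np.random.default_rng(noise.seed)
        ch_num = ch_num + rng.normal(0.0, noise.channel_sd, ch_num.shape)
        ch_den = ch_den + rng.normal(0.0, noise.channel_sd, ch_den.shape)
    return FluorescenceTrace(
        time=sim.time.copy(),
        ch_num=ch_num,
        ch_den=ch_den,
        stimulus_times=sim.protocol.stimulus_times,
        caffeine_onset=sim.protocol.caffeine_onset,
        dye="FuraRed (synthetic)",
        calibration_id=curve.name,
        meta={
            "channel_sd": noise.channel_sd,
            "noise_seed": noise.seed,
            "i0": i0,
            "caffeine_mm": sim.protocol.caffeine_mm,
            "generator": f"cahandling {__version__}",
        },
    )


@dataclass
class CohortResult:
    """Ground-truth table (one row per cell) plus optional rendered traces."""

    table: pd.DataFrame
    params: list
    traces: Optional[list]
    spec: CohortSpec

    GROUPS = ("group1", "group2")


def make_cohort(
    spec: CohortSpec,
    base: MyocyteParams = MyocyteParams(),
    protocol: Protocol = Protocol(),
    render: bool = False,
    curve: CalibrationCurve = DEFAULT_CURVE,
    noise_sd: float = 10.0,
) -> CohortResult:
    """Draw a two-group nested cohort of cells around ``base``.

    Group effects multiply the named fields in the second group.  ``fr``
    draws are capped at 0.95 to keep them valid fractions.  With
    ``render=True`` each cell is simulated and rendered with its own
    derived noise seed (expensive; the ground-truth table alone is cheap).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    params_list = []
    traces = [] if render else None
    for gi, group in enumerate(CohortResult.GROUPS):
        for ai in range(spec.n_animals_per_group):
            animal_id = f"{group}_a{ai}"
            a_fac = {
                f: math.exp(spec.animal_sd * rng.standard_normal())
                for f in COHORT_VARIED_FIELDS
            }
            for ci in range(spec.cells_per_animal):
                values = {}
                for f in COHORT_VARIED_FIELDS:
                    v = getattr(base, f) * a_fac[f] * math.exp(
                        spec.cell_sd * rng.standard_normal()
                    )
                    if gi == 1 and f in spec.group_effects:
                        v *= spec.group_effects[f]
                    if f == "fr":
                        v = min(v, 0.95)
                    values[f] = v
                p = replace(base, **values)
                trace_seed = int(rng.integers(0, 2**31 - 1))
                rows.append(
                    {
                        "group": group,
                        "animal_id": animal_id,
                        "cell_id": f"{animal_id}_c{ci}",
                        **values,
                        "c_rest": p.c_rest,
                        "beta": p.beta,
                        "trace_seed": trace_seed,
                    }
                )
                params_list.append(p)
                if render:
                    sim = simulate_myocyte(p, protocol)
                    traces.append(
                        render_fluorescence(
                            sim, curve, NoiseSpec(channel_sd=noise_sd, seed=trace_seed)
                        )
                    )
    return CohortResult(table=pd.DataFrame(rows), params=params_list, traces=traces, spec=spec)


def make_shortening_stack(
    n_frames: int = 60,
    rest_area_px: int = 10000,
    peak_shortening: float = 0.10,
    shape: tuple = (192, 128),
    bg: float = 100.0,
    fg: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic bright-ellipse image stack whose area dips during a twitch.

    The cell is a 2:1 ellipse on a dark background; its area follows a
    raised-cosine twitch over the middle third of the stack, dipping to
    exactly ``(1 - peak_shortening) * rest_area_px`` (up to pixel
    quantisation) at the midpoint.  Returns a float32 (frames, h, w) array
    suitable for TIFF export.
    """
    if not 0 <= peak_shortening < 1:
        raise ValueError("peak_shortening must be in [0, 1)")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    k0, k1 = n_frames // 3, 2 * n_frames // 3
    frames = np.empty((n_frames, h, w), dtype=np.float32)
    rng = np.random.default_rng(seed)
    for k in range(n_frames):
        if k0 <= k <= k1 and k1 > k0:
            pulse = math.sin(math.pi * (k - k0) / (k1 - k0)) ** 2
        else:
            pulse = 0.0
        area = rest_area_px * (1.0 - peak_shortening * pulse)
        b = math.sqrt(area / (2.0 * math.pi))  # semi-minor (x); semi-major (y) = 2b
        a = 2.0 * b
        if 2 * a > h or 2 * b > w:
            raise ValueError("frame shape too small for requested rest area")
        mask = ((yy - cy) / a) ** 2 + ((xx - cx) / b) ** 2 <= 1.0
        img = np.where(mask, fg, bg)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, img.shape)
        frames[k] = img
    return frames
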