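# Methods

## The measurement problem

A ventricular myocyte paced to steady state produces a train of calcium
transients (CaTs); a subsequent pulse of 10 mM caffeine holds the SR
release channels open and dumps the SR content into the cytosol (CaffT).
From one such concatenated recording, made with a ratiometric dye, one can
read off per-cell physiology: diastolic/systolic/resting free [Ca²⁺], SR
load, fractional release, and — from the recovery kinetics — the activity
of the two removal pathways, SERCA (SR Ca²⁺-ATPase) and NCX (sarcolemmal
Na⁺/Ca²⁺ exchanger), each summarised as a rate constant with the two
constant fluxes (SR backflux, sarcolemmal leak) required to balance them
at the resting operating point. This package implements that analysis
end-to-end and pairs it with a forward simulator so every stage is
checked by parameter recovery rather than by eye.

## Forward model

State: free cytosolic [Ca²⁺] `c` (µM) and SR content `s` (µM of total Ca,
cytosol-volume equivalent). Cytosolic buffering is a constant capacity
β = d[Ca]_total/d[Ca]_free. Between events,

    β dc/dt = J_release + J_back + J_leak + J_in − J_serca − J_ncx
      ds/dt = J_serca − J_back − J_release

with linear removal `J_serca = k_serca·c`, `J_ncx = k_ncx·c` and constant
balancing fluxes `J_back = k_serca·c_rest`, `J_leak = k_ncx·c_rest`, so a
quiescent cell sits exactly at `c = c_rest`. Each stimulus moves the
fraction `fr` of SR content to the cytosol instantaneously (`c` jumps by
`fr·s/β`), which makes fractional release exactly recoverable.

**Pacing-phase Ca entry.** Real pacing is flux-balanced by L-type entry;
without it this scheme loses `fr·s·k_ncx/(k_serca+k_ncx)` of SR content
per beat (≈8%/beat at defaults) and has no nontrivial periodic state. We
therefore add a constant sarcolemmal entry `J_in` while the train runs,
parameterised as `ca_entry_per_beat` (µM total per cycle). Integrating
the two balance equations over one period of a periodic solution gives

    ca_entry_per_beat = fr · s_ss · k_ncx / k_serca        (exactly),

independent of pacing rate and of how completely the transient recovers
between beats. The default entry is chosen from this identity so that the
steady state equals `sr_init`. A corollary used in tests: the paced
diastolic baseline sits at `c_rest + J_in/(k_serca+k_ncx)`, above the
true resting level — as in real cells.

**Caffeine.** From the onset the SR empties at rate `k_caff`, and SERCA
cycling is futile while the release channels are held open: net SR uptake
is treated as a null operation (uptake instantly re-released), so the
model sets `J_serca`, `J_back` and SR refilling to zero during caffeine
and net cytosolic removal is via NCX alone. The caffeine tail then decays
at exactly `k_ncx/β`, which is the oracle the NCX analysis is checked
against. (Keeping SERCA active instead makes the slow eigenvalue
`k_ncx·k_caff / (β·(k_caff + (k_serca+k_ncx)/β))` — an ~8% bias at the
default `k_caff = 50 s⁻¹` that would contaminate every NCX estimate.)

**Integration.** Fixed-step RK4, default dt = 1 ms; stimulus jumps applied
between steps; event times snapped to the grid. The sum
`β·c + s + ∫J_ncx − ∫(J_leak+J_in)` is conserved by construction at every
RK4 stage, so mass balance holds to floating-point accumulation
(~10⁻¹¹ relative), far inside the 10⁻⁶ tolerance asserted in tests.
Non-finite or negative states abort with the offending time.

### Defaults (all configurable)

| parameter | default | meaning |
|---|---|---|
| k_serca | 430 s⁻¹ | SERCA rate constant (slope of flux vs [Ca²⁺]) |
| k_ncx | 70 s⁻¹ | NCX rate constant |
| c_rest | 0.1 µM | resting free [Ca²⁺] |
| β | 100 | buffering capacity |
| fr | 0.6 | fractional SR release per beat |
| k_caff | 50 s⁻¹ | caffeine-open SR emptying rate |
| sr_init | 80 µM | initial (and steady-state) SR content |
| pacing | 2 Hz × 60 beats | steady-state pacing phase |
| caffeine onset | 36 s (5.5 s after the last beat) | rest gap covers the resting window |
| channel noise | s.d. = 1% of baseline intensity | additive Gaussian per emission channel |

The rate constants and β are round placeholders of physiological
magnitude; only the pacing rate (2 Hz), the nominal caffeine
concentration (metadata) and the FuraRed saturation ratio (below) are
literature-anchored values. 60 beats are simulated because the analysis
assumes steady-state pacing: the approach to the SR periodic state is
geometric with ratio ≈0.92/beat from the rest initial condition, so a
30-beat train still averages ~3% low.

## Calibration

Ratio of background-subtracted channels; hyperbolic map
`ca = Kd·(R−Rmin)/(Rmax−R)` and its exact inverse. Ratios above the
saturation threshold (2.4, the published FuraRed bound) are flagged;
ratios at or above `Rmax` are additionally capped at the value at the
threshold — capping rather than rejecting keeps peak *timing* usable
while `peak_unreliable` propagates to the report. `Rmin=1.0`, `Rmax=3.0`,
`Kd=0.4 µM` are stand-ins (the real constants belong to the user's
calibration) and are recorded in every report's provenance.

## Analysis pipeline

* **Segmentation** anchors to stimulus metadata when present; otherwise
  peaks are detected by prominence (threshold 4× a robust noise s.d. —
  MAD of the Savitzky–Golay residual — floored at 10% of the signal
  span), refined to the raw local maximum, and treated as stimulus
  estimates (the upstroke is instantaneous on this timescale). Beats
  whose segment would cross `caffeine_onset − 0.25 s` are excluded. Both
  modes agree exactly on clean traces.
* **Averaging** drops the first 2 beats (configurable), resamples onto a
  common post-stimulus base (linear interpolation) and averages
  pointwise. Diastolic = mean over the last 50 ms before the stimulus;
  systolic = maximum; CaT₉₀ = first crossing of
  `diastolic + 0.1·amplitude` after the peak, linearly interpolated,
  ties broken by earliest time; never-crossing series return NaN.
* **Caffeine transient**: resting = mean over a 2 s window ending 0.5 s
  before onset; peak = maximum of a 25-sample-smoothed trace within 2 s
  after onset (smoothing bounds the extreme-value bias of a noisy
  maximum); a rise below 4 noise s.d. warns and reports amplitude 0.
* **Flux curves**: `flux = −β·dc/dt` by Savitzky–Golay local-quadratic
  differentiation, paired with the equally smoothed `c`; points restricted
  to the decay between 90% and 10% of amplitude above baseline. Window
  defaults: 21 samples for the paced transient, 101 for the ~10× slower
  caffeine recovery (the quadratic-fit bias scales as (rate·window)², so
  both choices keep it below ~3×10⁻⁴ relative at 1 kHz while suppressing
  derivative noise).
* **Fits**: ordinary least squares with a *free* intercept — the constant
  backflux/leak terms imply nonzero flux at baseline [Ca²⁺]; the rate
  constant is the slope only. `k_serca` is reported in `ncx-subtracted`
  mode by default (CaT recovery reflects SERCA+NCX; the caffeine-derived
  NCX slope is subtracted), with `lumped` available and labelled; both
  the mode and all windows go into provenance. Backflux and leak are
  computed as `k_serca·diastolic` and `k_ncx·resting`, so those
  identities hold exactly in every report.

## Hierarchical statistics

Cells nest in animals; treating cells as independent pseudo-replicates
inflates type-I error by the design effect `1 + (m−1)·ICC`. Two
transparent procedures are provided instead of an opaque mixed-model
fit: (1) Welch's test on per-animal means (degenerate-variance
convention: p = 1 when both variances are zero and the means equal);
(2) a two-level bootstrap (animals with replacement, then cells within
each sampled animal; percentile CI; p from the two-sided tail at 0,
n_boot = 5000, single seed). The cohort generator draws lognormal
animal- and cell-level multipliers (median 1) so the null calibration of
both methods is verified by simulation: at defaults the animal-mean test
rejects at ≈0.05 while the pooled cell-level t-test rejects at ≈0.45.

## What the synthetic data does and does not show

The generator reproduces the protocol's structure — paced train, caffeine
pulse, heteroscedastic ratio noise from per-channel Gaussian noise, dye
saturation, nested animal/cell variability — with known ground truth, so
passing tests demonstrate that the *analysis* is unbiased and noise-robust
under the model's assumptions. It does not emulate motion artefacts, dye
bleaching or compartmentalisation, spatial Ca²⁺ gradients (sparks/waves),
nonlinear SERCA kinetics, Ca²⁺-dependent buffering, or alternans; results
on real recordings inherit none of these guarantees. β is pure scaling
(every flux and rate constant is linear in it; concentration metrics are
β-invariant) and is never estimated from data.

### Known measurement properties worth remembering

* **Fractional release is protocol-dependent.** During the rest gap
  before caffeine the SR refills from the decaying cytosolic residue
  (fraction `k_serca/(k_serca+k_ncx)` of it), i.e. rest potentiation.
  When removal is slow relative to pacing (e.g. k_serca = 200,
  k_ncx = 40 s⁻¹) the accumulated diastolic residue is large, the
  pre-caffeine SR load exceeds the paced steady state by ~25%, and
  CaT-amp/CaffT-amp underestimates `fr` even noiselessly. At the default
  parameter point the bias is ≈4%.
* **CaffT amplitude slightly underestimates SR load/β** because NCX
  extrudes while the SR is still emptying: the exact peak is
  `(s₀/β)·k/(k−λ)·(e^{−λt*} − e^{−kt*})` with `λ = k_ncx/β`,
  `t* = ln(k/λ)/(k−λ)` — a 5.9% deficit at `k_caff = 50 s⁻¹`, 3.4% at
  100 s⁻¹.

## Problem sizes

Default runs simulate 46 s at 1 kHz (46 001 samples, <0.5 s wall time);
the noisy recovery grid is 3×3 with one seeded rendering per point; the
null-calibration harness uses 2000 cohort replicates of 2×8 animals × 30
cells. The full test suite runs in under a minute on one CPU.
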