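# cahandling

Calcium-handling analysis for isolated cardiomyocytes: ratiometric dye
calibration, segmentation and averaging of paced Ca²⁺ transients (CaTs),
detection of the caffeine-evoked SR release (CaffT), buffering-scaled
decomposition of removal fluxes into SERCA, NCX, SR backflux and
sarcolemmal leak, and animal-nested statistics that avoid
pseudo-replication — together with a forward simulator that renders
synthetic fluorescence recordings with known ground truth so every stage
is verifiable by parameter recovery.

It is written for cellular cardiologists analysing recordings from a
concatenated protocol: a train of electrically evoked CaTs at steady-state
pacing followed by a 10 mM caffeine pulse, imaged with a ratiometric dye
such as FuraRed.

## The model and statistics

Free cytosolic [Ca²⁺] `c` is obtained from the background-subtracted
channel ratio `R` via the hyperbola

    ca = Kd (R − Rmin) / (Rmax − R),

with ratios above the FuraRed saturation bound (R > 2.4) flagged
unreliable. With constant cytoplasmic buffering capacity β
(= d[Ca]_total/d[Ca]_free), the total removal flux during a recovery is
`J = −β dc/dt`. Plotting `J` against the concurrent `c` and fitting a
line (free intercept) gives a rate constant (s⁻¹):

* CaT recovery → SERCA (+NCX; the caffeine-derived NCX slope is
  subtracted by default),
* CaffT recovery (SR held empty, SERCA futile) → NCX,

plus the balancing fluxes `backflux = k_serca · diastolic` and
`leak = k_ncx · resting`. Derived metrics: diastolic/systolic Ca²⁺, CaT
amplitude, CaT₉₀, resting Ca²⁺, SR load (β × CaffT amplitude) and
fractional release (CaT amp / CaffT amp). Group comparisons are made at
the animal level (Welch on per-animal means, or a two-level bootstrap),
because cells from one animal are not independent replicates.

See `docs/methods.md` for the forward model, its steady-state design,
all defaults, and known measurement properties.

## Worked example

Simulate a cell with known parameters, render it as a noisy two-channel
recording, and run the full analysis:

```python
from cahandling import (MyocyteParams, Protocol, NoiseSpec,
                        simulate_myocyte, render_fluorescence, full_report)

params = MyocyteParams(k_serca=430, k_ncx=70, fr=0.6, sr_init=80, beta=100)
sim = simulate_myocyte(params, Protocol())           # 2 Hz train + caffeine
trace = render_fluorescence(sim, noise=NoiseSpec(channel_sd=10.0, seed=1))
report = full_report(trace)
print(f"k_serca  = {report.k_serca:7.1f} /s   (truth 430)")
print(f"k_ncx    = {report.k_ncx:7.1f} /s   (truth 70)")
print(f"backflux = {report.backflux:7.1f} uM/s (= k_serca x diastolic)")
print(f"leak     = {report.leak:7.2f} uM/s (= k_ncx x resting)")
print(f"SR load  = {report.sr_load:7.1f} uM   (truth ~80)")
print(f"frac rel = {report.fractional_release:7.3f}      (truth 0.6)")
print(f"CaT90    = {report.cat90*1000:7.1f} ms")
```

prints

```
k_serca  =   438.7 /s   (truth 430)
k_ncx    =    68.6 /s   (truth 70)
backflux =    78.8 uM/s (= k_serca x diastolic)
leak     =    6.86 uM/s (= k_ncx x resting)
SR load  =    84.2 uM   (truth ~80)
frac rel =   0.554      (truth 0.6)
CaT90    =   337.5 ms
```

— the rate constants recover within a few percent at 1% channel noise
(exactly, without noise), the balancing identities hold by construction,
and fractional release lands near its ground truth (see the methods note
for why it is a slightly protocol-dependent estimator). The same pipeline
runs from the shell:

```
cahandling simulate --seed 1 --out run/
cahandling analyze --trace run/trace.csv --out run/
cahandling cohort --seed 2 --out cohort/
cahandling compare cohort/ground_truth.csv --metric k_serca
cahandling demo-pseudoreplication --n-reps 1000
```

The last command shows the point of the hierarchical statistics: on null
cohorts with between-animal variance, the pooled cell-level t-test
rejects at ≈0.45 while the animal-mean test stays at ≈0.05.

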