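# mietfcs

Analysis and simulation toolkit for **MIET/GIET-FCS**: measuring
nanometer-scale, microsecond-resolved out-of-plane fluctuations of lipid
membranes by combining metal-/graphene-induced energy transfer (MIET/GIET)
with fluorescence correlation spectroscopy (FCS).

A fluorophore within ~150 nm of a thin gold film (or ~25 nm of a graphene
sheet) transfers energy to the substrate, which shortens its fluorescence
lifetime and modulates its detectable brightness as a function of its
height `h`.  For a labeled membrane hovering above such a substrate, height
fluctuations `δh(t)` become intensity fluctuations `δI(t)`; in the linear
regime of the brightness curve,

    g_I(t) ≈ (dI/dh)²_{h₀} · g_h(t),

so the intensity autocorrelation measured by FCS gives the height
correlation `g_h(t) = ⟨δh(t′) δh(t′+t)⟩`.  Its zero-lag value yields the
rms fluctuation amplitude `ψ = √⟨δh²⟩` and its half-decay lag the
relaxation time `τ*`.  For a membrane confined near a wall, `g_h` follows
the Helfrich undulation spectrum with a harmonic wall interaction,

    g_h(t) = (k_B T / 2π) ∫_{q_min}^{q_max} dq · q ·
             exp[−Γ(q) t − w²q²/4] / (κq⁴ + σq² + γ),

    Γ(q) = (κq⁴ + σq² + γ)/(2ηq) ·
           [sinh²(qh₀) − (qh₀)²] / [sinh²(qh₀) + sinh(2qh₀)/2 + qh₀(1 − qh₀)],

with bending rigidity `κ`, tension `σ`, interaction strength `γ`, effective
viscosity `η`, mean height `h₀`, detection-spot radius `w`, and cutoffs
`q_min = (γ/κ)^¼`, `q_max = 1/h₀`.  Fitting this model to measured height
correlations yields membrane tension and rigidity.

The package provides:

* **`mietfcs.optics`** — dipole emission above arbitrary layered
  substrates (transfer-matrix electrodynamics): relative lifetime
  `τ_f(h)/τ₀`, relative brightness `b(h)`, invertible calibration curves,
  named substrate presets (10 nm gold MIET stack, graphene GIET stacks).
* **`mietfcs.correlate`** — photon streams, multi-tau correlation with
  per-lag errors, Poisson-likelihood TCSPC lifetime fits, 2-D diffusion
  ACF fits.
* **`mietfcs.membrane`** — the undulation model above, statsmodels-style:
  `MembraneUndulationModel(curve, start, free=...).fit()` returns a
  results object with estimates, standard errors, covariance, `ψ`, `τ*`
  and a `summary()` table.
* **`mietfcs.simulate`** — synthetic experiments: membranes as
  Ornstein–Uhlenbeck mode banks with the exact model spectrum and damping,
  photon generation through a calibration curve, lipid-diffusion control
  simulations, and an end-to-end pipeline with scene presets
  (`guv_deflated`, `rbc_atp_minus`, ...).
* **`mietfcs` CLI** — `calibrate`, `simulate`, `correlate`, `fit`,
  `pipeline` subcommands over CSV/HDF5/JSON artifacts.

Who it is for: membrane biophysicists running MIET/GIET-FCS experiments
who need calibration curves and model fits, and method developers who want
a faithful simulator of the whole photon chain to validate analysis
choices.

## Worked example

Fit the undulation model to a height-correlation curve generated at the
deflated-vesicle conditions (κ = 20 k_BT fixed, η = 1.2 mPa·s,
h₀ = 36.1 nm, w = 280 nm), starting 3× away from the generating
σ = 14 µJ/m², γ = 5 MJ/m⁴:

```python
import numpy as np
from mietfcs import (MembraneParams, MembraneUndulationModel,
                     HeightCorrelation, height_correlation_model)

truth = MembraneParams()                       # deflated-vesicle defaults
lags = np.geomspace(1e-6, 1.0, 60)
curve = HeightCorrelation(lags, height_correlation_model(lags, truth))

start = MembraneParams(sigma=42e-6, gamma_pot=15e6)
res = MembraneUndulationModel(curve, start, free=("sigma", "gamma_pot")).fit()
print(res.summary())
```

```
Membrane undulation fit
==========================================================
n lags:   60    free: sigma, gamma_pot
converged: True    ill-conditioned: False (cond 2.56e+01)
residual norm: 3.130e-31
----------------------------------------------------------
sigma      [free ] = 1.4000e-05 +/- 3.199e-20  J/m^2
gamma_pot  [free ] = 5.0000e+06 +/- 2.741e-08  J/m^4
kappa      [fixed] = 8.2328e-20  J
eta        [fixed] = 1.200e-03  Pa s
h0         [fixed] = 36.10  nm
w          [fixed] = 280.0  nm   T = 298.15 K
----------------------------------------------------------
psi (rms amplitude)      = 5.357 nm
tau* (model half-decay)  = 30.966 ms
tau* (data half-decay)   = 30.960 ms
```

The fit recovers the generating tension and interaction strength exactly
(noiseless curve), and reports the derived observables: an rms amplitude
of ≈5.4 nm — inside the 8.0 ± 2.6 nm band measured for deflated vesicles —
and a half-decay time of ≈31 ms, consistent with the ~50 ± 30 ms measured
relaxation times.

Compute a gold-substrate calibration curve and invert a lifetime:

```python
import numpy as np
from mietfcs import build_calibration, Emitter, Objective, miet_gold_default

curve = build_calibration(miet_gold_default(), Emitter(), Objective(),
                          np.linspace(0.5, 250, 200))
h = curve.height_from_lifetime(lifetime_ns=1.2, tau0_ns=3.0)   # -> 34.3 nm
```

Or from the shell:

```bash
mietfcs calibrate --preset miet_gold_default --out calibration.csv
mietfcs pipeline --preset guv_deflated --seed 1 --duration 2 --outdir run/
```

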