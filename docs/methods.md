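# Methods

This note records the models implemented in `mietfcs`, their assumptions,
the numerical choices behind them, and what the synthetic-data generator
does and does not emulate.

## Physical picture

A fluorophore at height `h` above a thin metal film (MIET) or a graphene
sheet (GIET) couples through its near field to surface plasmons or excitons
in the substrate.  This shortens its excited-state lifetime and changes its
detectable brightness in a distance-dependent way.  A fluorescently labeled
membrane hovering above such a substrate therefore converts its height
fluctuations into fluorescence-intensity fluctuations, which fluorescence
correlation spectroscopy (FCS) resolves down to microseconds.  The toolkit
implements the three stages of that measurement: the electrodynamic
calibration, the correlation analysis, and the mechanical model of the
fluctuating membrane — plus a simulator that generates photon data with
exactly the statistical structure the analysis assumes.

## Dipole emission above a layered substrate

The substrate is a stratified medium: glass half-space, finite layers
(bottom to top), aqueous half-space of index `n1` on top where the emitter
lives.  All fields are expanded in plane waves with normalized in-plane
wavevector `s = q/(n1 k0)`; the substrate enters through its s- and
p-polarized reflection and transmission amplitudes, computed by a Parratt
recursion.  p-amplitudes use the magnetic-field convention, for which a
perfect mirror has `r_s -> -1`, `r_p -> +1`.

Normalized total emission powers of vertical and parallel dipoles follow
the standard half-space formulas

    S_perp/S0 = 1 + (3/2) Re Int ds (s^3/s_z) r_p e^{2 i k1 s_z h}
    S_par /S0 = 1 + (3/4) Re Int ds (s/s_z)(r_s - s_z^2 r_p) e^{2 i k1 s_z h}

validated against the image-dipole closed form for an ideal reflector
(agreement ~4e-7) and the exact identities of the homogeneous scene.  The
observable lifetime for quantum yield `phi` is
`tau_f/tau_0 = S0 / (phi S + (1-phi) S0)`, with the fast-rotation average
`S = (S_perp + 2 S_par)/3` for randomly oriented dyes.

The glass-side far field `N` is the transmitted plane-wave flux, including
the supercritical channel `1 < s < n_glass/n1` that a high-NA oil objective
collects.  The collection fraction `C` is defined as the part of `N` inside
the cone of internal angles `<= arcsin(NA/n_glass)`.  With that convention
the brightness integrand `(N/S) C = N_coll/S` is the detected fraction of
all emitted power, and the relative brightness approaches the net (cone-
averaged) transparency of the substrate at large heights — the behavior a
distance-independent far field must have.  Defining `C` against the total
emission `S` instead would square the transparency in that limit, which is
unphysical; this choice is deliberate and tested.  Note an intentional
asymmetry kept from the method's formulation: the lifetime uses the
fast-rotation orientation average, while the brightness integrates `N_coll/S`
over *static* orientations `beta` with weight `sin(beta)` (64-node
Gauss-Legendre).  Brightness values are normalized to an identical-index
scene with no substrate.

### Quadrature

Both `S` and `N` are one-dimensional integrals over `s`:

* propagating region (`s < 1`): substitution `s = sin(psi)` removes the
  `1/s_z` edge singularity; panel count grows with the oscillation phase
  `2 k1 h`;
* evanescent region: substitution `s_z = i v`; the integrand is truncated
  where `exp(-2 k1 v h) < 1e-12`.  Two features require dedicated panel
  edges: the narrow surface-plasmon resonance of metal films just beyond
  the medium light line (dense panels at small `v`), and the light line of
  every lossless medium in the stack, each a branch point with sqrt-type
  flanks;
* glass-side far field: the supercritical part uses `u = s_z,glass` as
  variable, which absorbs the edge behavior at the glass light line, and
  the collection-cone angle is always a panel boundary so the collected
  fraction is integrated exactly up to the NA.

With 32 Gauss–Legendre nodes per panel (the default) all outputs are stable
to better than ~1e-6 relative under node tripling, for bare and full
substrate presets alike.

### Material constants and presets

The standard substrate presets are `miet_gold_default` (glass | 2 nm Ti |
10 nm Au | 1 nm Ti | 10 nm SiO2 [+ 3 nm BSA]) and `giet_graphene(spacer)`
(glass | 0.34 nm graphene | SiO2 spacer [+ 1 nm PLL]).  Optical constants
ship as a small built-in dispersion table (gold and titanium from standard
thin-film tabulations, silica 1.456, protein adlayers 1.45, graphene treated
as a homogeneous isotropic layer of index 2.72 + 1.42i at 680 nm); every
layer can be constructed with an explicit index instead.  Calculations are
monochromatic at the emission maximum; emission-spectrum averaging is not
performed.

### Calibration curves

`build_calibration` tabulates `tau_f(h)/tau_0` and `b(h)` on a user grid
(heights below 0.1 nm are rejected; the near-field integrals diverge at
contact).  The brightness slope `db/dh` comes from centered differences of
a cubic-spline refinement.  Height inversion solves the monotone PCHIP
interpolant by bisection, making lifetime→height→lifetime round trips
solver-exact.

The *monotone domain* is detected as the maximal interval from the grid
origin over which the relative lifetime increases (with a 1e-9 relative
tolerance so flat transparent-stack curves keep the full grid).  A caveat:
the strict first maximum of the gold curve lies near 250 nm, well beyond
the ~150 nm *useful sensitivity range* usually quoted for 10 nm gold, and
the graphene curve keeps rising (ever more slowly) far beyond its ~25 nm
sensitivity range.  The strict detector is the documented behavior; treat
quoted sensitivity ranges as statements about usable slope, not about the
first maximum.

Absolute height conversion of measured lifetimes additionally requires the
dye's free-space lifetime and effective quantum yield, which are
instrument- and label-specific inputs.

## Correlation analysis

The multi-tau correlator uses 16 linear lags per octave with pairwise ×2
coarsening, from the finest bin up to one tenth of the record.  The
symmetric normalization divides each lag by the means of the two
overlapping windows, removing the triangular bias of finite records.  Three
output normalizations exist: fluctuation (`<dI dI>/<I>^2`), unnormalized
rate covariance (counts²/s², the form required by the intensity→height
conversion), and raw covariance (trace units², used e.g. for height
traces).  Lag-by-lag standard errors come from splitting the record into 10
contiguous segments; lags longer than a segment can resolve inherit the
last resolved error scaled by `sqrt(lag)` (the estimator variance grows
about linearly in lag at fixed record length).  These segment-based errors
underestimate the true uncertainty when the record is not much longer than
the slowest correlation time — they are weights, not confidence intervals.

TCSPC decays are fitted by Poisson maximum likelihood with a
mono-exponential plus constant background (floated or fixed) on a tail
window; the standard error comes from the observed information, falling
back to the amplitude/lifetime block when the background sits at its zero
boundary.  Diffusion correlation curves are fitted with the standard 2-D
model `g(t) = (1/N)/(1 + t/tau_D) + offset`, `tau_D = w^2/(4D)`.

Throughout the package `w` = 280 nm denotes the 1/e² radius of the Gaussian
detection profile `exp(-2 r^2/w^2)`.  This single convention makes the
three places `w` appears mutually consistent: the diffusion time
`tau_D = w^2/4D`, the focal weighting `exp(-q^2 w^2/4)` of the membrane
spectrum (the squared normalized Fourier transform of the profile), and the
simulator's detection weight.

## Confined-membrane undulation model

The measured height correlation is modeled as

    g_h(t) = (kB T / 2 pi) Int_{q_min}^{q_max} dq q
             exp[-Gamma(q) t - w^2 q^2/4] / (kappa q^4 + sigma q^2 + gamma)

with bending rigidity `kappa`, tension `sigma`, harmonic membrane–wall
interaction `gamma`, confinement cutoff `q_min = (gamma/kappa)^{1/4}` and
mean-height cutoff `q_max = 1/h0`.  The damping rate

    Gamma(q) = (kappa q^4 + sigma q^2 + gamma)/(2 eta q) * f(q h0)

interpolates between the lubrication limit (`f ~ x^3/6`, so
`Gamma ~ E q^2 h0^3 / 12 eta`) and the free-membrane limit (`f -> 1/2`).
For `x < 0.05` the sinh expressions are evaluated by series
(numerator `x^4/3 + 2x^6/45`, denominator `2x + 2x^3/3 + x^4/3`) because
`sinh^2 x - x^2` cancels catastrophically in double precision; for `x > 20`
the limit 1/2 is exact to machine precision.  Defaults follow the published
measurement conditions: `kappa = 20 kB T`, `eta = 1.2 mPa s` (mean of inner
and outer buffer viscosities), `w = 280 nm`, `T = 298.15 K` ("room
temperature" is not a number; 25 °C is the conventional choice).

Two derived observables: `psi = sqrt(g_h(0))` (rms amplitude) and `tau*`
(first downward crossing of half the zero-lag value, interpolated linearly
in log lag; on measured curves without a zero-lag point the first lag
defines the normalization).  Fit results report `tau*` both from the data
curve and from the fitted model.

The model integral is evaluated two ways: an adaptive quadrature
(`scipy.integrate.quad` on log q, relative tolerance 1e-8 — the reference
path exposed as `height_correlation_model`) and a vectorized fixed
composite Gauss–Legendre rule (8 panels × 64 nodes on log q) used inside
fitting, where the model is called thousands of times.  The two agree to
~1e-12 wherever `g_h` is not vanishingly small, and the fixed rule is
cross-checked in the tests against a 2000-node reference.

### Fitting

`MembraneUndulationModel.fit()` performs weighted least squares in
log-parameter space (positivity by construction) with a bounded
trust-region solver (six decades around the start; trial parameter sets
violating `q_min < q_max` are rejected by a large residual).  Weights are
`1/stderr`; without error bars uniform weights are used with a warning and
the covariance is rescaled by the residual variance.  The protocols mirror
the published analyses: vesicles free `(sigma, gamma)` with `kappa` fixed;
red blood cells free `(sigma, kappa)` with `gamma` fixed.  `q_max` uses the
lifetime-derived `h0`, which is held fixed, and `q_min` moves with the
floated `gamma` — that boundary dependence is what identifies `gamma` when
its direct contribution to the denominator is small.  An ill-conditioning
flag is raised when the log-space weighted Jacobian has condition number
above 1e8; note that restricting data to the decay tail does *not* trigger
it (the parameters stay formally identifiable, condition ~30) — what
degrades is the statistical uncertainty, which the reported standard errors
reflect.

The intensity→height conversion `g_h = g_I/(dI/dh)^2` requires the
unnormalized covariance and an absolute slope (detection rate at reference
brightness × calibration slope).  It is a linearization: curves measured at
mean heights outside the linear regime of the brightness curve (30–70 nm
for the gold substrate, 10–25 nm for graphene) carry a warning flag.

## Synthetic experiments

`simulate_membrane_height` draws the membrane as a bank of independent
Ornstein–Uhlenbeck modes: 256 log-spaced `q`-bands on `[q_min, q_max]`,
each carrying the band-integrated stationary variance of the spectrum
*including* the focal factor, and relaxing at `Gamma(q_band)`.  The summed
trace therefore has, by construction, the model's stationary ACF up to band
discretization (0.01% at 256 bands; the band-variance sum matches `g_h(0)`
to quadrature accuracy).  The OU update is the exact discretization
`x' = x e^{-G dt} + N(0, var (1 - e^{-2 G dt}))` from a stationary draw, so
the sampled law is correct at any step.  By default `dt` must resolve the
stiffest band (`dt <= 0.1/Gamma_max`), which matters when the trace drives
photon generation; `enforce_dt=False` permits coarse *exact* sampling for
long-record statistical cross-checks, where fine steps would add cost but
no information.

Photons are generated by thinning a homogeneous Poisson process at the
trace's maximum rate, with rate `r0 b(h(t)) + background` — exact for the
piecewise-constant rate.  Optional TCSPC micro-times are drawn from an
exponential with the local lifetime, truncated to the excitation period;
background photons get uniform micro-times.  Lipid-diffusion controls place
Brownian walkers in a periodic box (≥ 5× the spot size) with Gaussian
detection weighting; steps larger than `w/5` are rejected.

The generator emulates an equilibrium membrane with additive Gaussian mode
statistics and a linear detection chain.  It does **not** emulate active
(ATP-driven) forces, the pore-rim hydrodynamics of pore-spanning membranes,
photophysics (blinking, bleaching), detector afterpulsing or dead time, or
mechanical drift.  Passing tests therefore demonstrate the correctness of
the analysis chain under the model's own assumptions, not robustness to
those real-world effects.  The absolute photon yield depends on label
number and excitation intensity, which the theory folds into an unknown
proportionality; the simulator exposes it as the free knob
`detection_rate0`.

### Scene presets

`guv_deflated` (sigma = 14 µJ/m², gamma = 5 MJ/m⁴, h0 = 36.1 nm) and
`rbc_atp_minus` (sigma = 2.7 µJ/m², kappa = 3.9e-20 J, h0 = 36.4 nm) use
published mean fitted values.  `guv_tense` keeps the published mean height
(2.3 nm) with a representative high tension of 500 µJ/m² chosen to
reproduce the sub-nanometer amplitude of osmotically tense vesicles; the
`psm` and mitochondrial presets likewise pair measured heights with
synthetic stand-in mechanics (their fluctuations are not described by this
equilibrium model, and no fit protocol is attached).  `zero_fluctuation`
(sigma = 0.1 J/m², gamma = 1e10 J/m⁴) is a degenerate control with
sub-ångström residual amplitude.

## Problem sizes in the validation suite

The statistical tests are sized so the estimator variance sits comfortably
inside the asserted tolerances: the simulator/model ACF cross-check uses
160 s (deflated-vesicle), 400 s (red-blood-cell) and 20 s
(confinement-dominated) records, coarsely sampled; the diffusion pipeline
uses five 60-s records of 50 walkers with a ≤ 0.2 s (~75 `tau_D`) fitting
window, since at longer lags the finite periodic box distorts the measured
tail; the full photon chain aggregates ten 12-s records before refitting —
per-record interaction-strength estimates scatter by tens of percent, which
matches the spread published for repeated vesicle measurements.  Lifetime
and correlator checks use 1e5-count histograms and 1e5–4e6-bin records.

## Known limitations

* Graphene is an isotropic effective layer; in-plane/out-of-plane
  anisotropy is out of scope.
* Excitation-side fields are not computed; the detection profile enters
  only through `w`.
* Only the emission-side energy transfer of a single emitter is treated —
  no defocused imaging, no laterally structured substrates.
* The equilibrium undulation model must not be fitted to active membranes
  (ATP-saturated cells) or pore-spanning membranes; the presets for those
  scenes exist for simulation only.
* Segment-based correlation errors are underestimates when the record is
  short relative to the slowest relaxation; the fits use them as relative
  weights.
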