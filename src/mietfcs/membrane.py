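"""Confined-membrane undulation model and height-correlation fitting.

A fluid membrane hovering at mean height ``h0`` above a wall undergoes
thermally driven bending undulations.  Each lateral mode ``q`` relaxes with a
hydrodynamic damping rate ``Gamma(q)`` (lubrication-limited close to the wall,
free-membrane-like far from it), and its stationary variance follows the
Helfrich energy with bending rigidity ``kappa``, lateral tension ``sigma`` and
a harmonic membrane-wall interaction of strength ``gamma``.  A confocal spot
of 1/e^2 radius ``w`` averages the membrane height laterally, which suppresses
modes with ``q w >~ 2`` by a factor ``exp(-q^2 w^2 / 4)``.  The measured
height autocorrelation is

    g_h(t) = (k_B T / 2 pi) Int_{q_min}^{q_max} dq q
             exp[-Gamma(q) t - w^2 q^2 / 4] / (kappa q^4 + sigma q^2 + gamma)

with the confinement cutoff ``q_min = (gamma/kappa)^{1/4}`` and the
mean-height cutoff ``q_max = 1/h0``.  Two derived observables summarize a
curve: the root-mean-square fluctuation amplitude ``psi = sqrt(g_h(0))`` and
the relaxation time ``tau*`` at which ``g_h`` has decayed to half its value
at zero lag.

The fitting interface follows the statsmodels pattern: build a
:class:`MembraneUndulationModel` from a measured :class:`HeightCorrelation`,
call :meth:`~MembraneUndulationModel.fit`, and read estimates, uncertainties
and a ``summary()`` table off the returned :class:`MembraneFitResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import least_squares

__all__ = [
    "KB",
    "MembraneParams",
    "HeightCorrelation",
    "ParameterInconsistencyError",
    "damping_rate",
    "height_correlation_model",
    "fluctuation_amplitude",
    "relaxation_time",
    "intensity_to_height",
    "MembraneUndulationModel",
    "MembraneFitResults",
]

#: Boltzmann constant (J/K)
KB = 1.380649e-23

#: linear intensity-height regime of the calibration curves (m)
LINEAR_DOMAIN_MIET = (30e-9, 70e-9)
LINEAR_DOMAIN_GIET = (10e-9, 25e-9)


class ParameterInconsistencyError(ValueError):
    """Raised when q_min = (gamma/kappa)^{1/4} >= q_max = 1/h0, i.e. the
    confinement cutoff exceeds the mean-height cutoff."""


@dataclass(frozen=True)
class MembraneParams:
    """Parameter vector of the undulation model (SI units).

    kappa      bending rigidity (J); 20 k_B T ~ 8.2e-20 J for SOPC
    sigma      membrane tension (J/m^2)
    gamma_pot  membrane-wall interaction strength (J/m^4)
    eta        effective viscosity of the surrounding medium (Pa s)
    h0         mean membrane height above the wall (m)
    temperature  absolute temperature (K)
    w          1/e^2 radius of the confocal detection profile (m)
    """

    kappa: float = 20.0 * KB * 298.15
    sigma: float = 14e-6
    gamma_pot: float = 5e6
    eta: float = 1.2e-3
    h0: float = 36.1e-9
    temperature: float = 298.15
    w: float = 280e-9

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.gamma_pot <= 0:
            raise ValueError("gamma_pot must be > 0 (q_min requires it)")
        if self.eta <= 0 or self.h0 <= 0 or self.w <= 0 or self.temperature <= 0:
            raise ValueError("eta, h0, w and temperature must be > 0")

    @property
    def q_min(self) -> float:
        return (self.gamma_pot / self.kappa) ** 0.25

    @property
    def q_max(self) -> float:
        return 1.0 / self.h0

    def check_consistent(self) -> None:
        if not self.q_min < self.q_max:
            raise ParameterInconsistencyError(
                f"q_min = (gamma/kappa)^(1/4) = {self.q_min:.3e} 1/m is not below "
                f"q_max = 1/h0 = {self.q_max:.3e} 1/m: confinement potential too "
                "strong for the given mean height"
            )


@dataclass
class HeightCorrelation:
    """Measured (or simulated) height correlation: lags (s), values (m^2)
    and optional per-lag standard errors (m^2)."""

    lags: np.ndarray
    values: np.ndarray
    stderr: np.ndarray | None = None
    linear_regime_warning: bool = False

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
            if np.any(self.stderr < 0):
                raise ValueError("stderr must be >= 0")
            if len(self.stderr) != len(self.lags):
                raise ValueError("stderr length mismatch")
        if len(self.values) != len(self.lags):
            raise ValueError("lags/values length mismatch")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")


# --------------------------------------------------------------------------
# model evaluation
# --------------------------------------------------------------------------

def _mode_energy_density(q: np.ndarray, p: MembraneParams) -> np.ndarray:
    return p.kappa * q**4 + p.sigma * q**2 + p.gamma_pot


def damping_rate(q, params: MembraneParams):
    """Hydrodynamic relaxation rate Gamma(q) (1/s) of mode q (1/m).

    The wall-distance factor f(x) with x = q h0 interpolates between the
    lubrication limit f ~ x^3/6 (so Gamma ~ (kappa q^4 + sigma q^2 + gamma)
    q^2 h0^3 / (12 eta)) and the free-membrane limit f -> 1/2 (so Gamma ->
    (kappa q^4 + sigma q^2 + gamma)/(4 eta q)).  For x < 0.05 the sinh
    expressions are evaluated by series to avoid catastrophic cancellation;
    for x > 20 the limit 1/2 is exact to double precision.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q must be > 0")
    x = q * params.h0
    small = x < 0.05
    large = x > 20.0
    mid = ~(small | large)
    f = np.empty_like(x)
    xs = x[small]
    f[small] = (xs**4 / 3.0 + 2.0 * xs**6 / 45.0) / (
        2.0 * xs + 2.0 * xs**3 / 3.0 + xs**4 / 3.0
    )
    xm = x[mid]
    sh2 = np.sinh(xm) ** 2
    f[mid] = (sh2 - xm**2) / (sh2 + 0.5 * np.sinh(2.0 * xm) + xm * (1.0 - xm))
    f[large] = 0.5
    gam = _mode_energy_density(q, params) / (2.0 * params.eta * q) * f
    return gam if gam.shape else float(gam)


def _gh_integrand(q: np.ndarray, t: float, p: MembraneParams) -> np.ndarray:
    e = _mode_energy_density(q, p)
    arg = -0.25 * p.w**2 * q**2
    if t > 0:
        arg = arg - damping_rate(q, p) * t
    return q / e * np.exp(arg)


_GL64 = np.polynomial.legendre.leggauss(64)


def _height_correlation_fixed(t_arr: np.ndarray, params: MembraneParams,
                              n_panels: int = 8) -> np.ndarray:
    """Vectorized composite Gauss-Legendre evaluation of the model on a
    log-q grid (64 nodes per panel).  Agrees with the adaptive path to
    better than 1e-8 relative for smooth parameter sets; used in fitting
    where the model is evaluated thousands of times."""
    params.check_consistent()
    y_edges = np.linspace(np.log(params.q_min), np.log(params.q_max), n_panels + 1)
    xg, wg = _GL64
    half = 0.5 * np.diff(y_edges)
    mid = 0.5 * (y_edges[:-1] + y_edges[1:])
    y = (mid[:, None] + half[:, None] * xg[None, :]).ravel()
    wy = (half[:, None] * wg[None, :]).ravel()
    q = np.exp(y)
    e = _mode_energy_density(q, params)
    rates = damping_rate(q, params)
    static = q * q / e * np.exp(-0.25 * params.w**2 * q * q) * wy
    pref = KB * params.temperature / (2.0 * np.pi)
    return pref * (static[None, :] * np.exp(-np.outer(t_arr, rates))).sum(axis=1)


def height_correlation_model(t, params: MembraneParams, rtol: float = 1e-8):
    """g_h(t) in m^2 by adaptive quadrature over log q between q_min and
    q_max; accepts scalar or array lags (t >= 0)."""
    params.check_consistent()
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("lag times must be >= 0")
    y_lo, y_hi = np.log(params.q_min), np.log(params.q_max)
    pref = KB * params.temperature / (2.0 * np.pi)
    # coarse scale estimate so quad gets a meaningful absolute floor
    q_scan = np.geomspace(params.q_min, params.q_max, 64)
    scale = float(np.trapezoid(q_scan * _gh_integrand(q_scan, 0.0, params), np.log(q_scan)))
    out = np.empty_like(t_arr)
    for i, ti in enumerate(t_arr):
        val, _ = quad(
            lambda y: (lambda q: q * _gh_integrand(q, ti, params))(np.exp(y)),
            y_lo,
            y_hi,
            epsrel=rtol,
            epsabs=max(scale, 1e-300) * 1e-12,
            limit=200,
        )
        out[i] = pref * val
    return out if np.ndim(t) else float(out[0])


def fluctuation_amplitude(params: MembraneParams, rtol: float = 1e-8) -> float:
    """Root-mean-square height fluctuation psi = sqrt(g_h(0)) in meters."""
    return float(np.sqrt(height_correlation_model(0.0, params, rtol=rtol)))


def relaxation_time(lags, values=None, params: MembraneParams | None = None):
    """Half-decay lag tau* (s): the first downward crossing of
    value/value(0) = 1/2, linearly interpolated in log lag.

    Either pass a measured curve (``lags``, ``values`` arrays, lag 0 or the
    first lag defining the maximum) or model ``params`` with a lag grid.
    With a non-monotone (noisy) curve the *first* crossing is used.
    """
    if params is not None:
        lags = np.asarray(lags, dtype=float)
        values = height_correlation_model(np.maximum(lags, 0.0), params)
    lags = np.asarray(lags, dtype=float)
    values = np.asarray(values, dtype=float)
    if lags[0] == 0.0:
        v0 = values[0]
        lags, values = lags[1:], values[1:]
    else:
        v0 = values[0]
    if v0 <= 0:
        raise ValueError("curve maximum must be positive to normalize")
    rel = values / v0
    below = np.nonzero(rel < 0.5)[0]
    if below.size == 0 or below[0] == 0:
        if below.size and below[0] == 0 and rel[0] < 0.5:
            # crossed before the first positive lag
            raise ValueError("curve already below half its maximum at the first lag")
        raise ValueError("curve does not decay to half its maximum within the lag range")
    i = below[0]
    x0, x1 = np.log(lags[i - 1]), np.log(lags[i])
    y0, y1 = rel[i - 1], rel[i]
    return float(np.exp(x0 + (0.5 - y0) / (y1 - y0) * (x1 - x0)))


def intensity_to_height(
    lags,
    covariance,
    slope,
    h0: float,
    stderr=None,
    linear_domain: tuple[float, float] = LINEAR_DOMAIN_MIET,
) -> HeightCorrelation:
    """Convert an *unnormalized* intensity covariance (counts^2/s^2) into a
    height correlation via g_h = g_I / (dI/dh)^2.

    ``slope`` is the absolute intensity-height slope dI/dh at h0 in
    counts/s per meter (detection rate times the calibration brightness
    slope).  If h0 lies outside ``linear_domain`` the returned curve carries
    ``linear_regime_warning=True`` (the linearization of the brightness
    curve is then questionable).  Fluctuation-normalized correlations must
    be rescaled by <I>^2 before calling this.
    """
    if slope == 0:
        raise ValueError("intensity-height slope is zero: no height sensitivity")
    lags = np.asarray(lags, dtype=float)
    vals = np.asarray(covariance, dtype=float) / slope**2
    err = None if stderr is None else np.asarray(stderr, dtype=float) / slope**2
    warn = not (linear_domain[0] <= h0 <= linear_domain[1])
    if warn:
        warnings.warn(
            f"mean height {h0 * 1e9:.1f} nm outside the linear intensity-height "
            f"regime [{linear_domain[0] * 1e9:.0f}, {linear_domain[1] * 1e9:.0f}] nm",
            stacklevel=2,
        )
    return HeightCorrelation(lags, vals, err, linear_regime_warning=warn)


# --------------------------------------------------------------------------
# fitting (statsmodels-style model / results pair)
# --------------------------------------------------------------------------

_FITTABLE = ("sigma", "gamma_pot", "kappa")


class MembraneUndulationModel:
    """Weighted least-squares fit of the undulation model to a measured
    height-correlation curve.

    Parameters
    ----------
    curve : HeightCorrelation
        Measured curve (>= 15 lags recommended).  If per-lag standard
        errors are present they define the weights 1/stderr^2; otherwise
        uniform weights are used (with a warning).
    params0 : MembraneParams
        Starting values; the non-free entries are held fixed.
    free : sequence of {"sigma", "gamma_pot", "kappa"}
        Parameters floated in log space (positivity by construction).
        The vesicle protocol frees (sigma, gamma_pot) with kappa fixed; the
        red-blood-cell protocol frees (sigma, kappa) with gamma_pot fixed.
    """

    def __init__(
        self,
        curve: HeightCorrelation,
        params0: MembraneParams,
        free: Sequence[str] = ("sigma", "gamma_pot"),
        rtol: float = 1e-8,
    ) -> None:
        for name in free:
            if name not in _FITTABLE:
                raise ValueError(f"cannot free {name!r}; choose from {_FITTABLE}")
        if len(curve.lags) < 15 and len(free) > 0:
            warnings.warn("fewer than 15 lags: fit may be poorly constrained")
        self.curve = curve
        self.params0 = params0
        self.free = tuple(free)
        self.rtol = rtol
        self._weighted = curve.stderr is not None and bool(np.all(curve.stderr > 0))
        if self._weighted:
            self._weights = 1.0 / curve.stderr
        else:
            if curve.stderr is not None:
                warnings.warn("non-positive stderr entries; using uniform weights")
            else:
                warnings.warn("no stderr on curve; using uniform weights")
            self._weights = np.ones_like(curve.values)

    # -- internals ---------------------------------------------------------

    def _params_from_theta(self, theta: np.ndarray) -> MembraneParams:
        return replace(
            self.params0, **{k: float(np.exp(v)) for k, v in zip(self.free, theta)}
        )

    @property
    def _scale(self) -> float:
        # with true stderr weights residuals are already dimensionless z-scores;
        # with unit weights rescale by the curve amplitude for conditioning
        if self._weighted:
            return 1.0
        return max(abs(self.curve.values[0]), 1e-30)

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        p = self._params_from_theta(theta)
        try:
            model = _height_correlation_fixed(self.curve.lags, p)
        except ParameterInconsistencyError:
            return np.full_like(self.curve.values, 1e6)
        return (model - self.curve.values) / self._scale * self._weights

    def fit(self, max_restarts: int = 2) -> "MembraneFitResults":
        if not self.free:
            p = self.params0
            resid = (
                height_correlation_model(self.curve.lags, p, rtol=self.rtol)
                - self.curve.values
            ) * self._weights
            return MembraneFitResults(
                model=self,
                params=p,
                theta=np.empty(0),
                cov_log=np.empty((0, 0)),
                residual_norm=float(np.linalg.norm(resid)),
                success=True,
                condition_number=0.0,
            )

        theta0 = np.log([getattr(self.params0, k) for k in self.free])
        span = np.log(1e6)  # allow 6 decades around the start
        best = None
        for attempt in range(max_restarts + 1):
            start = theta0 + (0.0 if attempt == 0 else np.log(2.0) * (-1) ** attempt)
            sol = least_squares(
                self._residuals, start, method="trf",
                bounds=(theta0 - span, theta0 + span),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
                max_nfev=400 * (1 + len(self.free)),
            )
            if best is None or sol.cost < best.cost:
                best = sol
            if sol.success and sol.cost < 1e-18:
                break
        sol = best

        # covariance of log-parameters from the weighted Jacobian
        J = sol.jac
        resid_phys = sol.fun * self._scale
        dof = max(len(resid_phys) - len(self.free), 1)
        jtj = J.T @ J
        try:
            cov_log = np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            cov_log = np.full((len(self.free),) * 2, np.nan)
        if not self._weighted:
            # unit weights: scale by residual variance
            cov_log = cov_log * (sol.fun @ sol.fun) / dof
        svals = np.linalg.svd(J, compute_uv=False)
        cond = float(svals[0] / svals[-1]) if svals[-1] > 0 else np.inf

        return MembraneFitResults(
            model=self,
            params=self._params_from_theta(sol.x),
            theta=sol.x,
            cov_log=cov_log,
            residual_norm=float(np.linalg.norm(resid_phys)),
            success=bool(sol.success),
            condition_number=cond,
        )


@dataclass
class MembraneFitResults:
    """Estimates, uncertainties and derived observables of an undulation fit."""

    model: MembraneUndulationModel
    params: MembraneParams
    theta: np.ndarray
    cov_log: np.ndarray
    residual_norm: float
    success: bool
    condition_number: float

    def __post_init__(self) -> None:
        self.ill_conditioned = bool(self.condition_number > 1e8)
        self.psi = float(np.sqrt(_height_correlation_fixed(np.zeros(1), self.params)[0]))
        lag_grid = np.geomspace(
            max(self.model.curve.lags[0], 1e-7) * 1e-2,
            self.model.curve.lags[-1] * 1e2,
            400,
        )
        try:
            self.tau_star_model = relaxation_time(
                lag_grid, _height_correlation_fixed(lag_grid, self.params)
            )
        except ValueError:
            self.tau_star_model = np.nan
        try:
            self.tau_star_data = relaxation_time(
                self.model.curve.lags, self.model.curve.values
            )
        except ValueError:
            self.tau_star_data = np.nan

    @property
    def free(self) -> tuple[str, ...]:
        return self.model.free

    @property
    def bse(self) -> dict[str, float]:
        """Standard errors of the free parameters (linear scale, delta
        method from the log-space covariance)."""
        if self.cov_log.size == 0:
            return {}
        se_log = np.sqrt(np.maximum(np.diag(self.cov_log), 0.0))
        return {
            k: float(getattr(self.params, k) * s) for k, s in zip(self.free, se_log)
        }

    def cov_params(self) -> np.ndarray:
        """Covariance of the free parameters on the linear scale."""
        vals = np.array([getattr(self.params, k) for k in self.free])
        return self.cov_log * np.outer(vals, vals)

    @property
    def tau_star(self) -> float:
        """Relaxation time of the fitted model (s)."""
        return self.tau_star_model

    def summary(self) -> str:
        p = self.params
        lines = [
            "Membrane undulation fit",
            "=" * 58,
            f"n lags: {len(self.model.curve.lags):4d}    free: {', '.join(self.free) or 'none'}",
            f"converged: {self.success}    ill-conditioned: {self.ill_conditioned}"
            f" (cond {self.condition_number:.2e})",
            f"residual norm: {self.residual_norm:.3e}",
            "-" * 58,
        ]
        units = {"sigma": "J/m^2", "gamma_pot": "J/m^4", "kappa": "J"}
        bse = self.bse
        for name in _FITTABLE:
            val = getattr(p, name)
            tag = "free " if name in self.free else "fixed"
            err = f" +/- {bse[name]:.3e}" if name in bse else ""
            lines.append(f"{name:10s} [{tag}] = {val:.4e}{err}  {units[name]}")
        lines += [
            f"eta        [fixed] = {p.eta:.3e}  Pa s",
            f"h0         [fixed] = {p.h0 * 1e9:.2f}  nm",
            f"w          [fixed] = {p.w * 1e9:.1f}  nm   T = {p.temperature:.2f} K",
            "-" * 58,
            f"psi (rms amplitude)      = {self.psi * 1e9:.3f} nm",
            f"tau* (model half-decay)  = {self.tau_star_model * 1e3:.3f} ms",
            f"tau* (data half-decay)   = {self.tau_star_data * 1e3:.3f} ms",
        ]
        return "\n".join(lines)

    def report_dict(self) -> dict:
        """JSON-serializable fit report."""
        return {
            "free": list(self.free),
            "params": {
                "sigma_J_m2": self.params.sigma,
                "gamma_pot_J_m4": self.params.gamma_pot,
                "kappa_J": self.params.kappa,
                "eta_Pa_s": self.params.eta,
                "h0_m": self.params.h0,
                "temperature_K": self.params.temperature,
                "w_m": self.params.w,
            },
            "stderr": self.bse,
            "psi_nm": self.psi * 1e9,
            "tau_star_model_ms": self.tau_star_model * 1e3,
            "tau_star_data_ms": self.tau_star_data * 1e3,
            "residual_norm": self.residual_norm,
            "flags": {
                "converged": self.success,
                "ill_conditioned": self.ill_conditioned,
                "linear_regime_warning": self.model.curve.linear_regime_warning,
            },
        }

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        c = self.model.curve
        ax.errorbar(c.lags, c.values * 1e18, yerr=None if c.stderr is None else c.stderr * 1e18,
                    fmt=".", label="data")
        grid = np.geomspace(c.lags[0], c.lags[-1], 200)
        ax.plot(grid, height_correlation_model(grid, self.params) * 1e18, label="fit")
        ax.set_xscale("log")
        ax.set_xlabel("lag (s)")
        ax.set_ylabel(r"$g_h$ (nm$^2$)")
        ax.legend()
        return ax
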