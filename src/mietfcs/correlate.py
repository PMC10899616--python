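"""Photon streams, intensity traces, multi-tau correlation and TCSPC fits.

The multi-tau correlator uses the community-standard geometry: ``m`` linear
lags per octave (default 16), with the trace coarsened by pairwise averaging
at every octave so that the lag grid is quasi-logarithmic from the finest bin
up to one tenth of the record length.  The symmetric normalization divides
each lag by the means of the two windows that actually overlap at that lag,
which removes the triangular bias of finite records.  Per-lag standard errors
come from splitting the record into contiguous segments and taking the spread
of the per-segment estimates.

Lifetime histograms are fitted by Poisson maximum likelihood with a
mono-exponential decay plus constant background; diffusion correlation
curves by the standard two-dimensional diffusion model
``g(t) = g(0) / (1 + t/tau_D)`` with ``tau_D = w^2 / (4D)`` where ``w`` is
the 1/e^2 radius of the Gaussian detection profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize

__all__ = [
    "PhotonStream",
    "IntensityTrace",
    "CorrelationCurve",
    "TCSPCHistogram",
    "LifetimeFit",
    "DiffusionFit",
    "bin_photons",
    "multitau_correlate",
    "direct_correlate",
    "coarsen_trace",
    "fit_monoexponential_lifetime",
    "fit_diffusion_acf",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class PhotonStream:
    """Timestamped photon record from a single detector channel."""

    macrotimes: np.ndarray  # arrival times, seconds, sorted
    duration: float  # seconds
    microtimes: np.ndarray | None = None  # TCSPC delays, ns
    channel: int = 0
    excitation_period_ns: float | None = None

    def __post_init__(self) -> None:
        self.macrotimes = np.asarray(self.macrotimes, dtype=float)
        if self.macrotimes.ndim != 1:
            raise ValueError("macrotimes must be 1-D")
        if np.any(np.diff(self.macrotimes) < 0):
            raise ValueError("macrotimes must be non-decreasing")
        if self.macrotimes.size and (
            self.macrotimes[0] < 0 or self.macrotimes[-1] > self.duration
        ):
            raise ValueError("macrotimes must lie within [0, duration]")
        if self.microtimes is not None:
            self.microtimes = np.asarray(self.microtimes, dtype=float)
            if len(self.microtimes) != len(self.macrotimes):
                raise ValueError("microtimes length mismatch")
            if self.excitation_period_ns is not None and self.microtimes.size and (
                np.min(self.microtimes) < 0
                or np.max(self.microtimes) >= self.excitation_period_ns
            ):
                raise ValueError("microtimes must lie in [0, excitation period)")

    def __len__(self) -> int:
        return len(self.macrotimes)


@dataclass
class IntensityTrace:
    """Uniformly binned intensity record (counts per bin)."""

    bin_width: float  # seconds
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or len(self.counts) < 2:
            raise ValueError("counts must be a 1-D array of length >= 2")
        if np.issubdtype(self.counts.dtype, np.integer) and np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def duration(self) -> float:
        return self.bin_width * len(self.counts)


@dataclass
class CorrelationCurve:
    """Correlation estimates on a quasi-logarithmic lag grid."""

    lags: np.ndarray  # seconds, strictly increasing
    values: np.ndarray
    stderr: np.ndarray | None = None
    normalization: str = "fluctuation"
    mean_rate: float = np.nan  # counts/s, for rescaling between normalizations

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
            if np.any(self.stderr < 0):
                raise ValueError("stderr must be >= 0")


@dataclass
class TCSPCHistogram:
    """Fluorescence decay histogram (counts vs micro-time)."""

    bin_edges_ns: np.ndarray
    counts: np.ndarray
    irf: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.bin_edges_ns = np.asarray(self.bin_edges_ns, dtype=float)
        self.counts = np.asarray(self.counts)
        if len(self.bin_edges_ns) != len(self.counts) + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def centers_ns(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ns[:-1] + self.bin_edges_ns[1:])

    @classmethod
    def from_microtimes(
        cls, microtimes_ns: np.ndarray, bin_width_ns: float, period_ns: float
    ) -> "TCSPCHistogram":
        edges = np.arange(0.0, period_ns + bin_width_ns * 0.5, bin_width_ns)
        counts, _ = np.histogram(microtimes_ns, bins=edges)
        return cls(edges, counts)


# --------------------------------------------------------------------------
# binning and correlation
# --------------------------------------------------------------------------

def bin_photons(stream: PhotonStream, bin_width: float) -> IntensityTrace:
    """Histogram photon arrival times into uniform bins covering the record."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    n_bins = max(int(np.ceil(stream.duration / bin_width)), 2)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(stream.macrotimes, bins=edges)
    return IntensityTrace(bin_width=bin_width, counts=counts.astype(np.int64))


def coarsen_trace(x: np.ndarray, levels: int) -> np.ndarray:
    """Pairwise-average coarsening as used between multi-tau octaves."""
    x = np.asarray(x, dtype=float)
    for _ in range(levels):
        n = len(x) // 2
        x = 0.5 * (x[: 2 * n : 2] + x[1 : 2 * n : 2])
    return x


def _lag_products(x: np.ndarray, k: int) -> tuple[float, float, float]:
    """(E[x_i x_{i+k}], mean of left window, mean of right window)."""
    n = len(x) - k
    left = x[:n]
    right = x[k:]
    return float(left @ right) / n, float(left.mean()), float(right.mean())


def _apply_norm(G, mL, mR, normalization, bin_width):
    if normalization == "fluctuation":
        denom = mL * mR
        return (G / denom - 1.0) if denom != 0 else 0.0
    if normalization == "unnormalized":
        return (G - mL * mR) / bin_width**2
    if normalization == "covariance":
        return G - mL * mR
    raise ValueError(f"unknown normalization {normalization!r}")


def _multitau_single(
    x: np.ndarray, bin_width: float, m: int, max_lag: float, normalization: str
):
    lags, vals = [], []
    level = 0
    x_lvl = np.asarray(x, dtype=float)
    while True:
        scale = 2**level
        dt = bin_width * scale
        k_start = 1 if level == 0 else m
        done = False
        for k in range(k_start, 2 * m):
            lag = k * dt
            if lag > max_lag or len(x_lvl) - k < max(4, k_start):
                done = True
                break
            G, mL, mR = _lag_products(x_lvl, k)
            lags.append(lag)
            vals.append(_apply_norm(G, mL, mR, normalization, bin_width))
        if done or len(x_lvl) < 4 * m:
            break
        x_lvl = coarsen_trace(x_lvl, 1)
        level += 1
    return np.asarray(lags), np.asarray(vals)


def multitau_correlate(
    data: IntensityTrace | PhotonStream,
    m: int = 16,
    normalization: Literal["fluctuation", "unnormalized", "covariance"] = "fluctuation",
    bin_width: float | None = None,
    max_lag: float | None = None,
    n_segments: int = 10,
) -> CorrelationCurve:
    """Multi-tau autocorrelation of a binned trace or photon stream.

    Photon streams are first binned at ``bin_width`` (the finest lag).  The
    maximum lag defaults to one tenth of the record; requesting more is an
    error.  ``stderr`` is estimated from ``n_segments`` contiguous blocks.

    Normalizations: ``fluctuation`` returns <dI dI>/<I>^2, ``unnormalized``
    the rate covariance <dI dI> in counts^2/s^2, ``covariance`` the raw
    covariance in (trace units)^2.
    """
    if isinstance(data, PhotonStream):
        if bin_width is None:
            raise ValueError("bin_width is required to correlate a photon stream")
        trace = bin_photons(data, bin_width)
    else:
        trace = data
    x = np.asarray(trace.counts, dtype=float)
    duration = trace.duration
    if max_lag is None:
        max_lag = duration / 10.0
    elif max_lag > duration / 10.0:
        raise ValueError(
            f"record of {duration:.3g} s is too short for max lag {max_lag:.3g} s "
            "(need max lag <= duration/10)"
        )
    if max_lag < trace.bin_width:
        raise ValueError("max lag is below the bin width")

    lags, vals = _multitau_single(x, trace.bin_width, m, max_lag, normalization)

    stderr = None
    if n_segments and n_segments >= 2:
        seg_len = len(x) // n_segments
        seg_vals = []
        if seg_len >= 4 * m:
            for i in range(n_segments):
                seg = x[i * seg_len : (i + 1) * seg_len]
                sl, sv = _multitau_single(
                    seg, trace.bin_width, m, max_lag, normalization
                )
                seg_vals.append((sl, sv))
            stderr = np.full_like(vals, np.nan)
            for j, lag in enumerate(lags):
                per_seg = [
                    sv[np.searchsorted(sl, lag)]
                    for sl, sv in seg_vals
                    if np.searchsorted(sl, lag) < len(sl)
                    and np.isclose(sl[min(np.searchsorted(sl, lag), len(sl) - 1)], lag)
                ]
                if len(per_seg) >= 3:
                    stderr[j] = np.std(per_seg, ddof=1) / np.sqrt(len(per_seg))
            # lags too long for the segments get an extrapolated error: the
            # variance of an ACF estimate grows roughly linearly with lag for
            # a fixed record, so extend the last resolved error with sqrt(lag)
            finite = np.isfinite(stderr)
            if np.any(finite):
                i_last = int(np.nonzero(finite)[0][-1])
                ref = max(stderr[i_last], np.nanmax(stderr) * 0.1)
                stderr = np.where(
                    finite, stderr, ref * np.sqrt(lags / lags[i_last])
                )
            else:
                stderr = None

    mean_rate = float(x.mean() / trace.bin_width)
    return CorrelationCurve(lags, vals, stderr, normalization, mean_rate)


def direct_correlate(
    trace: IntensityTrace,
    lag_bins: Sequence[int],
    normalization: str = "fluctuation",
) -> CorrelationCurve:
    """Brute-force correlation at integer lag bins with the same symmetric
    normalization as the multi-tau estimator (reference implementation)."""
    x = np.asarray(trace.counts, dtype=float)
    lags, vals = [], []
    for k in lag_bins:
        if not 0 < k < len(x):
            raise ValueError("lag bins must lie in (0, len(trace))")
        G, mL, mR = _lag_products(x, int(k))
        lags.append(k * trace.bin_width)
        vals.append(_apply_norm(G, mL, mR, normalization, trace.bin_width))
    return CorrelationCurve(np.asarray(lags), np.asarray(vals), None, normalization)


# --------------------------------------------------------------------------
# TCSPC lifetime fitting
# --------------------------------------------------------------------------

@dataclass
class LifetimeFit:
    tau_ns: float
    stderr_ns: float
    amplitude: float
    background: float
    success: bool
    message: str = ""


def _poisson_nll(theta, t, counts, fixed_bg):
    a, tau = np.exp(theta[0]), np.exp(theta[1])
    b = np.exp(theta[2]) if fixed_bg is None else fixed_bg
    mu = a * np.exp(-t / tau) + b
    mu = np.maximum(mu, 1e-300)
    return float(np.sum(mu - counts * np.log(mu)))


def fit_monoexponential_lifetime(
    hist: TCSPCHistogram,
    fit_window_ns: tuple[float, float] | None = None,
    background: Literal["fit"] | float = "fit",
) -> LifetimeFit:
    """Poisson maximum-likelihood mono-exponential tail fit.

    ``fit_window_ns`` selects the tail region (defaults to everything from
    the histogram peak onwards).  The background is either floated ("fit")
    or held at a fixed counts-per-bin value.  The standard error comes from
    the curvature (observed information) at the optimum.
    """
    t_all = hist.centers_ns
    c_all = np.asarray(hist.counts, dtype=float)
    if fit_window_ns is None:
        i0 = int(np.argmax(c_all))
        sel = slice(i0, None)
    else:
        lo, hi = fit_window_ns
        if lo < hist.bin_edges_ns[0] or hi > hist.bin_edges_ns[-1]:
            raise ValueError("fit window outside histogram support")
        sel = (t_all >= lo) & (t_all <= hi)
    t = t_all[sel]
    c = c_all[sel]
    if c.sum() < 100:
        raise ValueError("need >= 100 counts in the fit window")
    t0 = t[0]
    t = t - t0

    # non-decaying guard
    half = len(c) // 2
    if half >= 1 and c[:half].mean() <= c[half:].mean():
        return LifetimeFit(np.nan, np.nan, np.nan, np.nan, False, "histogram does not decay")

    fixed_bg = None if background == "fit" else float(background)
    b0 = max(np.mean(c[-max(len(c) // 20, 3):]), 0.1) if fixed_bg is None else fixed_bg
    a0 = max(c[0] - b0, 1.0)
    # crude initial tau from the 1/e point
    target = b0 + a0 / np.e
    idx = np.nonzero(c < target)[0]
    tau0 = t[idx[0]] if idx.size else (t[-1] * 0.5 or 1.0)
    tau0 = max(tau0, (t[1] - t[0]) if len(t) > 1 else 0.01)

    theta0 = [np.log(a0), np.log(tau0)] + ([np.log(b0)] if fixed_bg is None else [])
    if fixed_bg is None:
        fun = lambda th: _poisson_nll(th, t, c, None)
    else:
        fun = lambda th: _poisson_nll([th[0], th[1], 0.0], t, c, fixed_bg)
    sol = minimize(fun, theta0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 20000})
    theta = sol.x

    # observed information by central finite differences
    npar = len(theta)
    hess = np.zeros((npar, npar))
    step = 1e-4
    for i in range(npar):
        for j in range(i, npar):
            ei = np.eye(npar)[i] * step
            ej = np.eye(npar)[j] * step
            hess[i, j] = hess[j, i] = (
                fun(theta + ei + ej) - fun(theta + ei - ej)
                - fun(theta - ei + ej) + fun(theta - ei - ej)
            ) / (4 * step * step)
    se_logtau = np.nan
    try:
        cov = np.linalg.inv(hess)
        se_logtau = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        pass
    if not np.isfinite(se_logtau):
        # background at the boundary (-> 0) makes the full Hessian singular;
        # fall back to the (amplitude, lifetime) block with B held at its MLE
        try:
            cov2 = np.linalg.inv(hess[:2, :2])
            se_logtau = float(np.sqrt(max(cov2[1, 1], 0.0)))
        except np.linalg.LinAlgError:
            pass
    tau = float(np.exp(theta[1]))
    return LifetimeFit(
        tau_ns=tau,
        stderr_ns=tau * se_logtau,
        amplitude=float(np.exp(theta[0])),
        background=float(np.exp(theta[2])) if fixed_bg is None else fixed_bg,
        success=bool(sol.success),
        message=sol.message if not sol.success else "",
    )


# --------------------------------------------------------------------------
# 2-D diffusion ACF fitting
# --------------------------------------------------------------------------

@dataclass
class DiffusionFit:
    D_um2_s: float
    n_molecules: float
    offset: float
    tau_d_s: float
    stderr_D: float
    success: bool
    low_amplitude: bool = False
    message: str = ""


def fit_diffusion_acf(
    curve: CorrelationCurve,
    w_nm: float,
    free: Sequence[str] = ("N", "D", "offset"),
) -> DiffusionFit:
    """Weighted least-squares fit of g(t) = (1/N) / (1 + t/tau_D) + offset
    with tau_D = w^2/(4D); ``w`` is the 1/e^2 radius of the Gaussian
    detection profile (same convention as the simulator)."""
    if len(curve.lags) < 20:
        raise ValueError("need >= 20 lags spanning the decay")
    t = curve.lags
    g = curve.values
    if curve.stderr is not None and np.all(curve.stderr > 0):
        wgt = 1.0 / curve.stderr
    else:
        wgt = np.ones_like(g)

    n_head = max(len(g) // 10, 2)
    g0_est = float(np.mean(g[:n_head]))
    g_tail = float(np.mean(g[-n_head:]))
    if g0_est <= g_tail + 1e-15 and g0_est <= 0:
        return DiffusionFit(np.nan, np.inf, g_tail, np.nan, np.nan, False,
                            low_amplitude=True, message="no decaying amplitude")

    amp0 = max(g0_est - g_tail, 1e-12)
    # initial tau_d from half-amplitude crossing
    below = np.nonzero(g < g_tail + 0.5 * amp0)[0]
    tau0 = t[below[0]] if below.size else t[len(t) // 2]
    fit_offset = "offset" in free

    def resid(theta):
        a, tau_d = np.exp(theta[0]), np.exp(theta[1])
        c = theta[2] if fit_offset else 0.0
        return (a / (1.0 + t / tau_d) + c - g) * wgt

    theta0 = np.array([np.log(amp0), np.log(tau0), 0.0 if fit_offset else 0.0][: 2 + fit_offset])
    sol = least_squares(resid, theta0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=5000)
    a = float(np.exp(sol.x[0]))
    tau_d = float(np.exp(sol.x[1]))
    offset = float(sol.x[2]) if fit_offset else 0.0

    w_um = w_nm * 1e-3
    D = w_um**2 / (4.0 * tau_d)

    # stderr of D by delta method from the log-tau_d variance
    try:
        jtj = sol.jac.T @ sol.jac
        cov = np.linalg.inv(jtj)
        dof = max(len(g) - len(sol.x), 1)
        if curve.stderr is None or not np.all(curve.stderr > 0):
            cov = cov * (sol.fun @ sol.fun) / dof
        se_logtau = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se_logtau = np.nan
    low_amp = a < 10 * np.finfo(float).eps or a < 1e-3 * np.max(np.abs(g) + 1e-300)
    return DiffusionFit(
        D_um2_s=D,
        n_molecules=np.inf if low_amp else 1.0 / a,
        offset=offset,
        tau_d_s=tau_d,
        stderr_D=D * se_logtau,
        success=bool(sol.success) and not low_amp,
        low_amplitude=bool(low_amp),
    )
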