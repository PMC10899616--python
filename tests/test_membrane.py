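"""Confined-membrane undulation model: damping, spectrum integral, fits."""

import dataclasses
import warnings

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss
from scipy.signal import lfilter

from mietfcs import membrane as mb
from mietfcs.membrane import (
    KB,
    HeightCorrelation,
    MembraneParams,
    MembraneUndulationModel,
    ParameterInconsistencyError,
    damping_rate,
    fluctuation_amplitude,
    height_correlation_model,
    intensity_to_height,
    relaxation_time,
)

GUV = MembraneParams()  # published deflated-vesicle means
RBC = MembraneParams(sigma=2.7e-6, kappa=3.9e-20, h0=36.4e-9)


# --------------------------------------------------------------------------
# damping rate
# --------------------------------------------------------------------------

def test_damping_lubrication_limit():
    p = GUV
    q = 1e-4 / p.h0
    e = p.kappa * q**4 + p.sigma * q**2 + p.gamma_pot
    expected = e * q * q * p.h0**3 / (12.0 * p.eta)
    assert abs(damping_rate(q, p) / expected - 1.0) < 1e-6


def test_damping_free_membrane_limit():
    p = GUV
    q = 20.0 / p.h0
    e = p.kappa * q**4 + p.sigma * q**2 + p.gamma_pot
    expected = e / (4.0 * p.eta * q)
    assert abs(damping_rate(q, p) / expected - 1.0) < 1e-4


def test_damping_scales_inversely_with_viscosity():
    q = np.geomspace(GUV.q_min, GUV.q_max, 7)
    thick = dataclasses.replace(GUV, eta=2 * GUV.eta)
    assert np.allclose(damping_rate(q, thick), 0.5 * damping_rate(q, GUV), rtol=1e-12)


def test_damping_continuous_across_series_switch():
    p = GUV
    for x0 in (0.05, 20.0):  # series/exact and exact/asymptotic boundaries
        q = np.array([x0 * (1 - 1e-9), x0 * (1 + 1e-9)]) / p.h0
        g = damping_rate(q, p)
        assert abs(g[1] / g[0] - 1.0) < 1e-6


def test_damping_rejects_nonpositive_q():
    with pytest.raises(ValueError):
        damping_rate(0.0, GUV)


# --------------------------------------------------------------------------
# height-correlation integral
# --------------------------------------------------------------------------

def _reference_quadrature(t, p, n=2000):
    """Independent fixed high-order Gauss-Legendre evaluation directly in q."""
    x, w = leggauss(n)
    q = 0.5 * (p.q_min + p.q_max) + 0.5 * (p.q_max - p.q_min) * x
    wq = 0.5 * (p.q_max - p.q_min) * w
    e = p.kappa * q**4 + p.sigma * q**2 + p.gamma_pot
    arg = -0.25 * p.w**2 * q**2 - damping_rate(q, p) * t
    return KB * p.temperature / (2 * np.pi) * np.sum(wq * q / e * np.exp(arg))


@pytest.mark.parametrize("params", [GUV, RBC], ids=["guv", "rbc"])
def test_model_matches_reference_quadrature(params):
    for t in (0.0, 1e-3, 3e-2):
        ref = _reference_quadrature(t, params)
        assert abs(height_correlation_model(t, params) / ref - 1.0) < 1e-6
        assert abs(mb._height_correlation_fixed(np.array([t]), params)[0] / ref - 1.0) < 1e-6


def test_model_decreases_with_confinement_and_tension():
    stiff = dataclasses.replace(GUV, sigma=100 * GUV.sigma, gamma_pot=100 * GUV.gamma_pot)
    assert height_correlation_model(0.0, stiff) < height_correlation_model(0.0, GUV)


def test_model_monotone_in_lag_and_decays():
    t = np.geomspace(1e-5, 3.0, 40)
    g = height_correlation_model(t, GUV)
    assert np.all(np.diff(g) < 0)
    assert g[-1] < 1e-3 * g[0]


def test_quadrature_tolerance_halving():
    t = np.geomspace(1e-6, 0.3, 12)  # spans [0, 10 tau*]
    a = height_correlation_model(t, GUV, rtol=1e-8)
    b = height_correlation_model(t, GUV, rtol=5e-9)
    assert np.max(np.abs(a / b - 1.0)) < 1e-6


def test_inconsistent_cutoffs_rejected():
    bad = dataclasses.replace(GUV, gamma_pot=1e12)  # q_min above 1/h0
    with pytest.raises(ParameterInconsistencyError):
        height_correlation_model(0.0, bad)


# --------------------------------------------------------------------------
# derived observables
# --------------------------------------------------------------------------

def test_psi_is_sqrt_of_lag_zero():
    assert fluctuation_amplitude(GUV) == pytest.approx(
        np.sqrt(height_correlation_model(0.0, GUV)), rel=1e-12
    )


def test_psi_scales_with_sqrt_temperature():
    hot = dataclasses.replace(GUV, temperature=4 * GUV.temperature)
    assert fluctuation_amplitude(hot) == pytest.approx(
        2 * fluctuation_amplitude(GUV), rel=1e-9
    )


def test_psi_vanishes_with_large_tension():
    psis = [
        fluctuation_amplitude(dataclasses.replace(GUV, sigma=s))
        for s in (1e-5, 1e-3, 1e-1)
    ]
    assert psis[0] > psis[1] > psis[2]


def test_relaxation_time_exponential_closed_form():
    tau = 0.02
    lags = np.concatenate([[0.0], np.geomspace(1e-4, 1.0, 400)])
    assert relaxation_time(lags, np.exp(-lags / tau)) == pytest.approx(
        tau * np.log(2), rel=1e-4
    )


def test_relaxation_time_uses_first_crossing():
    lags = np.array([1e-3, 2e-3, 4e-3, 8e-3, 1.6e-2])
    vals = np.array([1.0, 0.4, 0.8, 0.3, 0.1])  # dips, recovers, dips again
    t_half = relaxation_time(lags, vals)
    assert 1e-3 < t_half < 2e-3


def test_relaxation_time_rbc_model_finite():
    t_half = relaxation_time(np.geomspace(1e-5, 10.0, 200), params=RBC)
    assert np.isfinite(t_half) and t_half > 0


def test_relaxation_time_without_crossing_errors():
    lags = np.geomspace(1e-4, 1e-2, 20)
    with pytest.raises(ValueError, match="does not decay"):
        relaxation_time(lags, np.full(20, 1.0))


# --------------------------------------------------------------------------
# intensity -> height conversion
# --------------------------------------------------------------------------

def test_slope_scaling_quarters_amplitude():
    lags = np.geomspace(1e-4, 1.0, 30)
    cov = np.exp(-lags / 0.05) * 1e4
    a = intensity_to_height(lags, cov, slope=1e9, h0=40e-9)
    b = intensity_to_height(lags, cov, slope=2e9, h0=40e-9)
    assert np.allclose(b.values, a.values / 4.0)


def test_zero_slope_rejected():
    with pytest.raises(ValueError, match="slope is zero"):
        intensity_to_height(np.array([1e-3]), np.array([1.0]), 0.0, 40e-9)


def test_linear_regime_warning_outside_domain():
    lags = np.array([1e-3, 2e-3])
    with pytest.warns(UserWarning, match="linear"):
        out = intensity_to_height(lags, np.ones(2), 1e9, h0=80e-9)
    assert out.linear_regime_warning
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        ok = intensity_to_height(lags, np.ones(2), 1e9, h0=40e-9)
    assert not ok.linear_regime_warning


def test_linear_intensity_map_recovers_ou_variance():
    """I(t) = a h(t) + c with h an OU process: the converted g_h at the
    first lag reproduces the OU variance within 2% (long record)."""
    rng = np.random.default_rng(9)
    gam, var, dt, n = 100.0, (3e-9) ** 2, 1e-4, 3_000_000
    decay = np.exp(-gam * dt)
    noise = rng.standard_normal(n) * np.sqrt(var * (1 - decay**2))
    noise[0] = rng.standard_normal() * np.sqrt(var)
    h = lfilter([1.0], [1.0, -decay], noise)
    a, c = 5e12, 2e4  # counts/s per m, counts/s
    intensity = a * h + c
    from mietfcs.correlate import IntensityTrace, multitau_correlate

    curve = multitau_correlate(
        IntensityTrace(dt, intensity * dt), normalization="unnormalized", n_segments=0
    )
    gh = intensity_to_height(curve.lags, curve.values, a, h0=40e-9)
    expected = var * np.exp(-gam * gh.lags[0])
    assert abs(gh.values[0] / expected - 1.0) < 0.02


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------

def _noiseless_curve(params, n=60):
    lags = np.geomspace(1e-6, 1.0, n)
    return HeightCorrelation(lags, height_correlation_model(lags, params))


def test_fixed_parameter_fit_is_residual_only():
    curve = _noiseless_curve(GUV, 20)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = MembraneUndulationModel(curve, GUV, free=()).fit()
    assert res.cov_log.size == 0
    assert res.residual_norm < 1e-12 * curve.values[0] * len(curve.lags)
    assert res.psi == pytest.approx(fluctuation_amplitude(GUV), rel=1e-6)


def test_free_parameter_validation():
    curve = _noiseless_curve(GUV, 20)
    with pytest.raises(ValueError, match="cannot free"):
        MembraneUndulationModel(curve, GUV, free=("eta",))


def test_tail_restricted_fit_has_inflated_uncertainty():
    """Without the lag-0 amplitude anchor (data only beyond 5 tau*), the
    reported parameter uncertainties blow up by orders of magnitude."""
    rng = np.random.default_rng(13)
    tau_star = 0.031
    full_lags = np.geomspace(1e-5, 60 * tau_star, 50)
    tail_lags = np.geomspace(5.5 * tau_star, 60 * tau_star, 50)
    noise = 0.02 * height_correlation_model(0.0, GUV)  # absolute floor
    results = {}
    for name, lags in (("full", full_lags), ("tail", tail_lags)):
        g = height_correlation_model(lags, GUV)
        err = noise * np.ones_like(g)
        curve = HeightCorrelation(lags, g + rng.standard_normal(len(g)) * err, err)
        start = MembraneParams(sigma=3 * GUV.sigma, gamma_pot=3 * GUV.gamma_pot)
        results[name] = MembraneUndulationModel(curve, start).fit()
    rel_full = results["full"].bse["gamma_pot"] / results["full"].params.gamma_pot
    rel_tail = results["tail"].bse["gamma_pot"] / results["tail"].params.gamma_pot
    assert rel_tail > 4 * rel_full
    assert rel_tail > 0.3  # grossly uncertain without the amplitude anchor


def test_summary_and_report_contain_observables():
    curve = _noiseless_curve(GUV, 30)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = MembraneUndulationModel(
            curve, MembraneParams(sigma=3 * GUV.sigma, gamma_pot=3 * GUV.gamma_pot)
        ).fit()
    text = res.summary()
    assert "psi" in text and "tau*" in text and "sigma" in text
    rep = res.report_dict()
    assert rep["psi_nm"] == pytest.approx(res.psi * 1e9)
    assert set(rep["flags"]) >= {"converged", "ill_conditioned", "linear_regime_warning"}
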