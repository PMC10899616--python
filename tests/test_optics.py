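"""Electrodynamics of dipole emission near layered substrates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mietfcs import optics
from mietfcs.optics import (
    Emitter,
    LayerStack,
    Objective,
    OpticalLayer,
    build_calibration,
    dipole_powers,
    farfield_fractions,
    interface_response,
    relative_brightness,
    relative_lifetime,
)

K0 = 2.0 * np.pi / 680.0
WATER, GLASS = 1.33, 1.52


# --------------------------------------------------------------------------
# interface response
# --------------------------------------------------------------------------

def test_identical_media_reflect_nothing():
    stack = LayerStack(WATER, (OpticalLayer(50.0, WATER + 0j, "w"),), WATER)
    for pol in ("s", "p"):
        for q in (0.0, 0.005, 0.012):
            r, t = interface_response(stack, 680.0, q, pol)
            assert abs(r) < 1e-12
            # t carries only the propagation phase through the layer
            assert abs(abs(t) - 1.0) < 1e-9


def test_fresnel_normal_incidence_closed_form():
    r, _ = interface_response(optics.bare_glass(), 680.0, 0.0, "s")
    assert abs(abs(r) - (GLASS - WATER) / (GLASS + WATER)) < 1e-12


def _airy_single_layer(n1, n2, n3, d_nm, wavelength, q, pol):
    """Independent multiple-reflection (Airy) summation for one layer."""
    k0 = 2 * np.pi / wavelength
    kz = [np.sqrt(complex(n * n * k0 * k0 - q * q)) for n in (n1, n2, n3)]
    kz = [k if k.imag >= 0 else -k for k in kz]

    def fresnel(i, j, ni, nj):
        if pol == "s":
            r = (kz[i] - kz[j]) / (kz[i] + kz[j])
            t = 2 * kz[i] / (kz[i] + kz[j])
        else:
            den = nj * nj * kz[i] + ni * ni * kz[j]
            r = (nj * nj * kz[i] - ni * ni * kz[j]) / den
            t = 2 * nj * nj * kz[i] / den
        return r, t

    r12, t12 = fresnel(0, 1, n1, n2)
    r21, t21 = fresnel(1, 0, n2, n1)
    r23, t23 = fresnel(1, 2, n2, n3)
    ph = np.exp(1j * kz[1] * d_nm)
    # explicit geometric series of bounce orders
    r_tot = r12
    t_tot = 0.0
    bounce = t12 * ph
    for _ in range(2000):
        t_tot += bounce * t23
        r_tot_new = r_tot + bounce * r23 * ph * t21
        bounce = bounce * r23 * ph * r21 * ph
        r_tot = r_tot_new
        if abs(bounce) < 1e-18:
            break
    return r_tot, t_tot


@pytest.mark.parametrize("pol", ["s", "p"])
def test_gold_layer_matches_airy_summation(pol):
    n_au = complex(0.146, 3.6816)  # interpolated table value at 680 nm
    # stack is seen from the water side; 45 degree internal angle in water
    q = WATER * K0 * np.sin(np.pi / 4)
    stack = LayerStack(GLASS, (OpticalLayer(10.0, n_au, "Au"),), WATER)
    r, t = interface_response(stack, 680.0, q, pol)
    r_ref, t_ref = _airy_single_layer(WATER, n_au, GLASS, 10.0, 680.0, q, pol)
    assert abs(r - r_ref) < 1e-10
    assert abs(t - t_ref) < 1e-10


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    n_layers=st.integers(1, 3),
    data=st.data(),
)
def test_energy_conservation_lossless_stacks(n_layers, data):
    """|r|^2 + transmitted flux = 1 for arbitrary lossless stacks at any
    propagating angle."""
    layers = tuple(
        OpticalLayer(
            data.draw(st.floats(1.0, 200.0)),
            complex(data.draw(st.floats(1.2, 2.5)), 0.0),
            f"L{i}",
        )
        for i in range(n_layers)
    )
    stack = LayerStack(GLASS, layers, WATER)
    s = data.draw(st.floats(0.0, 0.999))
    q = WATER * K0 * s
    kz1 = np.sqrt((WATER * K0) ** 2 - q * q)
    kzg = np.sqrt(complex((GLASS * K0) ** 2 - q * q))
    for pol in ("s", "p"):
        r, t = interface_response(stack, 680.0, q, pol)
        if pol == "s":
            flux = (kzg / kz1 * abs(t) ** 2).real
        else:
            flux = ((kzg / GLASS**2) / (kz1 / WATER**2) * abs(t) ** 2).real
        assert abs(abs(r) ** 2 + flux - 1.0) < 1e-10


def test_invalid_layers_rejected():
    with pytest.raises(ValueError):
        OpticalLayer(0.0, 1.5 + 0j, "zero")
    with pytest.raises(ValueError):
        OpticalLayer(10.0, complex(np.nan, 0.0), "nan")
    with pytest.raises(ValueError):
        OpticalLayer(10.0, 1.5 - 0.1j, "gain")


# --------------------------------------------------------------------------
# dipole powers
# --------------------------------------------------------------------------

def test_homogeneous_scene_unit_powers(emitter):
    hs = optics.homogeneous_stack()
    for h in (0.5, 30.0, 200.0):
        sp, sl = dipole_powers(hs, emitter, h)
        assert abs(sp - 1.0) < 1e-9
        assert abs(sl - 1.0) < 1e-9


def test_perfect_mirror_closed_form(emitter):
    """Image-dipole interference above an ideal reflector."""
    mirror = LayerStack(1e8 * (1 + 1j), (), WATER)
    k1 = WATER * K0
    for h in np.linspace(10.0, 500.0, 17):
        a = 2 * k1 * h
        s_perp_ref = 1 + 3 * (np.sin(a) / a**3 - np.cos(a) / a**2)
        s_par_ref = 1 - 1.5 * (np.sin(a) / a + np.cos(a) / a**2 - np.sin(a) / a**3)
        sp, sl = dipole_powers(mirror, emitter, h)
        assert abs(sp - s_perp_ref) < 1e-6
        assert abs(sl - s_par_ref) < 1e-6


def test_gold_quenching_diverges_near_contact(emitter, gold_stack):
    rates = [sum(dipole_powers(gold_stack, emitter, h)) for h in (1.0, 5.0, 30.0)]
    assert rates[0] > 10 * rates[2]
    assert rates[0] > rates[1] > rates[2]


def test_negative_height_rejected(emitter, gold_stack):
    with pytest.raises(ValueError):
        dipole_powers(gold_stack, emitter, -1.0)


# --------------------------------------------------------------------------
# far field and collection
# --------------------------------------------------------------------------

def test_homogeneous_collection_geometry(emitter):
    """With NA below the medium index, the collected fraction of the
    downward emission equals the closed-form pattern integrals."""
    from scipy.integrate import quad

    hs = optics.homogeneous_stack()
    obj = Objective(numerical_aperture=1.0, immersion_index=1.52)
    smax = 1.0 / WATER
    Np, Nl, Cp, Cl = farfield_fractions(hs, emitter, obj, 30.0)
    c_perp = quad(lambda s: s**3 / np.sqrt(1 - s * s), 0, smax)[0] / (2.0 / 3.0)
    c_par = quad(lambda s: s * (2 - s * s) / np.sqrt(1 - s * s), 0, smax)[0] / (4.0 / 3.0)
    assert abs(Np - 0.5) < 1e-9 and abs(Nl - 0.5) < 1e-9
    assert abs(Cp - c_perp) < 1e-9
    assert abs(Cl - c_par) < 1e-9


def test_farfield_below_total_emission(emitter, objective, gold_stack):
    for h in (5.0, 30.0, 120.0):
        sp, sl = dipole_powers(gold_stack, emitter, h)
        Np, Nl, Cp, Cl = farfield_fractions(gold_stack, emitter, objective, h)
        assert 0.0 < Np < sp and 0.0 < Nl < sl
        assert 0.0 <= Cp <= 1.0 and 0.0 <= Cl <= 1.0


def test_quadrature_stable_under_node_doubling(emitter, objective, gold_stack):
    h = 30.0
    coarse = farfield_fractions(gold_stack, emitter, objective, h, nodes=32)
    fine = farfield_fractions(gold_stack, emitter, objective, h, nodes=96)
    assert np.allclose(coarse, fine, rtol=1e-6)
    b32 = relative_brightness(gold_stack, emitter, objective, 50.0, nodes=32)
    b96 = relative_brightness(gold_stack, emitter, objective, 50.0, nodes=96)
    assert abs(b32 / b96 - 1.0) < 1e-5
    s32 = dipole_powers(gold_stack, emitter, h, nodes=32)
    s96 = dipole_powers(gold_stack, emitter, h, nodes=96)
    assert np.allclose(s32, s96, rtol=1e-6)


# --------------------------------------------------------------------------
# lifetime and brightness
# --------------------------------------------------------------------------

def test_zero_quantum_yield_gives_free_lifetime(gold_stack):
    dark = Emitter(quantum_yield=0.0)
    for h in (1.0, 40.0, 150.0):
        assert abs(relative_lifetime(gold_stack, dark, h) - 1.0) < 1e-12


def test_homogeneous_lifetime_and_brightness_are_unity(emitter, objective):
    hs = optics.homogeneous_stack()
    assert abs(relative_lifetime(hs, emitter, 25.0) - 1.0) < 1e-9
    assert abs(relative_brightness(hs, emitter, objective, 25.0) - 1.0) < 1e-9


def test_lifetime_monotone_near_contact(emitter):
    """tau_f/tau_0 strictly increasing on [0, 25] nm for both default
    substrate presets."""
    for stack in (optics.miet_gold_default(), optics.giet_graphene(10.0, pll=True)):
        hs = np.linspace(0.5, 25.0, 15)
        tau = [relative_lifetime(stack, emitter, h) for h in hs]
        assert np.all(np.diff(tau) > 0), stack.label


def test_lifetime_smooth_in_height(emitter, gold_stack):
    """No discontinuities: the curve at 0.1 nm spacing is locally linear to
    high order (second differences are a small fraction of first ones)."""
    hs = np.arange(20.0, 22.0, 0.1)
    tau = np.array([relative_lifetime(gold_stack, emitter, h) for h in hs])
    d1 = np.diff(tau)
    d2 = np.abs(np.diff(d1))
    assert np.max(d2) < 0.02 * np.max(np.abs(d1))


# --------------------------------------------------------------------------
# calibration curves
# --------------------------------------------------------------------------

def test_transparent_stack_calibration(emitter, objective):
    stack = LayerStack(WATER, (OpticalLayer(20.0, WATER + 0j, "w"),), WATER)
    curve = build_calibration(stack, emitter, objective, np.linspace(0.5, 100, 60))
    assert curve.monotone_domain_nm[1] == pytest.approx(100.0)
    assert np.max(np.abs(curve.relative_brightness - 1.0)) < 1e-6
    assert np.max(np.abs(curve.brightness_slope_per_nm)) < 1e-6


def test_height_inversion_round_trip(gold_calibration):
    rng = np.random.default_rng(5)
    lo, hi = gold_calibration.monotone_domain_nm
    tau0 = 2.0
    hs = rng.uniform(lo + 0.1, hi - 0.1, 200)
    errs = [
        abs(
            gold_calibration.height_from_lifetime(
                tau0 * gold_calibration.lifetime_at(h), tau0
            )
            - h
        )
        for h in hs
    ]
    assert max(errs) < 0.05


def test_height_inversion_out_of_range(gold_calibration):
    with pytest.raises(ValueError, match="outside the invertible range"):
        gold_calibration.height_from_lifetime(1e-6, 2.0)
    with pytest.raises(ValueError, match="outside the invertible range"):
        gold_calibration.height_from_lifetime(10.0, 2.0)


def test_calibration_grid_validation(emitter, objective, gold_stack):
    with pytest.raises(ValueError):
        build_calibration(gold_stack, emitter, objective, [10.0, 5.0, 20.0])
    with pytest.raises(ValueError):
        build_calibration(gold_stack, emitter, objective, [0.0, 10.0, 20.0])
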