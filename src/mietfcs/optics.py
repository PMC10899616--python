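"""Emission of a dipole above a planar layered MIET/GIET substrate.

This module computes the electrodynamics underlying metal-/graphene-induced
energy transfer (MIET/GIET): the total emission power of an oscillating
electric dipole at height ``h`` above a stratified substrate, the far-field
power transmitted into the glass half-space, the fraction collected by a
high-NA objective, and from these the distance-dependent relative fluorescence
lifetime and detectable brightness of a fluorophore.

The formalism is the classical angular-spectrum (plane-wave) representation of
dipole radiation near stratified media: the dipole field is decomposed into
s- and p-polarized plane waves with normalized in-plane wavevector
``s = q / (n_medium k0)``; the substrate enters only through its Fresnel
reflection and transmission amplitudes, evaluated with a transfer-matrix
(Parratt) recursion.  Normalized total emission powers follow the standard
half-space formulas

    S_perp/S0 = 1 + (3/2) Int_0^inf Re[(s^3/s_z) r_p e^{2 i k1 s_z h}] ds
    S_par /S0 = 1 + (3/4) Int_0^inf Re[(s/s_z)(r_s - s_z^2 r_p) e^{2 i k1 s_z h}] ds

with ``s_z = sqrt(1 - s^2)`` (Im >= 0) and ``r_s, r_p`` the stack reflection
amplitudes seen from the emitter's medium.  The glass-side far field is the
transmitted plane-wave flux, including the supercritical ("forbidden light")
channel ``1 < s < n_glass/n_medium`` that dominates collection through a
high-NA oil objective.

Conventions
-----------
* ``h`` is the dipole's distance from the top surface of the topmost finite
  layer (e.g. from the BSA surface when a BSA layer is part of the stack).
* p-polarized amplitudes use the magnetic-field (H) convention, for which the
  perfect-mirror limit is ``r_s -> -1``, ``r_p -> +1``.
* The collection fraction ``C`` is the fraction of the glass-side far-field
  power ``N`` that falls inside the objective's acceptance cone (internal
  angles ``<= arcsin(NA/n_glass)``), so that the brightness integrand
  ``(N/S) C = N_coll/S`` is the detected fraction of all emitted power and the
  relative brightness approaches the net transparency of the substrate far
  from it.
* Brightness values are normalized to an identical-index scene without any
  substrate, so ``b = 1`` means "as bright as in free medium".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.optimize import brentq

from .materials import GRAPHENE_THICKNESS_NM, refractive_index

__all__ = [
    "OpticalLayer",
    "LayerStack",
    "Emitter",
    "Objective",
    "CalibrationCurve",
    "interface_response",
    "dipole_powers",
    "farfield_fractions",
    "relative_lifetime",
    "relative_brightness",
    "build_calibration",
    "lifetime_to_height",
    "miet_gold_default",
    "giet_graphene",
    "bare_gold",
    "bare_graphene",
    "bare_glass",
    "homogeneous_stack",
]


# --------------------------------------------------------------------------
# scene description
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalLayer:
    """A finite homogeneous layer of the substrate stack."""

    thickness_nm: float
    refractive_index: complex
    label: str = ""

    def __post_init__(self) -> None:
        n = complex(self.refractive_index)
        if not np.isfinite(self.thickness_nm) or self.thickness_nm <= 0:
            raise ValueError(
                f"layer {self.label!r}: thickness must be positive and finite, "
                f"got {self.thickness_nm}"
            )
        if not (np.isfinite(n.real) and np.isfinite(n.imag)):
            raise ValueError(f"layer {self.label!r}: refractive index is not finite")
        if n.imag < 0:
            raise ValueError(
                f"layer {self.label!r}: imaginary part of the index must be >= 0 "
                "(passive material)"
            )


@dataclass(frozen=True)
class LayerStack:
    """Ordered substrate description: glass half-space, finite layers
    (bottom -> top), aqueous half-space on top where the emitter lives.

    The height origin ``h = 0`` is the top surface of the topmost finite
    layer (or the glass surface if there are no layers).
    """

    lower_halfspace_index: complex = 1.52
    layers: tuple[OpticalLayer, ...] = ()
    upper_halfspace_index: float = 1.33
    label: str = ""

    def __post_init__(self) -> None:
        n_up = self.upper_halfspace_index
        if isinstance(n_up, complex) and n_up.imag != 0:
            raise ValueError("upper half-space index must be real (aqueous medium)")
        if not float(np.real(n_up)) > 1.0:
            raise ValueError("upper half-space index must be real and > 1")
        object.__setattr__(self, "layers", tuple(self.layers))

    def media_top_down(self) -> tuple[np.ndarray, np.ndarray]:
        """Refractive indices from the emitter's medium down to the glass,
        and thicknesses of the interior layers (same order, first and last
        entries are half-spaces with thickness 0)."""
        ns = [complex(self.upper_halfspace_index)]
        ds = [0.0]
        for layer in reversed(self.layers):
            ns.append(complex(layer.refractive_index))
            ds.append(float(layer.thickness_nm))
        ns.append(complex(self.lower_halfspace_index))
        ds.append(0.0)
        return np.asarray(ns, dtype=complex), np.asarray(ds, dtype=float)


@dataclass(frozen=True)
class Emitter:
    """A fluorescent dipole emitter.

    orientation is either the fixed polar angle beta (radians, measured from
    the surface normal) or the string ``"random"`` for a fast-rotating dye.
    """

    wavelength_nm: float = 680.0
    quantum_yield: float = 0.8
    free_lifetime_ns: float = 3.0
    orientation: float | Literal["random"] = "random"

    def __post_init__(self) -> None:
        if not 0.0 <= self.quantum_yield <= 1.0:
            raise ValueError("quantum yield must lie in [0, 1]")
        if self.free_lifetime_ns <= 0:
            raise ValueError("free-space lifetime must be positive")
        if self.wavelength_nm <= 0:
            raise ValueError("emission wavelength must be positive")


@dataclass(frozen=True)
class Objective:
    numerical_aperture: float = 1.49
    immersion_index: float = 1.52

    def __post_init__(self) -> None:
        if not 0.0 < self.numerical_aperture < self.immersion_index:
            raise ValueError("need 0 < NA < immersion index")


# --------------------------------------------------------------------------
# Fresnel / transfer matrix
# --------------------------------------------------------------------------

def _kz(n: complex, k0: float, q: np.ndarray) -> np.ndarray:
    """Normal wavevector component with Im(kz) >= 0."""
    kz = np.sqrt(np.asarray(n * n * k0 * k0 - q * q, dtype=complex))
    kz = np.where(kz.imag < 0, -kz, kz)
    return kz


def _fresnel(na, kza, nb, kzb):
    """Interface a -> b amplitudes: (r_s, t_s) for the E field, (r_p, t_p)
    for the H field."""
    rs = (kza - kzb) / (kza + kzb)
    ts = 2.0 * kza / (kza + kzb)
    den = nb * nb * kza + na * na * kzb
    rp = (nb * nb * kza - na * na * kzb) / den
    tp = 2.0 * nb * nb * kza / den
    return rs, ts, rp, tp


def _stack_amplitudes(stack: LayerStack, wavelength_nm: float, q: np.ndarray):
    """Reflection/transmission of the full stack seen from the emitter medium.

    Returns (r_s, t_s, r_p, t_p, kz_top, kz_glass) for in-plane wavevector
    array ``q`` (1/nm).  t_s is an E-field amplitude, t_p an H-field
    amplitude (consistent with the r conventions above).
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    if np.any(q < 0):
        raise ValueError("in-plane wavevector must be >= 0")
    k0 = 2.0 * np.pi / wavelength_nm
    ns, ds = stack.media_top_down()
    kz = np.array([_kz(n, k0, q) for n in ns])  # (n_media, n_q)

    n_if = len(ns) - 1
    # bottom-most interface (into glass)
    rs, ts, rp, tp = _fresnel(ns[-2], kz[-2], ns[-1], kz[-1])
    for j in range(n_if - 2, -1, -1):
        rs_j, ts_j, rp_j, tp_j = _fresnel(ns[j], kz[j], ns[j + 1], kz[j + 1])
        ph = np.exp(1j * kz[j + 1] * ds[j + 1])
        ph2 = ph * ph
        den_s = 1.0 + rs_j * rs * ph2
        den_p = 1.0 + rp_j * rp * ph2
        ts = ts_j * ts * ph / den_s
        tp = tp_j * tp * ph / den_p
        rs = (rs_j + rs * ph2) / den_s
        rp = (rp_j + rp * ph2) / den_p
    return rs, ts, rp, tp, kz[0], kz[-1]


def interface_response(
    stack: LayerStack,
    wavelength_nm: float,
    inplane_wavevector: float | np.ndarray,
    polarization: Literal["s", "p"],
) -> tuple[np.ndarray, np.ndarray]:
    """Complex reflection and transmission amplitudes of the stack.

    ``inplane_wavevector`` is in 1/nm; values beyond the light lines
    (evanescent region) are allowed.  For p polarization the amplitudes refer
    to the magnetic field.
    """
    if polarization not in ("s", "p"):
        raise ValueError("polarization must be 's' or 'p'")
    if not np.isfinite(wavelength_nm) or wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    rs, ts, rp, tp, _, _ = _stack_amplitudes(stack, wavelength_nm, inplane_wavevector)
    r, t = (rs, ts) if polarization == "s" else (rp, tp)
    if r.size == 1:
        return complex(r[0]), complex(t[0])
    return r, t


# --------------------------------------------------------------------------
# quadrature helpers
# --------------------------------------------------------------------------

def _gl_panels(edges: np.ndarray, nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights composited over contiguous panels."""
    x0, w0 = leggauss(nodes)
    xs, ws = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        half = 0.5 * (b - a)
        xs.append(0.5 * (a + b) + half * x0)
        ws.append(half * w0)
    return np.concatenate(xs), np.concatenate(ws)


@dataclass
class _Spectra:
    """Per-height emission-power integrals, all in units of S0."""

    S_perp: float
    S_par: float
    N_perp: float = np.nan
    N_par: float = np.nan
    Ncoll_perp: float = np.nan
    Ncoll_par: float = np.nan


def _dipole_spectra(
    stack: LayerStack,
    wavelength_nm: float,
    h_nm: float,
    objective: Objective | None = None,
    nodes: int = 32,
) -> _Spectra:
    if h_nm < 0:
        raise ValueError("emitter height must be >= 0")
    n1 = float(np.real(stack.upper_halfspace_index))
    k1 = 2.0 * np.pi * n1 / wavelength_nm  # 1/nm

    # --- region A: propagating in the medium, s = sin(psi) ------------------
    n_osc = 4 + int(2.0 * k1 * h_nm / np.pi)
    psi_edges = np.linspace(0.0, 0.5 * np.pi, n_osc + 1)
    if objective is not None:
        # make the collection-cone edge a panel boundary so the collected
        # fraction is integrated exactly up to the NA angle
        s_edge = min(
            objective.numerical_aperture, float(np.real(stack.lower_halfspace_index))
        ) / n1
        if s_edge < 1.0:
            psi_edges = np.unique(np.append(psi_edges, np.arcsin(s_edge)))
    psi, wpsi = _gl_panels(psi_edges, nodes)
    sA = np.sin(psi)
    szA = np.cos(psi)
    qA = k1 * sA
    rsA, tsA, rpA, tpA, _, kzgA = _stack_amplitudes(stack, wavelength_nm, qA)
    phase = np.exp(2j * k1 * szA * h_nm)
    # ds = sz dpsi cancels the 1/sz of the standard integrands
    I_perp_A = np.sum(wpsi * np.real(sA**3 * rpA * phase))
    I_par_A = np.sum(wpsi * np.real(sA * (rsA - szA**2 * rpA) * phase))

    # --- region B: evanescent in the medium, s_z = i v ----------------------
    # dense panels at small v resolve the narrow surface-plasmon resonance
    # of metal films just beyond the medium light line; the light line of
    # every lossless medium in the stack is a branch point and gets its own
    # panel edge
    v_max = max(27.63 / (2.0 * k1 * max(h_nm, 1e-3)), 10.0)
    edges = [0.0, 0.05, 0.12, 0.2, 0.3, 0.4, 0.55, 0.75, 1.0]
    while edges[-1] < v_max:
        edges.append(min(edges[-1] * 2.5, v_max))
    ns_all, _ = stack.media_top_down()
    for n_med in ns_all:
        if abs(n_med.imag) < 1e-12 and n_med.real > n1:
            v_line = float(np.sqrt((n_med.real / n1) ** 2 - 1.0))
            if v_line < v_max:
                # the branch point plus short panels on both flanks, where
                # the integrand has sqrt-type behavior
                edges += [v_line, v_line * 0.93, min(v_line * 1.15, v_max)]
    edges = np.unique(np.asarray(edges))
    vB, wvB = _gl_panels(edges, nodes)
    sB = np.sqrt(1.0 + vB * vB)
    qB = k1 * sB
    rsB, _, rpB, tpB, _, kzgB = _stack_amplitudes(stack, wavelength_nm, qB)
    decay = np.exp(-2.0 * k1 * vB * h_nm)
    I_perp_B = np.sum(wvB * sB**2 * np.imag(rpB) * decay)
    I_par_B = np.sum(wvB * np.imag(rsB + vB**2 * rpB) * decay)

    out = _Spectra(
        S_perp=1.0 + 1.5 * (I_perp_A + I_perp_B),
        S_par=1.0 + 0.75 * (I_par_A + I_par_B),
    )
    if not (np.isfinite(out.S_perp) and np.isfinite(out.S_par)):
        raise ArithmeticError(
            f"dipole-power quadrature did not converge at h={h_nm} nm "
            f"(S_perp={out.S_perp}, S_par={out.S_par})"
        )
    if objective is None:
        return out

    # --- far field into the glass ------------------------------------------
    ng = float(np.real(stack.lower_halfspace_index))
    sg = ng / n1
    # collection cone capped at the glass light line (an NA larger than the
    # lower index collects every propagating glass-side mode)
    s_na = min(objective.numerical_aperture, ng) / n1
    ratio2 = (n1 / ng) ** 2

    def _farfield(s, weight, szg, decay2):
        """Transmitted flux densities (units of S0 per unit of the quadrature
        variable, weights already folded in)."""
        q = k1 * s
        _, ts, _, tp, _, _ = _stack_amplitudes(stack, wavelength_nm, q)
        sz2 = np.abs(1.0 - s * s)
        f_perp = 0.75 * s**3 / sz2 * np.abs(tp) ** 2 * szg * ratio2 * decay2
        f_par = 0.375 * (
            s / sz2 * np.abs(ts) ** 2 * szg
            + s * np.abs(tp) ** 2 * szg * ratio2
        ) * decay2
        return np.sum(weight * f_perp), np.sum(weight * f_par)

    # sub-critical part (s < 1): reuse the sin substitution; ds = sz dpsi.
    szgA = np.sqrt(sg * sg - sA * sA)
    NpA, NlA = _farfield(sA, wpsi * szA, szgA, 1.0)
    mask = sA <= s_na
    NpA_c, NlA_c = _farfield(sA[mask], (wpsi * szA)[mask], szgA[mask], 1.0)

    # supercritical part (1 < s < sg): substitute u = s_z,glass.
    u1 = np.sqrt(max(sg * sg - 1.0, 0.0))
    NpS = NlS = NpS_c = NlS_c = 0.0
    if u1 > 1e-9:
        u_na = np.sqrt(max(sg * sg - s_na * s_na, 0.0))
        edges = np.array([0.0, u_na, u1]) if u_na > 1e-9 else np.array([0.0, u1])
        uS, wuS = _gl_panels(edges, 2 * nodes)
        sS = np.sqrt(sg * sg - uS * uS)
        decay2 = np.exp(-2.0 * k1 * np.sqrt(sS * sS - 1.0) * h_nm)
        NpS, NlS = _farfield(sS, wuS * uS / sS, uS, decay2)
        maskS = sS <= s_na
        if np.any(maskS):
            NpS_c, NlS_c = _farfield(
                sS[maskS], (wuS * uS / sS)[maskS], uS[maskS], decay2[maskS]
            )

    out.N_perp = NpA + NpS
    out.N_par = NlA + NlS
    out.Ncoll_perp = NpA_c + NpS_c
    out.Ncoll_par = NlA_c + NlS_c
    return out


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------

def dipole_powers(
    stack: LayerStack, emitter: Emitter, h_nm: float, nodes: int = 32
) -> tuple[float, float]:
    """Normalized total emission powers (S_perp/S0, S_par/S0) at height h."""
    sp = _dipole_spectra(stack, emitter.wavelength_nm, h_nm, nodes=nodes)
    return sp.S_perp, sp.S_par


def farfield_fractions(
    stack: LayerStack,
    emitter: Emitter,
    objective: Objective,
    h_nm: float,
    nodes: int = 32,
) -> tuple[float, float, float, float]:
    """(N_perp/S0, N_par/S0, C_perp, C_par) at height h.

    N is the far-field power radiated into the glass; C is the fraction of N
    that falls inside the objective's collection cone (internal angles up to
    arcsin(NA/n_glass)).
    """
    sp = _dipole_spectra(stack, emitter.wavelength_nm, h_nm, objective, nodes=nodes)
    return (
        sp.N_perp,
        sp.N_par,
        sp.Ncoll_perp / sp.N_perp,
        sp.Ncoll_par / sp.N_par,
    )


def _mean_power(sp: _Spectra, orientation) -> float:
    if orientation == "random":
        return (sp.S_perp + 2.0 * sp.S_par) / 3.0
    beta = float(orientation)
    return sp.S_perp * np.cos(beta) ** 2 + sp.S_par * np.sin(beta) ** 2


def relative_lifetime(
    stack: LayerStack, emitter: Emitter, h_nm: float, nodes: int = 32
) -> float:
    """tau_f(h)/tau_0 = S0 / (phi S(h) + (1 - phi) S0)."""
    phi = emitter.quantum_yield
    if not 0.0 <= phi <= 1.0:
        raise ValueError("quantum yield must lie in [0, 1]")
    sp = _dipole_spectra(stack, emitter.wavelength_nm, h_nm, nodes=nodes)
    s_rel = _mean_power(sp, emitter.orientation)
    return 1.0 / (phi * s_rel + 1.0 - phi)


_BETA_NODES, _BETA_WEIGHTS = leggauss(64)
_BETA = 0.25 * np.pi * (_BETA_NODES + 1.0)
_BETA_W = 0.25 * np.pi * _BETA_WEIGHTS


def _brightness_unnormalized(sp: _Spectra) -> float:
    """Orientation integral of Eq-style brightness: int dbeta sin(beta)
    [N(beta)/S(beta)] C(beta) with C = Ncoll/N, i.e. the detected fraction of
    the total emission averaged over static dipole orientations."""
    c2 = np.cos(_BETA) ** 2
    s2 = 1.0 - c2
    S_beta = sp.S_perp * c2 + sp.S_par * s2
    Ncoll_beta = sp.Ncoll_perp * c2 + sp.Ncoll_par * s2
    return float(np.sum(_BETA_W * np.sin(_BETA) * Ncoll_beta / S_beta))


def homogeneous_stack(n_medium: float = 1.33) -> LayerStack:
    """An identical-index scene with no substrate (the brightness reference)."""
    return LayerStack(
        lower_halfspace_index=complex(n_medium),
        layers=(),
        upper_halfspace_index=n_medium,
        label="homogeneous",
    )


def relative_brightness(
    stack: LayerStack,
    emitter: Emitter,
    objective: Objective,
    h_nm: float,
    nodes: int = 32,
) -> float:
    """Detectable brightness b(h), normalized so the identical-index
    no-substrate scene gives b = 1."""
    sp = _dipole_spectra(stack, emitter.wavelength_nm, h_nm, objective, nodes=nodes)
    ref = _dipole_spectra(
        homogeneous_stack(float(np.real(stack.upper_halfspace_index))),
        emitter.wavelength_nm,
        h_nm,
        objective,
        nodes=nodes,
    )
    return _brightness_unnormalized(sp) / _brightness_unnormalized(ref)


# --------------------------------------------------------------------------
# calibration curves
# --------------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    """Tabulated MIET/GIET calibration: relative lifetime and brightness vs
    height, with the monotone (invertible) lifetime domain and the local
    brightness slope used for intensity -> height conversion."""

    heights_nm: np.ndarray
    relative_lifetime: np.ndarray
    relative_brightness: np.ndarray
    brightness_slope_per_nm: np.ndarray
    monotone_domain_nm: tuple[float, float]
    emitter: Emitter | None = None
    stack_label: str = ""

    def __post_init__(self) -> None:
        n = len(self.heights_nm)
        if not (
            len(self.relative_lifetime) == n
            and len(self.relative_brightness) == n
            and len(self.brightness_slope_per_nm) == n
        ):
            raise ValueError("calibration grids must have equal length")
        self._tau_interp = PchipInterpolator(self.heights_nm, self.relative_lifetime)
        self._b_interp = CubicSpline(self.heights_nm, self.relative_brightness)
        self._slope_interp = CubicSpline(
            self.heights_nm, self.brightness_slope_per_nm
        )

    def lifetime_at(self, h_nm: float) -> float:
        return float(self._tau_interp(h_nm))

    def brightness_at(self, h_nm):
        return self._b_interp(h_nm)

    def slope_at(self, h_nm) -> float:
        """db/dh (1/nm) at height h."""
        return float(self._slope_interp(h_nm))

    def height_from_lifetime(self, lifetime_ns: float, tau0_ns: float) -> float:
        """Invert the lifetime-versus-height relation on the monotone domain."""
        target = lifetime_ns / tau0_ns
        lo, hi = self.monotone_domain_nm
        f_lo = self.lifetime_at(lo)
        f_hi = self.lifetime_at(hi)
        if not f_lo <= target <= f_hi:
            raise ValueError(
                f"relative lifetime {target:.4f} outside the invertible range "
                f"[{f_lo:.4f}, {f_hi:.4f}] (heights {lo:.1f}-{hi:.1f} nm)"
            )
        return float(
            brentq(lambda h: self._tau_interp(h) - target, lo, hi, xtol=1e-9)
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.heights_nm, self.relative_lifetime, label=r"$\tau_f/\tau_0$")
        ax.plot(self.heights_nm, self.relative_brightness, label="b(h)")
        ax.axvline(self.monotone_domain_nm[1], ls=":", color="gray")
        ax.set_xlabel("height h (nm)")
        ax.set_ylabel("relative value")
        ax.legend()
        return ax


def build_calibration(
    stack: LayerStack,
    emitter: Emitter,
    objective: Objective,
    h_grid_nm: Sequence[float] | np.ndarray | None = None,
    nodes: int = 32,
) -> CalibrationCurve:
    """Compute a full calibration curve on ``h_grid_nm`` (strictly
    increasing; heights below 0.1 nm are rejected because the near-field
    quadrature diverges at contact)."""
    if h_grid_nm is None:
        h_grid_nm = np.linspace(0.1, 250.0, 240)
    h = np.asarray(h_grid_nm, dtype=float)
    if h.ndim != 1 or len(h) < 2 or np.any(np.diff(h) <= 0):
        raise ValueError("h_grid_nm must be a strictly increasing 1-D grid")
    if h[0] < 0.1:
        raise ValueError("heights below 0.1 nm are not supported in curve building")

    n1 = float(np.real(stack.upper_halfspace_index))
    ref_spectra = [
        _dipole_spectra(homogeneous_stack(n1), emitter.wavelength_nm, hi, objective, nodes)
        for hi in h
    ]
    spectra = [
        _dipole_spectra(stack, emitter.wavelength_nm, hi, objective, nodes)
        for hi in h
    ]
    phi = emitter.quantum_yield
    tau_rel = np.array(
        [1.0 / (phi * _mean_power(sp, emitter.orientation) + 1.0 - phi) for sp in spectra]
    )
    b = np.array(
        [
            _brightness_unnormalized(sp) / _brightness_unnormalized(ref)
            for sp, ref in zip(spectra, ref_spectra)
        ]
    )

    # slope by centered differences on a refined grid
    spline = CubicSpline(h, b)
    h_fine = np.linspace(h[0], h[-1], 4 * len(h))
    b_fine = spline(h_fine)
    slope_fine = np.gradient(b_fine, h_fine)
    slope = np.interp(h, h_fine, slope_fine)

    # maximal strictly-increasing lifetime interval starting at the grid
    # origin; a relative tolerance keeps numerical noise on flat curves
    # (e.g. fully transparent stacks) from truncating the domain
    d_tau = np.diff(tau_rel)
    falling = np.nonzero(d_tau <= -1e-9 * np.max(np.abs(tau_rel)))[0]
    i_top = int(falling[0]) if falling.size else len(h) - 1
    monotone = (float(h[0]), float(h[i_top]))

    return CalibrationCurve(
        heights_nm=h,
        relative_lifetime=tau_rel,
        relative_brightness=b,
        brightness_slope_per_nm=slope,
        monotone_domain_nm=monotone,
        emitter=emitter,
        stack_label=stack.label,
    )


def lifetime_to_height(
    curve: CalibrationCurve, lifetime_ns: float, tau0_ns: float
) -> float:
    """Module-level alias for :meth:`CalibrationCurve.height_from_lifetime`."""
    return curve.height_from_lifetime(lifetime_ns, tau0_ns)


# --------------------------------------------------------------------------
# named substrate presets
# --------------------------------------------------------------------------

def miet_gold_default(
    wavelength_nm: float = 680.0, bsa: bool = True
) -> LayerStack:
    """Standard MIET substrate: glass | 2 nm Ti | 10 nm Au | 1 nm Ti |
    10 nm SiO2, optionally topped by a 3 nm BSA passivation layer."""
    layers = [
        OpticalLayer(2.0, refractive_index("titanium", wavelength_nm), "Ti"),
        OpticalLayer(10.0, refractive_index("gold", wavelength_nm), "Au"),
        OpticalLayer(1.0, refractive_index("titanium", wavelength_nm), "Ti"),
        OpticalLayer(10.0, refractive_index("silica", wavelength_nm), "SiO2"),
    ]
    if bsa:
        layers.append(OpticalLayer(3.0, refractive_index("bsa", wavelength_nm), "BSA"))
    return LayerStack(1.52, tuple(layers), 1.33, label="miet_gold_default")


def giet_graphene(
    spacer_nm: float,
    wavelength_nm: float = 680.0,
    pll: bool = False,
) -> LayerStack:
    """GIET substrate: glass | graphene (0.34 nm) | SiO2 spacer, optionally
    topped by a 1 nm poly-L-lysine layer."""
    layers = [
        OpticalLayer(
            GRAPHENE_THICKNESS_NM, refractive_index("graphene", wavelength_nm), "graphene"
        )
    ]
    if spacer_nm > 0:
        layers.append(
            OpticalLayer(spacer_nm, refractive_index("silica", wavelength_nm), "SiO2")
        )
    if pll:
        layers.append(OpticalLayer(1.0, refractive_index("pll", wavelength_nm), "PLL"))
    return LayerStack(1.52, tuple(layers), 1.33, label=f"giet_graphene({spacer_nm:g})")


def bare_gold(wavelength_nm: float = 680.0, thickness_nm: float = 10.0) -> LayerStack:
    """A plain gold film on glass (the textbook MIET calibration scene)."""
    return LayerStack(
        1.52,
        (OpticalLayer(thickness_nm, refractive_index("gold", wavelength_nm), "Au"),),
        1.33,
        label="bare_gold",
    )


def bare_graphene(wavelength_nm: float = 680.0) -> LayerStack:
    """A single graphene sheet on glass."""
    return LayerStack(
        1.52,
        (
            OpticalLayer(
                GRAPHENE_THICKNESS_NM,
                refractive_index("graphene", wavelength_nm),
                "graphene",
            ),
        ),
        1.33,
        label="bare_graphene",
    )


def bare_glass() -> LayerStack:
    return LayerStack(1.52, (), 1.33, label="bare_glass")
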