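"""Built-in optical constants for common MIET/GIET substrate materials.

Complex refractive indices at visible/NIR wavelengths, linearly interpolated
in wavelength.  These are compiled from standard tabulations (evaporated gold
and titanium films, fused silica, protein adlayers, and the widely used
effective isotropic index of single-layer graphene).  Every value is a
*default*: any layer can be constructed with an explicit index instead.
"""

from __future__ import annotations

import numpy as np

# wavelength grid (nm), complex n = n' + i n''
_TABLES: dict[str, tuple[np.ndarray, np.ndarray]] = {
    "gold": (
        np.array([500.0, 550.0, 600.0, 650.0, 700.0, 750.0, 800.0]),
        np.array([
            0.97 + 1.87j, 0.43 + 2.46j, 0.25 + 2.99j, 0.17 + 3.44j,
            0.13 + 3.84j, 0.13 + 4.25j, 0.15 + 4.66j,
        ]),
    ),
    "titanium": (
        np.array([500.0, 600.0, 700.0, 800.0]),
        np.array([1.86 + 2.56j, 2.00 + 2.77j, 2.16 + 2.92j, 2.34 + 3.07j]),
    ),
    "silica": (
        np.array([400.0, 680.0, 800.0]),
        np.array([1.470 + 0.0j, 1.456 + 0.0j, 1.453 + 0.0j]),
    ),
    "graphene": (
        # effective homogeneous-layer index of a 0.34 nm graphene sheet
        np.array([500.0, 680.0, 800.0]),
        np.array([2.65 + 1.27j, 2.72 + 1.42j, 2.80 + 1.52j]),
    ),
    "bsa": (np.array([400.0, 800.0]), np.array([1.45 + 0.0j, 1.45 + 0.0j])),
    "pll": (np.array([400.0, 800.0]), np.array([1.45 + 0.0j, 1.45 + 0.0j])),
    "water": (np.array([400.0, 800.0]), np.array([1.33 + 0.0j, 1.33 + 0.0j])),
    "glass": (np.array([400.0, 800.0]), np.array([1.52 + 0.0j, 1.52 + 0.0j])),
}

#: thickness of a single graphene sheet treated as a homogeneous layer (nm)
GRAPHENE_THICKNESS_NM = 0.34


def available_materials() -> list[str]:
    return sorted(_TABLES)


def refractive_index(material: str, wavelength_nm: float) -> complex:
    """Complex refractive index of a built-in material at ``wavelength_nm``.

    Linear interpolation between tabulated points; clamped at the table edges.
    """
    key = material.lower()
    if key not in _TABLES:
        raise KeyError(
            f"unknown material {material!r}; available: {available_materials()}"
        )
    wl, n = _TABLES[key]
    lam = float(wavelength_nm)
    re = np.interp(lam, wl, n.real)
    im = np.interp(lam, wl, n.imag)
    return complex(re, im)
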