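"""File formats for every artifact the toolkit produces.

Curves travel as commented CSV with unit-annotated headers, photon streams as
HDF5 (datasets ``/macrotimes_s``, ``/microtimes_ns``, ``/channel``; attributes
``duration_s``, ``excitation_period_ns``) with a two-column CSV fallback, fit
reports and run logs as JSON.  Run configurations are plain YAML with an
explicit schema version; unknown keys fail fast.  All CSV round-trips are
lossless to double precision (values printed with 17 significant digits).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import yaml

from .correlate import CorrelationCurve, PhotonStream
from .membrane import HeightCorrelation
from .optics import CalibrationCurve, Emitter

__all__ = [
    "calibration_to_csv",
    "calibration_from_csv",
    "correlation_to_csv",
    "correlation_from_csv",
    "height_correlation_to_csv",
    "height_correlation_from_csv",
    "photons_to_hdf5",
    "photons_from_hdf5",
    "photons_to_csv",
    "photons_from_csv",
    "report_to_json",
    "load_config",
    "CONFIG_SCHEMA_VERSION",
]

_FMT = "%.17g"


def _write_table(path, header_comment: str, columns: dict[str, np.ndarray]) -> None:
    names = list(columns)
    data = np.column_stack([np.asarray(columns[k], dtype=float) for k in names])
    np.savetxt(
        path,
        data,
        fmt=_FMT,
        delimiter=",",
        header=header_comment + "\n" + ",".join(names),
        comments="# ",
    )


def _read_table(path) -> tuple[list[str], np.ndarray]:
    names: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line.lstrip("# ").strip()
                if "," in stripped and all(
                    not c.isdigit() for c in stripped.split(",")[0][:1]
                ):
                    names = [c.strip() for c in stripped.split(",")]
            else:
                break
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    return names, data


# -- calibration curves ----------------------------------------------------

def calibration_to_csv(curve: CalibrationCurve, path) -> None:
    _write_table(
        path,
        f"MIET/GIET calibration ({curve.stack_label}); monotone domain "
        f"{curve.monotone_domain_nm[0]:.6g}-{curve.monotone_domain_nm[1]:.6g} nm",
        {
            "h_nm": curve.heights_nm,
            "tau_rel": curve.relative_lifetime,
            "brightness_rel": curve.relative_brightness,
            "dbrightness_dh_per_nm": curve.brightness_slope_per_nm,
        },
    )


def calibration_from_csv(path, emitter: Emitter | None = None) -> CalibrationCurve:
    _, data = _read_table(path)
    h, tau, b, slope = data.T
    d_tau = np.diff(tau)
    falling = np.nonzero(d_tau <= -1e-9 * np.max(np.abs(tau)))[0]
    i_top = int(falling[0]) if falling.size else len(h) - 1
    return CalibrationCurve(
        heights_nm=h,
        relative_lifetime=tau,
        relative_brightness=b,
        brightness_slope_per_nm=slope,
        monotone_domain_nm=(float(h[0]), float(h[i_top])),
        emitter=emitter,
    )


# -- correlation curves ----------------------------------------------------

def correlation_to_csv(curve: CorrelationCurve, path) -> None:
    cols = {"lag_s": curve.lags, "g": curve.values}
    if curve.stderr is not None:
        cols["stderr"] = curve.stderr
    _write_table(path, f"correlation curve; normalization={curve.normalization}", cols)


def correlation_from_csv(path, normalization: str = "fluctuation") -> CorrelationCurve:
    names, data = _read_table(path)
    if data.shape[1] < 2:
        raise ValueError("correlation CSV needs at least lag_s and g columns")
    stderr = None
    if data.shape[1] >= 3:
        stderr = data[:, 2]
    else:
        warnings.warn("no stderr column; downstream fits will use uniform weights")
    # recover the normalization tag from the header comment if present
    with open(path) as fh:
        first = fh.readline()
    if "normalization=" in first:
        normalization = first.split("normalization=")[1].strip()
    return CorrelationCurve(data[:, 0], data[:, 1], stderr, normalization)


# -- height correlations ---------------------------------------------------

def height_correlation_to_csv(curve: HeightCorrelation, path) -> None:
    cols = {"lag_s": curve.lags, "gh_m2": curve.values}
    if curve.stderr is not None:
        cols["stderr_m2"] = curve.stderr
    _write_table(
        path,
        "height correlation; linear_regime_warning="
        + str(curve.linear_regime_warning),
        cols,
    )


def height_correlation_from_csv(path) -> HeightCorrelation:
    _, data = _read_table(path)
    stderr = data[:, 2] if data.shape[1] >= 3 else None
    if stderr is None:
        warnings.warn("no stderr column; downstream fits will use uniform weights")
    with open(path) as fh:
        first = fh.readline()
    warn = "linear_regime_warning=True" in first
    return HeightCorrelation(data[:, 0], data[:, 1], stderr, linear_regime_warning=warn)


# -- photon streams --------------------------------------------------------

def photons_to_hdf5(stream: PhotonStream, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("macrotimes_s", data=stream.macrotimes)
        if stream.microtimes is not None:
            f.create_dataset("microtimes_ns", data=stream.microtimes)
        f.create_dataset(
            "channel", data=np.full(len(stream), stream.channel, dtype=np.int16)
        )
        f.attrs["duration_s"] = stream.duration
        if stream.excitation_period_ns is not None:
            f.attrs["excitation_period_ns"] = stream.excitation_period_ns


def photons_from_hdf5(path) -> PhotonStream:
    import h5py

    with h5py.File(path, "r") as f:
        macro = f["macrotimes_s"][:]
        micro = f["microtimes_ns"][:] if "microtimes_ns" in f else None
        channel = int(f["channel"][0]) if "channel" in f and len(f["channel"]) else 0
        duration = float(f.attrs["duration_s"])
        period = f.attrs.get("excitation_period_ns")
    return PhotonStream(
        macrotimes=macro,
        duration=duration,
        microtimes=micro,
        channel=channel,
        excitation_period_ns=None if period is None else float(period),
    )


def photons_to_csv(stream: PhotonStream, path) -> None:
    """Two-column fallback: macrotime_s, microtime_ns (-1 when absent)."""
    micro = (
        stream.microtimes
        if stream.microtimes is not None
        else np.full(len(stream), -1.0)
    )
    _write_table(
        path,
        f"photon stream; duration_s={stream.duration!r}; "
        f"excitation_period_ns={stream.excitation_period_ns!r}",
        {"macrotime_s": stream.macrotimes, "microtime_ns": micro},
    )


def photons_from_csv(path) -> PhotonStream:
    with open(path) as fh:
        first = fh.readline()
    duration = None
    period = None
    for tok in first.split(";"):
        tok = tok.strip()
        if tok.startswith("duration_s="):
            duration = float(tok.split("=")[1])
        elif tok.startswith("excitation_period_ns="):
            val = tok.split("=")[1]
            period = None if val == "None" else float(val)
    _, data = _read_table(path)
    macro = data[:, 0]
    micro = data[:, 1] if data.shape[1] > 1 else None
    if micro is not None and np.all(micro < 0):
        micro = None
    if duration is None:
        duration = float(macro[-1]) if macro.size else 0.0
    return PhotonStream(macro, duration, micro, excitation_period_ns=period)


# -- reports and configuration --------------------------------------------

def report_to_json(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


CONFIG_SCHEMA_VERSION = 1

_CONFIG_KEYS = {
    "schema_version",
    "scene",  # preset name or explicit stack description
    "stack",  # list of {material|index, thickness_nm, label}
    "emitter",  # wavelength_nm, quantum_yield, free_lifetime_ns, orientation
    "objective",  # numerical_aperture, immersion_index
    "acquisition",  # bin_width_s, max_lag_s, m
    "model",  # kappa_J, sigma_J_m2, gamma_pot_J_m4, eta_Pa_s, h0_m, w_m, temperature_K
    "simulation",  # dt_s, n_steps, detection_rate0_cps, background_rate_cps
    "seed",
    "output_dir",
}


def load_config(path) -> dict:
    """Load and validate a YAML run configuration; unknown top-level keys
    fail fast with the list of valid keys."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(_CONFIG_KEYS)}"
        )
    version = cfg.get("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported schema_version {version} (supported: {CONFIG_SCHEMA_VERSION})"
        )
    return cfg
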