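"""Refractometric sensing readout: band-integrated differential signal,
peak fold-change, dose-response handling and the 3x-noise limit of
detection.

The sensor output metric is the emitted intensity integrated over a fixed
spectral band (default 620-700 nm), normalized to the bare-chip reference;
an analyte layer redshifts the dispersive antenna resonance into the
collection cone and raises this band signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .emission_combine import EmissionSpectrum, find_peak

__all__ = [
    "SensorResponse",
    "MonotonicityWarning",
    "differential_band_signal",
    "peak_fold_change",
    "limit_of_detection",
    "write_dose_response_csv",
]

DEFAULT_BAND_NM = (620.0, 700.0)


class MonotonicityWarning(UserWarning):
    pass


class DegenerateReferenceError(ZeroDivisionError):
    pass


@dataclass
class SensorResponse:
    """One dose point of a dose-response series."""

    mass_pg: float
    response_mean: float  # dimensionless, relative to bare reference
    response_sd: float
    n_replicates: int
    band_nm: tuple[float, float] = DEFAULT_BAND_NM
    thickness_nm: float | None = None


def _common_grid(a: EmissionSpectrum, b: EmissionSpectrum) -> None:
    if a.wavelength_nm.shape != b.wavelength_nm.shape or not np.allclose(
        a.wavelength_nm, b.wavelength_nm, rtol=0, atol=1e-9
    ):
        raise ValueError("spectra must share one wavelength grid")


def differential_band_signal(
    analyte: EmissionSpectrum,
    bare: EmissionSpectrum,
    band_nm: tuple[float, float] = DEFAULT_BAND_NM,
) -> float:
    """(integral_band(analyte) - integral_band(bare)) / integral_band(bare),
    trapezoid rule on the common grid."""
    _common_grid(analyte, bare)
    ref = bare.integrated(band_nm)
    if ref == 0:
        raise DegenerateReferenceError("bare-reference band integral is zero")
    return (analyte.integrated(band_nm) - ref) / ref


def peak_fold_change(
    analyte: EmissionSpectrum,
    bare: EmissionSpectrum,
    window_nm: tuple[float, float] = (550.0, 750.0),
) -> float:
    """Ratio of interpolated peak heights (analyte / bare) inside the search
    window; a peak on the window edge raises a PeakWindowWarning upstream."""
    _common_grid(analyte, bare)
    _, h_a = find_peak(analyte.wavelength_nm, analyte.intensity, window_nm)
    _, h_b = find_peak(bare.wavelength_nm, bare.intensity, window_nm)
    if h_b == 0:
        raise DegenerateReferenceError("bare peak height is zero")
    return h_a / h_b


def limit_of_detection(
    responses: Sequence[SensorResponse],
    noise_level: float,
    threshold_factor: float = 3.0,
) -> dict:
    """Smallest mass at which the interpolated mean response crosses
    ``threshold_factor * noise_level``.

    Mean responses must be (weakly) monotone in mass; otherwise a
    MonotonicityWarning is emitted and an isotonic (pool-adjacent-violators)
    regression of the means is used instead.  Returns a dict with the LOD
    mass, the threshold, the bracketing dose points, and flags for
    extrapolation below the lowest dose / saturation above the highest.
    """
    if noise_level <= 0:
        raise ValueError("noise level must be positive")
    pts = sorted(responses, key=lambda r: r.mass_pg)
    if len(pts) < 3:
        raise ValueError("need at least three dose points")
    mass = np.array([p.mass_pg for p in pts], dtype=float)
    mean = np.array([p.response_mean for p in pts], dtype=float)
    if np.any(np.diff(mean) < 0):
        warnings.warn(
            "mean responses are not monotone in mass; applying isotonic regression",
            MonotonicityWarning,
        )
        mean = _pava(mean)
    threshold = threshold_factor * noise_level
    out = {
        "threshold": threshold,
        "band_nm": pts[0].band_nm,
        "extrapolated_below": False,
        "saturated_above": False,
        "lod_mass_pg": None,
        "bracket_pg": None,
    }
    if mean[0] >= threshold:
        # already above threshold at the lowest dose: extrapolate through 0
        out["extrapolated_below"] = True
        out["lod_mass_pg"] = float(mass[0] * threshold / mean[0]) if mean[0] > 0 else 0.0
        out["bracket_pg"] = (0.0, float(mass[0]))
        return out
    above = np.flatnonzero(mean >= threshold)
    if above.size == 0:
        out["saturated_above"] = True  # never crosses inside the dose range
        return out
    i = int(above[0])
    m_lo, m_hi = mass[i - 1], mass[i]
    r_lo, r_hi = mean[i - 1], mean[i]
    lod = m_lo + (threshold - r_lo) / (r_hi - r_lo) * (m_hi - m_lo)
    out["lod_mass_pg"] = float(lod)
    out["bracket_pg"] = (float(m_lo), float(m_hi))
    return out


def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators for a non-decreasing fit (unit weights)."""
    y = y.astype(float).copy()
    n = len(y)
    vals = list(y)
    counts = [1] * n
    i = 0
    while i < len(vals) - 1:
        if vals[i] > vals[i + 1]:
            merged = (vals[i] * counts[i] + vals[i + 1] * counts[i + 1]) / (
                counts[i] + counts[i + 1]
            )
            vals[i : i + 2] = [merged]
            counts[i : i + 2] = [counts[i] + counts[i + 1]]
            i = max(i - 1, 0)
        else:
            i += 1
    return np.repeat(vals, counts)


def write_dose_response_csv(
    responses: Sequence[SensorResponse],
    path,
    noise_level: float | None = None,
    threshold_factor: float = 3.0,
) -> None:
    band = responses[0].band_nm if responses else DEFAULT_BAND_NM
    lines = [
        f"# band_nm: {band[0]},{band[1]}",
        f"# threshold_rule: {threshold_factor} x noise level",
    ]
    if noise_level is not None:
        lines.append(f"# noise_level: {noise_level}")
    lines.append("mass_pg,response_mean,response_sd,n_replicates")
    rows = np.array(
        [[r.mass_pg, r.response_mean, r.response_sd, r.n_replicates] for r in responses]
    )
    np.savetxt(path, rows, delimiter=",", header="\n".join(lines), comments="")
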