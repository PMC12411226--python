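"""Combine electronic and photonic factors into emission spectra and maps.

The emitted intensity is the pointwise product of the electronic factor H
(bias-dependent, featureless) and the photonic factor G (bias-independent,
carries the antenna resonances).  Because of this separability, intensity
ratios between biases at fixed wavelength equal the corresponding H ratios
regardless of the photonic model — used as a regression property.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .constants import HC_EV_NM
from .device_config import DeviceSpec, MaterialModel
from .electronic_h import ElectronicBands, HSpectrum, h_vs_bias, spectral_electronic_contribution
from .photonic_g import AngularEmissionMap, GSpectrum, photonic_contribution, photonic_map

__all__ = [
    "EmissionSpectrum",
    "GridAlignmentError",
    "PeakWindowWarning",
    "liet_spectrum",
    "find_peak",
    "spectra_vs_bias",
    "angle_resolved_emission",
    "write_spectrum_csv",
    "read_spectrum_csv",
]


class GridAlignmentError(ValueError):
    """Raised when spectra on different wavelength grids are combined (no
    silent interpolation)."""


class PeakWindowWarning(UserWarning):
    pass


@dataclass
class EmissionSpectrum:
    """Emitted intensity vs wavelength at one bias (arbitrary units)."""

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    bias_v: float
    na: float
    variant: str = ""
    scale: float = 1.0

    def cutoff_nm(self) -> float:
        """Quantum cut-off wavelength hc/(e*V_b)."""
        return HC_EV_NM / self.bias_v

    def integrated(self, band: tuple[float, float] | None = None) -> float:
        """Trapezoid integral of the intensity, optionally over a band."""
        lam, y = self.wavelength_nm, self.intensity
        if band is not None:
            lo, hi = band
            sel = (lam >= lo) & (lam <= hi)
            if sel.sum() < 2:
                raise ValueError("band contains fewer than two grid points")
            lam, y = lam[sel], y[sel]
        return float(np.trapezoid(y, lam))


def liet_spectrum(h: HSpectrum, g: GSpectrum) -> EmissionSpectrum:
    """Pointwise product of the two factors; grids must match exactly."""
    if h.wavelength_nm.shape != g.wavelength_nm.shape or not np.allclose(
        h.wavelength_nm, g.wavelength_nm, rtol=0, atol=1e-9
    ):
        raise GridAlignmentError(
            "H and G are sampled on different wavelength grids; resample "
            "explicitly before combining"
        )
    return EmissionSpectrum(
        wavelength_nm=h.wavelength_nm.copy(),
        intensity=h.values * g.values,
        bias_v=h.bias_v,
        na=g.na,
        scale=h.scale * g.scale,
    )


def find_peak(
    wavelength_nm: np.ndarray,
    values: np.ndarray,
    window: tuple[float, float] = (550.0, 750.0),
) -> tuple[float, float]:
    """(peak wavelength, peak height) of the maximum inside ``window``,
    refined by parabolic interpolation through the three samples around the
    grid maximum.  A maximum sitting on the window edge is returned as-is
    with a :class:`PeakWindowWarning`."""
    import warnings

    lam = np.asarray(wavelength_nm, dtype=float)
    y = np.asarray(values, dtype=float)
    sel = (lam >= window[0]) & (lam <= window[1])
    if sel.sum() < 3:
        raise ValueError("window contains fewer than three grid points")
    lam_w, y_w = lam[sel], y[sel]
    i = int(np.argmax(y_w))
    if i == 0 or i == len(y_w) - 1:
        warnings.warn(
            f"peak at search-window edge ({lam_w[i]:.1f} nm); no interior "
            "maximum inside the window",
            PeakWindowWarning,
        )
        return float(lam_w[i]), float(y_w[i])
    x0, x1, x2 = lam_w[i - 1 : i + 2]
    y0, y1, y2 = y_w[i - 1 : i + 2]
    # parabola y1 + b*t + a*t^2 (t = lambda - x1) through the three samples
    d0, d2 = x1 - x0, x2 - x1
    a = (d2 * (y0 - y1) + d0 * (y2 - y1)) / (d0 * d2 * (d0 + d2))
    b = (d0**2 * (y2 - y1) + d2**2 * (y1 - y0)) / (d0 * d2 * (d0 + d2))
    if a >= 0 or abs(a) < 1e-300:
        return float(x1), float(y1)
    t = -b / (2 * a)
    return float(x1 + t), float(y1 + b * t + a * t**2)


def spectra_vs_bias(
    device: DeviceSpec,
    bands: ElectronicBands,
    biases_v: Sequence[float],
    na: float | None = None,
    wavelength_nm: Sequence[float] | None = None,
    g: GSpectrum | None = None,
    n_theta: int | None = None,
    n_phi: int = 1,
    n_harmonics: int = 41,
    materials: Mapping[str, MaterialModel] | None = None,
    peak_window: tuple[float, float] = (550.0, 750.0),
) -> tuple[list[EmissionSpectrum], list[dict]]:
    """Family of emission spectra over a sorted bias list.

    The photonic factor is computed once (or supplied precomputed via
    ``g``); the electronic family shares one normalization so intensities
    are comparable across biases.  Returns (spectra, peak reports); each
    report carries the interpolated peak wavelength within ``peak_window``
    and the integrated intensity.
    """
    biases = list(biases_v)
    if sorted(biases) != biases:
        raise ValueError("biases must be sorted ascending")
    if g is None:
        g = photonic_contribution(
            device,
            wavelength_nm,
            na=na,
            n_theta=n_theta,
            n_phi=n_phi,
            n_harmonics=n_harmonics,
            materials=materials,
        )
    lam = g.wavelength_nm
    hs = h_vs_bias(bands, biases, lam)
    spectra = []
    reports = []
    import warnings

    for h in hs:
        sp = liet_spectrum(h, g)
        sp.variant = device.variant
        spectra.append(sp)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PeakWindowWarning)
            peak_lam, peak_val = find_peak(lam, sp.intensity, peak_window)
        reports.append(
            {
                "bias_V": h.bias_v,
                "peak_wavelength_nm": peak_lam,
                "peak_intensity_arb": peak_val,
                "integrated_intensity_arb": sp.integrated(),
                "cutoff_nm": sp.cutoff_nm(),
            }
        )
    return spectra, reports


def angle_resolved_emission(
    device: DeviceSpec,
    bands: ElectronicBands,
    bias_v: float,
    wavelength_nm: Sequence[float],
    theta_rad: Sequence[float],
    n_harmonics: int = 41,
    materials: Mapping[str, MaterialModel] | None = None,
    allow_coarse: bool = False,
) -> AngularEmissionMap:
    """H(omega,V_b) * photonic map on a (wavelength, theta) grid in the
    dispersion plane; access k_par through the returned map.

    The default contract requires >= 100 wavelength and >= 30 angle samples
    (``allow_coarse`` relaxes this for quick looks).
    """
    lam = np.asarray(wavelength_nm, dtype=float)
    th = np.asarray(theta_rad, dtype=float)
    if not allow_coarse and (lam.size < 100 or th.size < 30):
        raise ValueError(
            f"map grid too coarse ({lam.size} wavelengths x {th.size} angles); "
            "need >= 100 x >= 30, or pass allow_coarse=True"
        )
    amap = photonic_map(device, lam, th, 0.0, None, n_harmonics, materials)
    h = spectral_electronic_contribution(bands, bias_v, lam)
    return AngularEmissionMap(
        wavelength_nm=lam,
        theta_rad=th,
        values=amap.values * h.values[:, None],
    )


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------


def write_spectrum_csv(spectrum: EmissionSpectrum, path) -> None:
    header = (
        f"# bias_V: {spectrum.bias_v}\n"
        f"# NA: {spectrum.na}\n"
        f"# variant: {spectrum.variant}\n"
        f"# normalization_scale: {spectrum.scale}\n"
        "wavelength_nm,intensity_arb"
    )
    np.savetxt(
        path,
        np.column_stack([spectrum.wavelength_nm, spectrum.intensity]),
        delimiter=",",
        header=header,
        comments="",
    )


def read_spectrum_csv(path) -> EmissionSpectrum:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    data = np.loadtxt(path, delimiter=",", skiprows=len(meta) + 1)
    return EmissionSpectrum(
        wavelength_nm=data[:, 0],
        intensity=data[:, 1],
        bias_v=float(meta.get("bias_V", "nan")),
        na=float(meta.get("NA", "nan")),
        variant=meta.get("variant", ""),
        scale=float(meta.get("normalization_scale", "1.0")),
    )
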