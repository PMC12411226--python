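"""Spectral electronic contribution H of the tunnelling emission model.

H(omega, V_b) measures how many (initial, final) electron-state pairs can
emit a photon of energy hbar*omega while tunnelling under bias V_b:

    H ∝ ∫ dE  rho_em(E) f_em(E) rho_rc(E + eV_b - hbar*omega)
               * [1 - f_rc(E + eV_b - hbar*omega)]

i.e. the energy-conservation delta-function of the two-dimensional
state-pair integral has been carried out analytically.  Each metal's own
chemical potential is the zero of its energy axis; the bias enters only
through the eV_b offset.  Tunnelling is modelled emitter (Al) -> receptor
(Cr); the Au electrode is neglected in this factor.

The photon-energy cut-off hbar*omega_max = e*V_b emerges from the product
of occupation factors: at T -> 0, H vanishes identically for photon
energies above the bias energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import K_B_EV, nm_to_ev

__all__ = [
    "DosModel",
    "ElectronicBands",
    "HSpectrum",
    "fermi_occupation",
    "spectral_electronic_contribution",
    "h_vs_bias",
    "write_h_csv",
]


class ResolutionWarning(UserWarning):
    pass


@dataclass(frozen=True)
class DosModel:
    """Density of states of one electrode, energies relative to its own
    chemical potential (eV).

    Free-electron form: rho(E) = sqrt(E + band_bottom_ev) for
    E > -band_bottom_ev, else 0.  A tabulated (energy, rho) curve may be
    supplied instead; it is linearly interpolated and clamped to zero
    outside its range.
    """

    band_bottom_ev: float | None = None
    table_energy_ev: np.ndarray | None = None
    table_rho: np.ndarray | None = None

    def __post_init__(self):
        if (self.band_bottom_ev is None) == (self.table_energy_ev is None):
            raise ValueError("specify exactly one of band_bottom_ev / table")
        if self.band_bottom_ev is not None and self.band_bottom_ev <= 0:
            raise ValueError("band bottom depth must be positive")
        if self.table_energy_ev is not None:
            e = np.asarray(self.table_energy_ev, dtype=float)
            r = np.asarray(self.table_rho, dtype=float)
            if e.ndim != 1 or np.any(np.diff(e) <= 0):
                raise ValueError("DOS table energies must be strictly increasing")
            if np.any(r < 0):
                raise ValueError("DOS must be non-negative")
            object.__setattr__(self, "table_energy_ev", e)
            object.__setattr__(self, "table_rho", r)

    def rho(self, energy_ev) -> np.ndarray:
        e = np.asarray(energy_ev, dtype=float)
        if self.band_bottom_ev is not None:
            return np.sqrt(np.maximum(e + self.band_bottom_ev, 0.0))
        return np.interp(e, self.table_energy_ev, self.table_rho, left=0.0, right=0.0)


@dataclass(frozen=True)
class ElectronicBands:
    """Electrode pair for the tunnelling factor.

    Default band-bottom depths (emitter Al 11.7 eV, receptor Cr 7.0 eV below
    the respective chemical potentials) are free-electron stand-ins; actual
    band structures can be supplied as tabulated DOS curves.
    """

    emitter: DosModel = field(default_factory=lambda: DosModel(band_bottom_ev=11.7))
    receptor: DosModel = field(default_factory=lambda: DosModel(band_bottom_ev=7.0))
    temperature_k: float = 300.0

    def __post_init__(self):
        if self.temperature_k <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class HSpectrum:
    """Electronic contribution vs wavelength at one bias.

    ``values`` are normalized (see ``scale``): the raw integral is
    ``values * scale``, so spectra sharing one ``scale`` are mutually
    comparable.
    """

    wavelength_nm: np.ndarray
    values: np.ndarray
    bias_v: float
    scale: float = 1.0
    temperature_k: float = 300.0


def fermi_occupation(energy_ev, mu_ev: float, temperature_k: float):
    """Fermi-Dirac occupation 1/(exp((E-mu)/kT)+1), overflow-safe for
    |E-mu|/kT up to several hundred."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    x = (np.asarray(energy_ev, dtype=float) - mu_ev) / (K_B_EV * temperature_k)
    out = np.empty_like(x)
    pos = x > 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    if out.ndim == 0:
        return float(out)
    return out


def _h_raw(
    bands: ElectronicBands,
    bias_v: float,
    wavelength_nm: np.ndarray,
    energy_step_ev: float | None,
) -> np.ndarray:
    """Un-normalized H on the wavelength grid (trapezoid over the initial
    electron energy, the delta-function integrated out analytically)."""
    import warnings

    kt = K_B_EV * bands.temperature_k
    if energy_step_ev is None:
        energy_step_ev = kt / 4.0
    elif energy_step_ev > kt / 2.0:
        warnings.warn(
            f"energy step {energy_step_ev:.3g} eV coarser than kT/2 = {kt / 2:.3g} eV",
            ResolutionWarning,
        )
    # occupied-emitter window plus thermal tails
    e_lo = -(bias_v + 30.0 * kt)
    e_hi = 30.0 * kt
    n_e = max(int(np.ceil((e_hi - e_lo) / energy_step_ev)) + 1, 16)
    ei = np.linspace(e_lo, e_hi, n_e)

    hw = nm_to_ev(np.asarray(wavelength_nm, dtype=float))
    ef = ei[:, None] + (bias_v - hw)[None, :]  # final energies, receptor reference
    emit = bands.emitter.rho(ei) * fermi_occupation(ei, 0.0, bands.temperature_k)
    recv = bands.receptor.rho(ef) * (1.0 - fermi_occupation(ef, 0.0, bands.temperature_k))
    return np.trapezoid(emit[:, None] * recv, ei, axis=0)


def spectral_electronic_contribution(
    bands: ElectronicBands,
    bias_v: float,
    wavelength_nm: Sequence[float],
    energy_step_ev: float | None = None,
    normalize: bool = True,
) -> HSpectrum:
    """H(omega, V_b) on a wavelength grid, normalized to unit maximum with
    the divisor stored in ``scale``."""
    if bias_v <= 0:
        raise ValueError("bias must be positive")
    lam = np.asarray(wavelength_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelengths must be positive")
    raw = _h_raw(bands, bias_v, lam, energy_step_ev)
    scale = float(raw.max()) if normalize and raw.max() > 0 else 1.0
    return HSpectrum(
        wavelength_nm=lam,
        values=raw / scale,
        bias_v=float(bias_v),
        scale=scale,
        temperature_k=bands.temperature_k,
    )


def h_vs_bias(
    bands: ElectronicBands,
    biases_v: Sequence[float],
    wavelength_nm: Sequence[float],
    energy_step_ev: float | None = None,
) -> list[HSpectrum]:
    """Family of H spectra sharing one normalization scalar (the maximum of
    the raw integrals over the whole family)."""
    biases = list(biases_v)
    if not biases:
        raise ValueError("bias list must be non-empty")
    if any(b <= 0 for b in biases):
        raise ValueError("biases must be positive")
    if sorted(biases) != biases:
        raise ValueError("biases must be sorted ascending")
    lam = np.asarray(wavelength_nm, dtype=float)
    raws = [_h_raw(bands, b, lam, energy_step_ev) for b in biases]
    scale = max(float(r.max()) for r in raws)
    if scale <= 0:
        scale = 1.0
    return [
        HSpectrum(
            wavelength_nm=lam,
            values=r / scale,
            bias_v=float(b),
            scale=scale,
            temperature_k=bands.temperature_k,
        )
        for b, r in zip(biases, raws)
    ]


def write_h_csv(spectrum: HSpectrum, path) -> None:
    """Two-column CSV (wavelength_nm, H_arb) with metadata header lines."""
    header = (
        f"# bias_V: {spectrum.bias_v}\n"
        f"# temperature_K: {spectrum.temperature_k}\n"
        f"# normalization_scale: {spectrum.scale}\n"
        "wavelength_nm,H_arb"
    )
    np.savetxt(
        path,
        np.column_stack([spectrum.wavelength_nm, spectrum.values]),
        delimiter=",",
        header=header,
        comments="",
    )
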