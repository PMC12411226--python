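"""Physical constants and unit conversions used throughout the package.

Conventions: lengths in nm, photon/electron energies in eV, bias in volts,
temperatures in kelvin.  Time dependence of fields is exp(-i*omega*t), so
passive media have Im(eps) >= 0.
"""

# hc in eV*nm: E[eV] = HC_EV_NM / lambda[nm]
HC_EV_NM = 1239.841984

# Boltzmann constant in eV/K
K_B_EV = 8.617333262e-5

# SI constants (used only by the tunnelling current model)
E_CHARGE = 1.602176634e-19  # C
H_PLANCK = 6.62607015e-34  # J*s
M_ELECTRON = 9.1093837015e-31  # kg
EPS0 = 8.8541878128e-12  # F/m
C_LIGHT = 2.99792458e8  # m/s


def ev_to_nm(energy_ev: float) -> float:
    """Photon energy (eV) -> vacuum wavelength (nm)."""
    return HC_EV_NM / energy_ev


def nm_to_ev(wavelength_nm: float) -> float:
    """Vacuum wavelength (nm) -> photon energy (eV)."""
    return HC_EV_NM / wavelength_nm
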