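"""Planar multilayer transfer-matrix solver (p and s polarization).

Purely numerical: inputs are complex permittivities at a single wavelength.
Conventions:

* time dependence exp(-i*omega*t), passive media Im(eps) >= 0;
* incidence from the semi-infinite medium ``eps_in`` travelling towards
  +z; interior layers stacked along +z; z = 0 at the first interface;
* in-plane wavevector ``kx`` conserved; kz = sqrt(eps*k0^2 - kx^2) with the
  branch Im(kz) >= 0 (Re(kz) > 0 when lossless);
* p-polarization is formulated on Hy.  Electric fields are reported in
  normalized units Etilde = E/eta0 so plane-wave fluxes read
  0.5*Re(kz/(k0*eps))*|Hy|^2 without vacuum-impedance factors.

Lengths in nm, k0 = 2*pi/lambda_nm.

Besides the driven (plane-wave) solve, the module provides a source-driven
solve for a buried sheet of z-oriented dipoles; that is the independent
radiation oracle against which the reciprocity route of the photonic model
is validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TmmResult", "solve", "fields_at", "dipole_sheet_emission"]


def _kz(eps: complex, k0: float, kx: float) -> complex:
    kz = complex(np.sqrt(eps * k0**2 - kx**2 + 0j))
    if kz.imag < 0 or (kz.imag == 0 and kz.real < 0):
        kz = -kz
    return kz


@dataclass
class TmmResult:
    """Solution of a driven planar-stack problem at one (k0, kx).

    Amplitudes ``a`` (towards +z) and ``b`` (towards -z) hold the principal
    field (Hy for p, Ey for s) and are referenced at the top of each slab
    (at z=0 for the incident medium).
    """

    k0: float
    kx: float
    pol: str
    eps: np.ndarray  # len N+2, incident medium first
    d: np.ndarray  # len N+2, 0 for the semi-infinite media
    kz: np.ndarray
    a: np.ndarray
    b: np.ndarray
    r: complex  # reflection, E-field convention (Fresnel (n1-n2)/(n1+n2) at normal)
    t: complex  # transmission, full-E-field amplitude convention
    R: float
    T: float

    @property
    def A(self) -> float:
        return 1.0 - self.R - self.T

    def _gamma(self) -> np.ndarray:
        if self.pol == "p":
            return self.kz / (self.k0 * self.eps)
        return self.kz / self.k0

    def flux_at_slab_tops(self) -> np.ndarray:
        """Normal energy flux at the reference plane of each slab (normalized
        units, positive towards +z); entry 0 is at z=0 in the incident medium."""
        g = self._gamma()
        flux = np.empty(len(self.eps))
        for j in range(len(self.eps)):
            u = self.a[j] + self.b[j]
            v = g[j] * (self.a[j] - self.b[j])
            flux[j] = 0.5 * np.real(v * np.conj(u))
        return flux

    def absorption_per_layer(self) -> np.ndarray:
        """Dissipation per interior layer from the closed-form volume integral
        of k0*Im(eps)*|E|^2/2, normalized to unit incident flux."""
        inc_flux = 0.5 * np.real(self._gamma()[0]) * abs(self.a[0]) ** 2
        return np.array(
            [self._layer_dissipation(j) / inc_flux for j in range(1, len(self.eps) - 1)]
        )

    def _layer_dissipation(self, j: int) -> float:
        eps, kz, d = self.eps[j], self.kz[j], self.d[j]
        a, b = self.a[j], self.b[j]
        kp, kappa = kz.real, kz.imag
        if kappa > 1e-14:
            i_aa = (1.0 - np.exp(-2 * kappa * d)) / (2 * kappa)
            i_bb = (np.exp(2 * kappa * d) - 1.0) / (2 * kappa)
        else:
            i_aa = i_bb = d
        if abs(kp) > 1e-14:
            i_ab = (np.exp(2j * kp * d) - 1.0) / (2j * kp)
        else:
            i_ab = complex(d)
        quad_minus = (
            abs(a) ** 2 * i_aa + abs(b) ** 2 * i_bb - 2 * np.real(a * np.conj(b) * i_ab)
        )
        quad_plus = (
            abs(a) ** 2 * i_aa + abs(b) ** 2 * i_bb + 2 * np.real(a * np.conj(b) * i_ab)
        )
        if self.pol == "p":
            g_x = abs(kz / (self.k0 * eps)) ** 2
            g_z = abs(self.kx / (self.k0 * eps)) ** 2
            e2 = g_x * quad_minus + g_z * quad_plus
        else:
            e2 = quad_plus
        return 0.5 * self.k0 * eps.imag * e2


def solve(
    k0: float,
    kx: float,
    eps_in: complex,
    layers,
    eps_out: complex,
    pol: str = "p",
    a_inc: complex = 1.0,
) -> TmmResult:
    """Drive the stack with a plane wave of principal-field amplitude
    ``a_inc`` from the ``eps_in`` side.  ``layers``: sequence of
    (eps, thickness_nm)."""
    if pol not in ("p", "s"):
        raise ValueError("pol must be 'p' or 's'")
    eps = np.array([eps_in] + [e for e, _ in layers] + [eps_out], dtype=complex)
    d = np.array([0.0] + [t for _, t in layers] + [0.0], dtype=float)
    if np.any(d[1:-1] <= 0):
        raise ValueError("layer thicknesses must be positive")
    n = len(eps)
    kz = np.array([_kz(e, k0, kx) for e in eps])
    gamma = kz / (k0 * eps) if pol == "p" else kz / k0

    # Parratt recursion: r_from[j] = b/a for a wave inside medium j hitting
    # the interface below it (referenced at that interface), outgoing BC at
    # the bottom.
    r_from = np.zeros(n - 1, dtype=complex)
    for j in range(n - 2, -1, -1):
        r_ij = (gamma[j] - gamma[j + 1]) / (gamma[j] + gamma[j + 1])
        if j == n - 2:
            inner = 0.0 + 0j
        else:
            inner = r_from[j + 1] * np.exp(2j * kz[j + 1] * d[j + 1])
        r_from[j] = (r_ij + inner) / (1.0 + r_ij * inner)

    a = np.zeros(n, dtype=complex)
    b = np.zeros(n, dtype=complex)
    a[0] = a_inc
    b[0] = r_from[0] * a_inc
    for j in range(n - 1):
        pf = np.exp(1j * kz[j] * d[j])
        u = a[j] * pf + b[j] / pf
        v = gamma[j] * (a[j] * pf - b[j] / pf)
        a[j + 1] = 0.5 * (u + v / gamma[j + 1])
        b[j + 1] = 0.5 * (u - v / gamma[j + 1])
    b[-1] = 0.0  # outgoing BC; forward pass leaves roundoff here

    r_pf = b[0] / a[0]
    t_pf = a[-1] / a[0]
    R = abs(r_pf) ** 2
    T = float(np.real(gamma[-1]) / np.real(gamma[0]) * abs(t_pf) ** 2)
    if pol == "p":
        r_e = -r_pf
        t_e = t_pf * np.sqrt(eps[0]) / np.sqrt(eps[-1])
    else:
        r_e, t_e = r_pf, t_pf
    return TmmResult(
        k0=k0, kx=kx, pol=pol, eps=eps, d=d, kz=kz, a=a, b=b,
        r=complex(r_e), t=complex(t_e), R=float(R), T=T,
    )


def fields_at(res: TmmResult, z: float):
    """Fields at height z: (Hy, Ex, Ez) for p, (Ey, Hx, Hz) for s.

    E in normalized units (E/eta0); z measured from the first interface,
    increasing into the stack.
    """
    bounds = np.concatenate(([0.0], np.cumsum(res.d[1:-1])))
    if z < 0:
        j, zloc = 0, z
    elif z >= bounds[-1]:
        j, zloc = len(res.eps) - 1, z - bounds[-1]
    else:
        j = int(np.searchsorted(bounds, z, side="right"))
        zloc = z - bounds[j - 1]
    ph = np.exp(1j * res.kz[j] * zloc)
    u = res.a[j] * ph + res.b[j] / ph
    dv = res.a[j] * ph - res.b[j] / ph
    if res.pol == "p":
        ex = res.kz[j] / (res.k0 * res.eps[j]) * dv
        ez = -res.kx / (res.k0 * res.eps[j]) * u
        return u, ex, ez
    hx = res.kz[j] / res.k0 * dv
    hz = res.kx / res.k0 * u
    return u, hx, hz


def _halfstack_rt(k0, kx, eps_src, half_layers, eps_exit):
    """(r, t) principal-field coefficients for a p wave launched inside
    semi-infinite ``eps_src`` towards ``half_layers`` -> ``eps_exit``,
    referenced at the launch plane."""
    res = solve(k0, kx, eps_src, half_layers, eps_exit, pol="p")
    return res.b[0] / res.a[0], res.a[-1] / res.a[0]


def dipole_sheet_emission(
    k0: float,
    kx: float,
    eps_in: complex,
    layers,
    eps_out: complex,
    layer_index: int,
    z_offset: float,
):
    """Radiation of a buried sheet of z-oriented dipoles (phase exp(i*kx*x)).

    The sheet sits ``z_offset`` below the top of interior layer
    ``layer_index`` (0-based into ``layers``) and imposes a jump in Ex with
    Hy continuous.  Returns the outgoing Hy amplitudes
    ``(b_into_eps_in, a_into_eps_out)`` for unit source strength; the
    absolute scale is arbitrary but angle-independent, so angular patterns
    are meaningful.
    """
    eps_m, d_m = layers[layer_index]
    if not 0 < z_offset < d_m:
        raise ValueError("source plane must lie strictly inside its layer")
    gamma_m = _kz(eps_m, k0, kx) / (k0 * eps_m)

    # looking up (towards eps_in): residual slab above the sheet, then the
    # upper layers in reverse order
    up = [(eps_m, z_offset)] + [layers[j] for j in range(layer_index - 1, -1, -1)]
    r_up, t_up = _halfstack_rt(k0, kx, eps_m, up, eps_in)
    # looking down (towards eps_out)
    dn = [(eps_m, d_m - z_offset)] + list(layers[layer_index + 1 :])
    r_dn, t_dn = _halfstack_rt(k0, kx, eps_m, dn, eps_out)

    denom = 2.0 * gamma_m * (1.0 - r_up * r_dn)
    a_down = (1.0 + r_up) / denom  # down-going wave just below the sheet
    b_up = (1.0 + r_dn) / denom  # up-going wave just above the sheet
    return t_up * b_up, t_dn * a_down
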