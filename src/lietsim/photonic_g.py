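"""Antenna-mediated photonic contribution G of the emission model.

The far-field amplitude ``g`` of a surface-normal unit dipole buried in the
tunnelling gap is obtained by reciprocity: it is proportional to the
vertical near-field component induced at the dipole position by a
p-polarized plane wave sent from the observation direction.  The
angle-resolved photonic contribution sums ``|g|^2`` incoherently over
dipole positions across the wire (coherently along the wire, which
collapses to a single term for the y-invariant reduced geometry), and the
scalar spectrum ``G`` integrates it over the collection cone of the
objective.

Geometry and conventions
------------------------
Emission is collected through the glass substrate (inverted microscope).
The polar angle ``theta`` is parameterized by its in-air equivalent:
``k_par = k0*sin(theta)``, so the numerical aperture directly bounds
``sin(theta) <= NA``.  Plane waves therefore impinge from the glass side
with in-plane wavevector ``k0*sin(theta)``.  Azimuth is fixed to the plane
of the grating vector (the 1D-periodic model is invariant along y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import _rcwa, _tmm
from .device_config import (
    DeviceSpec,
    MaterialModel,
    default_materials,
    permittivity,
)

__all__ = [
    "PlaneWaveExcitation",
    "DipoleGrid",
    "AngularEmissionMap",
    "GSpectrum",
    "build_stack",
    "tmm_solve",
    "rcwa_solve",
    "farfield_amplitude",
    "angle_resolved_photonic",
    "photonic_map",
    "photonic_contribution",
]


class PolarizationError(ValueError):
    """Raised for s-polarized requests in the emission path (the tunnelling
    dipoles are surface-normal, so their far field is p-polarized)."""


class ConvergenceWarning(UserWarning):
    pass


class QuadratureWarning(UserWarning):
    pass


@dataclass(frozen=True)
class PlaneWaveExcitation:
    """Incident plane wave.

    ``theta_rad`` is the in-air polar angle (k_par = k0 sin theta);
    ``side`` selects the semi-infinite medium the wave comes from.
    """

    wavelength_nm: float
    theta_rad: float = 0.0
    azimuth_rad: float = 0.0
    polarization: str = "p"
    side: str = "substrate"

    def __post_init__(self):
        # in-air parameterization: |sin(theta)| <= 1 means theta in [-pi/2, pi/2]
        if abs(self.theta_rad) > np.pi / 2.0:
            raise ValueError("polar angle must lie in [-pi/2, pi/2]")
        if self.polarization not in ("p", "s"):
            raise ValueError("polarization must be 'p' or 's'")
        if self.side not in ("substrate", "superstrate"):
            raise ValueError("side must be 'substrate' or 'superstrate'")


@dataclass(frozen=True)
class DipoleGrid:
    """Surface-normal dipole positions inside the tunnelling layer.

    ``x_nm``: positions across the wire (index l, incoherent).  The along-
    wire index j collapses to one effective term in the y-invariant model.
    ``z_frac``: fractional height of the dipole plane inside the gap layer
    (0 = side facing the substrate, 1 = side facing the wire); defaults to
    the mid-plane.
    """

    x_nm: np.ndarray
    z_frac: float = 0.5
    n_j: int = 1

    def __post_init__(self):
        x = np.atleast_1d(np.asarray(self.x_nm, dtype=float))
        if x.size == 0:
            raise ValueError("dipole grid must be non-empty")
        object.__setattr__(self, "x_nm", x)
        if not 0.0 < self.z_frac < 1.0:
            raise ValueError("z_frac must lie strictly inside (0, 1)")

    @classmethod
    def under_wire(cls, device: DeviceSpec, n_x: int = 15, z_frac: float = 0.5):
        """Evenly spaced positions spanning the wire footprint."""
        w = device.grating.wire_width
        x = (np.arange(n_x) + 0.5) / n_x * w
        return cls(x_nm=x, z_frac=z_frac)


@dataclass
class GSpectrum:
    """NA-integrated photonic contribution, normalized to unit maximum.

    ``scale`` stores the normalization divisor so absolute (solver-unit)
    values are recoverable as ``values * scale``.
    """

    wavelength_nm: np.ndarray
    values: np.ndarray
    na: float
    scale: float


@dataclass
class AngularEmissionMap:
    """Angle-resolved photonic contribution on a (wavelength, theta) grid."""

    wavelength_nm: np.ndarray
    theta_rad: np.ndarray  # in-air polar angles
    values: np.ndarray  # shape (n_wavelength, n_theta), >= 0

    def k_parallel_per_um(self) -> np.ndarray:
        """In-air k_par = (2*pi/lambda)*sin(theta), in 1/um."""
        return (
            2.0
            * np.pi
            / self.wavelength_nm[:, None]
            * np.sin(self.theta_rad)[None, :]
            * 1e3
        )

    def to_dataframe(self):
        import pandas as pd

        lam, th = np.meshgrid(self.wavelength_nm, np.degrees(self.theta_rad), indexing="ij")
        return pd.DataFrame(
            {
                "lambda_nm": lam.ravel(),
                "theta_deg": th.ravel(),
                "G_arb": self.values.ravel(),
            }
        )

    def to_hdf5(self, path) -> None:
        """Dense-grid container (datasets wavelength_nm, theta_rad, values)."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("wavelength_nm", data=self.wavelength_nm)
            fh.create_dataset("theta_rad", data=self.theta_rad)
            fh.create_dataset("values", data=self.values)

    @classmethod
    def from_hdf5(cls, path) -> "AngularEmissionMap":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(
                wavelength_nm=fh["wavelength_nm"][:],
                theta_rad=fh["theta_rad"][:],
                values=fh["values"][:],
            )


# ---------------------------------------------------------------------------
# Stack construction
# ---------------------------------------------------------------------------


def build_stack(
    device: DeviceSpec,
    wavelength_nm: float,
    materials: Mapping[str, MaterialModel] | None = None,
    planarize: str | None = None,
):
    """Resolve the device into (eps_substrate, layers, eps_superstrate) at one
    wavelength, ordered from the glass side upward (the incidence side of
    the collection geometry).

    ``planarize``: None keeps the grating; ``"film"`` replaces the wires by
    continuous Au/Cr films (unpatterned junction reference); ``"bare"``
    removes them entirely.

    Returns ``(eps_in, layer_defs, eps_out, gap_index)`` where ``gap_index``
    indexes the tunnelling (Al2O3) layer within ``layer_defs``.
    """
    mats = materials if materials is not None else default_materials()

    def eps(name: str) -> complex:
        return complex(permittivity(mats[name], wavelength_nm))

    g = device.grating
    eps_sub = eps(device.substrate)
    eps_sup = eps(device.superstrate)
    eps_wire = eps(device.wire_material)
    eps_adh = eps(device.adhesion_material)
    eps_over = eps(device.overlayer_material)

    layers: list[_rcwa.LayerDef] = []
    gap_index = None
    # unpatterned films, listed superstrate->substrate in the spec, built here
    # substrate->superstrate
    for name, t in reversed(device.layers):
        layers.append(_rcwa.LayerDef(thickness=t, eps=eps(name)))
        if name == "Al2O3":
            gap_index = len(layers) - 1

    t_over = float(device.overlayer_nm)
    wire_h = g.adhesion_thickness + g.wire_thickness
    w, period = g.wire_width, g.period_x
    groove = period - w
    eps_tol = 1e-9

    if planarize == "bare":
        if t_over > eps_tol:
            layers.append(_rcwa.LayerDef(thickness=t_over, eps=eps_over))
        if gap_index is None:
            raise ValueError("device has no Al2O3 tunnelling layer")
        return eps_sub, layers, eps_sup, gap_index

    if planarize == "film":
        layers.append(_rcwa.LayerDef(thickness=g.adhesion_thickness, eps=eps_adh))
        layers.append(_rcwa.LayerDef(thickness=g.wire_thickness, eps=eps_wire))
        if t_over > eps_tol:
            layers.append(_rcwa.LayerDef(thickness=t_over, eps=eps_over))
        if gap_index is None:
            raise ValueError("device has no Al2O3 tunnelling layer")
        return eps_sub, layers, eps_sup, gap_index

    style = device.overlayer_style
    if style == "conformal" and t_over > wire_h + eps_tol:
        raise ValueError(
            "conformal coatings thicker than the wire height are not supported; "
            "use overlayer_style='fill'"
        )

    def groove_fill(z_lo: float, z_hi: float):
        """Segments of the groove region for a slab [z_lo, z_hi] above the gap."""
        if t_over <= eps_tol:
            return ((groove, eps_sup),)
        if style == "fill":
            filled = t_over >= z_hi - eps_tol
            return ((groove, eps_over if filled else eps_sup),)
        # conformal: analyte on the groove floor (z < t_over) and as sidewall
        # films of thickness t_over on both wire flanks
        if z_hi <= t_over + eps_tol:
            return ((groove, eps_over),)
        if 2.0 * t_over >= groove - eps_tol:
            return ((groove, eps_over),)
        return ((t_over, eps_over), (groove - 2.0 * t_over, eps_sup), (t_over, eps_over))

    # z-breakpoints measured upward from the top of the gap layer
    cuts = {0.0, g.adhesion_thickness, wire_h}
    if t_over > eps_tol:
        cuts.add(min(t_over, wire_h))
    zs = sorted(c for c in cuts if 0.0 <= c <= wire_h)
    for z_lo, z_hi in zip(zs[:-1], zs[1:]):
        if z_hi - z_lo <= eps_tol:
            continue
        metal = eps_adh if z_hi <= g.adhesion_thickness + eps_tol else eps_wire
        layers.append(
            _rcwa.LayerDef(
                thickness=z_hi - z_lo,
                segments=((w, metal),) + groove_fill(z_lo, z_hi),
            )
        )

    if t_over > eps_tol:
        if style == "fill":
            if t_over > wire_h + eps_tol:
                layers.append(_rcwa.LayerDef(thickness=t_over - wire_h, eps=eps_over))
        else:
            # conformal cap draped over the wire top and sidewall films,
            # spanning [-t_over, w + t_over] around the wire
            if 2.0 * t_over >= groove - eps_tol:
                layers.append(_rcwa.LayerDef(thickness=t_over, eps=eps_over))
            else:
                layers.append(
                    _rcwa.LayerDef(
                        thickness=t_over,
                        segments=(
                            (w + t_over, eps_over),
                            (groove - 2.0 * t_over, eps_sup),
                            (t_over, eps_over),
                        ),
                    )
                )

    if gap_index is None:
        raise ValueError("device has no Al2O3 tunnelling layer")
    return eps_sub, layers, eps_sup, gap_index


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------


def tmm_solve(
    device: DeviceSpec,
    excitation: PlaneWaveExcitation,
    materials: Mapping[str, MaterialModel] | None = None,
    planarize: str = "film",
) -> _tmm.TmmResult:
    """Planar reference solve (grating replaced per ``planarize``).

    Incidence from ``excitation.side``; supports both polarizations.
    Returns the low-level :class:`lietsim._tmm.TmmResult` (reflection and
    transmission in E-field convention, per-layer amplitudes, closed-form
    absorption).
    """
    lam = excitation.wavelength_nm
    k0 = 2.0 * np.pi / lam
    kx = k0 * np.sin(excitation.theta_rad)
    eps_sub, layer_defs, eps_sup, _ = build_stack(device, lam, materials, planarize=planarize)
    planar = [(l.eps, l.thickness) for l in layer_defs]
    if excitation.side == "substrate":
        return _tmm.solve(k0, kx, eps_sub, planar, eps_sup, pol=excitation.polarization)
    return _tmm.solve(
        k0, kx, eps_sup, [p for p in reversed(planar)], eps_sub, pol=excitation.polarization
    )


def rcwa_solve(
    device: DeviceSpec,
    excitation: PlaneWaveExcitation,
    n_harmonics: int = 41,
    materials: Mapping[str, MaterialModel] | None = None,
    check_convergence: bool = False,
) -> _rcwa.RcwaResult:
    """Full grating solve under p-polarized plane-wave excitation.

    ``n_harmonics`` is the total (odd) number of Fourier orders, >= 11.
    With ``check_convergence`` the solve is repeated at ``n+20`` harmonics
    and a :class:`ConvergenceWarning` is emitted if the total reflected
    power changes by more than 1%.
    """
    if n_harmonics % 2 == 0 or n_harmonics < 11:
        raise ValueError("n_harmonics must be odd and >= 11")
    if excitation.polarization != "p":
        raise PolarizationError("the grating solver is TM-only (p polarization)")
    lam = excitation.wavelength_nm
    k0 = 2.0 * np.pi / lam
    kx = k0 * np.sin(excitation.theta_rad)
    eps_sub, layer_defs, eps_sup, _ = build_stack(device, lam, materials)
    if excitation.side == "superstrate":
        eps_in, eps_out = eps_sup, eps_sub
        layer_defs = list(reversed(layer_defs))
    else:
        eps_in, eps_out = eps_sub, eps_sup
    res = _rcwa.solve_grating(
        k0, kx, eps_in, layer_defs, eps_out, device.grating.period_x, n_harmonics
    )
    if check_convergence:
        res2 = _rcwa.solve_grating(
            k0, kx, eps_in, layer_defs, eps_out, device.grating.period_x, n_harmonics + 20
        )
        denom = max(res2.R, 1e-30)
        rel = abs(res.R - res2.R) / denom
        if rel > 0.01:
            warnings.warn(
                f"RCWA not converged at {n_harmonics} harmonics: total R "
                f"{res.R:.6g} vs {res2.R:.6g} at {n_harmonics + 20}",
                ConvergenceWarning,
            )
    return res


# ---------------------------------------------------------------------------
# Reciprocity route
# ---------------------------------------------------------------------------


# Reference wavelength of the omega^2 reciprocity prefactor (the far-field
# amplitude of a fixed dipole scales as omega^2 times the reciprocal field;
# the dimensionless form (LAMBDA_REF/lambda)^2 keeps g of order unity).
LAMBDA_REF_NM = 1000.0


def _gap_ez(
    device: DeviceSpec,
    wavelength_nm: float,
    theta_rad: float,
    grid: DipoleGrid,
    n_harmonics: int,
    materials,
    phi_rad: float = 0.0,
):
    """Far-field amplitudes g of the gap dipoles at one observation
    direction: omega^2 prefactor times the vertical field at the dipole
    positions for a unit-E p-wave from the glass side at in-air angle
    ``theta_rad`` and azimuth ``phi_rad``."""
    lam = wavelength_nm
    k0 = 2.0 * np.pi / lam
    eps_sub, layer_defs, eps_sup, gap_index = build_stack(device, lam, materials)
    gap_d = layer_defs[gap_index].thickness
    w2 = (LAMBDA_REF_NM / lam) ** 2
    if abs(phi_rad) < 1e-12:
        kx = k0 * np.sin(theta_rad)
        res = _rcwa.solve_grating(
            k0, kx, eps_sub, layer_defs, eps_sup, device.grating.period_x, n_harmonics
        )
        # unit incident E amplitude: Hy = n_glass in normalized units
        n_sub = np.sqrt(eps_sub).real
        _, _, ez = res.field_at(gap_index, grid.x_nm, grid.z_frac * gap_d)
        return w2 * n_sub * ez
    kx = k0 * np.sin(theta_rad) * np.cos(phi_rad)
    ky = k0 * np.sin(theta_rad) * np.sin(phi_rad)
    res = _rcwa.solve_conical(
        k0, kx, ky, eps_sub, layer_defs, eps_sup, device.grating.period_x,
        n_harmonics, inc_pol="p", internals_for=gap_index,
    )
    return w2 * res.gap_ez(gap_index, grid.x_nm, grid.z_frac * gap_d)


def farfield_amplitude(
    device: DeviceSpec,
    theta_rad: float,
    dipole_x_nm: float,
    wavelength_nm: float,
    n_harmonics: int = 41,
    z_frac: float = 0.5,
    polarization: str = "p",
    materials: Mapping[str, MaterialModel] | None = None,
) -> complex:
    """Far-field amplitude ``g`` of one surface-normal gap dipole.

    Computed by reciprocity as the vertical near-field at the dipole
    position under unit-amplitude p-polarized plane-wave illumination from
    the observation direction (glass side, in-air angle ``theta_rad``).
    The proportionality constant between this quantity and the physical
    e^{ikr}/r far-field amplitude is angle-independent and fixed to 1
    (absolute emission scale is declared arbitrary).
    """
    if polarization != "p":
        raise PolarizationError(
            "surface-normal tunnelling dipoles emit p-polarized light only"
        )
    grid = DipoleGrid(x_nm=np.array([dipole_x_nm]), z_frac=z_frac)
    return complex(
        _gap_ez(device, wavelength_nm, theta_rad, grid, n_harmonics, materials)[0]
    )


def angle_resolved_photonic(
    device: DeviceSpec,
    wavelength_nm: float,
    theta_rad: float,
    phi_rad: float = 0.0,
    grid: DipoleGrid | None = None,
    n_harmonics: int = 41,
    materials: Mapping[str, MaterialModel] | None = None,
) -> float:
    """Angle-resolved photonic contribution at one observation direction:
    incoherent sum over across-wire dipole positions l of the coherent
    along-wire sum (a single term here) |g_l|^2."""
    if grid is None:
        grid = DipoleGrid.under_wire(device)
    g = _gap_ez(device, wavelength_nm, theta_rad, grid, n_harmonics, materials, phi_rad)
    # coherent j-sum: n_j identical in-phase terms per l-group
    return float(np.sum(np.abs(grid.n_j * g) ** 2))


def photonic_map(
    device: DeviceSpec,
    wavelength_nm: Sequence[float],
    theta_rad: Sequence[float],
    phi_rad: float = 0.0,
    grid: DipoleGrid | None = None,
    n_harmonics: int = 41,
    materials: Mapping[str, MaterialModel] | None = None,
) -> AngularEmissionMap:
    """Angle-resolved photonic contribution on a (wavelength, theta) grid at
    fixed azimuth (default: the dispersion plane of the grating vector)."""
    if grid is None:
        grid = DipoleGrid.under_wire(device)
    mats = materials if materials is not None else default_materials()
    lam = np.asarray(wavelength_nm, dtype=float)
    th = np.asarray(theta_rad, dtype=float)
    vals = np.empty((lam.size, th.size))
    for i, l in enumerate(lam):
        for j, t in enumerate(th):
            g = _gap_ez(device, l, t, grid, n_harmonics, mats, phi_rad)
            vals[i, j] = np.sum(np.abs(grid.n_j * g) ** 2)
    return AngularEmissionMap(wavelength_nm=lam, theta_rad=th, values=vals)


def photonic_contribution(
    device: DeviceSpec,
    wavelength_nm: Sequence[float] | None = None,
    na: float | None = None,
    n_theta: int | None = None,
    n_phi: int = 1,
    grid: DipoleGrid | None = None,
    n_harmonics: int = 41,
    materials: Mapping[str, MaterialModel] | None = None,
    normalize: bool = True,
) -> GSpectrum:
    """NA-integrated photonic spectrum G.

    sin(theta)-weighted trapezoid quadrature of the angle-resolved
    contribution over in-air polar angles [0, arcsin(NA)].  With
    ``n_phi > 1`` the azimuth is additionally integrated over the collection
    cone (trapezoid on [0, pi/2], exploiting the two mirror symmetries of
    the grating); ``n_phi = 1`` restricts to the dispersion plane.
    Normalized to unit maximum with the divisor stored in ``scale`` (so
    families of spectra can share absolute units via ``values*scale``).
    """
    det = device.detection
    if wavelength_nm is None:
        wavelength_nm = det.wavelength_nm
    na = det.na if na is None else na
    if not 0.0 < na <= 1.0:
        raise ValueError("NA must lie in (0, 1]")
    theta_max = float(np.arcsin(na))
    n_theta = det.n_theta if n_theta is None else n_theta
    th = np.linspace(0.0, theta_max, n_theta)
    if th.size > 1 and (th[1] - th[0]) > np.deg2rad(2.0) + 1e-12:
        warnings.warn(
            f"angular grid spacing {np.degrees(th[1] - th[0]):.2f} deg exceeds 2 deg",
            QuadratureWarning,
        )
    if n_phi < 1:
        raise ValueError("n_phi must be >= 1")
    if n_phi == 1:
        phis = np.array([0.0])
        phi_w = np.array([1.0])
    else:
        phis = np.linspace(0.0, np.pi / 2.0, n_phi)
        phi_w = np.full(n_phi, phis[1] - phis[0])
        phi_w[0] *= 0.5
        phi_w[-1] *= 0.5
        phi_w *= 4.0  # mirror symmetries x->-x and y->-y
    lam = np.asarray(wavelength_nm, dtype=float)
    g = np.zeros(lam.size)
    for phi, w in zip(phis, phi_w):
        amap = photonic_map(device, lam, th, phi, grid, n_harmonics, materials)
        g += w * np.trapezoid(amap.values * np.sin(th)[None, :], th, axis=1)
    scale = float(g.max()) if normalize else 1.0
    if scale <= 0:
        raise ValueError("photonic contribution vanished on the whole grid")
    return GSpectrum(
        wavelength_nm=lam,
        values=g / scale if normalize else g,
        na=na,
        scale=scale,
    )
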