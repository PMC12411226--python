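"""Rigorous coupled-wave analysis for 1D-periodic stacks.

The structure is periodic along x (period P) and uniform along y.  Two
solvers are provided: ``solve_grating`` for in-plane TM (p) incidence —
the natural polarization of the surface-normal tunnelling dipoles — and
``solve_conical`` for arbitrary azimuth (ky != 0), where the TE/TM
characters mix.  The permittivity product rules follow Li's correct
Fourier factorization (inverse rule for eps*Ex, Laurent rule for eps*Ey,
eps*Ez), which is essential for metallic gratings.

Conventions match :mod:`lietsim._tmm`: exp(-i*omega*t), incidence from
``eps_in`` travelling +z, lengths in nm.  Mode amplitudes ``c_plus`` are
referenced at the layer entry plane and ``c_minus`` at the exit plane so
that all stored exponentials decay (S-matrix / Redheffer formulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import toeplitz

__all__ = ["LayerDef", "RcwaResult", "ConicalResult", "solve_grating", "solve_conical"]


@dataclass(frozen=True)
class LayerDef:
    """One slab: homogeneous (``eps`` set) or lamellar (``segments`` set).

    ``segments`` is a sequence of (width_nm, eps) spanning one period.
    """

    thickness: float
    eps: complex | None = None
    segments: tuple | None = None

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError("layer thickness must be positive")
        if (self.eps is None) == (self.segments is None):
            raise ValueError("specify exactly one of eps / segments")

    @property
    def homogeneous(self) -> bool:
        return self.segments is None


def _fourier_coeffs(segments, period: float, orders: np.ndarray, inverse: bool):
    """Fourier coefficients of eps(x) (or 1/eps) for piecewise-constant
    segments; orders are the required difference indices."""
    widths = np.array([w for w, _ in segments], dtype=float)
    vals = np.array([1.0 / e if inverse else e for _, e in segments], dtype=complex)
    if abs(widths.sum() - period) > 1e-9 * period:
        raise ValueError("segment widths must sum to the period")
    edges = np.concatenate(([0.0], np.cumsum(widths)))
    k = 2.0 * np.pi * orders[:, None] / period
    phase = np.exp(-1j * k * edges[None, :])
    out = np.zeros(len(orders), dtype=complex)
    nz = orders != 0
    for i, v in enumerate(vals):
        out[nz] += v * (phase[nz, i] - phase[nz, i + 1]) / (1j * k[nz, 0] * period)
        out[~nz] += v * widths[i] / period
    return out


def _toeplitz_from_coeffs(c, n_t):
    # c holds coefficients for orders -(n_t-1)..(n_t-1), centered
    mid = len(c) // 2
    col = c[mid : mid + n_t]
    row = c[mid::-1][:n_t]
    return toeplitz(col, row)


def _mode_branch(q: np.ndarray) -> np.ndarray:
    """Branch: Re(q) > 0 (decay towards +z); for purely propagating modes
    (Re ~ 0) pick Im(q) < 0, i.e. phase advance towards +z.  Exactly grazing
    orders (q ~ 0, the Wood-anomaly degeneracy) are nudged to keep the mode
    impedance matrices invertible."""
    q = np.where(q.real < 0, -q, q)
    flip = (np.abs(q.real) < 1e-10 * np.abs(q)) & (q.imag > 0)
    q = np.where(flip, -q, q)
    return np.where(np.abs(q) < 1e-9, 1e-9 + 0j, q)


def _layer_modes(layer: LayerDef, k0: float, kx: float, period: float, n_t: int):
    """(W, Q, V) modal matrices for Hy; V is defined so the tangential-E
    harmonics are V @ (c_plus_terms - c_minus_terms)."""
    m = np.arange(n_t) - n_t // 2
    alpha = (kx + 2.0 * np.pi * m / period) / k0
    Kx = np.diag(alpha)
    if layer.homogeneous:
        q = _mode_branch(np.sqrt(alpha**2 - layer.eps + 0j))
        W = np.eye(n_t, dtype=complex)
        V = np.diag(q / layer.eps)
        return W, np.diag(q), V
    orders = np.arange(-(n_t - 1), n_t)
    E = _toeplitz_from_coeffs(_fourier_coeffs(layer.segments, period, orders, False), n_t)
    A = _toeplitz_from_coeffs(_fourier_coeffs(layer.segments, period, orders, True), n_t)
    M = np.linalg.solve(A, Kx @ np.linalg.solve(E, Kx) - np.eye(n_t))
    lam, W = np.linalg.eig(M)
    q = _mode_branch(np.sqrt(lam + 0j))
    V = A @ W @ np.diag(q)
    return W, np.diag(q), V


def _interface_smatrix(WA, VA, WB, VB):
    """S-matrix of the A|B interface from mode matching.

    With P = WA^-1 WB and Q = VA^-1 VB the matching conditions give
    S21 = 2(P+Q)^-1, S11 = (P-Q)(P+Q)^-1, S22 = -(P+Q)^-1 (P-Q),
    S12 = ((P+Q) - (P-Q)(P+Q)^-1(P-Q))/2.
    """
    P = np.linalg.solve(WA, WB)
    Q = np.linalg.solve(VA, VB)
    pm = P - Q
    ipq = np.linalg.inv(P + Q)
    s11 = pm @ ipq
    s21 = 2.0 * ipq
    s22 = -ipq @ pm
    s12 = 0.5 * ((P + Q) - pm @ ipq @ pm)
    return s11, s12, s21, s22


def _star(SA, SB):
    """Redheffer star product of two S-matrices given as (S11,S12,S21,S22)."""
    A11, A12, A21, A22 = SA
    B11, B12, B21, B22 = SB
    n = A11.shape[0]
    I = np.eye(n, dtype=complex)
    inv1 = np.linalg.solve(I - B11 @ A22, np.eye(n, dtype=complex))
    inv2 = np.linalg.solve(I - A22 @ B11, np.eye(n, dtype=complex))
    S11 = A11 + A12 @ inv1 @ B11 @ A21
    S12 = A12 @ inv1 @ B12
    S21 = B21 @ inv2 @ A21
    S22 = B22 + B21 @ inv2 @ A22 @ B12
    return S11, S12, S21, S22


@dataclass
class RcwaResult:
    """Diffraction solution for one (wavelength, angle) point."""

    k0: float
    kx: float
    period: float
    n_t: int
    eps_in: complex
    eps_out: complex
    r_orders: np.ndarray  # complex Hy amplitudes, order index m = -N..N
    t_orders: np.ndarray
    R_orders: np.ndarray  # efficiencies (0 for evanescent orders)
    T_orders: np.ndarray
    layer_fluxes: np.ndarray  # net +z flux at entry plane of each region boundary
    _internals: dict = field(default_factory=dict, repr=False)

    @property
    def orders(self) -> np.ndarray:
        return np.arange(self.n_t) - self.n_t // 2

    @property
    def R(self) -> float:
        return float(self.R_orders.sum())

    @property
    def T(self) -> float:
        return float(self.T_orders.sum())

    @property
    def A(self) -> float:
        return 1.0 - self.R - self.T

    def absorption_per_layer(self) -> np.ndarray:
        """Dissipation per interior layer from exact modal flux differences
        (entry minus exit flux), normalized to unit incident flux."""
        f = self.layer_fluxes.reshape(-1, 2)
        return f[:, 0] - f[:, 1]

    def gap_field_harmonics(self, layer_index: int, zeta: float):
        """(Hy_m, Ex_m, Ez_m) Fourier amplitudes inside interior layer
        ``layer_index`` at local height ``zeta`` from the layer entry."""
        W, Q, V, E, cp, cm, d = self._internals["layers"][layer_index]
        qd = np.diag(Q)
        up = W @ (np.exp(-self.k0 * qd * zeta) * cp) + W @ (
            np.exp(-self.k0 * qd * (d - zeta)) * cm
        )
        st = V @ (np.exp(-self.k0 * qd * zeta) * cp) - V @ (
            np.exp(-self.k0 * qd * (d - zeta)) * cm
        )
        ex = 1j * st
        m = self.orders
        alpha = (self.kx + 2.0 * np.pi * m / self.period) / self.k0
        if E is None:  # homogeneous layer
            eps = self._internals["eps_interior"][layer_index]
            ez = -(alpha / eps) * up
        else:
            ez = -np.linalg.solve(E, alpha * up)
        return up, ex, ez

    def field_at(self, layer_index: int, x, zeta: float):
        """Real-space (Hy, Ex, Ez) inside interior layer ``layer_index``."""
        hy_m, ex_m, ez_m = self.gap_field_harmonics(layer_index, zeta)
        m = self.orders
        kxm = self.kx + 2.0 * np.pi * m / self.period
        phase = np.exp(1j * np.outer(np.atleast_1d(x), kxm))
        return phase @ hy_m, phase @ ex_m, phase @ ez_m


def solve_grating(
    k0: float,
    kx: float,
    eps_in: complex,
    layers: Sequence[LayerDef],
    eps_out: complex,
    period: float,
    n_harmonics: int = 41,
    keep_internals: bool = True,
) -> RcwaResult:
    """Solve the periodic stack under unit-Hy p-polarized incidence from
    ``eps_in``.  ``n_harmonics`` is the total (odd) number of Fourier orders.
    """
    if n_harmonics % 2 == 0 or n_harmonics < 3:
        raise ValueError("n_harmonics must be odd and >= 3")
    n_t = n_harmonics
    half_in = LayerDef(thickness=1.0, eps=eps_in)
    half_out = LayerDef(thickness=1.0, eps=eps_out)
    W_in, Q_in, V_in = _layer_modes(half_in, k0, kx, period, n_t)
    W_out, Q_out, V_out = _layer_modes(half_out, k0, kx, period, n_t)

    modes = [_layer_modes(l, k0, kx, period, n_t) for l in layers]
    n = n_t
    # Build cumulative S-matrices:
    # S_before[i]: from incident medium up to entry of layer i (in layer-i basis)
    S_before = []
    Scum = (np.zeros((n, n), complex), np.eye(n, dtype=complex),
            np.eye(n, dtype=complex), np.zeros((n, n), complex))
    prevW, prevV = W_in, V_in
    for i, (W, Q, V) in enumerate(modes):
        Scum = _star(Scum, _interface_smatrix(prevW, prevV, W, V))
        S_before.append(Scum)
        X = np.diag(np.exp(-k0 * np.diag(Q) * layers[i].thickness))
        Scum = _star(Scum, (np.zeros((n, n), complex), X, X, np.zeros((n, n), complex)))
        prevW, prevV = W, V
    S_total = _star(Scum, _interface_smatrix(prevW, prevV, W_out, V_out))

    a_in = np.zeros(n, dtype=complex)
    a_in[n // 2] = 1.0
    r = S_total[0] @ a_in
    t = S_total[2] @ a_in

    m = np.arange(n_t) - n_t // 2
    alpha = (kx + 2.0 * np.pi * m / period) / k0
    q_in = np.diag(Q_in)
    q_out = np.diag(Q_out)
    g_in = 1j * q_in / eps_in  # Re(g) = Re(kz/(k0 eps)) for each order
    g_out = 1j * q_out / eps_out
    g0 = np.real(g_in[n // 2])
    R_orders = np.real(g_in) / g0 * np.abs(r) ** 2
    T_orders = np.real(g_out) / g0 * np.abs(t) ** 2

    # per-layer internal amplitudes (for fields and flux bookkeeping)
    internals = {"layers": [], "eps_interior": [l.eps for l in layers]}
    fluxes = []

    # S_after[i]: from exit of layer i to the output medium (layer-i basis)
    S_after = []
    Scum = (np.zeros((n, n), complex), np.eye(n, dtype=complex),
            np.eye(n, dtype=complex), np.zeros((n, n), complex))
    nextW, nextV = W_out, V_out
    for i in range(len(layers) - 1, -1, -1):
        W, Q, V = modes[i]
        Scum = _star(_interface_smatrix(W, V, nextW, nextV), Scum)
        S_after.insert(0, Scum)
        X = np.diag(np.exp(-k0 * np.diag(Q) * layers[i].thickness))
        Scum = _star((np.zeros((n, n), complex), X, X, np.zeros((n, n), complex)), Scum)
        nextW, nextV = W, V

    for i, (W, Q, V) in enumerate(modes):
        d = layers[i].thickness
        X = np.exp(-k0 * np.diag(Q) * d)
        Sb, Sa = S_before[i], S_after[i]
        # c_plus at entry; reflections of the upper part seen through the
        # layer phases: c_minus(exit) = Sa11 @ (X c_plus), and the lower part
        # feeds back Sb22 @ (X c_minus)
        M = np.eye(n, dtype=complex) - Sb[3] @ (X[:, None] * (Sa[0] @ np.diag(X)))
        cp = np.linalg.solve(M, Sb[2] @ a_in)
        cm = Sa[0] @ (X * cp)
        internals["layers"].append((W, Q, V, _eps_toeplitz(layers[i], kx, k0, period, n_t), cp, cm, d))
        # net +z flux at entry and exit planes of this layer
        for zeta in (0.0, d):
            qd = np.diag(Q)
            up = W @ (np.exp(-k0 * qd * zeta) * cp) + W @ (np.exp(-k0 * qd * (d - zeta)) * cm)
            st = V @ (np.exp(-k0 * qd * zeta) * cp) - V @ (np.exp(-k0 * qd * (d - zeta)) * cm)
            ex = 1j * st
            fluxes.append(0.5 * np.real(np.sum(ex * np.conj(up))))

    inc_flux = 0.5 * g0
    # fluxes per layer: entry, exit; normalize and reduce to region boundaries
    layer_fluxes = np.array(fluxes) / inc_flux if fluxes else np.array([])

    res = RcwaResult(
        k0=k0, kx=kx, period=period, n_t=n_t, eps_in=eps_in, eps_out=eps_out,
        r_orders=r, t_orders=t, R_orders=R_orders, T_orders=T_orders,
        layer_fluxes=layer_fluxes,
        _internals=internals if keep_internals else {},
    )
    return res


def _eps_toeplitz(layer: LayerDef, kx, k0, period, n_t):
    if layer.homogeneous:
        return None
    orders = np.arange(-(n_t - 1), n_t)
    return _toeplitz_from_coeffs(_fourier_coeffs(layer.segments, period, orders, False), n_t)


# ---------------------------------------------------------------------------
# Conical incidence (ky != 0)
# ---------------------------------------------------------------------------
#
# For azimuths out of the dispersion plane the TE/TM characters mix; the
# first-order Maxwell system in the (Ex, Ey) / (Hx, Hy) tangential harmonics
# closes into a 2*n_t eigenproblem per layer.  Li's rules enter through the
# eps*Ex (inverse) and eps*Ey, eps*Ez (Laurent) products.  Homogeneous
# layers get analytic TM/TE mode columns so diffraction orders keep a clean
# polarization labelling.


def _conical_FG(layer: LayerDef, k0, kx, ky, period, n_t):
    m = np.arange(n_t) - n_t // 2
    alpha = np.diag((kx + 2.0 * np.pi * m / period) / k0)
    beta = ky / k0
    I = np.eye(n_t, dtype=complex)
    if layer.homogeneous:
        Te = layer.eps * I
        Ti_inv = layer.eps * I
        Te_inv = I / layer.eps
    else:
        orders = np.arange(-(n_t - 1), n_t)
        Te = _toeplitz_from_coeffs(_fourier_coeffs(layer.segments, period, orders, False), n_t)
        Ti = _toeplitz_from_coeffs(_fourier_coeffs(layer.segments, period, orders, True), n_t)
        Ti_inv = np.linalg.inv(Ti)
        Te_inv = np.linalg.inv(Te)
    aTia = alpha @ Te_inv  # alpha * Te^-1 shorthand pieces
    F = np.block(
        [
            [beta * aTia, I - aTia @ alpha],
            [beta**2 * Te_inv - I, -beta * Te_inv @ alpha],
        ]
    )
    G = np.block(
        [
            [-alpha * beta, alpha @ alpha - Te],
            [Ti_inv - beta**2 * I, beta * alpha],
        ]
    )
    return F, G


def _conical_layer_modes(layer: LayerDef, k0, kx, ky, period, n_t):
    """(W, Q, V) for the 2*n_t conical system; W holds (Ex;Ey) harmonics,
    V the matching (Hx;Hy) harmonics (normalized h = eta0*H)."""
    m = np.arange(n_t) - n_t // 2
    alpha = (kx + 2.0 * np.pi * m / period) / k0
    beta = ky / k0
    if layer.homogeneous:
        eps = layer.eps
        kap2 = alpha**2 + beta**2
        zeta = np.sqrt(eps - kap2 + 0j)
        zeta = np.where((zeta.imag < 0) | ((zeta.imag == 0) & (zeta.real < 0)), -zeta, zeta)
        zeta = np.where(np.abs(zeta) < 1e-9, 1e-9 + 0j, zeta)  # Wood-anomaly guard
        q = -1j * zeta  # Re(q)>=0 for evanescent, phase advance for propagating
        n2 = 2 * n_t
        W = np.zeros((n2, n2), dtype=complex)
        V = np.zeros((n2, n2), dtype=complex)
        kap = np.sqrt(kap2)
        for i in range(n_t):
            if kap[i] > 1e-12:
                ca, cb = alpha[i] / kap[i], beta / kap[i]
            else:
                ca, cb = 1.0, 0.0
            # column i: TM-like (E parallel to transverse wavevector)
            W[i, i] = ca
            W[n_t + i, i] = cb
            V[i, i] = -cb * eps / zeta[i]
            V[n_t + i, i] = ca * eps / zeta[i]
            # column n_t+i: TE-like (E perpendicular)
            W[i, n_t + i] = cb
            W[n_t + i, n_t + i] = -ca
            V[i, n_t + i] = ca * zeta[i]
            V[n_t + i, n_t + i] = cb * zeta[i]
        return W, np.diag(np.concatenate([q, q])), V
    F, G = _conical_FG(layer, k0, kx, ky, period, n_t)
    lam, W = np.linalg.eig(-F @ G)
    q = _mode_branch(np.sqrt(lam + 0j))
    V = -1j * (G @ W) @ np.diag(1.0 / q)
    return W, np.diag(q), V


@dataclass
class ConicalResult:
    """Conical-incidence solution; mode coefficients are labelled
    (TM orders, TE orders) in each half-space."""

    k0: float
    kx: float
    ky: float
    period: float
    n_t: int
    eps_in: complex
    eps_out: complex
    r_coeffs: np.ndarray  # len 2*n_t
    t_coeffs: np.ndarray
    R_orders: np.ndarray  # (2, n_t): TM row, TE row
    T_orders: np.ndarray
    _internals: dict = field(default_factory=dict, repr=False)

    @property
    def R(self) -> float:
        return float(self.R_orders.sum())

    @property
    def T(self) -> float:
        return float(self.T_orders.sum())

    @property
    def A(self) -> float:
        return 1.0 - self.R - self.T

    def gap_ez(self, layer_index: int, x, zeta_z: float):
        """Vertical E field inside homogeneous interior layer ``layer_index``
        at local height ``zeta_z``, evaluated at positions ``x``."""
        W, Q, V, cp, cm, d, eps = self._internals["layers"][layer_index]
        qd = np.diag(Q)
        decay_p = np.exp(-self.k0 * qd * zeta_z)
        decay_m = np.exp(-self.k0 * qd * (d - zeta_z))
        h = V @ (decay_p * cp) - V @ (decay_m * cm)
        n_t = self.n_t
        hx, hy = h[:n_t], h[n_t:]
        m = np.arange(n_t) - n_t // 2
        alpha = (self.kx + 2.0 * np.pi * m / self.period) / self.k0
        beta = self.ky / self.k0
        ez_m = -(alpha * hy - beta * hx) / eps
        kxm = self.kx + 2.0 * np.pi * m / self.period
        phase = np.exp(1j * np.outer(np.atleast_1d(x), kxm))
        return phase @ ez_m


def _attach_prop(S, x):
    """star(S, prop(X)) with X = diag(x): closed form, no solves."""
    s11, s12, s21, s22 = S
    return s11, s12 * x[None, :], x[:, None] * s21, x[:, None] * s22 * x[None, :]


def _attach_prop_left(x, S):
    """star(prop(X), S) with X = diag(x)."""
    s11, s12, s21, s22 = S
    return x[:, None] * s11 * x[None, :], x[:, None] * s12, s21 * x[None, :], s22


def solve_conical(
    k0: float,
    kx: float,
    ky: float,
    eps_in: complex,
    layers: Sequence[LayerDef],
    eps_out: complex,
    period: float,
    n_harmonics: int = 41,
    inc_pol: str = "p",
    keep_internals: bool = True,
    internals_for: int | None = None,
) -> ConicalResult:
    """Plane-wave solve at arbitrary azimuth (ky conserved).

    The incident wave has unit |E| and polarization ``inc_pol`` ("p": E in
    the plane of incidence, "s": perpendicular).  At ky=0 this reduces to
    the in-plane TM/TE problems.  ``internals_for`` restricts the internal
    field bookkeeping to one interior layer (cheaper); None keeps all.
    """
    if n_harmonics % 2 == 0 or n_harmonics < 3:
        raise ValueError("n_harmonics must be odd and >= 3")
    n_t = n_harmonics
    n2 = 2 * n_t
    half_in = LayerDef(thickness=1.0, eps=eps_in)
    half_out = LayerDef(thickness=1.0, eps=eps_out)
    W_in, Q_in, V_in = _conical_layer_modes(half_in, k0, kx, ky, period, n_t)
    W_out, Q_out, V_out = _conical_layer_modes(half_out, k0, kx, ky, period, n_t)
    modes = [_conical_layer_modes(l, k0, kx, ky, period, n_t) for l in layers]

    n_layers = len(layers)
    seq = [(W_in, V_in)] + [(W, V) for W, _, V in modes] + [(W_out, V_out)]
    ifaces = [
        _interface_smatrix(seq[i][0], seq[i][1], seq[i + 1][0], seq[i + 1][1])
        for i in range(n_layers + 1)
    ]
    xs = [np.exp(-k0 * np.diag(Q) * l.thickness) for (_, Q, _), l in zip(modes, layers)]

    want = []
    if keep_internals:
        want = [internals_for] if internals_for is not None else list(range(n_layers))
    S_before = {}
    S_after = {}
    Scum = ifaces[0]
    for i in range(n_layers):
        if i in want:
            S_before[i] = Scum
        Scum = _attach_prop(Scum, xs[i])
        Scum = _star(Scum, ifaces[i + 1])
    S_total = Scum
    if want:
        Scum = ifaces[n_layers]
        for i in range(n_layers - 1, -1, -1):
            if i in want:
                S_after[i] = Scum
            if i > 0:
                Scum = _attach_prop_left(xs[i], Scum)
                Scum = _star(ifaces[i], Scum)

    # incident amplitude: unit |E| plane wave, 0th order
    kap0 = np.hypot(kx / k0, ky / k0)
    zeta0 = np.sqrt(eps_in - kap0**2 + 0j)
    a_in = np.zeros(n2, dtype=complex)
    if inc_pol == "p":
        # transverse E of a unit-|E| TM wave is cos(theta_medium) = zeta/n
        a_in[n_t // 2] = zeta0 / np.sqrt(eps_in)
    elif inc_pol == "s":
        a_in[n_t + n_t // 2] = 1.0
    else:
        raise ValueError("inc_pol must be 'p' or 's'")
    r = S_total[0] @ a_in
    t = S_total[2] @ a_in

    def order_fluxes(coeffs, eps_med, Q_med):
        q = np.diag(Q_med)[:n_t]
        zeta = 1j * q  # zeta = kz/k0 of each order
        tm = coeffs[:n_t]
        te = coeffs[n_t:]
        with np.errstate(divide="ignore", invalid="ignore"):
            f_tm = 0.5 * np.real(np.conj(eps_med / zeta)) * np.abs(tm) ** 2
        f_te = 0.5 * np.real(zeta) * np.abs(te) ** 2
        f_tm = np.where(np.real(zeta) > 1e-12, f_tm, 0.0)
        return np.vstack([f_tm, f_te])

    inc_flux = order_fluxes(a_in, eps_in, Q_in).sum()
    R_orders = order_fluxes(r, eps_in, Q_in) / inc_flux
    T_orders = order_fluxes(t, eps_out, Q_out) / inc_flux

    internals = {"layers": {}}
    for i in want:
        W, Q, V = modes[i]
        d = layers[i].thickness
        X = xs[i]
        Sb, Sa = S_before[i], S_after[i]
        M = np.eye(n2, dtype=complex) - Sb[3] @ (X[:, None] * (Sa[0] * X[None, :]))
        cp = np.linalg.solve(M, Sb[2] @ a_in)
        cm = Sa[0] @ (X * cp)
        internals["layers"][i] = (W, Q, V, cp, cm, d, layers[i].eps)

    return ConicalResult(
        k0=k0, kx=kx, ky=ky, period=period, n_t=n_t,
        eps_in=eps_in, eps_out=eps_out,
        r_coeffs=r, t_coeffs=t, R_orders=R_orders, T_orders=T_orders,
        _internals=internals,
    )
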