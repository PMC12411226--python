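"""Tunnel-junction current model, Fowler-Nordheim analysis and fitting.

The forward model is the intermediate-voltage mean-barrier tunnelling
current density of a symmetric junction (rectangular barrier of mean height
phi_bar and width delta_s, no image-force rounding), with the standard
effective-mass substitution:

    J(V) = e/(2 pi h ds^2) * [ p1 exp(-K sqrt(p1)) - p2 exp(-K sqrt(p2)) ]

with p1,2 = e*(phi_bar -/+ V/2) in joules and K = 4 pi ds sqrt(2 m_eff)/h.
The model is odd in V and is fitted in log space because measured curves
span many decades.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .constants import E_CHARGE, H_PLANCK, M_ELECTRON

__all__ = [
    "BarrierParams",
    "IVCurve",
    "FnCurve",
    "DataError",
    "FitError",
    "BoundaryWarning",
    "simmons_j",
    "fn_transform",
    "fit_simmons",
    "write_iv_csv",
    "read_iv_csv",
]

logger = logging.getLogger(__name__)


class DataError(ValueError):
    pass


class FitError(RuntimeError):
    pass


class BoundaryWarning(UserWarning):
    pass


@dataclass(frozen=True)
class BarrierParams:
    """Mean tunnel-barrier parameters."""

    phi_bar_ev: float
    delta_s_nm: float
    m_eff_ratio: float = 0.23

    def __post_init__(self):
        if self.phi_bar_ev <= 0:
            raise ValueError("barrier height must be positive")
        if self.delta_s_nm <= 0:
            raise ValueError("barrier width must be positive")
        if not 0 < self.m_eff_ratio <= 1:
            raise ValueError("effective mass ratio must lie in (0, 1]")


@dataclass
class IVCurve:
    """Bias / current-density pairs (V, A m^-2); bias strictly increasing."""

    bias_v: np.ndarray
    current_density: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        v = np.asarray(self.bias_v, dtype=float)
        j = np.asarray(self.current_density, dtype=float)
        if v.shape != j.shape or v.ndim != 1:
            raise ValueError("bias and current arrays must be 1-D of equal length")
        if np.any(np.diff(v) <= 0):
            raise ValueError("bias must be strictly increasing")
        self.bias_v = v
        self.current_density = j


@dataclass
class FnCurve:
    """Fowler-Nordheim representation (1/V, ln(J/V^2)) of a positive branch."""

    inv_v: np.ndarray
    ln_j_v2: np.ndarray
    minimum_v: float | None  # bias of the interior minimum, None if absent


def simmons_j(bias_v, params: BarrierParams, breakdown_guard_v: float = 5.0):
    """Current density (A m^-2) of the mean-barrier model; odd in bias.

    Above ``2*phi_bar`` volts (vanishing reduced barrier) the current
    switches to a field-emission expression; the switch is logged.
    Scalar in -> scalar out.
    """
    v = np.asarray(bias_v, dtype=float)
    scalar = v.ndim == 0
    v = np.atleast_1d(v)
    if np.any(np.abs(v) > breakdown_guard_v):
        raise ValueError(f"|bias| exceeds the {breakdown_guard_v} V breakdown guard")
    sign = np.sign(v)
    va = np.abs(v)
    ds = params.delta_s_nm * 1e-9
    m_eff = params.m_eff_ratio * M_ELECTRON
    k_exp = 4.0 * np.pi * ds * np.sqrt(2.0 * m_eff) / H_PLANCK  # per sqrt(J)
    j0 = E_CHARGE / (2.0 * np.pi * H_PLANCK * ds**2)

    out = np.zeros_like(va)
    direct = va < 2.0 * params.phi_bar_ev
    if np.any(direct):
        p1 = E_CHARGE * (params.phi_bar_ev - va[direct] / 2.0)
        p2 = E_CHARGE * (params.phi_bar_ev + va[direct] / 2.0)
        out[direct] = j0 * (
            p1 * np.exp(-k_exp * np.sqrt(p1)) - p2 * np.exp(-k_exp * np.sqrt(p2))
        )
    if np.any(~direct):
        logger.info(
            "bias beyond 2*phi_bar = %.3g V: using the field-emission branch",
            2.0 * params.phi_bar_ev,
        )
        vf = va[~direct]
        f_field = vf / ds  # V/m
        phi_j = E_CHARGE * params.phi_bar_ev
        pref = E_CHARGE**3 * f_field**2 / (8.0 * np.pi * H_PLANCK * phi_j)
        expo = -8.0 * np.pi * np.sqrt(2.0 * m_eff) * phi_j**1.5 / (
            3.0 * H_PLANCK * E_CHARGE * f_field
        )
        out[~direct] = pref * np.exp(expo)
    out = sign * out
    return float(out[0]) if scalar else out


def fn_transform(iv: IVCurve) -> FnCurve:
    """Fowler-Nordheim transform of a strictly positive branch.

    Reports the bias of the interior minimum of ln(J/V^2) vs 1/V (parabolic
    refinement); ``minimum_v`` is None when the curve has no interior
    minimum on the sampled range.
    """
    v, j = iv.bias_v, iv.current_density
    bad = np.flatnonzero((v <= 0) | (j <= 0))
    if bad.size:
        raise DataError(
            f"Fowler-Nordheim transform needs positive V and J; offending rows: {bad.tolist()}"
        )
    inv_v = 1.0 / v[::-1]  # ascending in 1/V
    lnjv2 = np.log(j[::-1] / v[::-1] ** 2)
    i = int(np.argmin(lnjv2))
    if i == 0 or i == len(lnjv2) - 1:
        return FnCurve(inv_v=inv_v, ln_j_v2=lnjv2, minimum_v=None)
    x0, x1, x2 = inv_v[i - 1 : i + 2]
    y0, y1, y2 = lnjv2[i - 1 : i + 2]
    d0, d2 = x1 - x0, x2 - x1
    a = (d2 * (y0 - y1) + d0 * (y2 - y1)) / (d0 * d2 * (d0 + d2))
    b = (d0**2 * (y2 - y1) + d2**2 * (y1 - y0)) / (d0 * d2 * (d0 + d2))
    x_min = x1 - b / (2 * a) if a > 0 else x1
    return FnCurve(inv_v=inv_v, ln_j_v2=lnjv2, minimum_v=float(1.0 / x_min))


def fit_simmons(
    iv: IVCurve,
    m_eff_ratio: float = 0.23,
    initial: tuple[float, float] = (1.5, 5.0),
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.5, 1.0), (5.0, 8.0)),
) -> tuple[BarrierParams, dict]:
    """Least-squares fit of (phi_bar, delta_s) on ln J, effective mass fixed.

    ``bounds`` is ((phi_lo, ds_lo), (phi_hi, ds_hi)) in (eV, nm).  Returns
    the fitted :class:`BarrierParams` and a diagnostics dict with the
    residual norm, parameter covariance estimate and a boundary flag; a
    :class:`BoundaryWarning` is emitted when the optimum sits on a bound.
    """
    v, j = iv.bias_v, iv.current_density
    pos = (v > 0) & (j > 0)
    if pos.sum() < 20:
        raise DataError("need at least 20 points with positive bias and current")
    v, j = v[pos], j[pos]
    lnj = np.log(j)

    def resid(p):
        model = simmons_j(v, BarrierParams(p[0], p[1], m_eff_ratio))
        model = np.maximum(model, 1e-300)
        return np.log(model) - lnj

    lo, hi = bounds
    sol = least_squares(resid, x0=np.asarray(initial, dtype=float), bounds=(lo, hi))
    if not sol.success:
        raise FitError(f"Simmons fit did not converge: {sol.message}")
    phi, ds = float(sol.x[0]), float(sol.x[1])
    at_bound = bool(
        np.any(np.isclose(sol.x, lo, rtol=0, atol=1e-9))
        or np.any(np.isclose(sol.x, hi, rtol=0, atol=1e-9))
    )
    if at_bound:
        warnings.warn(
            f"fit hit a parameter bound (phi={phi:.3g} eV, ds={ds:.3g} nm); "
            "the model likely does not describe the data",
            BoundaryWarning,
        )
    dof = max(len(v) - 2, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    jac = sol.jac
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    diagnostics = {
        "residual_norm": float(np.linalg.norm(sol.fun)),
        "rms_log_residual": float(np.sqrt(np.mean(sol.fun**2))),
        "covariance": cov,
        "at_bound": at_bound,
        "n_points": int(len(v)),
    }
    return BarrierParams(phi, ds, m_eff_ratio), diagnostics


# ---------------------------------------------------------------------------
# CSV
# ---------------------------------------------------------------------------


def write_iv_csv(iv: IVCurve, path) -> None:
    lines = [f"# {k}: {v}" for k, v in iv.meta.items()]
    lines.append("voltage_V,current_density_A_per_m2")
    header = "\n".join(lines)
    np.savetxt(
        path,
        np.column_stack([iv.bias_v, iv.current_density]),
        delimiter=",",
        header=header,
        comments="",
    )


def read_iv_csv(path) -> IVCurve:
    meta = {}
    n_meta = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                cols = [c.strip() for c in line.strip().split(",")]
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            n_meta += 1
        else:
            raise DataError("empty I-V file")
    if cols != ["voltage_V", "current_density_A_per_m2"]:
        raise DataError(
            f"unexpected I-V columns {cols}; "
            "need voltage_V,current_density_A_per_m2 (row "
            f"{n_meta + 1})"
        )
    data = np.loadtxt(path, delimiter=",", skiprows=n_meta + 1, ndmin=2)
    return IVCurve(bias_v=data[:, 0], current_density=data[:, 1], meta=meta)
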