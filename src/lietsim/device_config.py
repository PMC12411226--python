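"""Device geometry, material optical models and detection geometry.

This module is the single source of truth for every physical parameter of
the simulated junction device: the layered metal-insulator-metal stack, the
nanowire grating on top of it, the material permittivity models and the
collection optics (numerical aperture, wavelength and angle grids).

Units follow :mod:`lietsim.constants`: nm, eV, volts, kelvin.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .constants import nm_to_ev

__all__ = [
    "MaterialModel",
    "GratingSpec",
    "DetectionSpec",
    "DeviceSpec",
    "permittivity",
    "default_materials",
    "default_device",
    "save_device_config",
    "load_device_config",
]


class MaterialRangeError(ValueError):
    """Raised when a permittivity is requested outside a model's validity range."""


# ---------------------------------------------------------------------------
# Material models
# ---------------------------------------------------------------------------

# Lorentz-Drude parameterization of standard literature optical constants for
# the three metals in the stack (plasma energy in eV; oscillators as
# (strength f, damping Gamma eV, resonance energy eV); the j=0 row is the
# free-electron Drude term with resonance at 0).
_LD_PARAMS = {
    "Au": {
        "wp": 9.03,
        "f0": 0.760,
        "g0": 0.053,
        "osc": [
            (0.024, 0.241, 0.415),
            (0.010, 0.345, 0.830),
            (0.071, 0.870, 2.969),
            (0.601, 2.494, 4.304),
            (4.384, 2.214, 13.32),
        ],
    },
    "Al": {
        "wp": 14.98,
        "f0": 0.523,
        "g0": 0.047,
        "osc": [
            (0.227, 0.333, 0.162),
            (0.050, 0.312, 1.544),
            (0.166, 1.351, 1.808),
            (0.030, 3.382, 3.473),
        ],
    },
    "Cr": {
        "wp": 10.75,
        "f0": 0.168,
        "g0": 0.047,
        "osc": [
            (0.151, 3.175, 0.121),
            (0.150, 1.305, 0.543),
            (1.149, 2.676, 1.970),
            (0.825, 1.335, 8.775),
        ],
    },
}


def _lorentz_drude_eps(energy_ev: np.ndarray, params: Mapping) -> np.ndarray:
    """Evaluate a Lorentz-Drude permittivity at photon energies (eV)."""
    e = np.asarray(energy_ev, dtype=float)
    wp2 = params["wp"] ** 2
    eps = 1.0 - params["f0"] * wp2 / (e * (e + 1j * params["g0"]))
    for f_j, g_j, w_j in params["osc"]:
        eps = eps + f_j * wp2 / ((w_j**2 - e**2) - 1j * e * g_j)
    return eps


@dataclass(frozen=True)
class MaterialModel:
    """Tagged-union permittivity model.

    ``kind`` selects the payload:

    * ``"constant_index"`` -- real refractive index ``index``; eps = n**2.
    * ``"tabulated"`` -- wavelength table (strictly increasing, nm) with
      complex refractive index samples; log-linear interpolation in
      wavelength, valid only inside the table range.
    * ``"drude_lorentz"`` -- analytic Lorentz-Drude model ``dl_params``.
    """

    name: str
    kind: str
    index: float | None = None
    table_wl: np.ndarray | None = None
    table_nk: np.ndarray | None = None
    dl_params: Mapping | None = None
    wl_min: float = 300.0
    wl_max: float = 1300.0

    def __post_init__(self):
        if self.kind not in ("constant_index", "tabulated", "drude_lorentz"):
            raise ValueError(f"unknown material model kind {self.kind!r}")
        if self.kind == "constant_index" and (self.index is None or self.index <= 0):
            raise ValueError("constant_index model requires a positive index")
        if self.kind == "tabulated":
            wl = np.asarray(self.table_wl, dtype=float)
            if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
                raise ValueError(
                    f"tabulated material {self.name!r}: wavelength table must be "
                    "1-D and strictly increasing"
                )
            nk = np.asarray(self.table_nk, dtype=complex)
            if nk.shape != wl.shape:
                raise ValueError("wavelength and n+ik tables must have equal length")
            if np.any(nk.imag < -1e-12):
                raise ValueError(f"material {self.name!r}: negative extinction (gain)")
            object.__setattr__(self, "table_wl", wl)
            object.__setattr__(self, "table_nk", nk)
            object.__setattr__(self, "wl_min", float(wl[0]))
            object.__setattr__(self, "wl_max", float(wl[-1]))
        if self.kind == "drude_lorentz" and self.dl_params is None:
            raise ValueError("drude_lorentz model requires parameters")


def permittivity(material: MaterialModel, wavelength_nm) -> complex | np.ndarray:
    """Complex relative permittivity of ``material`` at ``wavelength_nm``.

    Raises :class:`MaterialRangeError` if the wavelength lies outside the
    model's validity range.  Scalar in -> scalar out; arrays broadcast.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    scalar = wl.ndim == 0
    wl = np.atleast_1d(wl)
    if np.any(wl < material.wl_min) or np.any(wl > material.wl_max):
        raise MaterialRangeError(
            f"wavelength outside validity range [{material.wl_min}, "
            f"{material.wl_max}] nm of material {material.name!r}"
        )
    if material.kind == "constant_index":
        eps = np.full(wl.shape, complex(material.index**2))
    elif material.kind == "drude_lorentz":
        eps = _lorentz_drude_eps(nm_to_ev(wl), material.dl_params)
    else:  # tabulated: log-linear interpolation of n and k in wavelength
        logwl = np.log(wl)
        logtab = np.log(material.table_wl)
        n = np.interp(logwl, logtab, material.table_nk.real)
        k = np.interp(logwl, logtab, material.table_nk.imag)
        eps = (n + 1j * k) ** 2
    return complex(eps[0]) if scalar else eps


def default_materials(tabulated_step_nm: float = 1.0) -> dict[str, MaterialModel]:
    """Registry of bundled materials.

    Metals (Au, Cr, Al) are shipped as wavelength tables sampled from the
    Lorentz-Drude parameterization on a dense grid (log-linear interpolation
    at use time); dielectrics are constant-index.
    """
    wl = np.arange(300.0, 1500.0 + tabulated_step_nm / 2, tabulated_step_nm)
    mats: dict[str, MaterialModel] = {}
    for name, params in _LD_PARAMS.items():
        eps = _lorentz_drude_eps(nm_to_ev(wl), params)
        nk = np.sqrt(eps.astype(complex))
        # principal sqrt keeps Im >= 0 for Im(eps) >= 0
        nk = np.where(nk.imag < 0, -nk, nk)
        mats[name] = MaterialModel(name=name, kind="tabulated", table_wl=wl, table_nk=nk)
    mats["Al2O3"] = MaterialModel(name="Al2O3", kind="constant_index", index=1.76)
    mats["glass"] = MaterialModel(name="glass", kind="constant_index", index=1.52)
    mats["PMMA"] = MaterialModel(name="PMMA", kind="constant_index", index=1.49)
    mats["air"] = MaterialModel(name="air", kind="constant_index", index=1.0)
    mats["vacuum"] = MaterialModel(name="vacuum", kind="constant_index", index=1.0)
    return mats


# ---------------------------------------------------------------------------
# Device / detection geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GratingSpec:
    """1D nanowire grating: period and wire cross-section (nm).

    The wire consists of the Au body (``wire_thickness``) on top of a
    patterned adhesion layer (``adhesion_thickness``); both share
    ``wire_width``.  The second period (along the wires) is >= 100 um and is
    treated as infinite, making the electromagnetic problem 1D-periodic.
    """

    period_x: float = 400.0
    wire_width: float = 92.0
    wire_thickness: float = 50.0
    adhesion_thickness: float = 5.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be > 0")
        if self.wire_width >= self.period_x:
            raise ValueError("wire_width must be smaller than period_x")


@dataclass(frozen=True)
class DetectionSpec:
    """Collection optics: NA and the spectral/angular sampling grids.

    ``theta_max_rad`` is the in-air polar collection half-angle
    arcsin(NA); emission is collected through the glass substrate and the
    polar angle is parameterized by its in-air equivalent (k_par = k0 sin
    theta), so NA maps directly onto the angular cutoff.
    """

    na: float = 0.8
    wavelength_nm: np.ndarray = field(
        default_factory=lambda: np.arange(500.0, 950.0 + 1e-9, 3.0)
    )
    n_theta: int = 27
    azimuth_rad: float = 0.0

    def __post_init__(self):
        if not 0 < self.na <= 1:
            raise ValueError("NA must lie in (0, 1]")
        wl = np.asarray(self.wavelength_nm, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be 1-D strictly increasing")
        object.__setattr__(self, "wavelength_nm", wl)
        if self.n_theta < 2:
            raise ValueError("need at least two polar angles")

    @property
    def theta_max_rad(self) -> float:
        return float(np.arcsin(self.na))

    def theta_grid_rad(self) -> np.ndarray:
        return np.linspace(0.0, self.theta_max_rad, self.n_theta)


@dataclass(frozen=True)
class DeviceSpec:
    """Layered junction stack plus the top nanowire grating.

    ``layers`` lists the unpatterned films from superstrate side to
    substrate side as (material name, thickness nm); the grating sits on top
    of the first layer.  Default stack (characterization variant):
    Au 50 / Cr 5 wires on Al2O3 5 / Al 25 / glass.
    """

    layers: tuple[tuple[str, float], ...] = (("Al2O3", 5.0), ("Al", 25.0))
    grating: GratingSpec = field(default_factory=GratingSpec)
    superstrate: str = "air"
    substrate: str = "glass"
    wire_material: str = "Au"
    adhesion_material: str = "Cr"
    detection: DetectionSpec = field(default_factory=DetectionSpec)
    variant: str = "characterization"
    # optional analyte coating of the metasurface: "conformal" drapes a film
    # of the given thickness over the wire topography (floor, sidewalls and
    # wire tops), "fill" pours it into the grooves from the bottom up
    overlayer_nm: float = 0.0
    overlayer_material: str = "PMMA"
    overlayer_style: str = "conformal"

    def __post_init__(self):
        for name, t in self.layers:
            if t <= 0:
                raise ValueError(f"layer {name!r} must have positive thickness")
        if self.overlayer_nm < 0:
            raise ValueError("overlayer thickness must be >= 0")
        if self.overlayer_style not in ("conformal", "fill"):
            raise ValueError("overlayer_style must be 'conformal' or 'fill'")

    @property
    def gap_layer_index(self) -> int:
        """Index (into ``layers``) of the tunnelling barrier layer."""
        for i, (name, _) in enumerate(self.layers):
            if name == "Al2O3":
                return i
        raise ValueError("device has no Al2O3 tunnelling layer")

    def with_overlayer(
        self, thickness_nm: float, material: str = "PMMA", style: str = "conformal"
    ) -> "DeviceSpec":
        return dataclasses.replace(
            self,
            overlayer_nm=float(thickness_nm),
            overlayer_material=material,
            overlayer_style=style,
        )


def default_device(variant: str) -> DeviceSpec:
    """Default device for a named experimental variant.

    ``characterization``: 92 nm wires, NA 0.8 collection;
    ``sensing``: 120 nm wires, NA 0.3 collection.  Both use a 400 nm period
    and the Au 50 / Cr 5 / Al2O3 5 / Al 25 / glass stack.
    """
    if variant == "characterization":
        return DeviceSpec(
            grating=GratingSpec(wire_width=92.0),
            detection=DetectionSpec(na=0.8),
            variant=variant,
        )
    if variant == "sensing":
        return DeviceSpec(
            grating=GratingSpec(wire_width=120.0),
            detection=DetectionSpec(na=0.3),
            variant=variant,
        )
    raise ValueError(
        f"unknown device variant {variant!r}; expected 'characterization' or 'sensing'"
    )


# ---------------------------------------------------------------------------
# Config serialization (strict round-trip YAML)
# ---------------------------------------------------------------------------

_DEVICE_KEYS = {
    "layers",
    "grating",
    "superstrate",
    "substrate",
    "wire_material",
    "adhesion_material",
    "detection",
    "variant",
    "overlayer_nm",
    "overlayer_material",
    "overlayer_style",
}
_GRATING_KEYS = {"period_x", "wire_width", "wire_thickness", "adhesion_thickness"}
_DETECTION_KEYS = {"na", "wavelength_nm", "n_theta", "azimuth_rad"}


def device_to_dict(device: DeviceSpec) -> dict:
    wl = device.detection.wavelength_nm
    return {
        "layers": [[n, float(t)] for n, t in device.layers],
        "grating": {k: float(getattr(device.grating, k)) for k in sorted(_GRATING_KEYS)},
        "superstrate": device.superstrate,
        "substrate": device.substrate,
        "wire_material": device.wire_material,
        "adhesion_material": device.adhesion_material,
        "detection": {
            "na": float(device.detection.na),
            "wavelength_nm": [float(x) for x in wl],
            "n_theta": int(device.detection.n_theta),
            "azimuth_rad": float(device.detection.azimuth_rad),
        },
        "variant": device.variant,
        "overlayer_nm": float(device.overlayer_nm),
        "overlayer_material": device.overlayer_material,
        "overlayer_style": device.overlayer_style,
    }


def device_from_dict(data: Mapping) -> DeviceSpec:
    unknown = set(data) - _DEVICE_KEYS
    if unknown:
        raise ValueError(f"unknown device config keys: {sorted(unknown)}")
    kwargs = dict(data)
    if "grating" in kwargs:
        g = dict(kwargs["grating"])
        bad = set(g) - _GRATING_KEYS
        if bad:
            raise ValueError(f"unknown grating config keys: {sorted(bad)}")
        kwargs["grating"] = GratingSpec(**g)
    if "detection" in kwargs:
        d = dict(kwargs["detection"])
        bad = set(d) - _DETECTION_KEYS
        if bad:
            raise ValueError(f"unknown detection config keys: {sorted(bad)}")
        if "wavelength_nm" in d:
            d["wavelength_nm"] = np.asarray(d["wavelength_nm"], dtype=float)
        kwargs["detection"] = DetectionSpec(**d)
    if "layers" in kwargs:
        kwargs["layers"] = tuple((str(n), float(t)) for n, t in kwargs["layers"])
    return DeviceSpec(**kwargs)


def save_device_config(device: DeviceSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(device_to_dict(device), fh, sort_keys=False)


def load_device_config(path) -> DeviceSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return device_from_dict(data)
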