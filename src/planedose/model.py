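"""Analytical beam model for FF and FFF photon beams.

The model decomposes the linac head into a primary point source at the
target (weight fixed at 1) and an extra-focal scatter source on a plane
below the target, represented as a sum of bivariate Gaussians:

    f(x, y) = sum_i A_i / (2 pi sx_i sy_i) exp(-x^2/(2 sx_i^2) - y^2/(2 sy_i^2))

The x/y asymmetry of the Gaussians carries the collimator-exchange and
monitor-backscatter physics implicitly.  FFF beams additionally carry a
rotationally symmetric off-axis ratio modelled as a degree-4 polynomial,
and dose deposition in water is described by a sum of three isotropic 2D
Gaussians.  MLC detail (rounded leaf end, interleaf gaps, tongue-and-groove)
is parameterised here and consumed by :mod:`planedose.aperture`.

Coordinate convention: x is the cross-plane (leaf-travel) direction, y the
in-plane (jaw-defined) direction; lateral coordinates are in cm projected to
the isocenter plane unless noted otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SourceParams",
    "OARPoly",
    "KernelParams",
    "LeafEndParams",
    "MlcTransmission",
    "MachineGeometry",
    "BeamModel",
    "ENERGY_MODES",
    "evaluate_source",
    "central_intensity",
    "half_max_radius",
    "total_extrafocal_intensity",
    "head_scatter_reduction",
    "evaluate_oar",
    "evaluate_kernel",
    "leaf_end_transmission",
    "load_builtin_model",
]

ENERGY_MODES = ("6FF", "6FFF", "10FF", "10FFF")


def _require_finite(name: str, *values) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class SourceParams:
    """Extra-focal source: bivariate Gaussian mixture on a plane below the target.

    Parameters
    ----------
    gaussians
        Sequence of ``(A, sigma_x, sigma_y)`` triples; ``A`` is the component
        intensity relative to the unit primary source, sigmas in cm on the
        source plane.
    source_plane_z
        Distance of the source plane from the target along the beam axis, cm.
        Sits at the flattening-filter base (FF) or primary-collimator base (FFF).
    """

    gaussians: tuple[tuple[float, float, float], ...]
    source_plane_z: float = 6.0

    def __post_init__(self):
        object.__setattr__(self, "gaussians",
                           tuple(tuple(float(v) for v in g) for g in self.gaussians))
        if not self.gaussians:
            raise ValueError("at least one Gaussian component required")
        for i, (a, sx, sy) in enumerate(self.gaussians):
            if not (a > 0 and sx > 0 and sy > 0):
                raise ValueError(f"component {i}: amplitude and sigmas must be > 0")
        if not self.source_plane_z > 0:
            raise ValueError("source_plane_z must be > 0 (below the target)")

    @property
    def n_components(self) -> int:
        return len(self.gaussians)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([g[0] for g in self.gaussians])

    @property
    def sigmas_x(self) -> np.ndarray:
        return np.array([g[1] for g in self.gaussians])

    @property
    def sigmas_y(self) -> np.ndarray:
        return np.array([g[2] for g in self.gaussians])


@dataclass(frozen=True)
class OARPoly:
    """Degree-4 polynomial off-axis ratio R(r) = sum a_i r^i, r in cm."""

    coeffs: tuple[float, float, float, float, float]

    def __post_init__(self):
        c = tuple(float(v) for v in self.coeffs)
        if len(c) != 5:
            raise ValueError("OAR polynomial requires exactly 5 coefficients")
        _require_finite("OAR coefficients", c)
        object.__setattr__(self, "coeffs", c)


@dataclass(frozen=True)
class KernelParams:
    """Dose deposition kernel: sum of three isotropic 2D Gaussians.

    ``components`` are ``(A, sigma)`` pairs, sigma in cm at the dose plane.
    The plane integral of the kernel equals ``sum(A)``.
    """

    components: tuple[tuple[float, float], ...]

    def __post_init__(self):
        comps = tuple((float(a), float(s)) for a, s in self.components)
        if len(comps) != 3:
            raise ValueError("kernel requires exactly 3 Gaussian components")
        for i, (a, s) in enumerate(comps):
            if not (a > 0 and s > 0):
                raise ValueError(f"kernel component {i}: weight and sigma must be > 0")
        object.__setattr__(self, "components", comps)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([c[0] for c in self.components])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([c[1] for c in self.components])

    @property
    def total_weight(self) -> float:
        return float(sum(c[0] for c in self.components))


@dataclass(frozen=True)
class LeafEndParams:
    """Rounded-leaf-end transmission curve L(d) = exp(-d^alpha / beta).

    ``d`` is the distance into the leaf measured from the tip, cm at
    isocenter projection; the curve applies over the first ``soft_range`` cm
    (default 1.0), beyond which bulk leaf transmission takes over.
    """

    alpha: float = 0.70
    beta: float = 0.24
    soft_range: float = 1.0

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be > 0")
        if not self.soft_range > 0:
            raise ValueError("soft_range must be > 0")


@dataclass(frozen=True)
class MlcTransmission:
    """Bulk / interleaf / tongue-and-groove transmission factors.

    ``tg_width_iso`` is the projected tongue-and-groove gap width at
    isocenter (Versa HD: 0.26 mm); ``leaf_width_iso`` the projected leaf
    width (Agility-like 5 mm default).
    """

    bulk: float = 0.01
    interleaf: float = 0.01
    tongue_and_groove: float = 0.01
    tg_width_iso: float = 0.026
    leaf_width_iso: float = 0.5
    interleaf_width_iso: float = 0.03

    def __post_init__(self):
        for name in ("bulk", "interleaf", "tongue_and_groove"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be a fraction in (0, 1)")
        if not (self.tg_width_iso > 0 and self.leaf_width_iso > 0
                and self.interleaf_width_iso > 0):
            raise ValueError("strip and leaf widths must be > 0")


@dataclass(frozen=True)
class MachineGeometry:
    """Collimator stack geometry, cm from the target along the beam axis.

    The Versa HD carries a single jaw pair below the MLC; the MLC defines
    the x (cross-plane) edges at ``z_mlc`` and the jaws the y (in-plane)
    edges at ``z_jaw``.  Defaults are plausible Elekta-like values and are
    declared assumptions, overridable in every entry point.
    """

    sad: float = 100.0
    z_mlc: float = 33.0
    z_jaw: float = 43.0

    def __post_init__(self):
        if not (0 < self.z_mlc < self.z_jaw < self.sad):
            raise ValueError("require 0 < z_mlc < z_jaw < sad")


@dataclass(frozen=True)
class BeamModel:
    """All fitted parameters for one energy/mode plus machine geometry."""

    energy_mode: str
    source: SourceParams
    kernel: KernelParams
    leaf_end: LeafEndParams = field(default_factory=LeafEndParams)
    mlc: MlcTransmission = field(default_factory=MlcTransmission)
    geometry: MachineGeometry = field(default_factory=MachineGeometry)
    oar: OARPoly | None = None

    def __post_init__(self):
        if self.energy_mode not in ENERGY_MODES:
            raise ValueError(f"energy_mode must be one of {ENERGY_MODES}")
        if self.is_fff and self.oar is None:
            raise ValueError("FFF modes require an off-axis-ratio polynomial")
        if not self.source.source_plane_z < self.geometry.z_mlc:
            raise ValueError("source plane must lie above the MLC")

    @property
    def is_fff(self) -> bool:
        return self.energy_mode.endswith("FFF")


# ---------------------------------------------------------------------------
# pointwise evaluation


def evaluate_source(source: SourceParams, x, y):
    """Extra-focal intensity density (cm^-2) at source-plane coordinates (x, y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _require_finite("source coordinates", x, y)
    a = source.amplitudes
    sx = source.sigmas_x
    sy = source.sigmas_y
    xx = x[..., None]
    yy = y[..., None]
    terms = a / (2.0 * np.pi * sx * sy) * np.exp(
        -xx**2 / (2.0 * sx**2) - yy**2 / (2.0 * sy**2))
    out = terms.sum(axis=-1)
    return out if out.ndim else float(out)


def central_intensity(source: SourceParams) -> float:
    """Intensity density at the center of the extra-focal source."""
    return float(evaluate_source(source, 0.0, 0.0))


def half_max_radius(source: SourceParams, rmax: float = 50.0) -> float:
    """Axis-averaged half-maximum radius of the combined source, cm.

    Finds r_x with f(r_x, 0) = f(0,0)/2 and r_y likewise along y by bracketed
    root finding and returns their mean.  For a mixture the profile along an
    axis is strictly decreasing, so the root is unique.
    """
    c = central_intensity(source)

    def _root(along_x: bool) -> float:
        def g(r):
            return (evaluate_source(source, r, 0.0) if along_x
                    else evaluate_source(source, 0.0, r)) - c / 2.0
        if g(rmax) >= 0:
            raise ValueError(f"no half-maximum crossing inside {rmax} cm "
                             "(degenerate source parameters)")
        return brentq(g, 0.0, rmax, xtol=1e-6)

    return 0.5 * (_root(True) + _root(False))


def total_extrafocal_intensity(source: SourceParams) -> float:
    """Plane-integrated extra-focal intensity relative to the primary source."""
    return float(source.amplitudes.sum())


def head_scatter_reduction(ff: SourceParams, fff: SourceParams) -> float:
    """Relative reduction, in percent, of the extra-focal intensity FF -> FFF."""
    t_ff = total_extrafocal_intensity(ff)
    t_fff = total_extrafocal_intensity(fff)
    if t_ff <= 0:
        raise ValueError("FF extra-focal intensity must be > 0")
    return 100.0 * (t_ff - t_fff) / t_ff


def evaluate_oar(oar: OARPoly, r, normalized: bool = False):
    """Off-axis ratio R(r) (or R(r)/R(0)) at radius r >= 0 cm."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("off-axis radius must be >= 0")
    out = np.polynomial.polynomial.polyval(r, np.asarray(oar.coeffs))
    if normalized:
        out = out / oar.coeffs[0]
    return out if out.ndim else float(out)


def evaluate_kernel(kernel: KernelParams, x, y):
    """Dose deposition kernel density at (x, y) cm; rotationally symmetric."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _require_finite("kernel coordinates", x, y)
    r2 = x[..., None] ** 2 + y[..., None] ** 2
    a = kernel.amplitudes
    s = kernel.sigmas
    out = (a / (2.0 * np.pi * s**2) * np.exp(-r2 / (2.0 * s**2))).sum(axis=-1)
    return out if out.ndim else float(out)


def leaf_end_transmission(p: LeafEndParams, d, bulk: float = 0.0):
    """Rounded-leaf-end transmission at depth ``d`` cm into the leaf from its tip.

    L(d) = exp(-d^alpha / beta) on [0, soft_range]; beyond the soft range the
    curve is clamped at max(L(soft_range), bulk), the hand-off point to the
    bulk leaf transmission applied by the aperture machinery.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("leaf-tip depth must be >= 0")
    dc = np.minimum(d, p.soft_range)
    out = np.maximum(np.exp(-dc**p.alpha / p.beta), bulk)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# packaged parameter sets


def _model_from_dict(doc: dict) -> BeamModel:
    src = doc["source"]
    oar = doc.get("oar")
    return BeamModel(
        energy_mode=doc["energy_mode"],
        source=SourceParams(tuple(map(tuple, src["gaussians"])),
                            source_plane_z=src["source_plane_z"]),
        oar=OARPoly(tuple(oar["coeffs"])) if oar else None,
        kernel=KernelParams(tuple(map(tuple, doc["kernel"]["components"]))),
        leaf_end=LeafEndParams(**doc["leaf_end"]),
        mlc=MlcTransmission(**doc["mlc"]),
        geometry=MachineGeometry(**doc["geometry"]),
    )


def load_builtin_model(energy_mode: str) -> BeamModel:
    """Load one of the shipped Versa HD parameter sets (6FF/6FFF/10FF/10FFF)."""
    if energy_mode not in ENERGY_MODES:
        raise ValueError(f"unknown energy mode {energy_mode!r}; "
                         f"choose from {ENERGY_MODES}")
    text = (resources.files("planedose.data") / f"{energy_mode.lower()}.json").read_text()
    return _model_from_dict(json.loads(text))
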