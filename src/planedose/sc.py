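"""In-air output factors (Sc) by back-projection and error-function integration.

The head-scatter fluence reaching a point is the integral of the extra-focal
Gaussian source over the source-plane region visible to that point through
the collimator stack.  For rectangular fields the visible region is itself a
rectangle, so the bivariate-Gaussian integral factorises into error
functions; Sc is the total (primary + scatter) fluence normalised to the
10 x 10 cm^2 reference field.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from .model import BeamModel, MachineGeometry, SourceParams

__all__ = [
    "RectField",
    "ScRecord",
    "ScDataset",
    "gaussian_rect_integral",
    "backproject_edge",
    "visible_rect",
    "compute_sc",
    "collimator_exchange",
]

_SQRT2 = np.sqrt(2.0)


@dataclass(frozen=True)
class RectField:
    """Symmetric rectangular field: openings at isocenter, cm.

    ``x_open`` is the MLC-defined (cross-plane) opening, ``y_open`` the
    jaw-defined (in-plane) opening; "A x B" means x_open=A, y_open=B.
    """

    x_open: float
    y_open: float

    def __post_init__(self):
        if not (self.x_open > 0 and self.y_open > 0):
            raise ValueError("field openings must be > 0")

    @classmethod
    def square(cls, side: float) -> "RectField":
        return cls(side, side)


@dataclass(frozen=True)
class ScRecord:
    """One in-air output-factor observation."""

    field: RectField
    sc: float
    role: str = "fit"   # fit | validate

    def __post_init__(self):
        if self.role not in ("fit", "validate"):
            raise ValueError("role must be 'fit' or 'validate'")
        if not self.sc > 0:
            raise ValueError("Sc must be > 0")


@dataclass(frozen=True)
class ScDataset:
    """Sc observations; must contain the 10 x 10 reference normalised to 1."""

    records: tuple[ScRecord, ...]

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        ref = [r for r in self.records
               if abs(r.field.x_open - 10) < 1e-9 and abs(r.field.y_open - 10) < 1e-9]
        if not ref or abs(ref[0].sc - 1.0) > 1e-6:
            raise ValueError("dataset must contain the 10 x 10 reference with Sc = 1")

    def subset(self, role: str) -> tuple[ScRecord, ...]:
        return tuple(r for r in self.records if r.role == role)


def gaussian_rect_integral(source: SourceParams, rect) -> float:
    """Integral of the bivariate-Gaussian source over a source-plane rectangle.

    ``rect`` is ``(x1, x2, y1, y2)`` in cm on the source plane with
    x1 <= x2 and y1 <= y2 (zero-width rectangles allowed).
    """
    x1, x2, y1, y2 = (float(v) for v in rect)
    if x1 > x2 or y1 > y2:
        raise ValueError(f"inverted rectangle bounds {rect!r}")
    a = source.amplitudes
    sx = source.sigmas_x
    sy = source.sigmas_y
    ex = erf(x2 / (_SQRT2 * sx)) - erf(x1 / (_SQRT2 * sx))
    ey = erf(y2 / (_SQRT2 * sy)) - erf(y1 / (_SQRT2 * sy))
    return float(np.sum(a / 4.0 * ex * ey))


def backproject_edge(e_iso: float, z_level: float, p: float, z_p: float,
                     z_source: float, sad: float = 100.0) -> float:
    """Project a collimator edge onto the source plane as seen from a point.

    Parameters
    ----------
    e_iso
        Edge lateral coordinate, cm, expressed at the isocenter plane.
    z_level
        Distance of the physical collimator level from the target, cm.
    p
        Lateral coordinate (same axis as the edge) of the viewing point, cm.
    z_p
        Distance of the viewing point from the target, cm (must lie below
        the collimator level).
    z_source
        Distance of the extra-focal source plane from the target, cm.

    Returns the lateral coordinate, on the source plane, of the ray from the
    viewing point through the physical edge.
    """
    if not (z_source < z_level < z_p):
        raise ValueError("require z_source < z_level < z_p")
    e_phys = e_iso * z_level / sad
    return p + (e_phys - p) * (z_p - z_source) / (z_p - z_level)


def visible_rect(field: RectField, geometry: MachineGeometry,
                 source_plane_z: float, point=(0.0, 0.0), z_p: float | None = None):
    """Source-plane rectangle visible through a symmetric rectangular field.

    x edges are defined by the MLC level, y edges by the jaw level; the
    viewing point defaults to the isocenter.
    """
    px, py = point
    if z_p is None:
        z_p = geometry.sad
    xs = sorted(
        backproject_edge(s * field.x_open / 2.0, geometry.z_mlc, px, z_p,
                         source_plane_z, geometry.sad) for s in (-1, 1))
    ys = sorted(
        backproject_edge(s * field.y_open / 2.0, geometry.z_jaw, py, z_p,
                         source_plane_z, geometry.sad) for s in (-1, 1))
    return (xs[0], xs[1], ys[0], ys[1])


def _scatter_term(model: BeamModel, field: RectField, point, z_p) -> float:
    rect = visible_rect(field, model.geometry, model.source.source_plane_z,
                        point, z_p)
    if rect[0] >= rect[1] or rect[2] >= rect[3]:
        warnings.warn("empty visible region: head-scatter term is zero "
                      "(primary-only Sc)", stacklevel=3)
        return 0.0
    return gaussian_rect_integral(model.source, rect)


def compute_sc(model: BeamModel, field: RectField, point=(0.0, 0.0),
               z_p: float | None = None,
               reference: RectField = RectField(10.0, 10.0)) -> float:
    """In-air output factor of ``field`` relative to the 10 x 10 reference.

    Sc = (1 + scatter(field)) / (1 + scatter(reference)) with unit primary
    source weight; Sc(reference) = 1 exactly.
    """
    num = 1.0 + _scatter_term(model, field, point, z_p)
    den = 1.0 + _scatter_term(model, reference, point, z_p)
    return num / den


def collimator_exchange(model: BeamModel, a: float, b: float) -> float:
    """Collimator exchange metric |Sc(a x b) - Sc(b x a)| / Sc(b x a), percent."""
    if a == b:
        raise ValueError("exchange metric requires a != b")
    s_ab = compute_sc(model, RectField(a, b))
    s_ba = compute_sc(model, RectField(b, a))
    return 100.0 * abs(s_ab - s_ba) / s_ba
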