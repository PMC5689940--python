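"""Energy-fluence planes for segments and MU-weighted IMRT beams.

Per calculation point p on the isocenter-depth plane the relative fluence is

    F(p) = [ T(p) + sum_rects integral of the extra-focal source ] * R(|p|)

where T is the primary transmission through the aperture, the rectangles are
the source-plane regions visible to p through the open leaf rows, and R is
the normalised off-axis ratio (identically 1 for FF modes).  The scatter
term exploits the fact that back-projected x-edges depend only on the
point's x and y-edges only on its y, so each row's contribution is an outer
product of 1D error-function factors.

Inverse-square and depth effects are absorbed into the relative
normalisation: the target plane is a single QA plane at fixed SSD/depth.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

from .aperture import BeamDelivery, Segment, transmission_map
from .grids import FluenceGrid, symmetric_axis
from .model import BeamModel, evaluate_oar

__all__ = ["segment_fluence", "beam_fluence", "scatter_map"]

_SQRT2 = np.sqrt(2.0)


def _affine_backprojection(z_level: float, z_p: float, z_source: float, sad: float):
    """Edge back-projection is affine in (edge, point): b = p*(1-c) + e*(z/sad)*c."""
    c = (z_p - z_source) / (z_p - z_level)
    return 1.0 - c, (z_level / sad) * c


def scatter_map(model: BeamModel, segment: Segment,
                x_axis: np.ndarray, y_axis: np.ndarray,
                z_p: float | None = None) -> np.ndarray:
    """Extra-focal scatter fluence on the lattice, shape (ny, nx)."""
    geo = model.geometry
    src = model.source
    if z_p is None:
        z_p = geo.sad
    px = np.asarray(x_axis, dtype=float)
    py = np.asarray(y_axis, dtype=float)
    km, cm = _affine_backprojection(geo.z_mlc, z_p, src.source_plane_z, geo.sad)
    kj, cj = _affine_backprojection(geo.z_jaw, z_p, src.source_plane_z, geo.sad)
    jy1 = py * kj + segment.jaw_y[0] * cj
    jy2 = py * kj + segment.jaw_y[1] * cj

    out = np.zeros((py.size, px.size))
    for lp in segment.leaf_pairs:
        if not lp.is_open:
            continue
        x1 = px * km + lp.x_left * cm
        x2 = px * km + lp.x_right * cm
        y1 = np.maximum(py * km + lp.y_low * cm, jy1)
        y2 = np.minimum(py * km + lp.y_high * cm, jy2)
        y2 = np.maximum(y1, y2)  # empty intersection -> zero contribution
        for a, sx, sy in model.source.gaussians:
            ex = erf(x2 / (_SQRT2 * sx)) - erf(x1 / (_SQRT2 * sx))
            ey = erf(y2 / (_SQRT2 * sy)) - erf(y1 / (_SQRT2 * sy))
            out += (a / 4.0) * np.outer(ey, ex)
    return out


def _oar_factor(model: BeamModel, x_axis, y_axis) -> np.ndarray:
    if not model.is_fff:
        return np.ones((len(y_axis), len(x_axis)))
    r = np.hypot(*np.meshgrid(x_axis, y_axis))
    return np.asarray(evaluate_oar(model.oar, r, normalized=True))


def segment_fluence(model: BeamModel, segment: Segment,
                    x_axis: np.ndarray | None = None,
                    y_axis: np.ndarray | None = None,
                    spacing: float = 0.1,
                    half_extent: float | None = None) -> FluenceGrid:
    """Relative energy fluence of one segment on the iso-depth lattice.

    Either pass explicit axes (uniform, equal spacing) or a symmetric
    ``half_extent`` in cm; the default covers the aperture bounding box
    plus a 3 cm margin.
    """
    if x_axis is None or y_axis is None:
        if half_extent is None:
            bb = segment.bounding_box()
            half_extent = max(abs(v) for v in bb) + 3.0
        x_axis = y_axis = symmetric_axis(half_extent, spacing)
    x_axis = np.asarray(x_axis, dtype=float)
    y_axis = np.asarray(y_axis, dtype=float)
    if x_axis.size == 0 or y_axis.size == 0:
        raise ValueError("empty fluence grid")
    dx = np.diff(x_axis)
    if x_axis.size > 1:
        spacing = float(dx[0])
        if spacing > 0.1 + 1e-9:
            raise ValueError("fluence grid spacing must be <= 0.1 cm")

    t = transmission_map(segment, model, x_axis, y_axis)
    s = scatter_map(model, segment, x_axis, y_axis)
    values = (t + s) * _oar_factor(model, x_axis, y_axis)
    return FluenceGrid(values, spacing=spacing, x0=float(x_axis[0]),
                       y0=float(y_axis[0]),
                       meta={"energy_mode": model.energy_mode,
                             "geometry": vars(model.geometry)})


def beam_fluence(model: BeamModel, beam: BeamDelivery,
                 x_axis: np.ndarray | None = None,
                 y_axis: np.ndarray | None = None,
                 spacing: float = 0.1,
                 half_extent: float | None = None,
                 normalization: str = "relative") -> FluenceGrid:
    """MU-weighted fluence of an IMRT beam.

    ``normalization='relative'`` weights each segment by mu/total_mu (so a
    uniform MU rescaling leaves the plane unchanged); ``'absolute'`` weights
    by raw MU.
    """
    if normalization not in ("relative", "absolute"):
        raise ValueError("normalization must be 'relative' or 'absolute'")
    if beam.total_mu <= 0:
        raise ValueError("beam has zero total MU")
    if x_axis is None or y_axis is None:
        if half_extent is None:
            half_extent = max(max(abs(v) for v in s.bounding_box())
                              for s in beam.segments) + 3.0
        x_axis = y_axis = symmetric_axis(half_extent, spacing)
    denom = beam.total_mu if normalization == "relative" else 1.0
    total = None
    for seg in beam.segments:
        if seg.mu_weight == 0:
            continue
        f = segment_fluence(model, seg, x_axis, y_axis)
        w = seg.mu_weight / denom
        total = f.values * w if total is None else total + f.values * w
        template = f
    out = template.copy_with(total, normalization=normalization)
    return FluenceGrid(out.values, spacing=template.spacing, x0=template.x0,
                       y0=template.y0, meta=out.meta)
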