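"""MLC/jaw segments: primary transmission maps and visible source rectangles.

A step-and-shoot segment is a stack of leaf pairs (tips along x, rows tiling
y) plus a single y jaw pair below the MLC.  Two quantities feed the fluence
engine: the primary transmission at each calculation point (1 in the open
aperture, rounded-tip / bulk / interleaf / tongue-and-groove factors under
the leaves, jaw factor outside the jaws), and the list of source-plane
rectangles visible to a point through the open rows, which drive the
head-scatter integrals.

Sub-pixel structure (the 0.26 mm tongue-and-groove strip, 0.3 mm interleaf
strips) is handled by exact area averaging in y within each pixel rather
than by a finer grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import BeamModel, MachineGeometry
from .sc import backproject_edge

__all__ = ["LeafPair", "Segment", "BeamDelivery", "transmission_map",
           "visible_rects", "rect_field_segment"]


@dataclass(frozen=True)
class LeafPair:
    """One leaf row: y extent and the two tip positions, cm at isocenter."""

    y_low: float
    y_high: float
    x_left: float
    x_right: float

    def __post_init__(self):
        if not self.y_low < self.y_high:
            raise ValueError("require y_low < y_high")
        if self.x_left > self.x_right:
            raise ValueError(f"leaf tips cross: x_left={self.x_left} > "
                             f"x_right={self.x_right}")

    @property
    def is_open(self) -> bool:
        return self.x_left < self.x_right


@dataclass(frozen=True)
class Segment:
    """One MLC/jaw aperture with its monitor-unit weight."""

    leaf_pairs: tuple[LeafPair, ...]
    jaw_y: tuple[float, float]
    mu_weight: float = 1.0

    def __post_init__(self):
        pairs = tuple(self.leaf_pairs)
        if not pairs:
            raise ValueError("segment requires at least one leaf pair")
        pairs = tuple(sorted(pairs, key=lambda lp: lp.y_low))
        for a, b in zip(pairs, pairs[1:]):
            if abs(a.y_high - b.y_low) > 1e-9:
                raise ValueError("leaf rows must tile a contiguous y-range")
        object.__setattr__(self, "leaf_pairs", pairs)
        j = (float(self.jaw_y[0]), float(self.jaw_y[1]))
        if not j[0] < j[1]:
            raise ValueError("require jaw_y[0] < jaw_y[1]")
        object.__setattr__(self, "jaw_y", j)
        if self.mu_weight < 0:
            raise ValueError("mu_weight must be >= 0")

    def mirrored_x(self) -> "Segment":
        return Segment(tuple(LeafPair(lp.y_low, lp.y_high, -lp.x_right, -lp.x_left)
                             for lp in self.leaf_pairs), self.jaw_y, self.mu_weight)

    def bounding_box(self):
        xs = [lp.x_left for lp in self.leaf_pairs] + [lp.x_right for lp in self.leaf_pairs]
        return (min(xs), max(xs), self.jaw_y[0], self.jaw_y[1])


@dataclass(frozen=True)
class BeamDelivery:
    """An ordered list of segments forming one IMRT beam."""

    segments: tuple[Segment, ...]
    energy_mode: str = "6FFF"

    def __post_init__(self):
        if not self.segments:
            raise ValueError("beam requires at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def total_mu(self) -> float:
        return float(sum(s.mu_weight for s in self.segments))


def rect_field_segment(x_open: float, y_open: float, mu: float = 1.0,
                       leaf_width: float = 0.5,
                       bank_half_extent: float | None = None) -> Segment:
    """Rectangular field: every leaf row open to +/- x_open/2, jaws at +/- y_open/2.

    The y edges are jaw-defined (Versa HD convention); leaves outside the jaw
    window stay open at the field tips, so the scatter-visible region matches
    the single back-projected rectangle used for Sc.  The bank must extend
    far enough that its edge never clips inside the jaw projection; the
    default guarantees that for any field up to the bank size.
    """
    if bank_half_extent is None:
        bank_half_extent = max(20.0, y_open)
    n = int(round(2 * bank_half_extent / leaf_width))
    edges = -bank_half_extent + leaf_width * np.arange(n + 1)
    pairs = [LeafPair(lo, hi, -x_open / 2, x_open / 2)
             for lo, hi in zip(edges[:-1], edges[1:])]
    return Segment(tuple(pairs), (-y_open / 2, y_open / 2), mu)


# ---------------------------------------------------------------------------
# transmission map


def _row_values(segment: Segment, model: BeamModel, x: float):
    """Per-row MLC transmission and exposure flag at cross-plane position x."""
    le, mlc = model.leaf_end, model.mlc
    vals = np.empty(len(segment.leaf_pairs))
    exposed = np.zeros(len(segment.leaf_pairs), dtype=bool)
    for i, lp in enumerate(segment.leaf_pairs):
        if lp.x_left < x < lp.x_right:
            vals[i] = 1.0
            exposed[i] = True
        else:
            d = (lp.x_left - x) if x <= lp.x_left else (x - lp.x_right)
            if d < le.soft_range:
                vals[i] = max(np.exp(-d**le.alpha / le.beta), mlc.bulk)
            else:
                vals[i] = mlc.bulk
    return vals, exposed


def transmission_map(segment: Segment, model: BeamModel,
                     x_axis: np.ndarray, y_axis: np.ndarray,
                     jaw_transmission: float | None = None,
                     area_average: bool = True) -> np.ndarray:
    """Primary-photon transmission on the iso-plane lattice, shape (ny, nx).

    Open aperture -> 1; rounded-tip decay within ``soft_range`` of a tip;
    bulk under leaf bodies; interleaf factor on boundary strips where both
    neighbouring leaves are shielded; tongue-and-groove factor on strips
    where an exposed row abuts a shielded one; jaw factor (default bulk)
    multiplies everything outside the jaw opening.  Strips narrower than a
    pixel are area-averaged in y.
    """
    x_axis = np.asarray(x_axis, dtype=float)
    y_axis = np.asarray(y_axis, dtype=float)
    h = float(np.diff(y_axis)[0]) if y_axis.size > 1 else model.mlc.tg_width_iso
    mlc = model.mlc
    if not area_average and h > mlc.tg_width_iso:
        warnings.warn("grid spacing coarser than the tongue-and-groove strip; "
                      "enable area_average to resolve sub-pixel strips",
                      stacklevel=2)
    jaw_t = mlc.bulk if jaw_transmission is None else float(jaw_transmission)
    rows_lo = np.array([lp.y_low for lp in segment.leaf_pairs])
    rows_hi = np.array([lp.y_high for lp in segment.leaf_pairs])
    y_min, y_max = rows_lo[0], rows_hi[-1]
    jaw1, jaw2 = segment.jaw_y

    out = np.empty((y_axis.size, x_axis.size))
    # pixel edges for area averaging in y
    edges_px = np.concatenate([y_axis - h / 2.0, [y_axis[-1] + h / 2.0]])

    for ix, x in enumerate(x_axis):
        vals, exposed = _row_values(segment, model, x)

        # breakpoints of the piecewise-constant y-profile
        bps = [edges_px[0], edges_px[-1], jaw1, jaw2, y_min, y_max]
        bps.extend(rows_lo)
        bps.append(rows_hi[-1])
        halfw_tg = mlc.tg_width_iso / 2.0
        halfw_il = mlc.interleaf_width_iso / 2.0
        strips = []  # (lo, hi, kind)
        for k in range(len(vals) - 1):
            yb = rows_hi[k]
            if exposed[k] != exposed[k + 1]:
                strips.append((yb - halfw_tg, yb + halfw_tg, "tg"))
            elif not exposed[k] and not exposed[k + 1]:
                strips.append((yb - halfw_il, yb + halfw_il, "il"))
        for lo, hi, _ in strips:
            bps.extend((lo, hi))
        bps = np.unique(np.clip(np.asarray(bps), edges_px[0], edges_px[-1]))

        mids = 0.5 * (bps[:-1] + bps[1:])
        # base value from the row containing each midpoint
        idx = np.clip(np.searchsorted(rows_lo, mids, side="right") - 1, 0,
                      len(vals) - 1)
        v = vals[idx].copy()
        v[(mids < y_min) | (mids > y_max)] = mlc.bulk  # beyond the leaf bank
        for lo, hi, kind in strips:
            m = (mids > lo) & (mids < hi)
            if kind == "tg":
                # factor applies to the open-side fluence (open side value 1)
                v[m] = mlc.tongue_and_groove
            else:
                v[m] = np.maximum(v[m], mlc.interleaf)
        v[(mids < jaw1) | (mids > jaw2)] *= jaw_t

        if area_average:
            # integrate the step function over each pixel
            cum = np.concatenate([[0.0], np.cumsum(v * np.diff(bps))])
            c_at = np.interp(edges_px, bps, cum)
            out[:, ix] = np.diff(c_at) / h
        else:
            idx2 = np.clip(np.searchsorted(bps, y_axis, side="right") - 1, 0,
                           len(v) - 1)
            out[:, ix] = v[idx2]
    return out


# ---------------------------------------------------------------------------
# visible source-plane rectangles


def visible_rects(segment: Segment, point, geometry: MachineGeometry,
                  source_plane_z: float, z_p: float | None = None):
    """Source-plane rectangles visible to ``point`` through the open rows.

    One rectangle per open leaf row: x-range from the back-projected tips
    (MLC level), y-range from the back-projected row edges (MLC level)
    intersected with the back-projected jaw edges (jaw level).  Empty
    intersections are dropped.
    """
    px, py = point
    if z_p is None:
        z_p = geometry.sad
    zs = source_plane_z
    jy1 = backproject_edge(segment.jaw_y[0], geometry.z_jaw, py, z_p, zs, geometry.sad)
    jy2 = backproject_edge(segment.jaw_y[1], geometry.z_jaw, py, z_p, zs, geometry.sad)
    rects = []
    for lp in segment.leaf_pairs:
        if not lp.is_open:
            continue
        x1 = backproject_edge(lp.x_left, geometry.z_mlc, px, z_p, zs, geometry.sad)
        x2 = backproject_edge(lp.x_right, geometry.z_mlc, px, z_p, zs, geometry.sad)
        y1 = max(backproject_edge(lp.y_low, geometry.z_mlc, py, z_p, zs, geometry.sad), jy1)
        y2 = min(backproject_edge(lp.y_high, geometry.z_mlc, py, z_p, zs, geometry.sad), jy2)
        if x1 < x2 and y1 < y2:
            rects.append((x1, x2, y1, y2))
    return rects
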