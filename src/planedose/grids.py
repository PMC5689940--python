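"""Planar lattices and 1D profiles at the isocenter-depth plane.

All grids are square-pixel lattices with uniform spacing (default 0.1 cm),
axes in cm at isocenter projection, and a pixel centered exactly on the
central axis.  ``values`` is indexed ``[iy, ix]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = ["Grid2D", "FluenceGrid", "DoseGrid", "Profile", "symmetric_axis"]


def symmetric_axis(half_extent: float, spacing: float) -> np.ndarray:
    """Axis of pixel centers covering [-half_extent, half_extent], 0 included."""
    if not (half_extent > 0 and spacing > 0):
        raise ValueError("half_extent and spacing must be > 0")
    n = int(np.ceil(half_extent / spacing - 1e-12))
    return np.arange(-n, n + 1) * spacing


@dataclass
class Grid2D:
    """2D lattice of values on the isocenter-depth plane."""

    values: np.ndarray
    spacing: float = 0.1
    x0: float | None = None   # coordinate of the first column center
    y0: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("grid values must be a non-empty 2D array")
        if not self.spacing > 0:
            raise ValueError("grid spacing must be > 0")
        ny, nx = self.values.shape
        # default: grid centered on the beam axis
        if self.x0 is None:
            self.x0 = -self.spacing * (nx - 1) / 2.0
        if self.y0 is None:
            self.y0 = -self.spacing * (ny - 1) / 2.0

    @property
    def x(self) -> np.ndarray:
        return self.x0 + self.spacing * np.arange(self.values.shape[1])

    @property
    def y(self) -> np.ndarray:
        return self.y0 + self.spacing * np.arange(self.values.shape[0])

    def copy_with(self, values: np.ndarray, **meta) -> "Grid2D":
        out = replace(self, values=np.asarray(values, dtype=float))
        out.meta = {**self.meta, **meta}
        return out


class FluenceGrid(Grid2D):
    """Relative energy-fluence plane (unit primary fluence = 1)."""


class DoseGrid(Grid2D):
    """Relative (or scalar-calibrated) planar dose; NaN marks unsampled points."""


@dataclass
class Profile:
    """1D dose profile along x or y at a fixed orthogonal coordinate."""

    positions: np.ndarray
    values: np.ndarray
    axis: Literal["x", "y"] = "x"
    fixed: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape or self.positions.ndim != 1:
            raise ValueError("positions and values must be matching 1D arrays")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("profile positions must be strictly increasing")

    @property
    def spacing(self) -> float | None:
        d = np.diff(self.positions)
        return float(d[0]) if np.allclose(d, d[0], rtol=1e-9, atol=1e-12) else None

    def value_at(self, pos) -> np.ndarray:
        return np.interp(pos, self.positions, self.values)
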