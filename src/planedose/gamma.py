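"""2D gamma-index comparison of measured and calculated dose planes.

For every evaluated reference point r the gamma index is

    gamma(r) = min over r' in a search disk of
               sqrt( (D_eval(r') - D_ref(r))^2 / delta(r)^2 + |r' - r|^2 / DTA^2 )

with delta the local (dose_pct * D_ref(r)/100) or global
(dose_pct * max D_ref / 100) dose criterion.  The evaluated plane is
bilinearly interpolated on a fine sub-grid (exhaustive scan, default 0.1 mm
step over a disk of radius 3*DTA), reference points below the low-dose
threshold are excluded, and NaN reference pixels (unsampled detector
positions) are ignored.  By convention the reference is the measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .grids import DoseGrid

__all__ = ["GammaCriteria", "GammaResult", "gamma_map"]


@dataclass(frozen=True)
class GammaCriteria:
    """Gamma criteria: dose difference (percent), DTA (cm), threshold (percent
    of the reference maximum), local or global dose normalisation."""

    dose_pct: float = 2.0
    dta: float = 0.2
    threshold_pct: float = 10.0
    mode: str = "local"
    search_radius_factor: float = 3.0
    interp_step: float = 0.01

    def __post_init__(self):
        if not (self.dose_pct > 0 and self.dta > 0 and self.threshold_pct > 0
                and self.search_radius_factor > 0 and self.interp_step > 0):
            raise ValueError("all gamma criteria must be positive")
        if self.mode not in ("local", "global"):
            raise ValueError("mode must be 'local' or 'global'")
        if self.interp_step > self.dta / 5.0:
            raise ValueError("interp_step must be <= dta/5 for a faithful "
                             "sub-grid search")


@dataclass
class GammaResult:
    """Per-point gamma map (NaN where not evaluated) and its summary."""

    gamma: np.ndarray
    passing_rate: float          # percent of evaluated points with gamma <= 1
    n_evaluated: int
    n_below_threshold: int
    n_zero_reference: int
    criteria: GammaCriteria


def _search_offsets(c: GammaCriteria) -> np.ndarray:
    rad = c.search_radius_factor * c.dta
    n = int(np.floor(rad / c.interp_step))
    ax = np.arange(-n, n + 1) * c.interp_step
    dx, dy = np.meshgrid(ax, ax)
    keep = dx**2 + dy**2 <= rad**2 + 1e-15
    return np.column_stack([dx[keep], dy[keep]])


def gamma_map(reference: DoseGrid, evaluated: DoseGrid,
              criteria: GammaCriteria = GammaCriteria(),
              offset_chunk: int = 2048) -> GammaResult:
    """Gamma comparison of an evaluated plane against a reference plane."""
    c = criteria
    if (reference.x[-1] < evaluated.x[0] or evaluated.x[-1] < reference.x[0] or
            reference.y[-1] < evaluated.y[0] or evaluated.y[-1] < reference.y[0]):
        raise ValueError("reference and evaluated planes do not overlap")

    interp = RegularGridInterpolator(
        (evaluated.y, evaluated.x), evaluated.values,
        method="linear", bounds_error=False, fill_value=np.nan)

    ref = reference.values
    finite = np.isfinite(ref)
    ref_max = np.max(ref[finite])
    thresh = c.threshold_pct / 100.0 * ref_max
    eval_mask = finite & (ref >= thresh)
    n_below = int(np.count_nonzero(finite) - np.count_nonzero(eval_mask))
    n_zero = 0
    if c.mode == "local":
        zero = eval_mask & (ref <= 0)
        n_zero = int(np.count_nonzero(zero))
        eval_mask &= ~zero

    yy, xx = np.meshgrid(reference.y, reference.x, indexing="ij")
    pts = np.column_stack([yy[eval_mask], xx[eval_mask]])
    d_ref = ref[eval_mask]
    if c.mode == "local":
        delta = c.dose_pct / 100.0 * d_ref
    else:
        delta = np.full(d_ref.shape, c.dose_pct / 100.0 * ref_max)

    offsets = _search_offsets(c)
    best = np.full(d_ref.shape, np.inf)
    for k in range(0, offsets.shape[0], offset_chunk):
        off = offsets[k:k + offset_chunk]
        # query points: (n_pts, n_off, 2) in (y, x) order
        q = pts[:, None, :] + off[None, :, ::-1]
        vals = interp(q.reshape(-1, 2)).reshape(len(pts), len(off))
        dd2 = (vals - d_ref[:, None]) ** 2 / delta[:, None] ** 2
        rr2 = (off[:, 0] ** 2 + off[:, 1] ** 2)[None, :] / c.dta**2
        g2 = dd2 + rr2
        g2 = np.where(np.isnan(g2), np.inf, g2)
        best = np.minimum(best, g2.min(axis=1))

    gamma = np.sqrt(best)
    gmap = np.full(ref.shape, np.nan)
    gmap[eval_mask] = gamma
    n_eval = int(gamma.size)
    if n_eval == 0:
        raise ValueError("no reference points above the dose threshold")
    rate = 100.0 * np.count_nonzero(gamma <= 1.0 + 1e-12) / n_eval
    return GammaResult(gmap, passing_rate=rate, n_evaluated=n_eval,
                       n_below_threshold=n_below, n_zero_reference=n_zero,
                       criteria=c)
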