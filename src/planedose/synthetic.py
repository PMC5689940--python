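"""Synthetic commissioning and QA inputs: Sc tables, scanned profiles,
step-and-shoot plans and pseudo-measured dose planes.

Everything the pipeline consumes can be generated here from a beam model,
deterministically per seed.  The defaults emulate the commissioning design
of the source machine: square fields 3-35 cm, rectangle families with one
jaw fixed at 10 cm (fit) and 4 cm (held-out validation), profiles scanned
at 10 cm depth / 90 cm SSD with a CC13-like chamber, and a MapCHECK-like
staggered diode array on 1 cm pitch for plan measurements.  Measurement
noise is multiplicative Gaussian (repeatability-like): 0.1% on Sc, 0.5% on
profiles and planes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aperture import BeamDelivery, LeafPair, Segment, rect_field_segment
from .commissioning import ProfileEntry, ProfileSet
from .dose import DetectorResponse, apply_detector_response, convolve_dose, extract_profile
from .fluence import beam_fluence, segment_fluence
from .grids import DoseGrid, Profile, symmetric_axis
from .model import BeamModel
from .sc import RectField, ScDataset, ScRecord, compute_sc

__all__ = ["FixtureSpec", "default_sc_fields", "make_sc_dataset",
           "make_profiles", "make_imrt_plan", "make_measurement"]


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions for a synthetic QA fixture."""

    energy_mode: str = "6FFF"
    noise_sc: float = 0.001
    noise_profile: float = 0.005
    detector_spacing: float = 1.0     # cm, staggered MapCHECK-like lattice
    n_segments: int = 10
    min_segment_area: float = 4.0     # cm^2
    total_mu: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sc < 0 or self.noise_profile < 0:
            raise ValueError("noise levels must be >= 0")
        if not (1 <= self.n_segments <= 70):
            raise ValueError("n_segments must be in [1, 70]")
        if self.min_segment_area <= 0:
            raise ValueError("min_segment_area must be > 0")


def default_sc_fields():
    """The commissioning Sc field menu: squares plus both rectangle families.

    Returns ``(fit_fields, validation_fields)``; the validation family keeps
    one side fixed at 4 cm and is held out of the fit by construction.
    """
    squares = [RectField.square(s) for s in (3, 4, 5, 6, 8, 10, 15, 20, 25, 30, 35)]
    var = (4, 6, 8, 15, 20, 25, 30)
    rect10 = [RectField(v, 10.0) for v in var] + [RectField(10.0, v) for v in var]
    # 10 is omitted from the validation family: 4 x 10 / 10 x 4 already sit
    # in the fit family, and the validation block must stay held out
    var_v = (6, 8, 15, 20, 25, 30)
    rect4 = [RectField(v, 4.0) for v in var_v] + [RectField(4.0, v) for v in var_v]
    return squares + rect10, rect4


def make_sc_dataset(model: BeamModel, fields=None, noise: float = 0.001,
                    seed: int = 0) -> ScDataset:
    """Sc table computed from the model with multiplicative Gaussian noise,
    renormalised so the 10 x 10 reference reads exactly 1."""
    if fields is None:
        fit_fields, val_fields = default_sc_fields()
    else:
        fit_fields, val_fields = fields
    rng = np.random.default_rng(seed)

    def noisy(f):
        return compute_sc(model, f) * (1.0 + noise * rng.standard_normal())

    ref = noisy(RectField(10.0, 10.0))
    records = []
    for f in fit_fields:
        if abs(f.x_open - 10) < 1e-9 and abs(f.y_open - 10) < 1e-9:
            records.append(ScRecord(f, 1.0, "fit"))
        else:
            records.append(ScRecord(f, noisy(f) / ref, "fit"))
    for f in val_fields:
        records.append(ScRecord(f, noisy(f) / ref, "validate"))
    return ScDataset(tuple(records))


def make_profiles(model: BeamModel, fields, axis: str,
                  det: DetectorResponse = DetectorResponse(),
                  noise: float = 0.005, seed: int = 0,
                  spacing: float = 0.1, margin: float = 5.0) -> ProfileSet:
    """Pseudo-scanned cross-beam profiles through the full engine.

    Each field's planar dose is computed with the complete aperture/fluence/
    convolution pipeline, the requested axis profile is extracted, convolved
    with the detector response (the volume averaging a real chamber scan
    shows), given multiplicative noise, and renormalised to the central axis.
    """
    rng = np.random.default_rng(seed)
    entries = []
    for f in fields:
        seg = rect_field_segment(f.x_open, f.y_open,
                                 leaf_width=model.mlc.leaf_width_iso)
        half = max(f.x_open, f.y_open) / 2.0 + margin
        ax = symmetric_axis(half, spacing)
        flu = segment_fluence(model, seg, ax, ax)
        dz = convolve_dose(flu, model.kernel)
        prof = extract_profile(dz, axis=axis, fixed=0.0, normalize=True)
        prof = apply_detector_response(prof, det)
        vals = prof.values * (1.0 + noise * rng.standard_normal(prof.values.size))
        vals = vals / np.interp(0.0, prof.positions, vals)
        entries.append(ProfileEntry(f, axis, Profile(prof.positions, vals, axis)))
    return ProfileSet(tuple(entries))


def make_imrt_plan(spec: FixtureSpec, leaf_width: float = 0.5,
                   max_draws: int = 1000) -> BeamDelivery:
    """Random step-and-shoot beam honouring the segment-count and
    minimum-segment-area constraints of a head-and-neck-like plan."""
    rng = np.random.default_rng(spec.seed)
    segments = []
    mu = rng.uniform(0.5, 1.5, spec.n_segments)
    mu *= spec.total_mu / mu.sum()
    bank_half = 10.0
    n_rows = int(round(2 * bank_half / leaf_width))
    edges = -bank_half + leaf_width * np.arange(n_rows + 1)
    for k in range(spec.n_segments):
        for attempt in range(max_draws):
            c_y = rng.uniform(-3.0, 3.0)
            h = rng.uniform(2.0, 8.0)
            lo, hi = c_y - h / 2.0, c_y + h / 2.0
            c_x = rng.uniform(-3.0, 3.0)
            pairs, area = [], 0.0
            for rl, rh in zip(edges[:-1], edges[1:]):
                mid = 0.5 * (rl + rh)
                if lo <= mid <= hi:
                    w = rng.uniform(1.0, 8.0)
                    off = c_x + rng.uniform(-1.5, 1.5)
                    pairs.append(LeafPair(rl, rh, off - w / 2.0, off + w / 2.0))
                    area += w * (rh - rl)
                else:
                    pairs.append(LeafPair(rl, rh, 0.0, 0.0))
            if area >= spec.min_segment_area:
                open_lo = min(p.y_low for p in pairs if p.is_open)
                open_hi = max(p.y_high for p in pairs if p.is_open)
                segments.append(Segment(tuple(pairs), (open_lo, open_hi), mu[k]))
                break
        else:
            raise RuntimeError(f"segment area constraint unsatisfiable after "
                               f"{max_draws} draws (seed {spec.seed})")
    return BeamDelivery(tuple(segments), energy_mode=spec.energy_mode)


def _detector_mask(x_axis: np.ndarray, y_axis: np.ndarray,
                   pitch: float) -> np.ndarray:
    """Staggered (MapCHECK-like) diode lattice on a half-pitch grid."""
    half = pitch / 2.0
    ix = np.round(x_axis / half).astype(int)
    iy = np.round(y_axis / half).astype(int)
    on_x = np.abs(x_axis - ix * half) < 1e-9
    on_y = np.abs(y_axis - iy * half) < 1e-9
    even = (ix[None, :] + iy[:, None]) % 2 == 0
    return even & on_x[None, :] & on_y[:, None]


def make_measurement(model: BeamModel, beam: BeamDelivery,
                     noise: float = 0.005, seed: int = 0,
                     detector_spacing: float = 1.0,
                     half_extent: float = 12.0,
                     spacing: float = 0.1) -> tuple[DoseGrid, DoseGrid]:
    """Pseudo-measurement of a beam on a staggered diode array.

    Computes the beam's planar dose at ``spacing`` resolution, samples it at
    the detector positions (NaN elsewhere), applies multiplicative Gaussian
    noise, and returns ``(measured, calculated)`` planes on the same lattice
    so the pair can go straight into a gamma comparison.
    """
    ax = symmetric_axis(half_extent, spacing)
    flu = beam_fluence(model, beam, ax, ax)
    dz = convolve_dose(flu, model.kernel)
    mask = _detector_mask(dz.x, dz.y, detector_spacing)
    rng = np.random.default_rng(seed)
    measured = np.full(dz.values.shape, np.nan)
    measured[mask] = dz.values[mask] * (1.0 + noise * rng.standard_normal(
        int(np.count_nonzero(mask))))
    meas_grid = DoseGrid(measured, spacing=dz.spacing, x0=dz.x0, y0=dz.y0,
                         meta={**dz.meta, "kind": "synthetic-measurement",
                               "seed": seed, "noise": noise})
    return meas_grid, dz
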