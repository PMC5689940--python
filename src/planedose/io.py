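"""Readers and writers for the package's file dialects.

Formats (all plain text, coordinates in cm at isocenter projection):

* beam model        — JSON, one model per energy mode (same schema as the
                      packaged parameter sets).
* Sc dataset        — CSV with columns field_x_cm, field_y_cm, sc, role.
* profile set       — CSV with columns field_x_cm, field_y_cm, axis,
                      depth_cm, ssd_cm, position_cm, value.
* beam delivery     — JSON dialect: {energy_mode, segments: [{mu,
                      jaw_y: [y1, y2], leaves: [{y: [lo, hi], x: [l, r]}]}]}.
* dose/fluence plane— ASCII grid: '#'-prefixed header (origin_cm,
                      spacing_cm, normalization, energy_mode) then
                      whitespace-delimited rows; 'nan' marks unsampled
                      points; CRLF tolerated.

All writers round-trip through their readers with 1e-12 numeric fidelity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aperture import BeamDelivery, LeafPair, Segment
from .commissioning import ProfileEntry, ProfileSet
from .grids import DoseGrid, Grid2D, Profile
from .model import BeamModel, _model_from_dict
from .sc import RectField, ScDataset, ScRecord

__all__ = ["read_beam_model", "write_beam_model", "read_sc_csv", "write_sc_csv",
           "read_profiles_csv", "write_profiles_csv", "read_beam_json",
           "write_beam_json", "read_plane", "write_plane", "RunConfig"]

_PLANE_MAGIC = "planedose-plane"


class FormatError(ValueError):
    """A file does not conform to its documented schema."""


# ---------------------------------------------------------------------------
# beam model JSON


def _model_to_dict(model: BeamModel) -> dict:
    return {
        "format": "planedose-beam-model",
        "version": 1,
        "energy_mode": model.energy_mode,
        "source": {"gaussians": [list(g) for g in model.source.gaussians],
                   "source_plane_z": model.source.source_plane_z},
        "oar": {"coeffs": list(model.oar.coeffs)} if model.oar else None,
        "kernel": {"components": [list(c) for c in model.kernel.components]},
        "leaf_end": {"alpha": model.leaf_end.alpha, "beta": model.leaf_end.beta,
                     "soft_range": model.leaf_end.soft_range},
        "mlc": {k: getattr(model.mlc, k) for k in
                ("bulk", "interleaf", "tongue_and_groove", "tg_width_iso",
                 "leaf_width_iso", "interleaf_width_iso")},
        "geometry": {"sad": model.geometry.sad, "z_mlc": model.geometry.z_mlc,
                     "z_jaw": model.geometry.z_jaw},
    }


def write_beam_model(model: BeamModel, path) -> None:
    Path(path).write_text(json.dumps(_model_to_dict(model), indent=1) + "\n")


def read_beam_model(path) -> BeamModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "planedose-beam-model":
        raise FormatError(f"{path}: not a planedose beam-model file")
    if doc.get("version") != 1:
        raise FormatError(f"{path}: unsupported beam-model version "
                          f"{doc.get('version')!r} (expected 1)")
    try:
        return _model_from_dict(doc)
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"{path}: invalid beam model: {exc}") from exc


# ---------------------------------------------------------------------------
# Sc dataset CSV


def write_sc_csv(sc: ScDataset, path) -> None:
    df = pd.DataFrame(
        [{"field_x_cm": r.field.x_open, "field_y_cm": r.field.y_open,
          "sc": r.sc, "role": r.role} for r in sc.records])
    df.to_csv(path, index=False, float_format="%.17g")


def read_sc_csv(path) -> ScDataset:
    df = pd.read_csv(path)
    required = {"field_x_cm", "field_y_cm", "sc", "role"}
    if missing := required - set(df.columns):
        raise FormatError(f"{path}: missing Sc columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(ScRecord(RectField(row.field_x_cm, row.field_y_cm),
                                    float(row.sc), str(row.role)))
        except ValueError as exc:
            raise FormatError(f"{path}: row {i + 2}: {exc}") from exc
    try:
        return ScDataset(tuple(records))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# profile set CSV


def write_profiles_csv(ps: ProfileSet, path) -> None:
    rows = []
    for e in ps.entries:
        for p, v in zip(e.profile.positions, e.profile.values):
            rows.append({"field_x_cm": e.field.x_open, "field_y_cm": e.field.y_open,
                         "axis": e.axis, "depth_cm": e.depth_cm,
                         "ssd_cm": e.ssd_cm, "position_cm": p, "value": v})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_profiles_csv(path) -> ProfileSet:
    df = pd.read_csv(path)
    required = {"field_x_cm", "field_y_cm", "axis", "depth_cm", "ssd_cm",
                "position_cm", "value"}
    if missing := required - set(df.columns):
        raise FormatError(f"{path}: missing profile columns {sorted(missing)}")
    entries = []
    keys = ["field_x_cm", "field_y_cm", "axis", "depth_cm", "ssd_cm"]
    for (fx, fy, axis, depth, ssd), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("position_cm")
        try:
            entries.append(ProfileEntry(
                RectField(fx, fy), str(axis),
                Profile(grp.position_cm.to_numpy(), grp.value.to_numpy(),
                        str(axis)),
                depth_cm=float(depth), ssd_cm=float(ssd)))
        except ValueError as exc:
            raise FormatError(f"{path}: field {fx}x{fy}/{axis}: {exc}") from exc
    return ProfileSet(tuple(entries))


# ---------------------------------------------------------------------------
# beam delivery JSON


def write_beam_json(beam: BeamDelivery, path) -> None:
    doc = {"format": "planedose-beam", "version": 1,
           "energy_mode": beam.energy_mode,
           "segments": [
               {"mu": s.mu_weight, "jaw_y": list(s.jaw_y),
                "leaves": [{"y": [lp.y_low, lp.y_high],
                            "x": [lp.x_left, lp.x_right]}
                           for lp in s.leaf_pairs]}
               for s in beam.segments]}
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_beam_json(path) -> BeamDelivery:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "planedose-beam":
        raise FormatError(f"{path}: not a planedose beam file")
    segments = []
    for si, s in enumerate(doc.get("segments", [])):
        pairs = []
        for li, leaf in enumerate(s["leaves"]):
            (ylo, yhi), (xl, xr) = leaf["y"], leaf["x"]
            try:
                pairs.append(LeafPair(ylo, yhi, xl, xr))
            except ValueError as exc:
                raise FormatError(f"{path}: segment {si}, leaf row {li}: "
                                  f"{exc}") from exc
        try:
            segments.append(Segment(tuple(pairs), tuple(s["jaw_y"]), s["mu"]))
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: segment {si}: {exc}") from exc
    if not segments:
        raise FormatError(f"{path}: beam contains no segments")
    return BeamDelivery(tuple(segments), energy_mode=doc.get("energy_mode", "6FFF"))


# ---------------------------------------------------------------------------
# dose / fluence plane ASCII


def write_plane(grid: Grid2D, path) -> None:
    meta = grid.meta or {}
    lines = [f"# {_PLANE_MAGIC} v1",
             f"# origin_cm: {grid.x0:.17g} {grid.y0:.17g}",
             f"# spacing_cm: {grid.spacing:.17g}",
             f"# normalization: {meta.get('normalization', 'relative')}",
             f"# energy_mode: {meta.get('energy_mode', 'unknown')}"]
    body = "\n".join(" ".join(f"{v:.17g}" for v in row) for row in grid.values)
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def read_plane(path, cls=DoseGrid) -> Grid2D:
    text = Path(path).read_text().replace("\r\n", "\n").replace("\r", "\n")
    lines = [ln for ln in text.split("\n") if ln.strip()]
    if not lines or _PLANE_MAGIC not in lines[0]:
        raise FormatError(f"{path}: not a planedose plane file")
    header, rows = {}, []
    for ln in lines[1:]:
        if ln.startswith("#"):
            key, _, val = ln[1:].partition(":")
            header[key.strip()] = val.strip()
        else:
            rows.append([float(v) for v in ln.split()])
    try:
        x0, y0 = (float(v) for v in header["origin_cm"].split())
        spacing = float(header["spacing_cm"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: bad or missing plane header: {exc}") from exc
    values = np.array(rows, dtype=float)
    if values.ndim != 2:
        raise FormatError(f"{path}: ragged data rows")
    return cls(values, spacing=spacing, x0=x0, y0=y0,
               meta={"normalization": header.get("normalization", "relative"),
                     "energy_mode": header.get("energy_mode", "unknown")})


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated top-level configuration for CLI runs."""

    model: str
    grid_spacing_cm: float = 0.1
    grid_half_extent_cm: float = 12.0
    gamma: dict = field(default_factory=dict)
    output: str | None = None
    log_level: str = "info"
    seed: int = 0

    _KEYS = {"model", "grid_spacing_cm", "grid_half_extent_cm", "gamma",
             "output", "log_level", "seed"}

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        if unknown := set(doc) - cls._KEYS:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        if "model" not in doc:
            raise FormatError(f"{path}: config requires a 'model' path")
        cfg = cls(**doc)
        if cfg.grid_spacing_cm <= 0 or cfg.grid_half_extent_cm <= 0:
            raise FormatError(f"{path}: grid sizes must be positive")
        return cfg
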