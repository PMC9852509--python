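"""Landmark data model, file I/O, calibration, and radiographic alignment measures.

A limb arrives as a JSON landmark file digitized from a standing
anteroposterior whole-leg radiograph (schema below).  Loading performs three
normalisations so that every downstream computation sees one canonical frame:

1. *Calibration*: pixel coordinates are scaled to millimetres using the
   radiograph's calibration marker (two digitized marker points a known
   distance apart).
2. *Side*: left limbs are mirrored (x -> -x) so that +x is always medial;
   one code path then serves both sides.
3. *Origin*: coordinates are translated so the femoral head center sits at
   (0, 0); +y increases distally.

Landmark file schema (``schema_version: 1``, all coordinates in pixels,
x increasing towards the viewer's right, y increasing distally)::

    {
      "schema_version": 1,
      "patient_id": "P01", "side": "right", "timepoint": "pre",
      "calibration": {"marker_a": [x, y], "marker_b": [x, y],
                      "known_distance_mm": 50.0},
      "landmarks": {"femoral_head_center": [x, y],
                    "plateau_medial_edge": [x, y],
                    "plateau_lateral_edge": [x, y],
                    "ankle_center": [x, y]},
      "polylines": {"medial_cortex": [[x, y], ...],
                    "lateral_cortex": [[x, y], ...]}
    }

The alignment measures implemented here are the standard frontal-plane
deformity measures:

* **WBL ratio** -- where the weight-bearing line (femoral head center to
  ankle center) crosses the tibial plateau, as a percentage of plateau width
  measured from the medial edge.  The crossing is taken on the *infinite*
  plateau line, so severe varus yields negative percentages rather than an
  error.
* **mFTA** -- mechanical femorotibial angle, the deviation from 180 deg of the
  angle between the femoral mechanical axis (F to knee center K) and the
  tibial mechanical axis (K to ankle center), signed positive for varus.
* **mMPTA** -- mechanical medial proximal tibial angle, the medial angle
  between the plateau joint line and the tibial mechanical axis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, ValidationError, model_validator

from .geometry import FrontalPoint, Polyline, angle_at_vertex

Side = Literal["left", "right"]
Timepoint = Literal["pre", "post"]

_Pt = tuple[float, float]


class SchemaError(ValueError):
    """The landmark file does not conform to the documented schema."""


class CalibrationModel(BaseModel):
    marker_a: _Pt
    marker_b: _Pt
    known_distance_mm: float = Field(gt=0)

    @model_validator(mode="after")
    def _markers_distinct(self) -> "CalibrationModel":
        if self.marker_a == self.marker_b:
            raise ValueError("calibration markers marker_a and marker_b coincide")
        return self

    @property
    def mm_per_px(self) -> float:
        d = math.dist(self.marker_a, self.marker_b)
        return self.known_distance_mm / d


class LandmarksModel(BaseModel):
    femoral_head_center: _Pt
    plateau_medial_edge: _Pt
    plateau_lateral_edge: _Pt
    ankle_center: _Pt


class PolylinesModel(BaseModel):
    medial_cortex: list[_Pt] = Field(min_length=2)
    lateral_cortex: list[_Pt] = Field(min_length=2)


class LandmarkFile(BaseModel):
    """Pydantic model of the on-disk landmark file (pixel coordinates)."""

    schema_version: Literal[1]
    patient_id: str
    side: Side
    timepoint: Timepoint
    calibration: CalibrationModel
    landmarks: LandmarksModel
    polylines: PolylinesModel


@dataclass(frozen=True)
class LimbLandmarks:
    """One limb's digitized landmarks in the canonical frame (mm, +x medial)."""

    femoral_head_center: FrontalPoint
    plateau_medial_edge: FrontalPoint
    plateau_lateral_edge: FrontalPoint
    ankle_center: FrontalPoint
    medial_cortex: Polyline
    lateral_cortex: Polyline
    side: Side = "right"
    patient_id: str = ""
    timepoint: Timepoint = "pre"

    def __post_init__(self) -> None:
        m, l = self.plateau_medial_edge, self.plateau_lateral_edge
        if not m.x > l.x:
            raise ValueError(
                "plateau_medial_edge must be medial (+x) of plateau_lateral_edge "
                f"in the canonical frame ({m.x} <= {l.x})"
            )
        f, a = self.femoral_head_center, self.ankle_center
        if not (a.y > m.y > f.y):
            raise ValueError(
                "landmarks must be ordered proximal to distal: "
                "femoral_head_center.y < plateau_medial_edge.y < ankle_center.y"
            )
        plateau_y = max(m.y, l.y)
        for name, pl in (("medial_cortex", self.medial_cortex),
                         ("lateral_cortex", self.lateral_cortex)):
            if pl.y_min > plateau_y + 1e-9:
                raise ValueError(f"{name} must start at or proximal to plateau level")
            if pl.y_max < plateau_y + 60.0:
                raise ValueError(f"{name} must extend at least 60 mm distal to the plateau")

    @property
    def knee_center(self) -> FrontalPoint:
        """Knee center K: midpoint of the two plateau edges."""
        return self.plateau_medial_edge.midpoint_with(self.plateau_lateral_edge)

    @property
    def plateau_width(self) -> float:
        return self.plateau_medial_edge.distance_to(self.plateau_lateral_edge)

    def scaled(self, k: float) -> "LimbLandmarks":
        """Uniformly scale every coordinate by ``k`` (> 0)."""
        if k <= 0:
            raise ValueError("scale factor must be positive")
        s = lambda p: FrontalPoint(k * p.x, k * p.y)  # noqa: E731
        return replace(
            self,
            femoral_head_center=s(self.femoral_head_center),
            plateau_medial_edge=s(self.plateau_medial_edge),
            plateau_lateral_edge=s(self.plateau_lateral_edge),
            ankle_center=s(self.ankle_center),
            medial_cortex=Polyline([s(p) for p in self.medial_cortex.points]),
            lateral_cortex=Polyline([s(p) for p in self.lateral_cortex.points]),
        )


@dataclass(frozen=True)
class AlignmentMeasures:
    """WBL ratio (%), mFTA (signed degrees, varus > 0) and mMPTA (degrees)."""

    wbl_ratio: float
    mfta: float
    mpta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.mpta < 180.0):
            raise ValueError(f"mpta must be in (0, 180) degrees, got {self.mpta}")

    @property
    def mfta_label(self) -> str:
        if self.mfta > 0:
            return f"varus {self.mfta:.1f}°"
        if self.mfta < 0:
            return f"valgus {-self.mfta:.1f}°"
        return "neutral 0.0°"


def load_landmarks(path: str | Path) -> LimbLandmarks:
    """Load, validate, calibrate and canonicalise a landmark file."""
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed landmark file {path}: {exc}") from exc
    try:
        model = LandmarkFile.model_validate(raw)
    except ValidationError as exc:
        missing = ", ".join(".".join(str(p) for p in e["loc"]) for e in exc.errors())
        raise SchemaError(f"invalid landmark file {path}: {missing}") from exc

    scale = model.calibration.mm_per_px
    sx = -scale if model.side == "left" else scale
    f_px = model.landmarks.femoral_head_center

    def canon(p: _Pt) -> FrontalPoint:
        return FrontalPoint(sx * (p[0] - f_px[0]), scale * (p[1] - f_px[1]))

    lm = model.landmarks
    try:
        return LimbLandmarks(
            femoral_head_center=canon(lm.femoral_head_center),
            plateau_medial_edge=canon(lm.plateau_medial_edge),
            plateau_lateral_edge=canon(lm.plateau_lateral_edge),
            ankle_center=canon(lm.ankle_center),
            medial_cortex=Polyline([canon(p) for p in model.polylines.medial_cortex]),
            lateral_cortex=Polyline([canon(p) for p in model.polylines.lateral_cortex]),
            side=model.side,
            patient_id=model.patient_id,
            timepoint=model.timepoint,
        )
    except ValueError as exc:
        raise SchemaError(f"invalid landmark file {path}: {exc}") from exc


def save_landmarks(limb: LimbLandmarks, path: str | Path) -> None:
    """Write a canonical-frame limb back to the landmark file schema.

    The file uses an identity calibration (100 px == 100 mm) and the limb's
    own side flag; loading it back reproduces the limb exactly (left limbs
    are written pre-mirrored so the load-time mirror restores them).
    """
    sx = -1.0 if limb.side == "left" else 1.0
    f = limb.femoral_head_center

    def raw(p: FrontalPoint) -> list[float]:
        return [sx * p.x + f.x, p.y + f.y]

    doc = {
        "schema_version": 1,
        "patient_id": limb.patient_id,
        "side": limb.side,
        "timepoint": limb.timepoint,
        "calibration": {"marker_a": [0.0, 0.0], "marker_b": [0.0, 100.0],
                        "known_distance_mm": 100.0},
        "landmarks": {
            "femoral_head_center": raw(limb.femoral_head_center),
            "plateau_medial_edge": raw(limb.plateau_medial_edge),
            "plateau_lateral_edge": raw(limb.plateau_lateral_edge),
            "ankle_center": raw(limb.ankle_center),
        },
        "polylines": {
            "medial_cortex": [raw(p) for p in limb.medial_cortex.points],
            "lateral_cortex": [raw(p) for p in limb.lateral_cortex.points],
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def wbl_ratio(
    limb: LimbLandmarks, line_through: tuple[FrontalPoint, FrontalPoint]
) -> float:
    """Percentage of plateau width at which a line crosses the plateau line.

    0 = medial edge, 100 = lateral edge; the crossing is taken on the
    infinite line through the plateau edges, so values outside [0, 100] are
    returned (not clipped) for crossings beyond the edges.
    """
    m, l = limb.plateau_medial_edge, limb.plateau_lateral_edge
    a, b = line_through
    # solve a + t(b-a) = m + u(l-m)
    dx, dy = b.x - a.x, b.y - a.y
    px, py = l.x - m.x, l.y - m.y
    det = dx * (-py) - dy * (-px)
    if abs(det) < 1e-12 * max(1.0, abs(dx) + abs(dy)):
        raise ValueError("line is parallel to the plateau line; WBL ratio undefined")
    u = (dx * (a.y - m.y) - dy * (a.x - m.x)) / (dx * py - dy * px)
    return 100.0 * u


def measure_mfta(limb: LimbLandmarks) -> float:
    """Mechanical femorotibial angle, signed degrees (varus positive)."""
    f, k, c1 = limb.femoral_head_center, limb.knee_center, limb.ankle_center
    if f == k or k == c1 or f == c1:
        raise ValueError("degenerate limb: F, K, C1 must be pairwise distinct")
    magnitude = 180.0 - angle_at_vertex(k, f, c1)
    # varus when the ankle lies medial (+x side) of the femoral mechanical axis
    ux, uy = k.x - f.x, k.y - f.y
    norm = math.hypot(ux, uy)
    medial_offset = ((c1.x - f.x) * uy - (c1.y - f.y) * ux) / norm
    # (uy, -ux)/norm is the medial-pointing normal of F->K in the canonical frame
    return math.copysign(magnitude, medial_offset) if medial_offset != 0 else 0.0


def measure_mpta(limb: LimbLandmarks) -> float:
    """Medial proximal tibial angle: medial angle between plateau and tibial axis."""
    k, m, c1 = limb.knee_center, limb.plateau_medial_edge, limb.ankle_center
    if k == c1 or limb.plateau_medial_edge == limb.plateau_lateral_edge:
        raise ValueError("degenerate limb: plateau edges and tibial axis required")
    return angle_at_vertex(k, m, c1)


def measure_all(limb: LimbLandmarks) -> AlignmentMeasures:
    """Bundle WBL ratio (along the actual weight-bearing line F->C1), mFTA, mMPTA."""
    return AlignmentMeasures(
        wbl_ratio=wbl_ratio(limb, (limb.femoral_head_center, limb.ankle_center)),
        mfta=measure_mfta(limb),
        mpta=measure_mpta(limb),
    )
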