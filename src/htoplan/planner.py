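"""Concentric-circle planning of a medial open-wedge high tibial osteotomy.

The plan is a five-step ruler-and-compass construction on the frontal
radiograph, built entirely from circle/line intersections so that every
distance is a radius of a drawn circle:

1. **Target line** -- draw the target weight-bearing line L1 from the femoral
   head center F through the target point O on the tibial plateau (by default
   50 % of plateau width from the medial edge) and extend it past the ankle.
2. **Hinge** -- place the lateral hinge H a fixed depth below the lateral
   plateau edge (default 15 mm) and a fixed distance medial to the lateral
   cortex (default 8 mm, applied horizontally).
3. **Osteotomy site** -- circle of fixed radius (default 40 mm) centred on the
   medial plateau edge M; its distal crossing with the medial cortex is the
   osteotomy entry site S.
4. **Correction angle** -- circle centred on H through the ankle center C1;
   its distal crossing with L1 is I, the ankle's post-correction image.  The
   angle C1-H-I is the correction angle theta: rotating the distal tibia
   about H by theta carries the ankle onto the target line exactly.
5. **Correction gap** -- circle centred on H through S crosses ray H->C1 at P
   and ray H->I at G; |PG| = 2 |HS| sin(theta/2) is the medial opening to
   produce at the osteotomy site.  The intraoperative opening adds the saw
   blade thickness (default 0.9 mm) lost to the kerf.

Only varus limbs are plannable: a limb whose weight-bearing line already
crosses at or lateral to the target cannot be corrected by a medial opening
wedge and is rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

from .geometry import (
    ConstructionError,
    FrontalPoint,
    angle_at_vertex,
    chord_length,
    circle_line_intersections,
    circle_polyline_intersection,
    signed_angle_at_vertex,
)
from .limb_model import LimbLandmarks, wbl_ratio

#: Classical lateral over-correction target, as % of plateau width.
FUJISAWA_RATIO = 62.5

CorrectionClass = Literal["under", "acceptable", "over"]


@dataclass(frozen=True)
class PlanParameters:
    """Tunable construction parameters (all lengths in mm, ratios in %)."""

    target_ratio: float = 50.0
    hinge_distal_offset: float = 15.0
    hinge_medial_offset: float = 8.0
    osteotomy_radius: float = 40.0
    blade_thickness: float = 0.9
    acceptable_halfwidth: float = 5.0

    def __post_init__(self) -> None:
        for name in ("hinge_distal_offset", "hinge_medial_offset",
                     "osteotomy_radius", "blade_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.target_ratio < 100.0:
            raise ValueError("target_ratio must be in (0, 100) percent")
        if self.acceptable_halfwidth <= 0:
            raise ValueError("acceptable_halfwidth must be positive")


@dataclass(frozen=True)
class OsteotomyPlan:
    """Full result of the construction, in the canonical frame of the limb."""

    target_point: FrontalPoint                      # O
    target_line: tuple[FrontalPoint, FrontalPoint]  # L1 (F -> beyond ankle)
    hinge: FrontalPoint                             # H
    osteotomy_site: FrontalPoint                    # S
    ankle_image: FrontalPoint                       # I
    chord_p: FrontalPoint                           # P on ray H->C1
    chord_g: FrontalPoint                           # G on ray H->I
    correction_angle: float                         # theta, degrees, >= 0
    correction_gap: float                           # |PG|, mm
    intraoperative_gap: float                       # |PG| + blade thickness, mm
    radius_ankle: float                             # |H C1|, mm
    radius_osteotomy: float                         # |H S|, mm
    rotation_deg: float                             # signed CCW rotation H->C1 onto H->I
    notes: tuple[str, ...] = field(default=())

    def to_dict(self) -> dict:
        pt = lambda p: [p.x, p.y]  # noqa: E731
        return {
            "target_point": pt(self.target_point),
            "target_line": [pt(self.target_line[0]), pt(self.target_line[1])],
            "hinge": pt(self.hinge),
            "osteotomy_site": pt(self.osteotomy_site),
            "ankle_image": pt(self.ankle_image),
            "chord_p": pt(self.chord_p),
            "chord_g": pt(self.chord_g),
            "correction_angle_deg": self.correction_angle,
            "correction_gap_mm": self.correction_gap,
            "intraoperative_gap_mm": self.intraoperative_gap,
            "radius_ankle_mm": self.radius_ankle,
            "radius_osteotomy_mm": self.radius_osteotomy,
            "rotation_deg": self.rotation_deg,
            "notes": list(self.notes),
        }


def target_wbl_line(
    limb: LimbLandmarks, params: PlanParameters = PlanParameters()
) -> tuple[FrontalPoint, tuple[FrontalPoint, FrontalPoint]]:
    """Step 1: target point O on the plateau and target line L1 = F->O extended."""
    m, l = limb.plateau_medial_edge, limb.plateau_lateral_edge
    t = params.target_ratio / 100.0
    o = FrontalPoint(m.x + t * (l.x - m.x), m.y + t * (l.y - m.y))
    f = limb.femoral_head_center
    if o.y <= f.y:
        raise ConstructionError("target point is not distal to the femoral head")
    # extend L1 80 mm past the ankle level so the drawn line crosses every circle
    s = (limb.ankle_center.y - f.y + 80.0) / (o.y - f.y)
    far = FrontalPoint(f.x + s * (o.x - f.x), f.y + s * (o.y - f.y))
    return o, (f, far)


def locate_hinge(
    limb: LimbLandmarks, params: PlanParameters = PlanParameters()
) -> FrontalPoint:
    """Step 2: lateral hinge H, offset distally from the lateral plateau edge
    and medially (horizontally) from the lateral cortex."""
    y_h = limb.plateau_lateral_edge.y + params.hinge_distal_offset
    try:
        x_cortex = limb.lateral_cortex.x_at_y(y_h)
    except ConstructionError as exc:
        raise ConstructionError(
            f"construction failed locating the hinge: lateral cortex does not "
            f"cover depth {y_h:.1f} mm ({exc})"
        ) from exc
    return FrontalPoint(x_cortex + params.hinge_medial_offset, y_h)


def locate_osteotomy_site(
    limb: LimbLandmarks, params: PlanParameters = PlanParameters()
) -> FrontalPoint:
    """Step 3: osteotomy site S on the medial cortex, at the fixed osteotomy
    radius from the medial plateau edge (distal branch)."""
    try:
        return circle_polyline_intersection(
            limb.plateau_medial_edge, params.osteotomy_radius,
            limb.medial_cortex, branch="distal",
        )
    except ConstructionError as exc:
        raise ConstructionError(
            f"construction failed locating the osteotomy site: {exc}"
        ) from exc


def correction_angle(
    limb: LimbLandmarks,
    hinge: FrontalPoint,
    target_line: tuple[FrontalPoint, FrontalPoint],
) -> tuple[float, FrontalPoint]:
    """Step 4: correction angle theta and the ankle's image I on the target line.

    I is the distal crossing of the circle (H, |H C1|) with L1; theta is the
    angle C1-H-I.
    """
    c1 = limb.ankle_center
    r = hinge.distance_to(c1)
    pts = circle_line_intersections(hinge, r, *target_line)
    distal = [p for p in pts if p.y > hinge.y]
    if not distal:
        raise ConstructionError(
            "target unreachable: the ankle circle does not cross the target "
            "weight-bearing line distally "
            f"(|H C1| = {r:.1f} mm, hinge at ({hinge.x:.1f}, {hinge.y:.1f}))"
        )
    image = max(distal, key=lambda p: p.y)
    if image.distance_to(c1) < 1e-9:
        return 0.0, c1
    return angle_at_vertex(hinge, c1, image), image


def correction_gap(
    hinge: FrontalPoint,
    site: FrontalPoint,
    ankle: FrontalPoint,
    ankle_image: FrontalPoint,
    theta: float,
    params: PlanParameters = PlanParameters(),
) -> tuple[float, float, FrontalPoint, FrontalPoint]:
    """Step 5: chord endpoints P (ray H->C1) and G (ray H->I) at radius |HS|,
    the correction gap |PG| and the intraoperative opening |PG| + blade."""
    r_s = hinge.distance_to(site)

    def on_ray(towards: FrontalPoint) -> FrontalPoint:
        d = hinge.distance_to(towards)
        if d == 0:
            raise ConstructionError("degenerate ray from hinge")
        f = r_s / d
        return FrontalPoint(hinge.x + f * (towards.x - hinge.x),
                            hinge.y + f * (towards.y - hinge.y))

    p = on_ray(ankle)
    g = on_ray(ankle_image) if theta > 0 else p
    gap = p.distance_to(g)
    assert abs(gap - chord_length(r_s, theta)) <= 1e-9 * max(1.0, gap)
    return gap, gap + params.blade_thickness, p, g


def make_plan(
    limb: LimbLandmarks, params: PlanParameters = PlanParameters()
) -> OsteotomyPlan:
    """Run the five construction steps and assemble the full plan."""
    preop = wbl_ratio(limb, (limb.femoral_head_center, limb.ankle_center))
    if preop > params.target_ratio + 1e-9:
        raise ConstructionError(
            "target unreachable by medial opening wedge: preoperative "
            f"weight-bearing-line ratio {preop:.1f}% already lies at or lateral "
            f"to the target {params.target_ratio:.1f}% (valgus or neutral limb)"
        )
    o, l1 = target_wbl_line(limb, params)
    hinge = locate_hinge(limb, params)
    site = locate_osteotomy_site(limb, params)
    theta, image = correction_angle(limb, hinge, l1)
    gap, intraop, p, g = correction_gap(hinge, site, limb.ankle_center, image,
                                        theta, params)
    notes: list[str] = []
    if theta == 0.0:
        notes.append("no correction needed")
    if intraop > 15.0:
        notes.append("opening > 15 mm: structural bone graft recommended")
    rotation = (signed_angle_at_vertex(hinge, limb.ankle_center, image)
                if theta > 0 else 0.0)
    return OsteotomyPlan(
        target_point=o,
        target_line=l1,
        hinge=hinge,
        osteotomy_site=site,
        ankle_image=image,
        chord_p=p,
        chord_g=g,
        correction_angle=theta,
        correction_gap=gap,
        intraoperative_gap=intraop,
        radius_ankle=hinge.distance_to(limb.ankle_center),
        radius_osteotomy=hinge.distance_to(site),
        rotation_deg=rotation,
        notes=tuple(notes),
    )


def classify_correction(
    postop_ratio: float, params: PlanParameters = PlanParameters()
) -> CorrectionClass:
    """Classify a postoperative WBL ratio against the acceptable band.

    The band is ``target_ratio +/- acceptable_halfwidth`` (default 50 +/- 5 %);
    only strict exceedance of a boundary counts as under-/over-correction.
    """
    if postop_ratio < params.target_ratio - params.acceptable_halfwidth:
        return "under"
    if postop_ratio > params.target_ratio + params.acceptable_halfwidth:
        return "over"
    return "acceptable"
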