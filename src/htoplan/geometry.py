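"""Exact 2D construction primitives for frontal-plane osteotomy planning.

All coordinates live in a canonical frontal frame: millimetres, +x medial,
+y distal (y increases from hip towards ankle).  Angles cross every public
interface in degrees; radians appear only inside function bodies.  All
computation is on real-valued coordinates -- there is no pixel grid and no
snapping, so intersection residuals are at machine precision.

Where a circle meets a line twice the caller must pick a branch explicitly
(``proximal``/``distal``); there is no silent default, because branch
confusion is the dominant failure mode of ruler-and-compass constructions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

Branch = Literal["proximal", "distal"]


class ConstructionError(RuntimeError):
    """A geometric construction required by a plan cannot be completed."""


@dataclass(frozen=True)
class FrontalPoint:
    """A point in the canonical frontal frame (mm; +x medial, +y distal)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"coordinates must be finite, got ({self.x}, {self.y})")

    def distance_to(self, other: "FrontalPoint") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)

    def midpoint_with(self, other: "FrontalPoint") -> "FrontalPoint":
        return FrontalPoint((self.x + other.x) / 2.0, (self.y + other.y) / 2.0)

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class Polyline:
    """An ordered proximal-to-distal chain of points (e.g. a cortex contour).

    The chain must be single-valued in depth: y is non-decreasing along the
    sequence, so the contour can be interpolated at a given depth.
    """

    points: tuple[FrontalPoint, ...]

    def __init__(self, points: Sequence[FrontalPoint]) -> None:
        pts = tuple(points)
        if len(pts) < 2:
            raise ValueError("polyline needs at least 2 points")
        for a, b in zip(pts, pts[1:]):
            if b.y < a.y:
                raise ValueError(
                    f"polyline y must be non-decreasing (found {a.y} -> {b.y})"
                )
        object.__setattr__(self, "points", pts)

    @property
    def y_min(self) -> float:
        return self.points[0].y

    @property
    def y_max(self) -> float:
        return self.points[-1].y

    def segments(self) -> Iterator[tuple[FrontalPoint, FrontalPoint]]:
        return zip(self.points, self.points[1:])

    def x_at_y(self, y: float) -> float:
        """Linearly interpolate the contour's x at depth ``y``."""
        if not (self.y_min <= y <= self.y_max):
            raise ConstructionError(
                f"polyline spans y in [{self.y_min}, {self.y_max}]; "
                f"depth {y} is outside it"
            )
        for a, b in self.segments():
            if a.y <= y <= b.y:
                if b.y == a.y:
                    return a.x
                t = (y - a.y) / (b.y - a.y)
                return a.x + t * (b.x - a.x)
        raise ConstructionError(f"no segment covers depth {y}")  # pragma: no cover


def circle_line_intersections(
    center: FrontalPoint, radius: float, a: FrontalPoint, b: FrontalPoint
) -> list[FrontalPoint]:
    """Intersect a circle with the infinite line through ``a`` and ``b``.

    Returns 0, 1 (tangency) or 2 points ordered by increasing y (ties by x).
    An empty result is a valid answer, not an error; a degenerate line
    (``a == b``) is an error.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    dx, dy = b.x - a.x, b.y - a.y
    if dx == 0.0 and dy == 0.0:
        raise ValueError("degenerate line: a and b coincide")
    # |a + t*d - c|^2 = r^2  ->  quadratic in t
    fx, fy = a.x - center.x, a.y - center.y
    qa = dx * dx + dy * dy
    qb = 2.0 * (fx * dx + fy * dy)
    qc = fx * fx + fy * fy - radius * radius
    disc = qb * qb - 4.0 * qa * qc
    if disc < 0.0:
        return []
    sq = math.sqrt(disc)
    if sq == 0.0:
        ts = [-qb / (2.0 * qa)]
    else:
        ts = [(-qb - sq) / (2.0 * qa), (-qb + sq) / (2.0 * qa)]
    pts = [FrontalPoint(a.x + t * dx, a.y + t * dy) for t in ts]
    pts.sort(key=lambda p: (p.y, p.x))
    return pts


def _circle_segment_intersections(
    center: FrontalPoint, radius: float, a: FrontalPoint, b: FrontalPoint
) -> list[FrontalPoint]:
    """Intersections restricted to the closed segment a-b."""
    dx, dy = b.x - a.x, b.y - a.y
    if dx == 0.0 and dy == 0.0:
        return []
    fx, fy = a.x - center.x, a.y - center.y
    qa = dx * dx + dy * dy
    qb = 2.0 * (fx * dx + fy * dy)
    qc = fx * fx + fy * fy - radius * radius
    disc = qb * qb - 4.0 * qa * qc
    if disc < 0.0:
        return []
    sq = math.sqrt(disc)
    ts = {(-qb - sq) / (2.0 * qa), (-qb + sq) / (2.0 * qa)}
    eps = 1e-12
    return [
        FrontalPoint(a.x + t * dx, a.y + t * dy) for t in sorted(ts) if -eps <= t <= 1 + eps
    ]


def circle_polyline_intersection(
    center: FrontalPoint, radius: float, pl: Polyline, branch: Branch
) -> FrontalPoint:
    """Crossing of a circle with a polyline, picking one branch.

    ``branch="proximal"`` returns the crossing with smallest y among all
    segment intersections, ``"distal"`` the one with largest y.  Raises
    :class:`ConstructionError` when the circle misses the polyline.
    """
    if branch not in ("proximal", "distal"):
        raise ValueError(f"branch must be 'proximal' or 'distal', got {branch!r}")
    hits: list[FrontalPoint] = []
    if radius > 0:
        for a, b in pl.segments():
            for p in _circle_segment_intersections(center, radius, a, b):
                # shared segment endpoints produce duplicate hits
                if all(p.distance_to(q) > 1e-9 for q in hits):
                    hits.append(p)
    if not hits:
        raise ConstructionError(
            f"construction failed: circle at ({center.x:.3f}, {center.y:.3f}) "
            f"with radius {radius:.3f} mm does not cross the polyline "
            f"(y span [{pl.y_min:.1f}, {pl.y_max:.1f}])"
        )
    key = min if branch == "proximal" else max
    return key(hits, key=lambda p: (p.y, p.x))


def angle_at_vertex(vertex: FrontalPoint, p1: FrontalPoint, p2: FrontalPoint) -> float:
    """Unsigned angle in degrees, in [0, 180], between rays vertex->p1 and vertex->p2."""
    ux, uy = p1.x - vertex.x, p1.y - vertex.y
    vx, vy = p2.x - vertex.x, p2.y - vertex.y
    if (ux == 0.0 and uy == 0.0) or (vx == 0.0 and vy == 0.0):
        raise ValueError("zero-length ray at vertex")
    cross = ux * vy - uy * vx
    dot = ux * vx + uy * vy
    return math.degrees(math.atan2(abs(cross), dot))


def signed_angle_at_vertex(
    vertex: FrontalPoint, p_from: FrontalPoint, p_to: FrontalPoint
) -> float:
    """Signed angle (degrees, CCW positive) rotating ray vertex->p_from onto vertex->p_to."""
    ux, uy = p_from.x - vertex.x, p_from.y - vertex.y
    vx, vy = p_to.x - vertex.x, p_to.y - vertex.y
    if (ux == 0.0 and uy == 0.0) or (vx == 0.0 and vy == 0.0):
        raise ValueError("zero-length ray at vertex")
    return math.degrees(math.atan2(ux * vy - uy * vx, ux * vx + uy * vy))


def rotate_about(p: FrontalPoint, center: FrontalPoint, angle: float) -> FrontalPoint:
    """Rotate ``p`` about ``center`` by ``angle`` degrees (CCW positive)."""
    rad = math.radians(angle)
    c, s = math.cos(rad), math.sin(rad)
    dx, dy = p.x - center.x, p.y - center.y
    return FrontalPoint(center.x + c * dx - s * dy, center.y + s * dx + c * dy)


def chord_length(radius: float, angle: float) -> float:
    """Chord subtending ``angle`` degrees on a circle of the given radius.

    This is the opening produced at radius r by a hinged rotation of angle
    theta: 2 * r * sin(theta / 2).
    """
    if radius < 0:
        raise ValueError(f"radius must be non-negative, got {radius}")
    if not (0.0 <= angle <= 180.0):
        raise ValueError(f"angle must be in [0, 180] degrees, got {angle}")
    return 2.0 * radius * math.sin(math.radians(angle) / 2.0)
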