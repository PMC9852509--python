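import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from htoplan.geometry import (
    ConstructionError,
    FrontalPoint,
    Polyline,
    angle_at_vertex,
    chord_length,
    circle_line_intersections,
    circle_polyline_intersection,
    rotate_about,
    signed_angle_at_vertex,
)

P = FrontalPoint

finite = st.floats(-500, 500, allow_nan=False)
points = st.builds(P, finite, finite)
angles = st.floats(0, 180, allow_nan=False)
radii = st.floats(0.1, 400, allow_nan=False)


def vertical(x, y0, y1, n=10):
    step = (y1 - y0) / (n - 1)
    return Polyline([P(x, y0 + i * step) for i in range(n)])


class TestCircleLine:
    @pytest.mark.parametrize(
        "center, r, a, b, expected",
        [
            (P(0, 0), 1.0, P(0, -5), P(0, 5), [(0, -1), (0, 1)]),
            (P(0, 0), 1.0, P(2, -5), P(2, 5), []),
            # hand-solved: (0+25)^2 + (y-415)^2 = 387.62...^2, distal root
            (P(-25, 415), math.hypot(45, 385), P(0, 0), P(0, 1),
             [(0, 415 - math.sqrt(149625)), (0, 415 + math.sqrt(149625))]),
        ],
    )
    def test_known_intersections(self, center, r, a, b, expected):
        got = circle_line_intersections(center, r, a, b)
        assert len(got) == len(expected)
        for p, (ex, ey) in zip(got, expected):
            assert p.x == pytest.approx(ex, abs=1e-9)
            assert p.y == pytest.approx(ey, abs=1e-9)

    def test_distal_root_matches_worked_value(self):
        pts = circle_line_intersections(P(-25, 415), 387.62094886628614,
                                        P(0, 0), P(0, 800))
        assert pts[-1].y == pytest.approx(801.8139087468288, abs=1e-6)

    def test_degenerate_line_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            circle_line_intersections(P(0, 0), 1.0, P(1, 1), P(1, 1))

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            circle_line_intersections(P(0, 0), 0.0, P(0, 0), P(1, 0))

    @given(center=points, r=radii, a=points, b=points)
    def test_residual_on_circle(self, center, r, a, b):
        if a.distance_to(b) < 1e-6:
            return
        for p in circle_line_intersections(center, r, a, b):
            assert abs(p.distance_to(center) - r) <= 1e-9 * max(1.0, r)

    @given(center=points, r=radii, a=points, b=points)
    def test_points_ordered_by_y(self, center, r, a, b):
        if a.distance_to(b) < 1e-6:
            return
        pts = circle_line_intersections(center, r, a, b)
        assert all(p.y <= q.y for p, q in zip(pts, pts[1:]))


class TestAngleAtVertex:
    @pytest.mark.parametrize(
        "vertex, p1, p2, expected",
        [
            (P(0, 0), P(1, 0), P(0, 1), 90.0),
            (P(0, 0), P(1, 0), P(1, 0), 0.0),
            (P(0, 0), P(1, 0), P(-1, 0), 180.0),
            # atan(45/385) - atan(25/386.8139...) in degrees
            (P(-25, 415), P(20, 800), P(0, 415 + math.sqrt(149625)),
             2.9687446496855827),
        ],
    )
    def test_known_angles(self, vertex, p1, p2, expected):
        assert angle_at_vertex(vertex, p1, p2) == pytest.approx(expected, abs=1e-9)

    def test_zero_length_ray_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            angle_at_vertex(P(1, 1), P(1, 1), P(2, 2))

    @given(v=points, p1=points, p2=points)
    def test_symmetric_and_bounded(self, v, p1, p2):
        if v.distance_to(p1) < 1e-6 or v.distance_to(p2) < 1e-6:
            return
        a = angle_at_vertex(v, p1, p2)
        assert 0.0 <= a <= 180.0
        assert a == angle_at_vertex(v, p2, p1)

    @given(v=points, p1=points, p2=points, dx=finite, dy=finite,
           rot=st.floats(-180, 180, allow_nan=False))
    def test_invariant_under_rigid_motion(self, v, p1, p2, dx, dy, rot):
        if v.distance_to(p1) < 1e-3 or v.distance_to(p2) < 1e-3:
            return
        a = angle_at_vertex(v, p1, p2)
        move = lambda p: rotate_about(P(p.x + dx, p.y + dy), P(dx, dy), rot)  # noqa: E731
        b = angle_at_vertex(move(v), move(p1), move(p2))
        assert b == pytest.approx(a, abs=1e-7)


class TestRotateAbout:
    def test_quarter_turn_is_ccw(self):
        q = rotate_about(P(1, 0), P(0, 0), 90.0)
        assert (q.x, q.y) == (pytest.approx(0, abs=1e-12), pytest.approx(1))

    @given(p=points, angle=st.floats(-360, 360, allow_nan=False))
    def test_center_is_fixed_point(self, p, angle):
        q = rotate_about(p, p, angle)
        assert q.x == pytest.approx(p.x) and q.y == pytest.approx(p.y)

    def test_maps_ankle_onto_target_line(self):
        # rotating the ankle about the hinge by the signed correction angle
        # must land it on the target line x = 0, distal branch
        h, c1 = P(-25, 415), P(20, 800)
        target = circle_line_intersections(h, h.distance_to(c1), P(0, 0), P(0, 1))[-1]
        phi = signed_angle_at_vertex(h, c1, target)
        q = rotate_about(c1, h, phi)
        assert q.x == pytest.approx(0.0, abs=1e-9)
        assert q.y == pytest.approx(801.8139087468288, abs=1e-9)

    @given(ps=st.lists(points, min_size=2, max_size=5), center=points,
           angle=st.floats(-360, 360, allow_nan=False))
    def test_isometry(self, ps, center, angle):
        qs = [rotate_about(p, center, angle) for p in ps]
        for (a, b), (c, d) in zip(
            [(x, y) for i, x in enumerate(ps) for y in ps[i + 1:]],
            [(x, y) for i, x in enumerate(qs) for y in qs[i + 1:]],
        ):
            assert c.distance_to(d) == pytest.approx(
                a.distance_to(b), rel=1e-9, abs=1e-9
            )


class TestChordLength:
    @pytest.mark.parametrize(
        "r, angle, expected",
        [(63.14, 0.0, 0.0), (63.14, 180.0, 126.28),
         (63.14, 2.97, 2 * 63.14 * math.sin(math.radians(1.485)))],
    )
    def test_known_values(self, r, angle, expected):
        assert chord_length(r, angle) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("r, angle", [(-1.0, 10.0), (1.0, -1.0), (1.0, 181.0)])
    def test_domain_errors(self, r, angle):
        with pytest.raises(ValueError):
            chord_length(r, angle)

    @given(r=radii, angle=angles, q=points, center=points)
    def test_equals_rotated_endpoint_distance(self, r, angle, q, center):
        # place a point at radius r from the center, rotate by +-angle/2:
        # the chord between the two images must match the closed form
        d = center.distance_to(q)
        if d < 1e-6:
            return
        f = r / d
        on_circle = P(center.x + f * (q.x - center.x), center.y + f * (q.y - center.y))
        a = rotate_about(on_circle, center, angle / 2)
        b = rotate_about(on_circle, center, -angle / 2)
        assert a.distance_to(b) == pytest.approx(
            chord_length(r, angle), rel=1e-9, abs=1e-9
        )


class TestCirclePolyline:
    def test_distal_crossing_of_vertical_cortex(self):
        pl = vertical(33, 390, 600)
        p = circle_polyline_intersection(P(35, 400), 40.0, pl, "distal")
        assert p.x == pytest.approx(33.0)
        assert p.y == pytest.approx(400 + math.sqrt(1596), abs=1e-9)  # 439.94997

    def test_proximal_branch_differs(self):
        pl = vertical(33, 300, 600)
        prox = circle_polyline_intersection(P(35, 400), 40.0, pl, "proximal")
        dist = circle_polyline_intersection(P(35, 400), 40.0, pl, "distal")
        assert prox.y == pytest.approx(400 - math.sqrt(1596), abs=1e-9)
        assert prox.y < dist.y

    def test_zero_radius_never_crosses(self):
        pl = vertical(33, 390, 600)
        with pytest.raises(ConstructionError, match="construction failed"):
            circle_polyline_intersection(P(33, 400), 0.0, pl, "distal")

    def test_disjoint_polyline_fails_with_context(self):
        pl = vertical(100, 390, 600)
        with pytest.raises(ConstructionError, match="does not cross"):
            circle_polyline_intersection(P(35, 400), 40.0, pl, "distal")

    def test_invalid_branch_rejected(self):
        pl = vertical(33, 390, 600)
        with pytest.raises(ValueError, match="branch"):
            circle_polyline_intersection(P(35, 400), 40.0, pl, "middle")

    @given(cx=st.floats(-50, 50), cy=st.floats(350, 450), r=st.floats(5, 80),
           x=st.floats(-45, 45))
    def test_residual_on_circle(self, cx, cy, r, x):
        pl = vertical(x, 300, 700)
        try:
            p = circle_polyline_intersection(P(cx, cy), r, pl, "distal")
        except ConstructionError:
            return
        assert abs(p.distance_to(P(cx, cy)) - r) <= 1e-9 * max(1.0, r)


class TestPolyline:
    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            Polyline([P(0, 0)])

    def test_y_must_be_monotone(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            Polyline([P(0, 0), P(0, 10), P(0, 5)])

    def test_interpolation(self):
        pl = Polyline([P(0, 0), P(10, 10)])
        assert pl.x_at_y(5.0) == pytest.approx(5.0)
        with pytest.raises(ConstructionError):
            pl.x_at_y(11.0)

    def test_non_finite_point_rejected(self):
        with pytest.raises(ValueError):
            P(float("nan"), 0.0)
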