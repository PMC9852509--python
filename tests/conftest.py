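import json

import pytest
from hypothesis import HealthCheck, settings

from htoplan import FrontalPoint, LimbLandmarks, Polyline

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def vertical_polyline(x, y0, y1, step=5.0):
    ys = []
    y = y0
    while y < y1:
        ys.append(y)
        y += step
    ys.append(y1)
    return Polyline([FrontalPoint(x, y) for y in ys])


def build_limb(ankle_x=20.0, ankle_y=800.0, plateau_half=35.0, plateau_y=400.0,
               cortex_x=33.0, **kwargs):
    """Hand-built limb with vertical cortex contours (the worked fixture shape)."""
    return LimbLandmarks(
        femoral_head_center=FrontalPoint(0.0, 0.0),
        plateau_medial_edge=FrontalPoint(plateau_half, plateau_y),
        plateau_lateral_edge=FrontalPoint(-plateau_half, plateau_y),
        ankle_center=FrontalPoint(ankle_x, ankle_y),
        medial_cortex=vertical_polyline(cortex_x, plateau_y - 5.0, ankle_y),
        lateral_cortex=vertical_polyline(-cortex_x, plateau_y - 5.0, ankle_y),
        **kwargs,
    )


@pytest.fixture
def worked_limb():
    """The hand-computed planning fixture: F=(0,0), plateau edges (+-35, 400),
    ankle (20, 800), vertical cortices at x = +-33."""
    return build_limb()


@pytest.fixture
def straight_limb():
    """A perfectly aligned limb (WBL 50 %, mFTA 0, mMPTA 90)."""
    return build_limb(ankle_x=0.0)


def landmark_doc(side="right", scale_px_per_mm=1.0, ankle=(20.0, 800.0),
                 timepoint="pre", patient_id="P01"):
    """Landmark-file dict for the worked limb, in pixels at the given scale.

    The file frame has x increasing to the viewer's right; for a left-side
    file the limb is written pre-mirrored so that canonical loading (which
    mirrors left limbs) reproduces the same canonical limb.
    """
    s = scale_px_per_mm
    sx = -s if side == "left" else s

    def px(x, y):
        return [sx * x + 500.0, s * y + 100.0]

    cortex = lambda x: [px(x, y) for y in range(395, 801, 5)]  # noqa: E731
    return {
        "schema_version": 1,
        "patient_id": patient_id,
        "side": side,
        "timepoint": timepoint,
        "calibration": {
            "marker_a": [0.0, 0.0],
            "marker_b": [0.0, 100.0 * s],
            "known_distance_mm": 100.0,
        },
        "landmarks": {
            "femoral_head_center": px(0.0, 0.0),
            "plateau_medial_edge": px(35.0, 400.0),
            "plateau_lateral_edge": px(-35.0, 400.0),
            "ankle_center": px(*ankle),
        },
        "polylines": {"medial_cortex": cortex(33.0), "lateral_cortex": cortex(-33.0)},
    }


@pytest.fixture
def landmark_file(tmp_path):
    def write(doc, name="limb.json"):
        path = tmp_path / name
        path.write_text(json.dumps(doc))
        return path

    return write
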