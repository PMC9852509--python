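"""SVG overlay of a plan on the landmark frame (matplotlib SVG backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Circle

from .limb_model import LimbLandmarks
from .planner import OsteotomyPlan


def render_plan_svg(limb: LimbLandmarks, plan: OsteotomyPlan,
                    path: str | Path) -> None:
    """Draw the construction (L1, circles, H, S, I, P, G) over the limb.

    The canonical frame is shown with distal pointing down; medial (+x) is to
    the right, i.e. the view of a right limb on an AP radiograph.
    """
    fig, ax = plt.subplots(figsize=(4.5, 9))
    for pl, color in ((limb.medial_cortex, "0.4"), (limb.lateral_cortex, "0.4")):
        ax.plot([p.x for p in pl.points], [p.y for p in pl.points],
                color=color, lw=1.2)
    m, l = limb.plateau_medial_edge, limb.plateau_lateral_edge
    ax.plot([m.x, l.x], [m.y, l.y], color="0.4", lw=1.2)

    a, b = plan.target_line
    ax.plot([a.x, b.x], [a.y, b.y], "b-", lw=1.0, label="target WBL (L1)")
    f, c1 = limb.femoral_head_center, limb.ankle_center
    ax.plot([f.x, c1.x], [f.y, c1.y], "r--", lw=0.8, label="preop WBL")

    h = plan.hinge
    ax.add_patch(Circle((h.x, h.y), plan.radius_ankle, fill=False,
                        ec="g", lw=0.6, ls=":"))
    ax.add_patch(Circle((h.x, h.y), plan.radius_osteotomy, fill=False,
                        ec="g", lw=0.6, ls=":"))
    ax.add_patch(Circle((m.x, m.y), m.distance_to(plan.osteotomy_site),
                        fill=False, ec="m", lw=0.6, ls=":"))

    labelled = {
        "F": f, "C1": c1, "O": plan.target_point, "H": h,
        "S": plan.osteotomy_site, "I": plan.ankle_image,
        "P": plan.chord_p, "G": plan.chord_g,
    }
    for name, p in labelled.items():
        ax.plot(p.x, p.y, "ko", ms=3)
        ax.annotate(name, (p.x, p.y), textcoords="offset points",
                    xytext=(4, 4), fontsize=8)

    ax.set_aspect("equal")
    ax.invert_yaxis()
    ax.set_xlabel("medial  +x  (mm)")
    ax.set_ylabel("distal  +y  (mm)")
    ax.set_title(
        f"θ = {plan.correction_angle:.2f}°, gap = {plan.correction_gap:.2f} mm"
    )
    ax.legend(loc="lower right", fontsize=7)
    fig.savefig(Path(path), format="svg", bbox_inches="tight")
    plt.close(fig)
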