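"""Synthetic limbs, landmark noise, simulated plan execution, Monte-Carlo studies.

The generator emulates the frontal-plane skeleton seen on a standing
whole-leg radiograph.  The femur is straight and vertical (head at the
origin, knee center directly below); the whole varus deformity is placed in
the proximal tibia as an MPTA deficit, which is the deformity pattern a
medial open-wedge tibial osteotomy exists to treat.  ``tibia_length`` is the
vertical (proximal-distal) extent of the tibial segment, so a limb with
varus angle v has its ankle offset medially by ``tibia_length * tan(v)``.

Cortical contours are polylines parallel to the tibial mechanical axis,
inset horizontally from the plateau edges, with an optional exponentially
decaying metaphyseal flare.  Landmark noise is isotropic Gaussian and
independent per landmark; each cortex polyline is perturbed rigidly (one
shared offset) so contours never self-intersect.

Executing a plan is a rigid rotation of everything distal to the osteotomy
level about the hinge -- the idealised geometric model of opening the wedge.
The Monte-Carlo driver separates *planning error* (the plan is built on a
noisy digitization) from *measurement error* (the outcome is read off a
second noisy digitization), with the true limb in between.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .geometry import ConstructionError, FrontalPoint, Polyline, rotate_about
from .limb_model import LimbLandmarks, measure_all
from .planner import OsteotomyPlan, PlanParameters, classify_correction, make_plan

#: Vertical spacing of generated cortex polyline points (mm).
_CORTEX_STEP = 5.0
#: Decay depth of the metaphyseal flare (mm below the plateau).
_FLARE_DECAY = 30.0


@dataclass(frozen=True)
class SyntheticLimbSpec:
    """Parameters of the synthetic limb generator (lengths in mm, angle in deg)."""

    femur_length: float = 420.0
    tibia_length: float = 365.0
    plateau_width: float = 75.0
    varus_angle: float = 6.4
    cortex_inset: float = 2.0
    cortex_flare: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("femur_length", "tibia_length", "plateau_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tibia_length < 80.0:
            raise ValueError("tibia_length must be at least 80 mm (cortex extent)")
        if not 0.0 <= self.varus_angle < 15.0:
            raise ValueError("varus_angle must be in [0, 15) degrees")
        if not 0.0 <= self.cortex_inset < self.plateau_width / 2:
            raise ValueError("cortex_inset must be in [0, plateau_width/2)")
        if self.cortex_flare < 0:
            raise ValueError("cortex_flare must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class SimulationResult:
    """Aggregate outcome of a Monte-Carlo plan-execute-measure study."""

    n: int
    postop_ratios: tuple[float, ...]
    fraction_under: float
    fraction_acceptable: float
    fraction_over: float
    mean_theta: float
    mean_gap: float
    n_failed: int

    def __post_init__(self) -> None:
        if self.n != len(self.postop_ratios):
            raise ValueError("n must equal the number of postop ratios")
        if self.n > 0:
            total = self.fraction_under + self.fraction_acceptable + self.fraction_over
            if abs(total - 1.0) > 1e-12:
                raise ValueError("class fractions must sum to 1")


def generate_limb(
    spec: SyntheticLimbSpec,
    *,
    patient_id: str = "synthetic",
    timepoint: str = "pre",
) -> LimbLandmarks:
    """Build one synthetic limb; deterministic given ``spec.seed``.

    With ``noise_sigma == 0`` the limb measures back exactly:
    mFTA = ``varus_angle``, MPTA = 90 - ``varus_angle``, and (for varus 0)
    WBL ratio = 50 %.
    """
    hw = spec.plateau_width / 2.0
    tan_v = math.tan(math.radians(spec.varus_angle))
    knee_y = spec.femur_length
    ankle = FrontalPoint(spec.tibia_length * tan_v, knee_y + spec.tibia_length)

    def cortex(sign: float) -> Polyline:
        # sign +1 = medial contour, -1 = lateral; the trace starts 10 mm
        # proximal to the plateau so digitization noise cannot strand it distal
        pts = []
        depth = -10.0
        while depth <= spec.tibia_length:
            half = hw - spec.cortex_inset + spec.cortex_flare * hw * math.exp(
                -depth / _FLARE_DECAY
            )
            pts.append(FrontalPoint(depth * tan_v + sign * half, knee_y + depth))
            depth += _CORTEX_STEP
        return Polyline(pts)

    limb = LimbLandmarks(
        femoral_head_center=FrontalPoint(0.0, 0.0),
        plateau_medial_edge=FrontalPoint(hw, knee_y),
        plateau_lateral_edge=FrontalPoint(-hw, knee_y),
        ankle_center=ankle,
        medial_cortex=cortex(+1.0),
        lateral_cortex=cortex(-1.0),
        side="right",
        patient_id=patient_id,
        timepoint=timepoint,  # type: ignore[arg-type]
    )
    if spec.noise_sigma > 0:
        limb = perturb_landmarks(limb, spec.noise_sigma,
                                 np.random.default_rng(spec.seed))
    return limb


def perturb_landmarks(
    limb: LimbLandmarks, sigma: float, rng: np.random.Generator
) -> LimbLandmarks:
    """Observer-style digitization noise: iid isotropic Gaussian per landmark,
    one rigid Gaussian offset per cortex polyline."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return limb

    def jitter(p: FrontalPoint) -> FrontalPoint:
        d = rng.normal(0.0, sigma, 2)
        return FrontalPoint(p.x + d[0], p.y + d[1])

    def shift(pl: Polyline) -> Polyline:
        d = rng.normal(0.0, sigma, 2)
        return Polyline([FrontalPoint(p.x + d[0], p.y + d[1]) for p in pl.points])

    return replace(
        limb,
        femoral_head_center=jitter(limb.femoral_head_center),
        plateau_medial_edge=jitter(limb.plateau_medial_edge),
        plateau_lateral_edge=jitter(limb.plateau_lateral_edge),
        ankle_center=jitter(limb.ankle_center),
        medial_cortex=shift(limb.medial_cortex),
        lateral_cortex=shift(limb.lateral_cortex),
    )


def apply_osteotomy(limb: LimbLandmarks, plan: OsteotomyPlan) -> LimbLandmarks:
    """Execute a plan: rotate everything distal to the osteotomy level about
    the hinge by the plan's correction angle (towards valgus).

    The osteotomy "plane" is the horizontal line through the osteotomy site
    S; the ankle center and all cortex points distal to it rotate, proximal
    structures stay fixed.  The result carries ``timepoint="post"``.
    """
    h = plan.hinge
    xs = [p.x for p in (limb.femoral_head_center, limb.plateau_medial_edge,
                        limb.plateau_lateral_edge, limb.ankle_center)]
    ys = [p.y for p in (limb.femoral_head_center, limb.ankle_center)]
    if not (min(xs) - 50.0 <= h.x <= max(xs) + 50.0
            and min(ys) - 50.0 <= h.y <= max(ys) + 50.0):
        raise ValueError(
            "plan/limb mismatch: hinge lies far outside the limb's bounds"
        )
    cut_y = plan.osteotomy_site.y
    phi = plan.rotation_deg

    def move(p: FrontalPoint) -> FrontalPoint:
        return rotate_about(p, h, phi) if p.y > cut_y else p

    def move_pl(pl: Polyline) -> Polyline:
        return Polyline([move(p) for p in pl.points])

    return replace(
        limb,
        ankle_center=rotate_about(limb.ankle_center, h, phi),
        medial_cortex=move_pl(limb.medial_cortex),
        lateral_cortex=move_pl(limb.lateral_cortex),
        timepoint="post",
    )


def monte_carlo_accuracy(
    spec: SyntheticLimbSpec,
    params: PlanParameters,
    n: int,
    noise_sigma: float,
    seed: int,
    varus_range: tuple[float, float] | None = None,
) -> SimulationResult:
    """Plan-execute-measure error propagation under landmark noise.

    Per replicate: build the noiseless true limb (varus either from ``spec``
    or drawn uniformly from ``varus_range``); plan on a noise-perturbed copy
    (planning error); execute that plan on the true limb; measure the
    postoperative WBL ratio on a second noise-perturbed copy (measurement
    error); classify.  Replicates whose plan construction fails are counted
    in ``n_failed``, never silently dropped.  One RNG stream per replicate,
    derived from ``(seed, replicate index)``, makes the result independent
    of replicate ordering and exactly reproducible.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    ratios: list[float] = []
    thetas: list[float] = []
    gaps: list[float] = []
    counts = {"under": 0, "acceptable": 0, "over": 0}
    n_failed = 0
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        varus = (rng.uniform(*varus_range) if varus_range is not None
                 else spec.varus_angle)
        true_limb = generate_limb(replace(spec, varus_angle=varus, noise_sigma=0.0))
        try:
            plan = make_plan(perturb_landmarks(true_limb, noise_sigma, rng), params)
            post = apply_osteotomy(true_limb, plan)
            measured = perturb_landmarks(post, noise_sigma, rng)
            ratio = measure_all(measured).wbl_ratio
        except (ConstructionError, ValueError):
            n_failed += 1
            continue
        ratios.append(ratio)
        thetas.append(plan.correction_angle)
        gaps.append(plan.correction_gap)
        counts[classify_correction(ratio, params)] += 1
    n_ok = len(ratios)
    if n_ok == 0:
        raise ConstructionError(
            f"all {n} replicates failed plan construction (noise too large "
            "or deformity outside the plannable range)"
        )
    return SimulationResult(
        n=n_ok,
        postop_ratios=tuple(ratios),
        fraction_under=counts["under"] / n_ok,
        fraction_acceptable=counts["acceptable"] / n_ok,
        fraction_over=counts["over"] / n_ok,
        mean_theta=float(np.mean(thetas)),
        mean_gap=float(np.mean(gaps)),
        n_failed=n_failed,
    )
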