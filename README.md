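# htoplan

Preoperative planning geometry for **medial open-wedge high tibial osteotomy
(OWHTO)** on standing whole-leg anteroposterior radiographs.

OWHTO treats medial-compartment knee osteoarthritis in varus knees by cutting
the proximal tibia, hinging it laterally, and opening a medial wedge until the
limb's weight-bearing line (WBL) — the line from the femoral head center to
the ankle joint center — crosses the tibial plateau at a chosen target
(50 % of plateau width by default, or the Fujisawa point at 62.5 %).
Getting the opening angle and gap right preoperatively is what determines the
postoperative alignment. `htoplan` implements the whole planning workflow as
a 2D geometry library plus CLI:

- **Alignment measures** from digitized landmarks: the WBL ratio (% of
  plateau width, from the medial edge), the mechanical femorotibial angle
  (mFTA, varus positive), and the medial proximal tibial angle (mMPTA).
- **The concentric-circle construction** of the correction, built entirely
  from circle/line intersections:
  1. target line L1 from femoral head F through the target point O on the
     plateau;
  2. lateral hinge H, 15 mm distal to the lateral plateau edge and 8 mm
     medial to the lateral cortex;
  3. osteotomy site S where a 40 mm circle about the medial plateau edge M
     meets the medial cortex;
  4. correction angle θ = ∠C1-H-I, where I is the distal crossing of the
     circle (H, |HC1|) with L1 and C1 is the ankle center — rotating the
     distal tibia about H by θ carries the ankle exactly onto L1;
  5. correction gap |PG| = 2 |HS| sin(θ/2), the chord of θ at the osteotomy
     radius; adding the 0.9 mm saw-blade thickness gives the opening to
     produce in the operating room.
- **A virtual osteotomy simulator**: synthetic limbs with prescribed varus,
  observer-style Gaussian landmark noise, rigid execution of a plan
  (rotation about the hinge), and Monte-Carlo plan–execute–measure studies.
- **Cohort statistics**: paired *t*-tests of pre/post measures, ICC(2,1) /
  ICC(3,1) rater agreement with the conventional categories (poor < 0.40,
  fair to good 0.40–0.75, excellent > 0.75), and correction classification
  (under / acceptable / over against the 50 ± 5 % band).

## Worked example

The test suite's planning fixture is a limb with femoral head F = (0, 0),
plateau edges (±35, 400), ankle center (20, 800) and vertical cortices at
x = ±33 (mm; +x medial, +y distal). Planning it from the CLI:

```sh
htoplan generate --varus 2.8624 --femur 400 --tibia 400 --plateau 70 -o limb.json
htoplan plan limb.json --svg plan.svg
```

prints

```
patient synthetic (right): preop WBL 35.7 %, varus 2.9°, mMPTA 87.1°
  hinge H            : (-24.25, 415.00) mm
  osteotomy site S   : (35.00, 440.00) mm
  correction angle θ : 2.97°
  correction gap     : 3.33 mm
  intraoperative gap : 4.23 mm (incl. 0.9 mm blade)
```

The preoperative WBL crosses the plateau 35.7 % from the medial edge
(10 mm medial of the 50 % target); rotating the distal tibia 2.97° about the
hinge moves it exactly onto the target, which needs a 3.3 mm opening at the
osteotomy site, 4.2 mm as cut with the saw kerf. (The hand-computed fixture
with *vertical* cortices gives H = (−25, 415), S = (33, 439.95), θ = 2.97°,
gap = 3.27 mm; the generated limb's cortices follow the tilted tibial axis,
hence the few-hundred-micron differences.) `plan.svg` shows the whole
construction overlaid on the limb.

Executing the plan virtually closes the loop:

```python
from htoplan import *
limb = generate_limb(SyntheticLimbSpec(varus_angle=6.4))
plan = make_plan(limb)
post = apply_osteotomy(limb, plan)
print(measure_all(post).wbl_ratio)   # 50.000000000000014
```

## CLI overview

| command | purpose |
|---|---|
| `htoplan measure limb.json` | WBL ratio, mFTA, mMPTA of one limb |
| `htoplan plan limb.json [--target-ratio 50\|fujisawa] [--svg f.svg]` | build the osteotomy plan |
| `htoplan generate --varus 6.4 -o limb.json` | synthetic limb as a landmark file |
| `htoplan simulate --n 2000 --noise 1.5 -o mc.csv` | Monte-Carlo accuracy study |
| `htoplan cohort cohort.csv` | pre/post summary, *t*-tests, classification |
| `htoplan icc ratings.csv --form inter` | rater agreement of a rating table |

The landmark-file JSON schema (pixel coordinates plus a two-point
millimetre calibration) is documented in `htoplan/limb_model.py`.
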