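# autoimrt

Automated class-solution IMRT planning with iterative **regional
optimization** — an open, desk-scale re-implementation of the scripted
planning workflow used clinically for complex sites such as head-and-neck
cancer with multiple prescription levels.

For complex IMRT cases a planner normally iterates by hand: build helper
structures (planning risk volumes, rings, overlap-free optimization
targets), place beams, set objective doses and weights, optimize, inspect
the dose, then chase residual hot and cold spots with extra objectives —
again and again. `autoimrt` encodes that entire loop as a machine-readable
*class solution* (a plan template) plus an automated pipeline, so the whole
process runs unattended from a voxelized structure set. It is aimed at
medical-physics researchers and students studying plan automation; it is
**not** a clinical dose engine (see `docs/methods.md` for the declared
simplified beamlet model).

## What it does

Given binary ROI masks on a regular 3D grid and a template, the pipeline:

1. **Validates** the required ROIs (CTVs, OARs, body contour), halting
   with the missing names if any are absent.
2. **Derives** the optimization structures by recipe: PTV = CTV + margin,
   PRVs (e.g. cord + 5 mm), `modPTV` = PTV kept 5 mm off the skin and
   excluding the PRVs, `optPTV` lower-dose targets minus higher-dose ones,
   parotid-avoidance volumes, chained 1 cm conformality rings, and the
   total target TPTV.
3. **Places beams** from the template (for the head-and-neck reference: six
   fields at gantry 75/15/148/218/285/345°), shares one isocenter at the
   TPTV centroid, fits jaws to the target projection + 8 mm, caps field
   width at 14.5 cm to avoid beam splitting, and fixes the posterior
   obliques' posterior jaw 20 mm from the axis.
4. **Optimizes fluence** against the template's objective list. Each
   objective is a one-sided quadratic voxel penalty (minimum dose, maximum
   dose, uniform dose) or a maximum-EUD penalty with
   EUD = (1/N Σᵢ dᵢᵃ)^(1/a); the weighted sum is minimized by monotone
   projected-gradient descent on the non-negative fluence orthant.
5. **Regional optimization** (the core method): converts isodose surfaces
   of the current dose into masks, segments **cold spots**
   (target − minimum-isodose region, e.g. `cold70 = modPTV70 − 70 Gy line`)
   and **hot spots** (isodose region − structures allowed to carry that
   dose, e.g. `hot63 = 69.3 Gy line − PTV70 − ring70`), injects
   high-priority objectives on them, and re-optimizes warm-started from
   the previous fluence — iterating until the spot volume stabilizes or a
   round cap is reached.
6. **Reports**: dose renormalized to the prescription point, DVH curves,
   per-ROI metrics (Dmax, Dmean, D95, V-levels), and a per-round spot
   report.

A seedable synthetic phantom generator (head-and-neck-like and generic
multi-level) makes the whole pipeline runnable without any clinical data.

## Worked example

```python
import autoimrt as ai

spec = ai.PhantomSpec(grid=ai.Grid((64, 64, 48), (4.0, 4.0, 4.0)), seed=1)
template = ai.bundled_template("hn6")
structures = ai.make_hn_phantom(spec)
result = ai.run_plan(structures, template, out_dir="plan_out")
```

The narrative scripts in `examples/` break this into stages. Running
`examples/04_regional_optimization.py` prints:

```
spots after the initial optimization:
  hot_out_70  (hot, 7000 cGy):   0.00 cc
  hot63       (hot, 6930 cGy):   0.00 cc
  hot56       (hot, 6160 cGy):   3.14 cc
  hot70       (hot, 7560 cGy):   8.90 cc
  cold70      (cold, 7000 cGy):  10.94 cc
  cold63      (cold, 6300 cGy):   2.43 cc
  cold56      (cold, 5600 cGy):   7.87 cc

per-round totals (volumes measured at round start):
  round 1: hot  12.03 cc, cold  21.25 cc, composite 6.473e+06
  round 2: hot   9.02 cc, cold  18.30 cc, composite 6.519e+06
  round 3: hot   8.64 cc, cold  18.24 cc, composite 6.423e+06
best round by composite: 3
total hot+cold volume: 33.28 cc after the initial plan -> 27.33 cc after the loop
```

Reading: after the initial optimization ~11 cc of the 70 Gy target sits
below its prescription and ~9 cc of tissue exceeds the 75.6 Gy global
ceiling; three regional rounds shrink the combined defect volume from
33.3 cc to 27.3 cc while the composite objective of the selected round is
the lowest seen.

The same workflow is available from the shell:

```bash
autoimrt phantom --site hn --seed 1 --out phantom_dir
autoimrt validate --structures phantom_dir --template hn6
autoimrt run --structures phantom_dir --template hn6 --out plan_dir
```

## Layout

- `src/autoimrt/roi_algebra.py` — grids, masks, Boolean algebra, Euclidean
  margins, isodose masks, DVHs
- `src/autoimrt/structures.py` — ROI validation and derivation recipes
- `src/autoimrt/beams.py` — beam geometry, jaw fitting, beamlet influence
- `src/autoimrt/objectives.py` — objective functions, gradients, optimizer
- `src/autoimrt/regional.py` — hot/cold spot segmentation and the loop
- `src/autoimrt/template.py`, `templates/` — class-solution templates
  (`hn6` reference, `generic3`)
- `src/autoimrt/pipeline.py`, `cli.py` — orchestration and the CLI
- `src/autoimrt/phantom.py` — synthetic structure-set generators
- `docs/methods.md` — models, parameters, numerical choices, limitations
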