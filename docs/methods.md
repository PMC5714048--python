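# Methods

This note documents the models behind `autoimrt`, the parameters that
matter, the numerical choices, and what the synthetic phantoms can and
cannot show. Everything quantitative stated here is computed by the test
suite or the example scripts; nothing is quoted from external runs.

## Geometry kernel

All structures are binary occupancy masks on one shared regular lattice
(axis order x = left–right, y = anterior–posterior, z = inferior–superior;
0-based indices; lengths in mm, doses in cGy — templates may write Gy,
converted on load). There is no resampling: masks and dose always live on
the planning grid, which matches how a scripted planning workflow operates
inside a single dose grid.

Margins use the voxel-centre Euclidean metric with anisotropic spacing,
evaluated by exact distance transforms (`scipy.ndimage.distance_transform_edt`):

- *expand(m, r)*: a voxel is in the result iff its centre lies within
  `r` mm of some occupied centre of `m` — always a superset of `m`.
- *contract(m, r)*: occupied voxels whose distance to the nearest
  unoccupied centre exceeds `r` — always a subset; contracting a mask to
  nothing is legal (it is logged by callers, not an error), because thin
  structures legitimately vanish under a 5 mm pullback.
- *ring(seeds, t, exclusions)* = expand(∪seeds, t) − ∪seeds − ∪exclusions.

Isodose masks use an **inclusive** threshold (dose ≥ level). This makes a
cold spot "target − prescription isodose" exclude voxels sitting exactly at
prescription, which is the intent of `cold70 = modPTV70 − 70 Gy line`; the
same convention is used on both hot and cold sides rather than mixing
strict/non-strict comparisons.

The margin semantics discretize: `expand(expand(m,a),b)` can exceed
`expand(m,a+b)` by up to half a voxel diagonal, so only the containment
direction is asserted in tests.

One interpretation worth flagging: the derived structure glossed as
"body contour with a 5 mm margin" is implemented as the **inward**
contraction of the body contour, since its purpose is to keep the modPTVs
5 mm away from the skin (an outward margin would be meaningless for that).

## Derived structures

Recipes are declarative and evaluated strictly in declaration order;
forward references are errors rather than auto-resolved, which keeps a
template's dependency structure readable and makes derivation
deterministic and idempotent. ROI names are matched case-insensitively
with spaces/underscores ignored ("rt parotid opt" ≡ `rt_parotid_opt`),
because real structure sets and published tables mix these freely.

The reference head-and-neck template derives, per prescription level:
PTV = CTV + 5 mm (the CTV→PTV margin is a template parameter, since the
class solution presumes protocol-level margins); `modPTV` = PTV ∩
contract(external, 5 mm) − cord_prv − brainstem_prv;
`optPTV_lower` = modPTV_lower − modPTV_higher; and `optPTV_lower_m` =
modPTV_lower − expand(modPTV_higher, 10 mm) — the latter interpreted as a
1 cm dose-gradient buffer on which the uniform-dose objectives act.
The parotid-avoidance volumes subtract the un-expanded TPTV (no margin is
specified for them in the source configuration; the no-margin reading is
the conservative one and is noted here as an open choice). Ring chaining:
`ring70` around PTV70; `ring63` around {ring70, PTV63} excluding PTV70;
lower rings exclude all higher targets and rings so that every ring is
disjoint from everything it is meant to constrain.

## Beam model

Beams carry an orthonormal frame (u, v, w): w is the central axis, u/v the
jaw axes in the isocentric plane. Couch rotation (about the vertical y
axis) is composed before gantry rotation (about z); the collimator spins
u/v about w. The order is fixed and IEC-like; exact clinical IEC
compliance is not claimed (nothing downstream depends on the convention,
only on its consistency).

Jaw fitting projects the target's voxel centres into the isocentric plane
and opens the jaws to the projection plus a margin (default 8 mm). If the
x-width would exceed the template's cap (14.5 cm for the anterior
obliques — the beam-splitting limit), the width is clamped keeping the
template-named edge flush, so the field edge stays exactly on the side
where a high dose gradient is wanted (the target–parotid boundary); the
sacrificed side is logged. Per-beam jaw overrides (the posterior obliques'
posterior jaw at 20 mm) are applied last. Jaws are fitted once at plan
build and never re-fitted after structure edits, mirroring the fixed-jaw
policy of the source workflow ("reduce the local-minimum problem").

### Dose-influence model (declared simplification)

The clinical collapsed-cone engine is out of scope. The influence of a
beamlet of unit intensity at a voxel inside the body contour is

    D = exp(−μ · depth) · exp(−r² / (2σ²))

with `depth` the path length through the body upstream of the voxel along
the beam axis (parallel geometry, no divergence), `r` the lateral distance
from the beamlet ray, and zero dose outside the body. Defaults, all
template-overridable and *not* presented as clinically accurate:

| parameter | default | meaning |
|---|---|---|
| μ | 0.005 /mm | effective linear attenuation (water-like order) |
| σ | 3 mm | lateral Gaussian spread (penumbra surrogate) |
| beamlet size | 5 mm | fluence-map resolution in the isocentric plane |

The kernel is truncated at 3σ laterally and stored as a sparse
voxel-by-beamlet matrix (float32). Depth is accumulated on an auxiliary
lattice aligned with the beam frame (step = the smallest grid spacing,
nearest-neighbour resampling, depth counted over cells strictly upstream
so a ray's first occupied cell has depth 0). Beamlets whose ray misses the
body are flagged inert and pinned at zero intensity. The model preserves
what matters for studying the optimization workflow — linearity in
fluence, depth attenuation, lateral falloff, beam's-eye-view geometry —
and none of what does not (heterogeneity, scatter, MU calibration,
deliverability/MLC segmentation).

## Objectives and optimizer

The clinical system's objective functionals are proprietary; the standard
open form is used and documented as a substitution: one-sided quadratic
voxel penalties normalized by ROI voxel count, scalarized by the published
weights,

- min dose:     w · mean(max(0, D − d)²)
- max dose:     w · mean(max(0, d − D)²)
- uniform dose: w · mean((d − D)²)
- max EUD:      w · max(0, EUD − D)², EUD = (mean dᵃ)^{1/a}

The published parotid EUD row prints dose and weight but no exponent;
this template uses a = 1 (mean dose), the standard surrogate for a
parallel organ like the parotid. For a < 1 the voxel dose inside the power
mean is floored at 0.1 cGy so the mean and its gradient stay finite at
zero dose; the EUD itself is evaluated in normalized form
(max · mean((d/max)^a)^{1/a}) to avoid overflow at large a.

Fluence is optimized by projected gradient descent on x ≥ 0 with
Barzilai–Borwein step proposals and Armijo backtracking; only steps that
decrease the composite are accepted, so the objective trace is monotone
non-increasing by construction. Gradients are exact (chain rule through
the sparse influence matrix) and verified against central finite
differences in the suite. Initialization is deterministic — uniform
fluence scaled so the mean dose over the minimum-dose ROIs reaches the
highest such target — so the entire pipeline is reproducible without
seeds. Convergence: relative objective change below 1e-6 or the iteration
cap (template default 200 for the initial solve — these projected-gradient
iterations are far cheaper than a DMPO iteration, so the count is a
package choice — and 20 per regional pass, as published for the regional
re-optimization).

The published re-optimization constraint (only MLC segment shapes and
weights re-optimized) is approximated by warm-starting the fluence from
the previous solution, with no variable freezing: aperture optimization is
out of scope, and the warm start preserves the "continue from the current
plan" character of the step.

## Regional optimization

Each round: (1) compute dose from the current fluence; (2) segment every
rule's spot — cold = base ROI minus its minimum isodose region, hot =
isodose region minus the subtraction list; (3) **replace** the previous
round's regional objectives with the current spots' (spots are recomputed
from scratch each round; accumulating stale geometry would mislead the
optimizer); empty spots are skipped with a log line, not errors — a
well-covered plan legitimately has no cold spots; (4) re-optimize
warm-started.

The source workflow iterates "until an optimal plan is achieved" without a
stated criterion, so termination is a design choice here: round cap 3,
early stop when the relative change of the total hot+cold volume between
consecutive rounds falls below 0.05 (or the spots vanish entirely), and
the returned plan is the round with the lowest final composite. Hot/cold
isodose levels are stored as absolute cGy in the template (6930 = 110% of
63 Gy, 6160 = 110% of 56 Gy, 7560 = 108% of the 70 Gy prescription).

**Known property of weighted-sum regional re-optimization:** layering
high-weight regional objectives onto a converged plan shifts the
optimizer's equilibrium, so the *base* objective set evaluated alone can
end somewhat higher after the loop even as the spot volumes shrink — the
regional terms buy coverage/conformality in the spots at the cost of the
OAR and ring terms that previously balanced them. The suite therefore
asserts what the method claims: spot volumes strictly decrease on the
bundled phantom, the loop terminates within its cap, and each individual
warm-started optimization never ends above its own starting value.

## Prescription and reporting

The point-prescription concept (dose to a reference point at the target
centre) is modeled as post-hoc renormalization: after the loop, the
fluence is scaled so the reference ROI's centre voxel (the occupied voxel
nearest its centroid) receives the prescription dose. Optimization and
spot generation run in absolute cGy — the objective doses already pin the
plan near prescription — and only the reported dose/DVH/metrics are
renormalized; there is no MU model.

DVHs are cumulative (fraction of ROI volume receiving at least each dose
edge; default bin 25 cGy for reports). D95 is the 5th percentile of ROI
voxel doses; V(level) the fraction at or above the level; volumes in cc
from the voxel volume. Saved plans re-verify that stored metrics equal a
recomputation from the stored dose and masks.

## Synthetic phantoms

The head-and-neck phantom emulates the *topology* that stresses this
workflow: three nested target levels (the lowest extended laterally to
abut the parotid regions, creating the classic target–parotid trade-off),
a posterior serial organ (cord) with a superior brainstem, lateral parotid
ellipsoids, mandible arc, larynx, oral cavity, cochleae, inside an
elliptic-cylinder body. Defaults: 128×128×96 grid at 2 mm isotropic
(desk-scale runtime for the full pipeline), organ-centre jitter ±3 mm
drawn from a single seeded generator with fixed placement order (same seed
→ bit-identical masks; organs violating the 5 mm body clearance are
redrawn with bounded retries). The generic phantom nests 1–3 concentric
targets with two lateral OARs for the multi-level pattern of other sites.

What passing tests on these phantoms show: the machinery — derivation
algebra, beam fitting, optimizer correctness, spot segmentation, loop
behaviour — is sound on anatomically-shaped inputs. What they do not
show: performance on real patient geometry, with a real dose engine, or
any clinical dose-accuracy claim; the phantoms have no CT intensities,
no heterogeneity, and idealized convex-ish organs.

## Degenerate inputs and numerical edges

- Empty expansion input → empty output (not an error); contraction may
  empty a mask (allowed, logged by callers).
- Empty ROI under an *initial* objective is an error naming the ROI;
  under a *regional* objective it contributes zero (spots may be empty).
- Isocenter snapping resolves distance ties toward the lower voxel index.
- Non-finite composite values abort the optimizer with diagnostics.
- Inert beamlets (no body intersection) are excluded from optimization.
- The influence builder's nearest-neighbour depth lookup is exact when
  the beam frame aligns with the grid (the closed-form slab test) and
  within one lattice step otherwise.

## Limitations

No MLC/aperture model, no deliverability constraints, no heterogeneity or
scatter, no DICOM-RT, no multi-grid resampling, no interactive tweaking.
Only structurally-generic templates ship besides the head-and-neck
reference; site templates for e.g. pelvic-node sites can be written with
the same mechanism but are not provided as validated configurations.
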