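"""Place the class-solution beams and build the beamlet dose operator.

The six-field head-and-neck arrangement is instantiated against the
phantom's total PTV: one shared isocenter, jaws fitted to the target
projection with an 8 mm margin, the anterior obliques width-capped at
14.5 cm (the beam-splitting limit), and the posterior obliques' posterior
jaw fixed 20 mm from the central axis.
"""

import numpy as np

import autoimrt as ai

spec = ai.PhantomSpec(grid=ai.Grid((64, 64, 48), (4.0, 4.0, 4.0)), seed=1)
derived = ai.derive_structures(ai.make_hn_phantom(spec),
                               ai.bundled_template("hn6").recipes)
template = ai.bundled_template("hn6")

log = []
beams = ai.build_beams(template.beams, derived["TPTV"], log=log)
print(f"isocenter (mm): {beams[0].isocenter_mm}")
print(f"{'beam':<6}{'gantry':>7}{'coll':>6}{'couch':>7}{'x-width':>9}{'y-width':>9}")
for b in beams:
    print(f"{b.name:<6}{b.gantry_deg:>7.0f}{b.collimator_deg:>6.0f}"
          f"{b.couch_deg:>7.0f}{b.jaws.width:>9.1f}{b.jaws.height:>9.1f}")
for line in log:
    print("  note:", line)

A = ai.compute_influence(beams, derived.grid, derived["external"],
                         model=template.dose_model)
print(f"\ninfluence operator: {A.matrix.shape[0]} voxels x {A.n_beamlets} beamlets, "
      f"{A.matrix.nnz} nonzeros ({A.inert.sum()} inert beamlets)")

# uniform unit fluence: the raw (unoptimized) dose pattern
d = ai.total_dose(A, np.where(A.inert, 0.0, 1.0))
print(f"uniform-fluence dose: max {d.max():.2f} cGy/intensity-unit inside the body")
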