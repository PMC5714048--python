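"""Generate a synthetic head-and-neck structure set and derive the
optimization structures a class solution needs.

The phantom provides only the "clinician-drawn" inputs (CTVs, organs at
risk, body contour); everything else — PTVs, planning risk volumes,
skin-trimmed modPTVs, overlap-free optPTVs, conformality rings — is
produced by the template's derivation recipes.
"""

import autoimrt as ai

# 4 mm grid keeps this demo instant; the default phantom grid is 2 mm
spec = ai.PhantomSpec(grid=ai.Grid((64, 64, 48), (4.0, 4.0, 4.0)), seed=1)
structures = ai.make_hn_phantom(spec)
template = ai.bundled_template("hn6")

report = ai.validate_required(structures, template.required_rois)
print(report.summary())

derived = ai.derive_structures(structures, template.recipes)
print(f"{len(structures.names())} input ROIs -> {len(derived.names())} after derivation\n")
print(f"{'ROI':<16}{'voxels':>8}{'volume (cc)':>14}  provenance")
for name in ["CTV70", "PTV70", "modPTV70", "optPTV63", "TPTV", "cord_prv",
             "ring70", "ring63", "lt_parotid_opt"]:
    m = derived[name]
    print(f"{name:<16}{m.n_voxels:>8}{m.volume_cc:>14.1f}  {derived.provenance[m.name]}")

# the derived volumes respect the recipe semantics, e.g. optPTV63 avoids
# the higher-prescription modPTV70 entirely:
overlap = ai.intersect(derived["optPTV63"], derived["modPTV70"])
print(f"\noptPTV63 ∩ modPTV70 voxels: {overlap.n_voxels} (always 0 by construction)")
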