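"""The complete automated workflow in one call, plus its CLI equivalent.

run_plan chains validation -> derivation -> beams -> influence -> initial
optimization -> regional loop -> prescription renormalization -> report,
and writes every artifact (structures, dose volume, DVH table, metrics,
per-round spot report, log) to the output directory.

Shell equivalent:
    autoimrt phantom --site hn --seed 1 --out phantom_dir
    autoimrt run --structures phantom_dir --template hn6 --out plan_dir
"""

import tempfile
from pathlib import Path

import autoimrt as ai

spec = ai.PhantomSpec(grid=ai.Grid((64, 64, 48), (4.0, 4.0, 4.0)), seed=1)
structures = ai.make_hn_phantom(spec)
template = ai.bundled_template("hn6")

out = Path(tempfile.mkdtemp(prefix="autoimrt_plan_"))
result = ai.run_plan(structures, template, out_dir=out)

print(f"artifacts in {out}:")
for p in sorted(out.iterdir()):
    print("  ", p.name)

print(f"\nprescription renormalization factor: {result.renorm_factor:.4f}")
print("selected plan metrics (after renormalization to 7000 cGy at the "
      "CTV70 reference voxel):")
cols = ["roi", "volume_cc", "Dmean_cGy", "Dmax_cGy", "D95_cGy"]
sel = result.metrics[result.metrics.roi.isin(
    ["CTV70", "modPTV70", "optPTV63", "cord", "brain_stem", "lt_parotid"])]
print(sel[cols].to_string(index=False, float_format=lambda v: f"{v:.1f}"))
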