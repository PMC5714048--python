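"""Structure sets: required-ROI validation and derived-contour generation.

A class-solution template assumes clinicians delineate only the basic
anatomy (CTVs, organs at risk, the body contour). Everything the optimizer
actually works on — planning risk volumes, skin-trimmed modPTVs,
overlap-free optPTVs, conformality rings, parotid-avoidance volumes — is
derived here from declarative recipes evaluated in order.

ROI names are matched case-insensitively with spaces and underscores
ignored, so "rt parotid opt", "rt_parotid_opt" and "RT_Parotid_Opt" all
refer to the same structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import roi_algebra as ra
from .roi_algebra import Grid, Mask


class DerivationError(ValueError):
    """A recipe referenced an undefined operand or collided on a name."""


def canonical(name: str) -> str:
    """Normalized lookup key: lower-case, underscores/spaces stripped."""
    return name.lower().replace("_", "").replace(" ", "")


@dataclass
class ValidationReport:
    missing: list[str]
    present: list[str]

    @property
    def passed(self) -> bool:
        return not self.missing

    def summary(self) -> str:
        if self.passed:
            return f"all {len(self.present)} required ROIs present"
        return "missing required ROIs: " + ", ".join(self.missing)


@dataclass
class DerivationRecipe:
    """One derived-structure rule.

    operation:
        expand           — operands[0] grown by margin_mm (PTVs from CTVs,
                           PRVs from serial OARs)
        contract_external— operands[0] shrunk inward by margin_mm (the
                           "external 5mm" skin-avoidance shell)
        mod_ptv          — operands[0] ∩ operands[1] minus operands[2:]
                           (PTV kept inside the trimmed external, excluding
                           the PRVs)
        opt_ptv          — operands[0] minus operands[1:] (lower-dose PTV
                           avoiding the higher-dose ones)
        opt_ptv_margin   — operands[0] minus expand(operands[i], margin_mm)
                           for each higher-dose operand (gradient buffer)
        avoid_ptv        — operands[0] minus operands[1:] (e.g. parotid
                           avoiding the total PTV)
        union_all        — union of all operands (TPTV)
        ring             — shell of thickness margin_mm around the union of
                           operands, excluding the operands themselves and
                           every ROI in `exclude`
    """

    output_name: str
    operation: str
    operands: list[str]
    margin_mm: float = 0.0
    exclude: list[str] = field(default_factory=list)


_OPERATIONS = {
    "expand",
    "contract_external",
    "mod_ptv",
    "opt_ptv",
    "opt_ptv_margin",
    "avoid_ptv",
    "union_all",
    "ring",
}


class StructureSet:
    """Named masks on one grid, with input/derived provenance."""

    def __init__(self, grid: Grid):
        self.grid = grid
        self._rois: dict[str, Mask] = {}
        self._display: dict[str, str] = {}
        self.provenance: dict[str, str] = {}

    # -- mapping-style access (canonical-name keyed) ---------------------
    def add(self, mask: Mask, provenance: str = "input", replace: bool = False) -> None:
        if mask.grid != self.grid:
            raise ra.GeometryError(f"ROI '{mask.name}' is not on the structure-set grid")
        key = canonical(mask.name)
        if key in self._rois and not replace:
            raise DerivationError(f"ROI name collision: '{mask.name}'")
        self._rois[key] = mask
        self._display[key] = mask.name
        self.provenance[mask.name] = provenance

    def __contains__(self, name: str) -> bool:
        return canonical(name) in self._rois

    def __getitem__(self, name: str) -> Mask:
        key = canonical(name)
        if key not in self._rois:
            raise KeyError(f"no ROI named '{name}' in structure set")
        return self._rois[key]

    def get(self, name: str) -> Mask | None:
        return self._rois.get(canonical(name))

    def names(self) -> list[str]:
        return [self._display[k] for k in self._rois]

    def masks(self) -> list[Mask]:
        return list(self._rois.values())

    def copy(self) -> "StructureSet":
        out = StructureSet(self.grid)
        for key, mask in self._rois.items():
            out._rois[key] = mask
            out._display[key] = self._display[key]
        out.provenance = dict(self.provenance)
        return out


def validate_required(s: StructureSet, required: list[str]) -> ValidationReport:
    """Check that every required ROI is present; never raises.

    The orchestrator halts the pipeline when ``passed`` is false and shows
    the missing names so the user can add or rename structures.
    """
    if not required:
        raise ValueError("required ROI list must be non-empty")
    missing = [name for name in required if name not in s]
    present = [name for name in required if name in s]
    return ValidationReport(missing=missing, present=present)


def _resolve(s: StructureSet, recipe: DerivationRecipe, names: list[str]) -> list[Mask]:
    masks = []
    for n in names:
        m = s.get(n)
        if m is None:
            raise DerivationError(
                f"recipe '{recipe.output_name}' references undefined ROI '{n}'"
            )
        masks.append(m)
    return masks


def apply_recipe(s: StructureSet, recipe: DerivationRecipe) -> Mask:
    """Evaluate one recipe against the current structure set."""
    op = recipe.operation
    if op not in _OPERATIONS:
        raise DerivationError(f"recipe '{recipe.output_name}': unknown operation '{op}'")
    ops = _resolve(s, recipe, recipe.operands)
    out_name = recipe.output_name

    if op == "expand":
        return ra.expand(ops[0], recipe.margin_mm, name=out_name)
    if op == "contract_external":
        return ra.contract(ops[0], recipe.margin_mm, name=out_name)
    if op == "mod_ptv":
        if len(ops) < 2:
            raise DerivationError(f"mod_ptv '{out_name}' needs a PTV and a trimmed external")
        result = ra.intersect(ops[0], ops[1], name=out_name)
        for prv in ops[2:]:
            result = ra.subtract(result, prv, name=out_name)
        return result
    if op in ("opt_ptv", "avoid_ptv"):
        result = ops[0].with_name(out_name)
        for higher in ops[1:]:
            result = ra.subtract(result, higher, name=out_name)
        return result
    if op == "opt_ptv_margin":
        result = ops[0].with_name(out_name)
        for higher in ops[1:]:
            result = ra.subtract(result, ra.expand(higher, recipe.margin_mm), name=out_name)
        return result
    if op == "union_all":
        return ra.union_all(ops, out_name)
    if op == "ring":
        exclusions = _resolve(s, recipe, recipe.exclude)
        return ra.make_ring(ops, recipe.margin_mm, exclusions, name=out_name)
    raise AssertionError("unreachable")


def derive_structures(s: StructureSet, recipes: list[DerivationRecipe]) -> StructureSet:
    """Evaluate recipes in declaration order on a copy of ``s``.

    Forward references are errors: each recipe may only use input ROIs or
    outputs of earlier recipes. Derivation is deterministic and idempotent.
    """
    out = s.copy()
    for recipe in recipes:
        if recipe.output_name in out:
            raise DerivationError(
                f"recipe output '{recipe.output_name}' collides with an existing ROI"
            )
        out.add(apply_recipe(out, recipe), provenance="derived")
    return out


def provenance_sidecar(s: StructureSet, recipes: list[DerivationRecipe]) -> list[dict]:
    """JSON-serializable record of how each derived ROI was produced."""
    return [
        {
            "name": r.output_name,
            "operation": r.operation,
            "operands": list(r.operands),
            "exclude": list(r.exclude),
            "margin_mm": r.margin_mm,
        }
        for r in recipes
        if r.output_name in s
    ]
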