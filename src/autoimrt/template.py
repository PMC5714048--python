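"""Plan templates: the machine-readable class solution.

A template is a YAML document bundling everything a site's class solution
fixes across patients: the required input ROIs, the derivation recipes for
optimization structures, the beam arrangement with jaw-fitting policy, the
prescription, the initial objective list, the hot/cold spot rules with
their regional objectives, and optimizer/termination settings.

Doses may be written in cGy (``dose_cGy``, ``iso_level_cGy``) or Gy
(``dose_Gy``, ``iso_level_Gy``); everything is normalized to cGy on load.
Lengths are mm throughout.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .beams import BeamSpec, DoseModel
from .objectives import OBJECTIVE_KINDS, ObjectiveSpec, OptimizerParams
from .regional import HotColdRule, RegionalObjectiveSpec, TerminationPolicy
from .structures import DerivationRecipe, canonical


class TemplateError(ValueError):
    """Schema violation, with the offending field path in the message."""


@dataclass
class Prescription:
    dose_cGy: float
    fractions: int
    reference_roi: str  # ROI whose centre voxel receives the prescription

    def __post_init__(self) -> None:
        if self.dose_cGy <= 0:
            raise TemplateError("prescription.dose_cGy must be positive")
        if self.fractions < 1:
            raise TemplateError("prescription.fractions must be >= 1")


@dataclass
class PlanTemplate:
    site_name: str
    required_rois: list[str]
    recipes: list[DerivationRecipe]
    beams: list[BeamSpec]
    prescription: Prescription
    initial_objectives: list[ObjectiveSpec]
    hotcold_rules: list[HotColdRule]
    regional_objectives: list[RegionalObjectiveSpec]
    initial_opt: OptimizerParams
    regional_opt: OptimizerParams
    termination: TerminationPolicy
    dose_model: DoseModel = field(default_factory=DoseModel)
    dvh_levels_cGy: list[float] = field(default_factory=list)
    roi_colors: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._check_cross_references()

    def known_roi_names(self) -> set[str]:
        names = {canonical(n) for n in self.required_rois}
        names |= {canonical(r.output_name) for r in self.recipes}
        names |= {canonical(r.name) for r in self.hotcold_rules}
        return names

    def _check_cross_references(self) -> None:
        known = self.known_roi_names()

        def check(name: str, where: str) -> None:
            if canonical(name) not in known:
                raise TemplateError(f"{where} references ROI '{name}' that is neither "
                                    "required nor derived")

        for i, r in enumerate(self.recipes):
            for n in list(r.operands) + list(r.exclude):
                check(n, f"derivations[{i}] ({r.output_name})")
        for i, o in enumerate(self.initial_objectives):
            check(o.roi, f"objectives[{i}]")
        rule_names = {canonical(r.name) for r in self.hotcold_rules}
        for i, r in enumerate(self.hotcold_rules):
            if r.base_roi:
                check(r.base_roi, f"hotcold_rules[{i}] ({r.name})")
            for n in r.subtract:
                check(n, f"hotcold_rules[{i}] ({r.name})")
        for i, ro in enumerate(self.regional_objectives):
            if canonical(ro.rule_name) not in rule_names:
                raise TemplateError(
                    f"regional_objectives[{i}] references unknown rule '{ro.rule_name}'"
                )
        check(self.prescription.reference_roi, "prescription.reference")
        if not self.beams:
            raise TemplateError("beams: template defines no beams")


def _dose_value(entry: dict, base: str, where: str, required: bool = True) -> float | None:
    """Read a dose field given in cGy or Gy, normalized to cGy."""
    if f"{base}_cGy" in entry:
        return float(entry[f"{base}_cGy"])
    if f"{base}_Gy" in entry:
        return float(entry[f"{base}_Gy"]) * 100.0
    if required:
        raise TemplateError(f"{where}: missing {base}_cGy (or {base}_Gy)")
    return None


def _section(doc: dict, key: str, kind: type) -> object:
    if key not in doc:
        raise TemplateError(f"template missing section '{key}'")
    value = doc[key]
    if not isinstance(value, kind):
        raise TemplateError(f"section '{key}' must be a {kind.__name__}")
    return value


def template_from_dict(doc: dict) -> PlanTemplate:
    site = doc.get("site", "unnamed")
    required = list(_section(doc, "required_rois", list))

    recipes = []
    for i, entry in enumerate(_section(doc, "derivations", list)):
        where = f"derivations[{i}]"
        try:
            recipes.append(
                DerivationRecipe(
                    output_name=entry["name"],
                    operation=entry["op"],
                    operands=list(entry.get("of", [])),
                    margin_mm=float(entry.get("margin_mm", 0.0)),
                    exclude=list(entry.get("exclude", [])),
                )
            )
        except KeyError as k:
            raise TemplateError(f"{where}: missing field {k}") from None

    beams = []
    for i, entry in enumerate(_section(doc, "beams", list)):
        where = f"beams[{i}]"
        try:
            beams.append(
                BeamSpec(
                    name=entry["name"],
                    gantry_deg=float(entry["gantry"]) % 360.0,
                    couch_deg=float(entry.get("couch", 0.0)) % 360.0,
                    collimator_deg=float(entry.get("collimator", 0.0)) % 360.0,
                    margin_mm=float(entry.get("margin_mm", 8.0)),
                    max_width_mm=(float(entry["max_width_mm"])
                                  if entry.get("max_width_mm") is not None else None),
                    coverage_side=entry.get("coverage", "both"),
                    jaw_overrides={k: float(v)
                                   for k, v in (entry.get("jaw_overrides") or {}).items()},
                )
            )
        except KeyError as k:
            raise TemplateError(f"{where}: missing field {k}") from None
        if beams[-1].coverage_side not in ("both", "left_edge", "right_edge"):
            raise TemplateError(f"{where}: bad coverage '{beams[-1].coverage_side}'")

    p = _section(doc, "prescription", dict)
    ref = p.get("reference", {})
    if not isinstance(ref, dict) or "roi_center" not in ref:
        raise TemplateError("prescription.reference must give roi_center")
    prescription = Prescription(
        dose_cGy=_dose_value(p, "dose", "prescription"),
        fractions=int(p.get("fractions", 0)),
        reference_roi=ref["roi_center"],
    )

    objectives = []
    for i, entry in enumerate(_section(doc, "objectives", list)):
        where = f"objectives[{i}]"
        kind = entry.get("kind")
        if kind not in OBJECTIVE_KINDS:
            raise TemplateError(f"{where}: unknown objective kind '{kind}'")
        objectives.append(
            ObjectiveSpec(
                roi=entry["roi"], kind=kind,
                dose_cGy=_dose_value(entry, "dose", where),
                weight=float(entry.get("weight", 1.0)),
                eud_a=(float(entry["eud_a"]) if "eud_a" in entry else None),
                tag="initial",
            )
        )

    rules = []
    for i, entry in enumerate(doc.get("hotcold_rules", []) or []):
        where = f"hotcold_rules[{i}]"
        rules.append(
            HotColdRule(
                name=entry["name"], polarity=entry["polarity"],
                iso_level_cGy=_dose_value(entry, "iso_level", where),
                base_roi=entry.get("base"),
                subtract=list(entry.get("subtract", [])),
            )
        )

    regional = []
    for i, entry in enumerate(doc.get("regional_objectives", []) or []):
        where = f"regional_objectives[{i}]"
        kind = entry.get("kind")
        if kind not in OBJECTIVE_KINDS:
            raise TemplateError(f"{where}: unknown objective kind '{kind}'")
        regional.append(
            RegionalObjectiveSpec(
                rule_name=entry["rule"], kind=kind,
                dose_cGy=_dose_value(entry, "dose", where),
                weight=float(entry.get("weight", 1.0)),
            )
        )

    opt = doc.get("optimizer", {}) or {}
    initial_opt = OptimizerParams(
        max_iterations=int(opt.get("initial_iterations", 200)),
        convergence_tol=float(opt.get("convergence_tol", 1e-6)),
    )
    regional_opt = OptimizerParams(
        max_iterations=int(opt.get("regional_iterations", 20)),
        convergence_tol=float(opt.get("convergence_tol", 1e-6)),
    )

    term = doc.get("termination", {}) or {}
    termination = TerminationPolicy(
        max_rounds=int(term.get("max_rounds", 3)),
        min_relative_spot_change=float(term.get("min_relative_spot_change", 0.05)),
    )

    dm = doc.get("dose_model", {}) or {}
    dose_model = DoseModel(
        mu_per_mm=float(dm.get("mu_per_mm", DoseModel().mu_per_mm)),
        sigma_mm=float(dm.get("sigma_mm", DoseModel().sigma_mm)),
        beamlet_size_mm=float(dm.get("beamlet_size_mm", DoseModel().beamlet_size_mm)),
    )

    return PlanTemplate(
        site_name=site,
        required_rois=required,
        recipes=recipes,
        beams=beams,
        prescription=prescription,
        initial_objectives=objectives,
        hotcold_rules=rules,
        regional_objectives=regional,
        initial_opt=initial_opt,
        regional_opt=regional_opt,
        termination=termination,
        dose_model=dose_model,
        dvh_levels_cGy=[float(x) for x in doc.get("dvh_levels_cGy", [])],
        roi_colors=dict(doc.get("roi_colors", {}) or {}),
    )


def template_to_dict(t: PlanTemplate) -> dict:
    return {
        "site": t.site_name,
        "required_rois": list(t.required_rois),
        "derivations": [
            {"name": r.output_name, "op": r.operation, "of": list(r.operands),
             "margin_mm": r.margin_mm, "exclude": list(r.exclude)}
            for r in t.recipes
        ],
        "beams": [
            {"name": b.name, "gantry": b.gantry_deg, "collimator": b.collimator_deg,
             "couch": b.couch_deg, "margin_mm": b.margin_mm,
             "max_width_mm": b.max_width_mm, "coverage": b.coverage_side,
             "jaw_overrides": dict(b.jaw_overrides)}
            for b in t.beams
        ],
        "prescription": {"dose_cGy": t.prescription.dose_cGy,
                         "fractions": t.prescription.fractions,
                         "reference": {"roi_center": t.prescription.reference_roi}},
        "objectives": [
            {k: v for k, v in
             [("roi", o.roi), ("kind", o.kind), ("dose_cGy", o.dose_cGy),
              ("weight", o.weight), ("eud_a", o.eud_a)] if v is not None}
            for o in t.initial_objectives
        ],
        "hotcold_rules": [
            {k: v for k, v in
             [("name", r.name), ("polarity", r.polarity),
              ("iso_level_cGy", r.iso_level_cGy), ("base", r.base_roi),
              ("subtract", list(r.subtract))] if v not in (None, [])}
            for r in t.hotcold_rules
        ],
        "regional_objectives": [
            {"rule": r.rule_name, "kind": r.kind, "dose_cGy": r.dose_cGy,
             "weight": r.weight}
            for r in t.regional_objectives
        ],
        "optimizer": {"initial_iterations": t.initial_opt.max_iterations,
                      "regional_iterations": t.regional_opt.max_iterations,
                      "convergence_tol": t.initial_opt.convergence_tol},
        "termination": {"max_rounds": t.termination.max_rounds,
                        "min_relative_spot_change": t.termination.min_relative_spot_change},
        "dose_model": {"mu_per_mm": t.dose_model.mu_per_mm,
                       "sigma_mm": t.dose_model.sigma_mm,
                       "beamlet_size_mm": t.dose_model.beamlet_size_mm},
        "dvh_levels_cGy": list(t.dvh_levels_cGy),
        "roi_colors": dict(t.roi_colors),
    }


def load_template(path: str | Path) -> PlanTemplate:
    """Parse and fully validate a template file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise TemplateError(f"template {path} is not a mapping")
    return template_from_dict(doc)


def save_template(t: PlanTemplate, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(template_to_dict(t), fh, sort_keys=False)


def bundled_template(name: str) -> PlanTemplate:
    """Load a template shipped with the package (``hn6`` or ``generic3``)."""
    res = importlib.resources.files("autoimrt") / "templates" / f"{name}.yaml"
    if not res.is_file():
        raise TemplateError(f"no bundled template named '{name}'")
    return template_from_dict(yaml.safe_load(res.read_text()))
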