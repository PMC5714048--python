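"""End-to-end plan orchestration: the class-solution workflow.

``run_plan`` executes the fixed stage order — required-ROI validation,
derived-structure generation, beam build, influence computation, initial
fluence optimization, iterative regional optimization, prescription
renormalization, reporting — and there is no public entry point that skips
a stage. Each stage error is re-raised with the stage name attached.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from . import roi_algebra as ra
from .beams import InfluenceMatrix, build_beams, compute_influence, total_dose
from .objectives import ObjectiveSpec, OptResult, composite, optimize_fluence
from .regional import RegionalReport, regional_loop, spot_volumes_cc, generate_hotcold
from .roi_algebra import DoseGrid, DVHCurve, Mask
from .structures import StructureSet, derive_structures, validate_required, ValidationReport
from .template import PlanTemplate


class ValidationFailure(RuntimeError):
    """Pipeline halted because required ROIs are missing."""

    def __init__(self, report: ValidationReport):
        super().__init__(report.summary())
        self.report = report


class StageError(RuntimeError):
    """Any stage failure, annotated with the stage name."""


@dataclass
class PlanResult:
    template_site: str
    fluence: np.ndarray
    dose: DoseGrid
    structures: StructureSet
    dvhs: dict[str, DVHCurve]
    metrics: pd.DataFrame
    regional_report: RegionalReport | None
    initial_result: OptResult
    final_result: OptResult
    renorm_factor: float
    validation: ValidationReport
    log: list[str] = field(default_factory=list)

    def save(self, out_dir: str | Path, roi_colors: dict[str, str] | None = None) -> None:
        """Write all artifacts; verifies metric self-consistency first."""
        recomputed = plan_metrics(self.dose, self.structures,
                                  levels_cGy=_metric_levels(self.metrics))
        if not _metrics_equal(self.metrics, recomputed):
            raise StageError("stored metrics disagree with dose recomputation")
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        aio.write_structure_set(self.structures, out / "structures")
        aio.write_dose(self.dose, out / "dose.nii.gz")
        dvh_frame(self.dvhs).to_csv(out / "dvh.csv", index=False)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        with open(out / "metrics.json", "w") as fh:
            json.dump(self.metrics.replace({np.nan: None}).to_dict(orient="records"), fh, indent=1)
        if self.regional_report is not None:
            rounds_frame(self.regional_report).to_csv(out / "rounds.csv", index=False)
        with open(out / "plan.log", "w") as fh:
            fh.write("\n".join(self.log) + "\n")
        if roi_colors:
            # cosmetic display settings only; never read back by computation
            with open(out / "display.json", "w") as fh:
                json.dump({"roi_colors": roi_colors}, fh, indent=1)


def dvh_frame(dvhs: dict[str, DVHCurve]) -> pd.DataFrame:
    rows = [
        {"roi": name, "dose_cGy": float(e), "volume_fraction": float(v)}
        for name, curve in dvhs.items()
        for e, v in zip(curve.dose_edges, curve.volume_fraction)
    ]
    return pd.DataFrame(rows, columns=["roi", "dose_cGy", "volume_fraction"])


def rounds_frame(report: RegionalReport) -> pd.DataFrame:
    rows = []
    for rec in report.rounds:
        for roi, vol in rec.spot_volumes_cc_by_roi.items():
            rows.append({"round": rec.round, "roi": roi, "volume_cc": vol,
                         "composite": rec.composite})
    return pd.DataFrame(rows, columns=["round", "roi", "volume_cc", "composite"])


def _metric_levels(metrics: pd.DataFrame) -> list[float]:
    return [float(c[1:-4]) for c in metrics.columns if c.startswith("V") and c.endswith("_cGy")]


def _metrics_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for col in a.columns:
        x, y = a[col].to_numpy(), b[col].to_numpy()
        if col == "roi":
            if not (x == y).all():
                return False
        else:
            x = x.astype(float)
            y = y.astype(float)
            both_nan = np.isnan(x) & np.isnan(y)
            if not np.all(both_nan | np.isclose(x, y, rtol=1e-9, atol=1e-9, equal_nan=True)):
                return False
    return True


def plan_metrics(d: DoseGrid, s: StructureSet, levels_cGy: list[float] | None = None) -> pd.DataFrame:
    """Per-ROI dose statistics: volume (cc), Dmax, Dmean, D95, V(level).

    Empty derived ROIs report volume 0 and null dose statistics.
    """
    if not s.names():
        raise ValueError("structure set is empty")
    levels = levels_cGy or []
    rows = []
    for name in s.names():
        mask = s[name]
        stats = ra.dose_statistics(d, mask)
        row = {"roi": name, **stats}
        for lv in levels:
            row[f"V{lv:g}_cGy"] = (ra.volume_at_dose(d, mask, lv) if not mask.is_empty() else 0.0)
        rows.append(row)
    cols = ["roi", "volume_cc", "Dmax_cGy", "Dmean_cGy", "D95_cGy"] + [f"V{lv:g}_cGy" for lv in levels]
    return pd.DataFrame(rows, columns=cols)


def _reference_voxel(mask: Mask) -> tuple[int, int, int]:
    """Occupied voxel nearest the ROI centroid (the prescription point)."""
    idx = np.argwhere(mask.data)
    centre = idx.mean(axis=0)
    d2 = ((idx - centre) * np.asarray(mask.grid.spacing)) ** 2
    return tuple(idx[int(np.argmin(d2.sum(axis=1)))])


def renormalize_to_prescription(
    A: InfluenceMatrix, fluence: np.ndarray, reference: Mask, dose_cGy: float
) -> tuple[np.ndarray, float]:
    """Scale fluence so the reference ROI's centre voxel receives the
    prescription dose (point-prescription surrogate; no MU model)."""
    d = total_dose(A, fluence)
    ref = d.dose[_reference_voxel(reference)]
    if ref <= 0:
        raise StageError("reference-point dose is zero; cannot renormalize")
    factor = dose_cGy / float(ref)
    return fluence * factor, factor


def run_plan(
    structures: StructureSet | str | Path,
    template: PlanTemplate,
    out_dir: str | Path | None = None,
    max_rounds: int | None = None,
    regional: bool = True,
) -> PlanResult:
    """Run the full automated-planning workflow for one structure set.

    Halts with :class:`ValidationFailure` (listing the missing names) if a
    required ROI is absent. The pipeline contains no random number
    generation: rerunning with identical inputs reproduces the plan
    bit for bit.
    """
    log: list[str] = []

    def stage(name: str):
        log.append(f"stage: {name}")
        return name

    current = stage("load structures")
    try:
        if not isinstance(structures, StructureSet):
            structures = aio.read_structure_set(structures)

        current = stage("validate required ROIs")
        report = validate_required(structures, template.required_rois)
        log.append(report.summary())
        if not report.passed:
            raise ValidationFailure(report)

        current = stage("derive structures")
        s = derive_structures(structures, template.recipes)

        current = stage("build beams")
        beams = build_beams(template.beams, s["TPTV"], log=log)

        current = stage("compute influence")
        A = compute_influence(beams, s.grid, s["external"], model=template.dose_model, log=log)
        log.append(f"influence matrix: {A.matrix.shape[0]} voxels x {A.n_beamlets} beamlets, "
                   f"{A.matrix.nnz} nonzeros, {int(A.inert.sum())} inert beamlets")

        current = stage("initial optimization")
        initial = optimize_fluence(A, s, template.initial_objectives, template.initial_opt, log=log)
        log.append(f"initial optimization: {initial.n_iterations} iterations, "
                   f"composite {initial.final_objective:.6g}, converged={initial.converged}")

        current = stage("regional optimization")
        reg_report = None
        final = initial
        if regional and template.hotcold_rules:
            policy = template.termination
            if max_rounds is not None:
                policy = type(policy)(max_rounds=max_rounds,
                                      min_relative_spot_change=policy.min_relative_spot_change)
            final, reg_report, s = regional_loop(
                A, s, template.initial_objectives, template.hotcold_rules,
                template.regional_objectives, template.regional_opt, policy,
                initial, log=log,
            )
            log.append(f"regional loop: best round {reg_report.best_round}, "
                       f"spot volume {reg_report.initial_spot_volume_cc:.2f} -> "
                       f"{reg_report.final_spot_volume_cc:.2f} cc")

        current = stage("renormalize to prescription")
        fluence, factor = renormalize_to_prescription(
            A, final.fluence, s[template.prescription.reference_roi],
            template.prescription.dose_cGy,
        )
        log.append(f"prescription renormalization factor {factor:.4f}")
        dose = total_dose(A, fluence)

        current = stage("report")
        dvhs = {}
        for name in s.names():
            mask = s[name]
            if not mask.is_empty():
                dvhs[name] = ra.dvh(dose, mask, bin_width_cGy=25.0)
        metrics = plan_metrics(dose, s, levels_cGy=template.dvh_levels_cGy)
    except ValidationFailure:
        raise
    except Exception as err:
        raise StageError(f"stage '{current}' failed: {err}") from err

    result = PlanResult(
        template_site=template.site_name,
        fluence=fluence,
        dose=dose,
        structures=s,
        dvhs=dvhs,
        metrics=metrics,
        regional_report=reg_report,
        initial_result=initial,
        final_result=final,
        renorm_factor=factor,
        validation=report,
        log=log,
    )
    if out_dir is not None:
        result.save(out_dir, roi_colors=template.roi_colors)
    return result
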