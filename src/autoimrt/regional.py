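"""Iterative regional optimization on auto-segmented hot/cold spots.

After the first fluence optimization, the plan's residual defects are
localized: small cold regions inside targets that missed their minimum
dose, and hot regions where an isodose surface bulges past where it is
allowed. Each round of regional optimization

1. converts the relevant isodose surfaces of the current dose into masks,
2. builds cold spots (target minus its minimum-dose isodose region) and
   hot spots (an isodose region minus the structures allowed to carry that
   dose),
3. replaces the previous round's regional objectives with high-priority
   objectives on the fresh spots, and
4. re-optimizes the fluence warm-started from the previous solution.

The loop stops at ``max_rounds`` or when the total hot+cold spot volume
stops changing, and returns the best round by final composite objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import roi_algebra as ra
from .beams import InfluenceMatrix, total_dose
from .objectives import ObjectiveSpec, OptimizerParams, OptResult, optimize_fluence
from .roi_algebra import DoseGrid
from .structures import StructureSet


class RuleError(ValueError):
    pass


@dataclass
class HotColdRule:
    """How one hot or cold spot is segmented from an isodose surface.

    Cold rules: spot = base_roi minus the iso_level isodose region (target
    voxels below their required minimum). Hot rules: spot = the iso_level
    isodose region minus every ROI in ``subtract`` (dose that high is only
    legitimate inside those structures). A global hot rule such as a
    107.5%-of-prescription ceiling subtracts nothing.
    """

    name: str
    polarity: str  # {hot, cold}
    iso_level_cGy: float
    base_roi: str | None = None
    subtract: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.polarity not in ("hot", "cold"):
            raise RuleError(f"rule '{self.name}': polarity must be hot or cold")
        if self.iso_level_cGy <= 0:
            raise RuleError(f"rule '{self.name}': iso level must be positive")
        if self.polarity == "cold" and not self.base_roi:
            raise RuleError(f"cold rule '{self.name}' needs a base_roi")


@dataclass
class RegionalObjectiveSpec:
    """Objective applied to one rule's generated spot each round."""

    rule_name: str
    kind: str
    dose_cGy: float
    weight: float

    def to_objective(self) -> ObjectiveSpec:
        return ObjectiveSpec(
            roi=self.rule_name, kind=self.kind, dose_cGy=self.dose_cGy,
            weight=self.weight, tag="regional",
        )


@dataclass
class TerminationPolicy:
    """Bounded, reproducible loop termination.

    The source workflow iterates "until an optimal plan is achieved"; here
    the loop is capped at ``max_rounds`` and stops early once the relative
    change of the total hot+cold spot volume between consecutive rounds
    falls below ``min_relative_spot_change``.
    """

    max_rounds: int = 3
    min_relative_spot_change: float = 0.05

    def __post_init__(self) -> None:
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.min_relative_spot_change < 0:
            raise ValueError("min_relative_spot_change must be non-negative")


@dataclass
class RoundRecord:
    round: int
    hot_volume_cc: float
    cold_volume_cc: float
    composite: float
    spot_volumes_cc_by_roi: dict[str, float] = field(default_factory=dict)

    @property
    def spot_volume_cc(self) -> float:
        return self.hot_volume_cc + self.cold_volume_cc


@dataclass
class RegionalReport:
    rounds: list[RoundRecord]
    best_round: int
    initial_spot_volume_cc: float
    final_spot_volume_cc: float
    final_hot_volume_cc: float
    final_cold_volume_cc: float


def generate_hotcold(
    d: DoseGrid, s: StructureSet, rules: list[HotColdRule]
) -> StructureSet:
    """Segment every rule's spot from the current dose.

    A pure function of (dose, structures, rules): the returned set is a
    copy of ``s`` with one derived mask per rule added (replacing any
    earlier spot of the same name). Empty spots are retained at volume 0.
    """
    out = s.copy()
    for rule in rules:
        iso = ra.isodose_mask(d, rule.iso_level_cGy, name=f"_iso_{rule.name}")
        if rule.polarity == "cold":
            base = out.get(rule.base_roi)
            if base is None:
                raise RuleError(f"rule '{rule.name}' references unknown ROI '{rule.base_roi}'")
            spot = ra.subtract(base, iso, name=rule.name)
        else:
            spot = iso.with_name(rule.name)
            for roi_name in rule.subtract:
                roi = out.get(roi_name)
                if roi is None:
                    raise RuleError(f"rule '{rule.name}' references unknown ROI '{roi_name}'")
                spot = ra.subtract(spot, roi, name=rule.name)
        out.add(spot, provenance="derived", replace=True)
    return out


def spot_volumes_cc(
    s: StructureSet, rules: list[HotColdRule]
) -> tuple[float, float]:
    """(total hot, total cold) spot volume in cc."""
    hot = sum(s[r.name].volume_cc for r in rules if r.polarity == "hot" and r.name in s)
    cold = sum(s[r.name].volume_cc for r in rules if r.polarity == "cold" and r.name in s)
    return hot, cold


def inject_regional(
    objs: list[ObjectiveSpec],
    regional: list[RegionalObjectiveSpec],
    spots: StructureSet,
    log: list[str] | None = None,
) -> list[ObjectiveSpec]:
    """Replace the previous round's regional objectives with fresh ones.

    Initial objectives pass through untouched; regional specs whose spot
    has zero volume are skipped (logged), so injecting twice never
    duplicates entries and an all-empty round degrades to the initial set.
    """
    out = [o for o in objs if o.tag != "regional"]
    for spec in regional:
        spot = spots.get(spec.rule_name)
        if spot is None:
            raise RuleError(
                f"regional objective references rule '{spec.rule_name}' with no generated spot"
            )
        if spot.is_empty():
            if log is not None:
                log.append(f"regional objective on empty spot '{spec.rule_name}' skipped")
            continue
        out.append(spec.to_objective())
    return out


def regional_loop(
    A: InfluenceMatrix,
    s: StructureSet,
    initial_objs: list[ObjectiveSpec],
    rules: list[HotColdRule],
    regional_objs: list[RegionalObjectiveSpec],
    opt_params: OptimizerParams,
    policy: TerminationPolicy,
    initial_result: OptResult,
    log: list[str] | None = None,
) -> tuple[OptResult, RegionalReport, StructureSet]:
    """Run the iterative regional re-optimization.

    Each round recomputes dose from the current fluence, segments the
    spots, swaps in their objectives, and re-optimizes warm-started from
    the current fluence. Per-round hot/cold volumes (measured at round
    start) and the round's final composite are recorded; the fluence of
    the best round by composite is returned together with the structure
    set holding the final spots.
    """
    current = initial_result
    results: list[OptResult] = []
    records: list[RoundRecord] = []
    spots_prev: float | None = None
    initial_spot_volume = None
    working = s

    for rnd in range(1, policy.max_rounds + 1):
        try:
            d = total_dose(A, current.fluence)
            working = generate_hotcold(d, working, rules)
            hot_cc, cold_cc = spot_volumes_cc(working, rules)
            total_cc = hot_cc + cold_cc
            if initial_spot_volume is None:
                initial_spot_volume = total_cc
            objs = inject_regional(initial_objs, regional_objs, working, log=log)
            current = optimize_fluence(A, working, objs, opt_params, x0=current.fluence, log=log)
        except Exception as err:
            raise type(err)(f"regional round {rnd}: {err}") from err
        results.append(current)
        records.append(
            RoundRecord(round=rnd, hot_volume_cc=hot_cc, cold_volume_cc=cold_cc,
                        composite=current.final_objective,
                        spot_volumes_cc_by_roi={r.name: working[r.name].volume_cc
                                                for r in rules})
        )
        if log is not None:
            log.append(
                f"regional round {rnd}: hot {hot_cc:.2f} cc, cold {cold_cc:.2f} cc, "
                f"composite {current.final_objective:.6g}"
            )
        if total_cc == 0.0:
            break  # nothing to fix: the plan already satisfies every rule
        if spots_prev is not None:
            denom = max(spots_prev, 1e-12)
            if abs(total_cc - spots_prev) / denom < policy.min_relative_spot_change:
                break
        spots_prev = total_cc

    best_idx = int(np.argmin([r.composite for r in records]))
    best = results[best_idx]
    final_dose = total_dose(A, best.fluence)
    working = generate_hotcold(final_dose, working, rules)
    hot_cc, cold_cc = spot_volumes_cc(working, rules)
    report = RegionalReport(
        rounds=records,
        best_round=records[best_idx].round,
        initial_spot_volume_cc=float(initial_spot_volume or 0.0),
        final_spot_volume_cc=hot_cc + cold_cc,
        final_hot_volume_cc=hot_cc,
        final_cold_volume_cc=cold_cc,
    )
    return best, report, working
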