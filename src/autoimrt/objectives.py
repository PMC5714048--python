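"""Inverse-planning objectives and the constrained fluence optimizer.

The clinical system's exact objective functionals are proprietary; this
module uses the standard open formulation — one-sided quadratic voxel
penalties normalized by ROI voxel count, scalarized as a weighted sum —
which reproduces the qualitative behaviour the class-solution objective
tables rely on:

* ``min_dose``:      weight * mean_ROI( max(0, D - d)^2 )
* ``max_dose``:      weight * mean_ROI( max(0, d - D)^2 )
* ``uniform_dose``:  weight * mean_ROI( (d - D)^2 )
* ``max_eud``:       weight * max(0, EUD - D)^2,
                     EUD = ( mean_ROI d^a )^(1/a)  (generalized power mean;
                     a=1 is mean dose, large a approaches max dose)

Fluence is optimized by monotone projected gradient descent on the
non-negative orthant: Barzilai-Borwein step proposal, Armijo backtracking,
accepted steps never increase the composite. Initialization is
deterministic (uniform fluence scaled to the dose targets), so runs are
reproducible without seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beams import InfluenceMatrix
from .roi_algebra import DoseGrid
from .structures import StructureSet

OBJECTIVE_KINDS = ("min_dose", "max_dose", "uniform_dose", "max_eud")

#: voxel-dose floor (cGy) inside the EUD power mean when a < 1, to keep
#: the generalized mean and its gradient finite at zero dose
EUD_DOSE_FLOOR_CGY = 0.1


class ObjectiveError(ValueError):
    pass


class NumericalError(RuntimeError):
    pass


@dataclass
class ObjectiveSpec:
    """One inverse-planning objective on a named ROI."""

    roi: str
    kind: str
    dose_cGy: float
    weight: float
    eud_a: float | None = None
    tag: str = "initial"  # {initial, regional}

    def __post_init__(self) -> None:
        if self.kind not in OBJECTIVE_KINDS:
            raise ObjectiveError(f"unknown objective kind '{self.kind}'")
        if self.weight < 0:
            raise ObjectiveError("objective weight must be non-negative")
        if self.dose_cGy <= 0:
            raise ObjectiveError("objective dose must be positive")
        if self.kind == "max_eud":
            if self.eud_a is None or self.eud_a == 0:
                raise ObjectiveError("max_eud objective requires a non-zero eud_a")
        elif self.eud_a is not None:
            raise ObjectiveError(f"eud_a is only meaningful for max_eud, not {self.kind}")


@dataclass
class OptimizerParams:
    max_iterations: int = 200
    convergence_tol: float = 1e-6
    armijo_c: float = 1e-4
    backtrack_factor: float = 0.5
    max_backtracks: int = 40

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


@dataclass
class OptResult:
    fluence: np.ndarray
    objective_trace: list[float]
    converged: bool
    n_iterations: int = 0

    @property
    def final_objective(self) -> float:
        return self.objective_trace[-1]


def eud(doses: np.ndarray, a: float) -> float:
    """Generalized power-mean dose ( mean d^a )^(1/a) over one ROI."""
    d = np.asarray(doses, dtype=float)
    if a < 1:
        d = np.maximum(d, EUD_DOSE_FLOOR_CGY)
    # compute in log space for large |a| stability
    m = d.max()
    if m == 0:
        return 0.0
    return float(m * np.mean((d / m) ** a) ** (1.0 / a))


def _roi_doses(d: DoseGrid, s: StructureSet, o: ObjectiveSpec) -> np.ndarray:
    mask = s.get(o.roi)
    if mask is None:
        raise ObjectiveError(f"objective references unknown ROI '{o.roi}'")
    if mask.is_empty():
        raise ObjectiveError(f"objective on empty ROI '{o.roi}'")
    return d.dose[mask.data]


def objective_value(d: DoseGrid, s: StructureSet, o: ObjectiveSpec) -> float:
    """Weighted penalty of one objective under the current dose."""
    dv = _roi_doses(d, s, o)
    D = o.dose_cGy
    if o.kind == "min_dose":
        val = float(np.mean(np.maximum(0.0, D - dv) ** 2))
    elif o.kind == "max_dose":
        val = float(np.mean(np.maximum(0.0, dv - D) ** 2))
    elif o.kind == "uniform_dose":
        val = float(np.mean((dv - D) ** 2))
    else:  # max_eud
        val = max(0.0, eud(dv, o.eud_a) - D) ** 2
    return o.weight * val


def composite(
    d: DoseGrid,
    s: StructureSet,
    objs: list[ObjectiveSpec],
    log: list[str] | None = None,
) -> float:
    """Weighted-sum scalarization of all objectives.

    Regional objectives whose spot ROI came out empty contribute zero (a
    well-covered plan legitimately has no cold spots); an empty ROI on an
    initial objective is an error.
    """
    total = 0.0
    for o in objs:
        mask = s.get(o.roi)
        if o.tag == "regional" and (mask is None or mask.is_empty()):
            if log is not None:
                log.append(f"regional objective on empty spot '{o.roi}' skipped")
            continue
        total += objective_value(d, s, o)
    return total


def _dose_gradient(d: DoseGrid, s: StructureSet, objs: list[ObjectiveSpec]) -> np.ndarray:
    """d(composite)/d(dose), one value per voxel (flat C-order)."""
    g = np.zeros(d.grid.n_voxels)
    flat_dose = d.dose.ravel()
    for o in objs:
        mask = s.get(o.roi)
        if o.tag == "regional" and (mask is None or mask.is_empty()):
            continue
        if mask is None or mask.is_empty():
            raise ObjectiveError(f"objective on empty ROI '{o.roi}'")
        idx = mask.indices()
        dv = flat_dose[idx]
        n = dv.size
        D = o.dose_cGy
        if o.kind == "min_dose":
            g[idx] += o.weight * (-2.0 / n) * np.maximum(0.0, D - dv)
        elif o.kind == "max_dose":
            g[idx] += o.weight * (2.0 / n) * np.maximum(0.0, dv - D)
        elif o.kind == "uniform_dose":
            g[idx] += o.weight * (2.0 / n) * (dv - D)
        else:  # max_eud
            a = o.eud_a
            e = eud(dv, a)
            excess = e - D
            if excess > 0:
                dfloor = np.maximum(dv, EUD_DOSE_FLOOR_CGY) if a < 1 else dv
                with np.errstate(divide="ignore"):
                    # dEUD/dd_i = (1/n) d_i^(a-1) EUD^(1-a)
                    deud = (1.0 / n) * np.power(dfloor, a - 1.0) * e ** (1.0 - a)
                deud = np.where(np.isfinite(deud), deud, 0.0)
                g[idx] += o.weight * 2.0 * excess * deud
    return g


def gradient(
    A: InfluenceMatrix,
    s: StructureSet,
    objs: list[ObjectiveSpec],
    fluence: np.ndarray,
) -> np.ndarray:
    """Exact analytic gradient of composite(total_dose(fluence))."""
    from .beams import total_dose

    d = total_dose(A, fluence)
    gd = _dose_gradient(d, s, objs)
    g = np.asarray(A.matrix.T @ gd).ravel()
    g[A.inert] = 0.0
    return g


def default_fluence(A: InfluenceMatrix, s: StructureSet, objs: list[ObjectiveSpec]) -> np.ndarray:
    """Deterministic uniform starting fluence.

    Uniform intensity scaled so that the mean dose over the ROIs carrying
    minimum-dose objectives reaches the highest such target; no RNG.
    """
    x = np.ones(A.n_beamlets)
    x[A.inert] = 0.0
    unit = np.asarray(A.matrix @ x).ravel()
    target, achieved = 0.0, 0.0
    for o in objs:
        if o.kind != "min_dose":
            continue
        mask = s.get(o.roi)
        if mask is None or mask.is_empty():
            continue
        mean_unit = float(unit[mask.indices()].mean())
        if o.dose_cGy > target and mean_unit > 0:
            target, achieved = o.dose_cGy, mean_unit
    if target > 0:
        x *= target / achieved
    return x


def optimize_fluence(
    A: InfluenceMatrix,
    s: StructureSet,
    objs: list[ObjectiveSpec],
    params: OptimizerParams | None = None,
    x0: np.ndarray | None = None,
    log: list[str] | None = None,
) -> OptResult:
    """Projected-gradient descent of the composite on the orthant x >= 0.

    Warm restart is the intended use for regional re-optimization: pass the
    previous round's fluence as ``x0``. The accepted-step policy guarantees
    the objective trace is monotonically non-increasing; the run stops at
    ``max_iterations`` or when the relative objective change drops below
    ``convergence_tol``.
    """
    from .beams import total_dose

    params = params or OptimizerParams()
    if x0 is None:
        x = default_fluence(A, s, objs)
    else:
        x = np.asarray(x0, dtype=float).copy()
        if x.shape != (A.n_beamlets,):
            raise ValueError("x0 length does not match beamlet count")
    x = np.maximum(x, 0.0)
    x[A.inert] = 0.0

    def f_and_g(xv: np.ndarray) -> tuple[float, np.ndarray]:
        d = total_dose(A, xv)
        fv = composite(d, s, objs, log=log)
        if not np.isfinite(fv):
            raise NumericalError(f"non-finite composite objective ({fv}) during optimization")
        gv = np.asarray(A.matrix.T @ _dose_gradient(d, s, objs)).ravel()
        gv[A.inert] = 0.0
        return fv, gv

    f, g = f_and_g(x)
    trace = [f]
    # stationarity on the orthant: projected gradient is zero
    proj_g = np.where((x > 0) | (g < 0), g, 0.0)
    if not np.any(proj_g):
        return OptResult(fluence=x, objective_trace=trace, converged=True, n_iterations=0)

    gnorm2 = float(proj_g @ proj_g)
    t = f / gnorm2 if gnorm2 > 0 else 1.0  # Cauchy-like first step for a penalty with optimum 0

    converged = False
    it = 0
    for it in range(1, params.max_iterations + 1):
        accepted = False
        for _ in range(params.max_backtracks):
            x_new = np.maximum(x - t * g, 0.0)
            step = x - x_new
            decrease = float(g @ step)
            if decrease <= 0:
                break  # stationary: no feasible descent
            d_new = total_dose(A, x_new)
            f_new = composite(d_new, s, objs, log=log)
            if f_new <= f - params.armijo_c * decrease:
                accepted = True
                break
            t *= params.backtrack_factor
        if not accepted:
            converged = True
            break
        _, g_new = f_and_g(x_new)
        sdiff = x_new - x
        ydiff = g_new - g
        sy = float(sdiff @ ydiff)
        if sy > 1e-30:  # Barzilai-Borwein step proposal for the next iterate
            t = float(sdiff @ sdiff) / sy
        x, g = x_new, g_new
        rel = (f - f_new) / max(abs(f), 1e-30)
        f = f_new
        trace.append(f)
        if rel < params.convergence_tol:
            converged = True
            break

    return OptResult(fluence=x, objective_trace=trace, converged=converged, n_iterations=it)


def trace_rows(
    d: DoseGrid, s: StructureSet, objs: list[ObjectiveSpec]
) -> list[dict[str, float | str]]:
    """Per-objective values for the optimizer log CSV."""
    rows = []
    for o in objs:
        mask = s.get(o.roi)
        if o.tag == "regional" and (mask is None or mask.is_empty()):
            value = 0.0
        else:
            value = objective_value(d, s, o)
        rows.append(
            {"roi": o.roi, "kind": o.kind, "dose_cGy": o.dose_cGy, "weight": o.weight,
             "tag": o.tag, "value": value}
        )
    return rows
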