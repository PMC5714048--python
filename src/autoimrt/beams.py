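"""Class-solution beam placement and the beamlet dose-influence model.

Beam geometry
-------------
Patient axes: x = left-right, y = anterior-posterior (+y posterior),
z = inferior-superior. Each beam carries an orthonormal frame (u, v, w):
w is the central-axis direction (source toward isocenter), u and v span
the isocentric plane (u is the cross-plane "x-jaw" axis, v the in-plane
"y-jaw" axis). At all angles zero the beam enters anteriorly:
u = (1,0,0), v = (0,0,1), w = (0,1,0).

Rotation order (fixed, IEC-like; exact clinical IEC compliance is not
claimed): couch rotation about the vertical (y) axis is composed first,
then gantry rotation about the longitudinal (z) axis; the collimator
rotates u and v about the resulting beam axis w.

Dose model
----------
A deliberately simplified parallel-beam beamlet kernel, declared as such:
for a beamlet of unit intensity the dose at a voxel inside the body
contour is ``exp(-mu * depth) * exp(-r^2 / (2 sigma^2))`` where ``depth``
is the path length through the body contour upstream of the voxel along
the beam axis and ``r`` the lateral distance from the beamlet's ray; dose
is zero outside the body. There is no divergence, scatter kernel,
heterogeneity correction or MU calibration — the model preserves the
*structure* of the fluence-optimization problem at desk scale, nothing
more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, sparse

from .roi_algebra import DoseGrid, GeometryError, Grid, Mask


class ConfigurationError(ValueError):
    pass


#: default linear attenuation, 1/mm (water-like order of magnitude, declared)
DEFAULT_MU_PER_MM = 0.005
#: default lateral Gaussian spread of a beamlet, mm
DEFAULT_SIGMA_MM = 3.0
#: default beamlet pitch in the isocentric plane, mm
DEFAULT_BEAMLET_MM = 5.0
#: lateral truncation radius of the beamlet kernel, in units of sigma
KERNEL_CUTOFF_SIGMAS = 3.0


@dataclass
class Jaws:
    """Rectangular field edges in the isocentric plane, mm from central axis."""

    x1: float
    x2: float
    y1: float
    y2: float

    def __post_init__(self) -> None:
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ConfigurationError(f"degenerate jaw setting {self}")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1


@dataclass
class BeamSpec:
    """One treatment field of the class solution."""

    name: str
    gantry_deg: float
    couch_deg: float = 0.0
    collimator_deg: float = 0.0
    jaws: Jaws | None = None
    beamlet_size_mm: float = DEFAULT_BEAMLET_MM
    coverage_side: str = "both"  # {both, left_edge, right_edge}
    margin_mm: float = 8.0
    max_width_mm: float | None = None
    jaw_overrides: dict[str, float] = field(default_factory=dict)
    isocenter_mm: tuple[float, float, float] | None = None

    def frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal beam frame (u, v, w) in patient coordinates."""
        g = math.radians(self.gantry_deg)
        c = math.radians(self.couch_deg)
        k = math.radians(self.collimator_deg)
        # couch about y, then gantry about z
        ry = np.array([[math.cos(c), 0, math.sin(c)], [0, 1, 0], [-math.sin(c), 0, math.cos(c)]])
        rz = np.array([[math.cos(g), -math.sin(g), 0], [math.sin(g), math.cos(g), 0], [0, 0, 1]])
        rot = rz @ ry
        u = rot @ np.array([1.0, 0.0, 0.0])
        v = rot @ np.array([0.0, 0.0, 1.0])
        w = rot @ np.array([0.0, 1.0, 0.0])
        # collimator spins the jaw axes about the central axis
        ck, sk = math.cos(k), math.sin(k)
        u, v = ck * u + sk * v, -sk * u + ck * v
        return u, v, w


@dataclass
class DoseModel:
    """Declared constants of the simplified beamlet kernel."""

    mu_per_mm: float = DEFAULT_MU_PER_MM
    sigma_mm: float = DEFAULT_SIGMA_MM
    beamlet_size_mm: float = DEFAULT_BEAMLET_MM


@dataclass
class InfluenceMatrix:
    """Sparse beamlet-by-voxel dose operator.

    ``matrix`` has one row per grid voxel (flat C-order index) and one
    column per beamlet; entries are dose per unit beamlet intensity (cGy
    per intensity unit). ``beamlet_beam``/``beamlet_row``/``beamlet_col``
    map each column back to its field and lattice position. Beamlets whose
    ray never meets the body contour are flagged inert and must be held at
    zero intensity.
    """

    grid: Grid
    matrix: sparse.csc_matrix
    beamlet_beam: np.ndarray
    beamlet_row: np.ndarray
    beamlet_col: np.ndarray
    inert: np.ndarray
    beams: list[BeamSpec]

    @property
    def n_beamlets(self) -> int:
        return self.matrix.shape[1]

    def beamlets_of(self, beam_index: int) -> np.ndarray:
        return np.flatnonzero(self.beamlet_beam == beam_index)


def place_isocenter(tptv: Mask) -> np.ndarray:
    """Centroid of the total PTV snapped to the nearest voxel centre.

    The same isocenter is shared by every beam of the plan. Distance ties
    between neighbouring voxel centres resolve toward the lower index.
    """
    if tptv.is_empty():
        raise GeometryError("cannot place isocenter: total PTV is empty")
    frac = (tptv.centroid_mm() - np.asarray(tptv.grid.origin)) / np.asarray(tptv.grid.spacing)
    idx = np.ceil(frac - 0.5).astype(int)  # ties toward the lower index
    idx = np.clip(idx, 0, np.asarray(tptv.grid.shape) - 1)
    return tptv.grid.index_to_mm(idx)


def _project(points_mm: np.ndarray, beam: BeamSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Beam-frame coordinates (u, v, w) of points, relative to isocenter."""
    if beam.isocenter_mm is None:
        raise ConfigurationError(f"beam '{beam.name}' has no isocenter")
    u, v, w = beam.frame()
    rel = points_mm - np.asarray(beam.isocenter_mm)
    return rel @ u, rel @ v, rel @ w


def fit_jaws(
    beam: BeamSpec,
    tptv: Mask,
    margin_mm: float | None = None,
    max_width_mm: float | None = None,
    log: list[str] | None = None,
) -> BeamSpec:
    """Fit the rectangular jaws around the target projection.

    The target's voxel centres are projected into the beam's isocentric
    plane and the jaws are opened to the projection plus ``margin_mm`` on
    every side. If the required x-jaw width exceeds ``max_width_mm`` (the
    beam-splitting limit), the width is clamped to the cap keeping the edge
    named by ``coverage_side`` flush with projection+margin; the sacrificed
    side is logged. Explicit per-beam ``jaw_overrides`` are applied last.
    """
    if tptv.is_empty():
        raise GeometryError("cannot fit jaws: target mask is empty")
    margin = beam.margin_mm if margin_mm is None else margin_mm
    cap = beam.max_width_mm if max_width_mm is None else max_width_mm
    if margin < 0:
        raise ConfigurationError("jaw margin must be non-negative")
    if cap is not None and cap <= 0:
        raise ConfigurationError(f"jaw width cap must be positive, got {cap}")

    pts = tptv.grid.index_to_mm(np.argwhere(tptv.data))
    pu, pv, _ = _project(pts, beam)
    x1, x2 = float(pu.min() - margin), float(pu.max() + margin)
    y1, y2 = float(pv.min() - margin), float(pv.max() + margin)

    if cap is not None and (x2 - x1) > cap:
        if beam.coverage_side == "left_edge":
            x2 = x1 + cap
            sacrificed = "x2"
        elif beam.coverage_side == "right_edge":
            x1 = x2 - cap
            sacrificed = "x1"
        else:  # both: clamp symmetrically about the projection centre
            mid = 0.5 * (x1 + x2)
            x1, x2 = mid - cap / 2, mid + cap / 2
            sacrificed = "x1,x2"
        if log is not None:
            log.append(
                f"beam {beam.name}: x-jaw width capped at {cap} mm, edge(s) {sacrificed} pulled in"
            )

    jaws = {"x1": x1, "x2": x2, "y1": y1, "y2": y2}
    for key, value in beam.jaw_overrides.items():
        if key not in jaws:
            raise ConfigurationError(f"beam {beam.name}: unknown jaw '{key}'")
        jaws[key] = float(value)
        if log is not None:
            log.append(f"beam {beam.name}: jaw {key} fixed at {value} mm")
    return replace(beam, jaws=Jaws(**jaws))


def build_beams(template_beams: list[BeamSpec], tptv: Mask, log: list[str] | None = None) -> list[BeamSpec]:
    """Instantiate the template's fields against the patient's total PTV.

    Places the shared isocenter at the TPTV centroid and fits jaws per
    beam (honouring per-beam caps, coverage sides and fixed-jaw
    overrides). Jaws are fitted once, at plan build.
    """
    if not template_beams:
        raise ConfigurationError("template defines no beams")
    iso = tuple(place_isocenter(tptv))
    out = []
    for beam in template_beams:
        beam = replace(beam, isocenter_mm=iso)
        out.append(fit_jaws(beam, tptv, log=log))
    return out


def _beamlet_lattice(jaws: Jaws, size_mm: float) -> tuple[np.ndarray, np.ndarray]:
    """Beamlet centre coordinates along u and v covering the open field."""
    if size_mm <= 0:
        raise ConfigurationError("beamlet size must be positive")
    nu = max(1, int(math.ceil(jaws.width / size_mm - 1e-9)))
    nv = max(1, int(math.ceil(jaws.height / size_mm - 1e-9)))
    cu = jaws.x1 + (np.arange(nu) + 0.5) * size_mm
    cv = jaws.y1 + (np.arange(nv) + 0.5) * size_mm
    return cu, cv


def _depth_map(beam: BeamSpec, external: Mask, pu: np.ndarray, pv: np.ndarray, pw: np.ndarray) -> np.ndarray:
    """Upstream path length through the body for each external voxel (mm).

    Works on an auxiliary lattice aligned with the beam frame: the body
    mask is resampled onto it (nearest neighbour), the water path is
    accumulated along the beam axis, and each patient voxel reads the depth
    at its nearest lattice cell. Depth is counted over lattice cells
    strictly upstream, so the first occupied cell of a ray has depth 0.
    """
    step = float(min(external.grid.spacing))
    u, v, w = beam.frame()
    lo = np.array([pu.min(), pv.min(), pw.min()])
    hi = np.array([pu.max(), pv.max(), pw.max()])
    n = np.maximum(1, np.ceil((hi - lo) / step).astype(int) + 1)
    axes = [lo[i] + step * np.arange(n[i]) for i in range(3)]
    gu, gv, gw = np.meshgrid(*axes, indexing="ij")
    # lattice points back in patient mm coordinates
    iso = np.asarray(beam.isocenter_mm)
    pts = (
        iso[None, None, None, :]
        + gu[..., None] * u[None, None, None, :]
        + gv[..., None] * v[None, None, None, :]
        + gw[..., None] * w[None, None, None, :]
    )
    idx = (pts - np.asarray(external.grid.origin)) / np.asarray(external.grid.spacing)
    idx = np.rint(idx).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(external.grid.shape)), axis=-1)
    occ = np.zeros(tuple(n), dtype=bool)
    ii = idx[inside]
    occ[inside] = external.data[ii[:, 0], ii[:, 1], ii[:, 2]]
    # exclusive cumulative water path along the beam axis (axis 2 of the lattice)
    depth = (np.cumsum(occ, axis=2) - occ) * step
    # read back at each patient voxel's nearest lattice cell
    vi = np.rint((np.stack([pu, pv, pw], axis=1) - lo) / step).astype(int)
    vi = np.clip(vi, 0, n - 1)
    return depth[vi[:, 0], vi[:, 1], vi[:, 2]]


def compute_influence(
    beams: list[BeamSpec],
    grid: Grid,
    external: Mask,
    model: DoseModel | None = None,
    log: list[str] | None = None,
) -> InfluenceMatrix:
    """Assemble the sparse dose-influence operator for all beams.

    Every beamlet inside each beam's fitted jaws is traced through the
    body contour; its column holds the kernel dose at every voxel within
    the lateral truncation radius. Beamlets with no dose anywhere are
    flagged inert.
    """
    model = model or DoseModel()
    if external.is_empty():
        raise GeometryError("body contour (external) is empty")
    for b in beams:
        if b.jaws is None:
            raise ConfigurationError(f"beam '{b.name}' has no fitted jaws")

    vox_idx = np.argwhere(external.data)
    flat_idx = np.ravel_multi_index(vox_idx.T, grid.shape)
    pts = grid.index_to_mm(vox_idx)

    sigma = model.sigma_mm
    cutoff = KERNEL_CUTOFF_SIGMAS * sigma
    rows_all: list[np.ndarray] = []
    cols_all: list[np.ndarray] = []
    data_all: list[np.ndarray] = []
    bl_beam: list[int] = []
    bl_row: list[int] = []
    bl_col: list[int] = []
    inert: list[bool] = []
    col0 = 0

    for bi, beam in enumerate(beams):
        pu, pv, pw = _project(pts, beam)
        depth = _depth_map(beam, external, pu, pv, pw)
        atten = np.exp(-model.mu_per_mm * depth).astype(np.float32)

        cu, cv = _beamlet_lattice(beam.jaws, model.beamlet_size_mm)
        size = model.beamlet_size_mm
        # spatial hash of voxels on the beamlet lattice for candidate lookup
        iu = np.floor((pu - beam.jaws.x1) / size).astype(int)
        iv = np.floor((pv - beam.jaws.y1) / size).astype(int)
        reach = int(math.ceil(cutoff / size)) + 1
        nu, nv = len(cu), len(cv)
        iu_c = np.clip(iu, -reach, nu + reach)
        iv_c = np.clip(iv, -reach, nv + reach)
        span_v = nv + 2 * reach + 1
        key = (iu_c + reach) * span_v + (iv_c + reach)
        order = np.argsort(key, kind="stable")
        key_sorted = key[order]

        for j, vc in enumerate(cv):
            for i, uc in enumerate(cu):
                # gather voxels from the hash cells within the kernel reach
                cand: list[np.ndarray] = []
                for du in range(-reach, reach + 1):
                    k0 = (i + du + reach) * span_v + (j - reach + reach)
                    k1 = k0 + 2 * reach
                    a = np.searchsorted(key_sorted, k0, side="left")
                    b = np.searchsorted(key_sorted, k1, side="right")
                    if b > a:
                        cand.append(order[a:b])
                col = col0 + j * nu + i
                bl_beam.append(bi)
                bl_row.append(j)
                bl_col.append(i)
                if not cand:
                    inert.append(True)
                    continue
                sel = np.concatenate(cand)
                r2 = (pu[sel] - uc) ** 2 + (pv[sel] - vc) ** 2
                keep = r2 <= cutoff * cutoff
                sel = sel[keep]
                if sel.size == 0:
                    inert.append(True)
                    continue
                vals = atten[sel] * np.exp(-r2[keep] / (2.0 * sigma * sigma)).astype(np.float32)
                rows_all.append(flat_idx[sel])
                cols_all.append(np.full(sel.size, col, dtype=np.int64))
                data_all.append(vals.astype(np.float32))
                inert.append(False)
        col0 += nu * nv
        if log is not None:
            log.append(f"beam {beam.name}: {nu * nv} beamlets ({nu}x{nv})")

    n_beamlets = col0
    if n_beamlets == 0:
        raise ConfigurationError("no beamlets generated (degenerate beamlet lattice)")
    rows = np.concatenate(rows_all) if rows_all else np.empty(0, dtype=np.int64)
    cols = np.concatenate(cols_all) if cols_all else np.empty(0, dtype=np.int64)
    data = np.concatenate(data_all) if data_all else np.empty(0, dtype=np.float32)
    mat = sparse.csc_matrix((data, (rows, cols)), shape=(grid.n_voxels, n_beamlets))
    return InfluenceMatrix(
        grid=grid,
        matrix=mat,
        beamlet_beam=np.asarray(bl_beam),
        beamlet_row=np.asarray(bl_row),
        beamlet_col=np.asarray(bl_col),
        inert=np.asarray(inert, dtype=bool),
        beams=list(beams),
    )


def total_dose(A: InfluenceMatrix, fluence: np.ndarray) -> DoseGrid:
    """Dose = influence matrix times fluence, clamped non-negative."""
    fluence = np.asarray(fluence, dtype=float)
    if fluence.shape != (A.n_beamlets,):
        raise ValueError(
            f"fluence length {fluence.shape} does not match {A.n_beamlets} beamlets"
        )
    if np.any(fluence < 0):
        raise ValueError("fluence must be non-negative")
    dose = np.asarray(A.matrix @ fluence).reshape(A.grid.shape)
    np.maximum(dose, 0.0, out=dose)
    return DoseGrid(A.grid, dose)
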