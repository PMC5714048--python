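"""Voxel-grid geometry kernel for inverse planning.

Everything downstream of this module — derived optimization structures,
hot/cold spot segmentation, DVH analysis — is Boolean algebra and Euclidean
morphology on binary occupancy masks that share one regular 3D lattice.

Conventions
-----------
* Axis order is (x, y, z): x = patient left-right, y = anterior-posterior,
  z = inferior-superior. Voxel indices are 0-based.
* All lengths are millimetres, all doses centigray (cGy).
* Margins are measured on the voxel-centre Euclidean metric with the grid's
  (possibly anisotropic) spacing, via exact distance transforms.
* Masks and dose fields live on a single shared grid; there is no
  resampling anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class GeometryError(ValueError):
    """Raised when masks or dose grids disagree about their lattice."""


class DVHError(ValueError):
    """Raised when a DVH is requested for an empty ROI."""


@dataclass(frozen=True)
class Grid:
    """Regular 3D voxel lattice.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z).
    spacing : tuple of float
        Voxel pitch in mm along each axis; strictly positive.
    origin : tuple of float
        Physical position (mm) of the centre of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise GeometryError(f"grid shape must be three entries >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"grid spacing must be three positive reals, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def coordinates(self) -> np.ndarray:
        """Voxel-centre physical coordinates, shape ``(*grid.shape, 3)`` (mm)."""
        axes = [
            self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
            for i in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def center_mm(self) -> np.ndarray:
        """Physical centre of the lattice bounding box."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0


@dataclass
class Mask:
    """Named binary occupancy on a :class:`Grid`."""

    name: str
    grid: Grid
    data: np.ndarray

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("mask name must be non-empty")
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.shape != self.grid.shape:
            raise GeometryError(
                f"mask '{self.name}' occupancy shape {self.data.shape} "
                f"does not match grid shape {self.grid.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cc(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_cc

    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def indices(self) -> np.ndarray:
        """Flat (C-order) indices of occupied voxels."""
        return np.flatnonzero(self.data.ravel())

    def with_name(self, name: str) -> "Mask":
        return Mask(name, self.grid, self.data)

    def centroid_mm(self) -> np.ndarray:
        if self.is_empty():
            raise GeometryError(f"centroid of empty mask '{self.name}'")
        idx = np.argwhere(self.data)
        return self.grid.index_to_mm(idx.mean(axis=0))


@dataclass
class DoseGrid:
    """Scalar dose per voxel (cGy, non-negative) on a :class:`Grid`."""

    grid: Grid
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.shape != self.grid.shape:
            raise GeometryError(
                f"dose shape {self.dose.shape} does not match grid {self.grid.shape}"
            )
        if np.any(self.dose < 0):
            raise ValueError("dose must be non-negative everywhere")

    def max(self) -> float:
        return float(self.dose.max())


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram for one ROI.

    ``volume_fraction[k]`` is the fraction of the ROI volume receiving at
    least ``dose_edges[k]`` cGy; the curve is non-increasing and starts at
    1.0 for a non-empty ROI.
    """

    roi_name: str
    dose_edges: np.ndarray
    volume_fraction: np.ndarray

    def value_at(self, dose_cGy: float) -> float:
        """Volume fraction receiving >= ``dose_cGy`` (step interpolation)."""
        i = int(np.searchsorted(self.dose_edges, dose_cGy, side="right")) - 1
        if i < 0:
            return 1.0
        return float(self.volume_fraction[i])


def _require_same_grid(*masks: Mask) -> Grid:
    grid = masks[0].grid
    for m in masks[1:]:
        if m.grid != grid:
            raise GeometryError(
                f"masks '{masks[0].name}' and '{m.name}' live on different grids"
            )
    return grid


def combine(a: Mask, b: Mask, op: str, name: str | None = None) -> Mask:
    """Voxelwise set operation on two masks sharing a grid.

    ``op`` is one of ``union``, ``intersect``, ``subtract``;
    subtraction is ``a AND NOT b``.
    """
    _require_same_grid(a, b)
    if op == "union":
        data = a.data | b.data
    elif op == "intersect":
        data = a.data & b.data
    elif op == "subtract":
        data = a.data & ~b.data
    else:
        raise ValueError(f"unknown set operation '{op}'")
    return Mask(name or f"{a.name}_{op}_{b.name}", a.grid, data)


def union(a: Mask, b: Mask, name: str | None = None) -> Mask:
    return combine(a, b, "union", name)


def intersect(a: Mask, b: Mask, name: str | None = None) -> Mask:
    return combine(a, b, "intersect", name)


def subtract(a: Mask, b: Mask, name: str | None = None) -> Mask:
    return combine(a, b, "subtract", name)


def union_all(masks: list[Mask], name: str) -> Mask:
    if not masks:
        raise ValueError("union_all requires at least one mask")
    grid = _require_same_grid(*masks)
    data = np.zeros(grid.shape, dtype=bool)
    for m in masks:
        data |= m.data
    return Mask(name, grid, data)


def expand(m: Mask, margin_mm: float, name: str | None = None) -> Mask:
    """Euclidean margin expansion.

    A voxel is included iff the distance from its centre to the nearest
    occupied voxel centre of ``m`` is <= ``margin_mm`` (anisotropic spacing
    respected). Always a superset of ``m``; the expansion of an empty mask
    is empty.
    """
    if margin_mm <= 0:
        raise ValueError(f"margin must be positive, got {margin_mm}")
    name = name or f"{m.name}+{margin_mm:g}mm"
    if m.is_empty():
        return Mask(name, m.grid, np.zeros(m.grid.shape, dtype=bool))
    # Distance from every voxel centre to the nearest occupied centre.
    dist = ndimage.distance_transform_edt(~m.data, sampling=m.grid.spacing)
    return Mask(name, m.grid, dist <= margin_mm)


def contract(m: Mask, margin_mm: float, name: str | None = None) -> Mask:
    """Euclidean margin contraction.

    A voxel is kept iff it is occupied and its distance to the nearest
    *unoccupied* voxel centre exceeds ``margin_mm``. Always a subset of
    ``m``; contracting a mask to nothing is legal.
    """
    if margin_mm <= 0:
        raise ValueError(f"margin must be positive, got {margin_mm}")
    name = name or f"{m.name}-{margin_mm:g}mm"
    if m.is_empty():
        return Mask(name, m.grid, np.zeros(m.grid.shape, dtype=bool))
    dist = ndimage.distance_transform_edt(m.data, sampling=m.grid.spacing)
    return Mask(name, m.grid, dist > margin_mm)


def make_ring(
    seeds: list[Mask],
    thickness_mm: float,
    exclusions: list[Mask] | None = None,
    name: str = "ring",
) -> Mask:
    """Shell of fixed thickness around the union of ``seeds``.

    ring = expand(union(seeds), thickness) - union(seeds) - union(exclusions).
    Rings carry maximum-dose objectives that force the dose to fall off
    around a target, so they must not overlap the target itself nor any
    structure listed in ``exclusions``.
    """
    if not seeds:
        raise ValueError("make_ring requires at least one seed mask")
    exclusions = exclusions or []
    _require_same_grid(*seeds, *exclusions)
    seed = union_all(seeds, "_seed")
    ring = subtract(expand(seed, thickness_mm), seed, name)
    for ex in exclusions:
        ring = subtract(ring, ex, name)
    return ring


def isodose_mask(d: DoseGrid, level_cGy: float, name: str | None = None) -> Mask:
    """Voxels receiving at least ``level_cGy`` (inclusive threshold)."""
    if level_cGy <= 0:
        raise ValueError(f"isodose level must be positive, got {level_cGy}")
    return Mask(name or f"iso{level_cGy:g}", d.grid, d.dose >= level_cGy)


def dvh(d: DoseGrid, m: Mask, bin_width_cGy: float = 10.0) -> DVHCurve:
    """Cumulative DVH of ``m`` under dose ``d``.

    The fraction at edge ``e`` is the share of ROI voxels with dose >= e.
    """
    if d.grid != m.grid:
        raise GeometryError(f"dose grid and mask '{m.name}' live on different grids")
    if bin_width_cGy <= 0:
        raise ValueError("bin width must be positive")
    if m.is_empty():
        raise DVHError(f"DVH requested for empty ROI '{m.name}'")
    doses = d.dose[m.data]
    top = float(doses.max())
    n_bins = int(np.floor(top / bin_width_cGy)) + 2
    edges = np.arange(n_bins) * bin_width_cGy
    # fraction receiving >= edge; vectorised as a survival function
    order = np.sort(doses)
    counts = len(order) - np.searchsorted(order, edges, side="left")
    frac = counts / len(order)
    return DVHCurve(m.name, edges, frac)


def dose_statistics(d: DoseGrid, m: Mask) -> dict[str, float | None]:
    """Dmax / Dmean / D95 (cGy) and volume (cc) for one ROI.

    D95 is the minimum dose received by the best-covered 95% of the ROI.
    An empty ROI reports volume 0 and null dose statistics.
    """
    if m.is_empty():
        return {"volume_cc": 0.0, "Dmax_cGy": None, "Dmean_cGy": None, "D95_cGy": None}
    doses = d.dose[m.data]
    return {
        "volume_cc": m.volume_cc,
        "Dmax_cGy": float(doses.max()),
        "Dmean_cGy": float(doses.mean()),
        "D95_cGy": float(np.percentile(doses, 5.0)),
    }


def volume_at_dose(d: DoseGrid, m: Mask, level_cGy: float) -> float:
    """V(level): fraction of ROI volume receiving >= ``level_cGy``."""
    if m.is_empty():
        return 0.0
    return float((d.dose[m.data] >= level_cGy).mean())
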