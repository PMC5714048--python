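"""NIfTI I/O for masks and dose grids.

One ROI per file; the ROI name is the file stem, the grid geometry comes
from the image affine (axis-aligned, no rotation/shear supported — this
package operates on a single planning grid). Masks are stored as uint8
0/1, dose as float32 cGy.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .roi_algebra import DoseGrid, GeometryError, Grid, Mask
from .structures import StructureSet


def _affine(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid.spacing
    aff[:3, 3] = grid.origin
    return aff


def _grid_from(img: nib.Nifti1Image) -> Grid:
    aff = img.affine
    off_diag = aff[:3, :3] - np.diag(np.diag(aff[:3, :3]))
    if np.any(np.abs(off_diag) > 1e-6):
        raise GeometryError("only axis-aligned NIfTI volumes are supported")
    spacing = tuple(round(float(aff[i, i]), 6) for i in range(3))
    origin = tuple(round(float(aff[i, 3]), 6) for i in range(3))
    return Grid(shape=tuple(img.shape[:3]), spacing=spacing, origin=origin)


def write_mask(mask: Mask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(mask.grid))
    nib.save(img, str(path))


def read_mask(path: str | Path) -> Mask:
    path = Path(path)
    img = nib.load(str(path))
    name = path.name.removesuffix(".gz").removesuffix(".nii")
    return Mask(name, _grid_from(img), np.asarray(img.dataobj) > 0)


def write_dose(d: DoseGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(d.dose.astype(np.float32), _affine(d.grid))
    nib.save(img, str(path))


def read_dose(path: str | Path) -> DoseGrid:
    img = nib.load(str(path))
    return DoseGrid(_grid_from(img), np.maximum(np.asarray(img.dataobj, dtype=float), 0.0))


def write_structure_set(s: StructureSet, out_dir: str | Path) -> None:
    """One NIfTI per ROI plus a provenance JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for mask in s.masks():
        write_mask(mask, out_dir / f"{mask.name}.nii.gz")
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(s.provenance, fh, indent=1, sort_keys=True)


def read_structure_set(in_dir: str | Path) -> StructureSet:
    """Load every NIfTI in a directory as one structure set on one grid."""
    in_dir = Path(in_dir)
    paths = sorted(list(in_dir.glob("*.nii")) + list(in_dir.glob("*.nii.gz")))
    if not paths:
        raise FileNotFoundError(f"no NIfTI files found in {in_dir}")
    masks = [read_mask(p) for p in paths]
    s = StructureSet(masks[0].grid)
    prov_path = in_dir / "provenance.json"
    provenance = json.loads(prov_path.read_text()) if prov_path.exists() else {}
    for m in masks:
        s.add(m, provenance=provenance.get(m.name, "input"))
    return s
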