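"""Case serialization: NIfTI volumes plus a JSON manifest.

One NIfTI file per ROI mask and per dose grid; a JSON manifest records the
case id, prescription, grid geometry and the file for every ROI of each
structure set.  The manifest geometry (written at full float precision) is
authoritative; NIfTI headers (float32 affines) are cross-checked against it
within the grid tolerances on load.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Union

import nibabel as nib
import numpy as np

from .errors import CaseIOError, GeometryError, ValidationError
from .grids import Case, DoseGrid, Mask, StructureSet, VoxelGrid, assert_compatible

MANIFEST_NAME = "case.json"


def _affine(grid: VoxelGrid) -> np.ndarray:
    dz, dy, dx = grid.spacing
    oz, oy, ox = grid.origin
    aff = np.diag([dx, dy, dz, 1.0])
    aff[:3, 3] = [ox, oy, oz]
    return aff


def _write_volume(path: Path, grid: VoxelGrid, data: np.ndarray) -> None:
    # our arrays are (z, y, x); NIfTI wants x fastest
    img = nib.Nifti1Image(np.ascontiguousarray(data.transpose(2, 1, 0)), _affine(grid))
    nib.save(img, str(path))


def _read_volume(path: Path, expected: VoxelGrid) -> np.ndarray:
    if not path.exists():
        raise CaseIOError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise CaseIOError(f"{path}: expected a 3D volume, got shape {data.shape}")
    arr = data.transpose(2, 1, 0)
    aff = img.affine
    header_grid = VoxelGrid(
        dims=arr.shape,
        spacing=(abs(aff[2, 2]), abs(aff[1, 1]), abs(aff[0, 0])),
        origin=(aff[2, 3], aff[1, 3], aff[0, 3]),
    )
    try:
        assert_compatible(expected, header_grid)
    except GeometryError as exc:
        raise GeometryError(f"{path}: header disagrees with manifest grid: {exc}") from exc
    return arr


def _safe_name(roi: str) -> str:
    return "".join(c if (c.isalnum() or c in "-_") else "_" for c in roi)


def save_case(case: Case, directory: Union[str, Path]) -> Path:
    """Write all volumes of ``case`` plus a JSON manifest; return the
    manifest path."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise CaseIOError(f"cannot create case directory {directory}: {exc}") from exc

    manifest: Dict = {
        "case_id": case.case_id,
        "prescription_gy": case.prescription_gy,
        "grid": {
            "dims": list(case.grid.dims),
            "spacing_mm": list(case.grid.spacing),
            "origin_mm": list(case.grid.origin),
        },
    }
    try:
        for prov, ss in (("manual", case.manual), ("auto", case.auto)):
            entry: Dict[str, str] = {}
            for roi, mask in ss.rois.items():
                fname = f"{prov}_{_safe_name(roi)}.nii.gz"
                _write_volume(directory / fname, case.grid, mask.occupancy.astype(np.uint8))
                entry[roi] = fname
            manifest[prov] = entry
        for key, dose in (("dose_manual", case.dose_manual), ("dose_auto", case.dose_auto)):
            fname = f"{key}.nii.gz"
            _write_volume(directory / fname, case.grid, dose.dose.astype(np.float64))
            manifest[key] = fname
        path = directory / MANIFEST_NAME
        path.write_text(json.dumps(manifest, indent=1))
    except OSError as exc:
        raise CaseIOError(f"cannot write case to {directory}: {exc}") from exc
    return path


def load_case(manifest_path: Union[str, Path]) -> Case:
    """Read a manifest written by :func:`save_case` and return a validated
    :class:`~contourdose.grids.Case`."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise CaseIOError(f"manifest not found: {manifest_path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise CaseIOError(f"cannot parse manifest {manifest_path}: {exc}") from exc
    base = manifest_path.parent

    try:
        g = manifest["grid"]
        grid = VoxelGrid(tuple(g["dims"]), tuple(g["spacing_mm"]), tuple(g["origin_mm"]))
        case_id = manifest["case_id"]
        prescription = float(manifest["prescription_gy"])
        roi_files = {prov: dict(manifest[prov]) for prov in ("manual", "auto")}
        dose_files = {k: manifest[k] for k in ("dose_manual", "dose_auto")}
    except KeyError as exc:
        raise ValidationError(f"manifest {manifest_path} is missing field {exc}") from exc

    sets = {}
    for prov, files in roi_files.items():
        rois = {}
        for roi, fname in files.items():
            arr = _read_volume(base / fname, grid)
            rois[roi] = Mask(grid, arr, roi_name=roi)  # raises if non-binary
        sets[prov] = StructureSet(grid, rois, provenance=prov)
    doses = {
        key: DoseGrid(grid, _read_volume(base / fname, grid).astype(float))
        for key, fname in dose_files.items()
    }
    return Case(
        case_id=case_id,
        manual=sets["manual"],
        auto=sets["auto"],
        dose_manual=doses["dose_manual"],
        dose_auto=doses["dose_auto"],
        prescription_gy=prescription,
    )
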