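"""Shared voxel-grid data model.

All masks and dose grids of a case live on one :class:`VoxelGrid` with
axis order ``(z, y, x)`` = (slice, row, column), 0-based indices and a
voxel-center physical mapping: voxel ``(k, j, i)`` sits at
``origin + (k*dz, j*dy, i*dx)`` in mm.  The package validates geometric
compatibility everywhere but never resamples; producing co-registered
volumes on a common grid is the data producer's job.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

import numpy as np

from .errors import GeometryError, ValidationError

#: tolerance for spacing agreement between grids, in mm
SPACING_TOL_MM = 1e-6
#: tolerance for origin agreement between grids, in mm
ORIGIN_TOL_MM = 1e-3


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry contract shared by all volumes of a case.

    Parameters
    ----------
    dims :
        ``(nz, ny, nx)`` number of voxels per axis, each >= 1.
    spacing :
        ``(dz, dy, dx)`` voxel spacing in mm, each > 0.  Anisotropic
        spacing (e.g. 5 mm slices, finer in-plane) is the normal case.
    origin :
        Physical position in mm of the center of voxel ``(0, 0, 0)``.
    """

    dims: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        dims = tuple(int(d) for d in self.dims)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(dims) != 3 or len(spacing) != 3 or len(origin) != 3:
            raise ValidationError("VoxelGrid requires 3-element dims/spacing/origin")
        if any(d < 1 for d in dims):
            raise ValidationError(f"all dims must be >= 1, got {dims}")
        if any(not np.isfinite(s) or s <= 0 for s in spacing):
            raise ValidationError(f"all spacings must be > 0 mm, got {spacing}")
        object.__setattr__(self, "dims", dims)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.dims

    @property
    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def axis_coordinates(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical center coordinates along each axis, in mm."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.dims[a], dtype=float)
            for a in range(3)
        )

    def physical_points(self, indices: np.ndarray) -> np.ndarray:
        """Map an ``(n, 3)`` array of (k, j, i) indices to mm coordinates."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


def assert_compatible(a: VoxelGrid, b: VoxelGrid) -> None:
    """Raise :class:`GeometryError` unless ``a`` and ``b`` describe the
    same grid (dims exactly; spacing within 1e-6 mm; origin within 1e-3 mm).
    """
    if a.dims != b.dims:
        raise GeometryError(f"grid dims differ: {a.dims} vs {b.dims}")
    for name, tol, av, bv in (
        ("spacing", SPACING_TOL_MM, a.spacing, b.spacing),
        ("origin", ORIGIN_TOL_MM, a.origin, b.origin),
    ):
        diff = np.abs(np.subtract(av, bv))
        if np.any(diff > tol):
            raise GeometryError(
                f"grid {name} differs beyond {tol} mm: {av} vs {bv}"
            )


def _as_binary(values: np.ndarray, roi_name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype == bool:
        return arr
    uniq = np.unique(arr)
    if not np.isin(uniq, (0, 1)).all():
        raise ValidationError(
            f"mask '{roi_name}' contains non-binary voxel values {uniq[:8]}"
        )
    return arr.astype(bool)


@dataclass(frozen=True, eq=False)
class Mask:
    """Binary occupancy of one ROI on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    occupancy: np.ndarray
    roi_name: str = ""

    def __post_init__(self) -> None:
        occ = _as_binary(self.occupancy, self.roi_name)
        if occ.shape != self.grid.dims:
            raise GeometryError(
                f"mask '{self.roi_name}' shape {occ.shape} does not match "
                f"grid dims {self.grid.dims}"
            )
        object.__setattr__(self, "occupancy", occ)

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.occupancy))

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_mm3

    @property
    def is_empty(self) -> bool:
        return self.voxel_count == 0

    def foreground_points_mm(self) -> np.ndarray:
        """Physical centers (mm) of all foreground voxels, shape (n, 3)."""
        idx = np.argwhere(self.occupancy)
        return self.grid.physical_points(idx)

    def with_name(self, roi_name: str) -> "Mask":
        return Mask(self.grid, self.occupancy, roi_name)


@dataclass(frozen=True, eq=False)
class DoseGrid:
    """Per-voxel absorbed dose in Gy on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    dose: np.ndarray

    def __post_init__(self) -> None:
        dose = np.asarray(self.dose, dtype=float)
        if dose.shape != self.grid.dims:
            raise GeometryError(
                f"dose shape {dose.shape} does not match grid dims {self.grid.dims}"
            )
        if not np.isfinite(dose).all():
            raise ValidationError("dose grid contains non-finite values")
        if (dose < 0).any():
            raise ValidationError("dose grid contains negative values")
        object.__setattr__(self, "dose", dose)

    def scaled(self, factor: float) -> "DoseGrid":
        return DoseGrid(self.grid, self.dose * float(factor))


@dataclass(frozen=True, eq=False)
class StructureSet:
    """A named collection of ROI masks sharing one grid.

    ``provenance`` records whether the contours are the clinician's
    ("manual") or the auto-segmentation's ("auto").
    """

    grid: VoxelGrid
    rois: Dict[str, Mask]
    provenance: str

    def __post_init__(self) -> None:
        if self.provenance not in ("manual", "auto"):
            raise ValidationError(
                f"provenance must be 'manual' or 'auto', got {self.provenance!r}"
            )
        for name, mask in self.rois.items():
            if mask.roi_name != name:
                raise ValidationError(
                    f"ROI key {name!r} disagrees with mask.roi_name {mask.roi_name!r}"
                )
            assert_compatible(self.grid, mask.grid)

    def __getitem__(self, roi_name: str) -> Mask:
        return self.rois[roi_name]

    def __contains__(self, roi_name: str) -> bool:
        return roi_name in self.rois

    def __iter__(self) -> Iterator[str]:
        return iter(self.rois)

    @property
    def roi_names(self) -> Tuple[str, ...]:
        return tuple(self.rois)


@dataclass(frozen=True, eq=False)
class Case:
    """One patient-like unit: two structure sets and two dose grids.

    ``dose_manual`` / ``dose_auto`` are the plans optimized on the manual
    and auto PTV respectively; both are defined on the shared grid, and
    the ROI named ``"PTV"`` must exist and be non-empty in both sets.
    """

    case_id: str
    manual: StructureSet
    auto: StructureSet
    dose_manual: DoseGrid
    dose_auto: DoseGrid
    prescription_gy: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.prescription_gy) or self.prescription_gy <= 0:
            raise ValidationError(
                f"prescription must be a positive dose in Gy, got {self.prescription_gy}"
            )
        grid = self.manual.grid
        for label, other in (
            ("auto structure set", self.auto.grid),
            ("manual dose", self.dose_manual.grid),
            ("auto dose", self.dose_auto.grid),
        ):
            try:
                assert_compatible(grid, other)
            except GeometryError as exc:
                raise GeometryError(
                    f"case {self.case_id!r}: manual structure set vs {label}: {exc}"
                ) from exc
        for prov, ss in (("manual", self.manual), ("auto", self.auto)):
            if "PTV" not in ss:
                raise ValidationError(
                    f"case {self.case_id!r}: {prov} structure set has no 'PTV' ROI"
                )
            if ss["PTV"].is_empty:
                raise ValidationError(
                    f"case {self.case_id!r}: {prov} PTV is empty"
                )

    @property
    def grid(self) -> VoxelGrid:
        return self.manual.grid
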