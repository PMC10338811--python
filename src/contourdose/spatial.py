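"""Spatial evaluation metrics relating OARs to the target, and the XOR
boundary-error analysis.

RV (relative volume) and DM (distance metric) characterize each organ at
risk by its size and distance relative to the PTV.  The XOR region — the
voxels labeled PTV by exactly one of the two contour sets — localizes the
boundary error of the auto-segmentation; its overlap with an OAR is the
quantity that drives that organ's dose change when the plan is
re-optimized on the auto contour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from .errors import UndefinedMetricError
from .grids import Mask, assert_compatible
from .geometry import mda


def relative_volume(oar: Mask, ptv: Mask) -> float:
    """RV = V_ROI / V_PTV (dimensionless; may exceed 1, e.g. lung vs PTV)."""
    assert_compatible(oar.grid, ptv.grid)
    if ptv.is_empty:
        raise UndefinedMetricError("relative volume undefined: PTV is empty")
    if oar.is_empty:
        raise UndefinedMetricError(
            f"relative volume undefined: OAR '{oar.roi_name}' is empty"
        )
    return oar.voxel_count / ptv.voxel_count


def distance_metric(oar: Mask, ptv: Mask) -> float:
    """DM = MDA(OAR, PTV) in mm: the mean surface distance between an organ
    at risk and the target."""
    return mda(oar, ptv)


def xor_mask(auto_ptv: Mask, manual_ptv: Mask) -> Mask:
    """Voxelwise exclusive-or of two PTV masks: ``(A ∪ B) \\ (A ∩ B)``."""
    assert_compatible(auto_ptv.grid, manual_ptv.grid)
    return Mask(
        auto_ptv.grid,
        auto_ptv.occupancy ^ manual_ptv.occupancy,
        roi_name=f"XOR({auto_ptv.roi_name},{manual_ptv.roi_name})",
    )


def xor_overlap(oar: Mask, xor: Mask) -> Tuple[float, float]:
    """Overlap of an OAR with the XOR boundary-error region.

    Returns ``(overlap_mm3, overlap_fraction)`` where the fraction
    normalizes by the OAR volume (in [0, 1]).
    """
    assert_compatible(oar.grid, xor.grid)
    if oar.is_empty:
        raise UndefinedMetricError(
            f"XOR overlap undefined: OAR '{oar.roi_name}' is empty"
        )
    inter = int(np.count_nonzero(oar.occupancy & xor.occupancy))
    vv = oar.grid.voxel_volume_mm3
    return inter * vv, inter / oar.voxel_count


@dataclass(frozen=True)
class SpatialMetrics:
    """RV and DM of one OAR relative to the PTV."""

    rv: float
    dm_mm: float


def spatial_report(oar: Mask, ptv: Mask) -> SpatialMetrics:
    return SpatialMetrics(rv=relative_volume(oar, ptv), dm_mm=distance_metric(oar, ptv))


@dataclass(frozen=True)
class XorAnalysis:
    """XOR region volume and its per-OAR overlaps."""

    xor_volume_mm3: float
    oar_overlap_mm3: Dict[str, float]
    oar_overlap_fraction: Dict[str, float]


def xor_analysis(auto_ptv: Mask, manual_ptv: Mask, oars: Dict[str, Mask]) -> XorAnalysis:
    """XOR the two PTVs and measure each OAR's overlap with the result."""
    xor = xor_mask(auto_ptv, manual_ptv)
    mm3: Dict[str, float] = {}
    frac: Dict[str, float] = {}
    for name, oar in oars.items():
        mm3[name], frac[name] = xor_overlap(oar, xor)
    return XorAnalysis(
        xor_volume_mm3=xor.volume_mm3, oar_overlap_mm3=mm3, oar_overlap_fraction=frac
    )
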