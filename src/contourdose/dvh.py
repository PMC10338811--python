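"""DVH computation and plan evaluation indices.

``D_X`` (minimum dose to the hottest X% of an ROI) is computed by exact
sorting of the ROI's voxel doses with linear interpolation between order
statistics; the binned cumulative DVH exists only for reporting and
plotting.  ``HI = D5/D95`` and ``CI = (V_R*V_R)/(V_T*V_dose)`` follow the
standard homogeneity/conformity definitions, with the reference isodose
defaulting to 100% of the prescription — the natural choice given the
plan-normalization convention that 95% of the PTV receives the full
prescription dose.

Per-ROI clinical evaluation follows the breast plan protocol: targets get
Dmean/Dmax/Dmin/CI/HI (constraints D95 > prescription, D2 < 110%
prescription); OARs get their organ-specific endpoint (heart mean dose
< 8 Gy; lung V5 < 60% and V20 < 35%; spinal cord Dmax < 45 Gy; esophagus,
thyroid and humeral-head mean dose < 25 Gy; contralateral breast V5 < 10%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .errors import NormalizationError, UndefinedMetricError
from .grids import Case, DoseGrid, Mask, assert_compatible

DEFAULT_BIN_WIDTH_GY = 0.01


def _roi_doses(dose: DoseGrid, roi: Mask) -> np.ndarray:
    assert_compatible(dose.grid, roi.grid)
    if roi.is_empty:
        raise UndefinedMetricError(
            f"dosimetric metric undefined: ROI '{roi.roi_name}' is empty"
        )
    return dose.dose[roi.occupancy]


@dataclass(frozen=True)
class DVH:
    """Cumulative dose-volume curve of one ROI under one plan."""

    roi_name: str
    dose_edges_gy: np.ndarray
    cumulative_volume_pct: np.ndarray
    total_volume_mm3: float


def cumulative_dvh(dose: DoseGrid, roi: Mask,
                   bin_width_gy: float = DEFAULT_BIN_WIDTH_GY) -> DVH:
    """Cumulative DVH: at each dose edge d, the percentage of the ROI
    volume receiving at least d.  Edges span [0, max dose + one bin]."""
    if bin_width_gy <= 0:
        raise ValueError("bin width must be > 0 Gy")
    ds = np.sort(_roi_doses(dose, roi))
    n = ds.size
    n_bins = int(np.ceil(ds[-1] / bin_width_gy)) + 1
    edges = np.arange(n_bins + 1) * bin_width_gy
    pct = 100.0 * (n - np.searchsorted(ds, edges, side="left")) / n
    return DVH(
        roi_name=roi.roi_name,
        dose_edges_gy=edges,
        cumulative_volume_pct=pct,
        total_volume_mm3=roi.volume_mm3,
    )


def dose_at_volume(dose: DoseGrid, roi: Mask, x_pct: float) -> float:
    """D_X in Gy: the dose received by at least X% of the ROI volume,
    from exact voxel-dose sorting with linear interpolation."""
    if not 0 < x_pct <= 100:
        raise ValueError(f"x_pct must be in (0, 100], got {x_pct}")
    ds = _roi_doses(dose, roi)
    return float(np.quantile(ds, 1.0 - x_pct / 100.0, method="linear"))


def volume_at_dose(dose: DoseGrid, roi: Mask, d_gy: float) -> float:
    """V_d as a percentage: 100 * fraction of ROI voxels with dose >= d."""
    if d_gy < 0:
        raise ValueError(f"dose threshold must be >= 0 Gy, got {d_gy}")
    ds = _roi_doses(dose, roi)
    return float(100.0 * np.count_nonzero(ds >= d_gy) / ds.size)


def homogeneity_index(dose: DoseGrid, target: Mask) -> float:
    """HI = D5 / D95 (>= 1; 1 means perfectly uniform target dose)."""
    d95 = dose_at_volume(dose, target, 95.0)
    if d95 <= 0:
        raise UndefinedMetricError(
            f"HI undefined for '{target.roi_name}': D95 is zero"
        )
    return dose_at_volume(dose, target, 5.0) / d95


def conformity_index(dose: DoseGrid, target: Mask,
                     reference_dose_gy: float) -> float:
    """CI = (V_R * V_R) / (V_T * V_dose) in [0, 1].

    V_T is the target volume, V_dose the volume of the reference isodose
    region (dose >= reference), V_R the target volume covered by that
    region.  Returns 0 in the limiting case V_R = 0 (target entirely
    below the reference dose).
    """
    assert_compatible(dose.grid, target.grid)
    if target.is_empty:
        raise UndefinedMetricError("CI undefined: target is empty")
    if reference_dose_gy <= 0:
        raise ValueError("reference dose must be > 0 Gy")
    isodose = dose.dose >= reference_dose_gy
    v_dose = int(np.count_nonzero(isodose))
    if v_dose == 0:
        raise UndefinedMetricError(
            f"CI undefined: no voxel reaches the reference dose {reference_dose_gy} Gy"
        )
    v_t = target.voxel_count
    v_r = int(np.count_nonzero(isodose & target.occupancy))
    return (v_r * v_r) / (v_t * v_dose)


def conformity_inputs_mm3(dose: DoseGrid, target: Mask,
                          reference_dose_gy: float) -> Tuple[float, float, float]:
    """(V_T, V_dose, V_R) in mm^3 for the conformity index."""
    isodose = dose.dose >= reference_dose_gy
    vv = dose.grid.voxel_volume_mm3
    return (
        target.voxel_count * vv,
        int(np.count_nonzero(isodose)) * vv,
        int(np.count_nonzero(isodose & target.occupancy)) * vv,
    )


def normalize_to_coverage(dose: DoseGrid, ptv: Mask,
                          prescription_gy: float) -> DoseGrid:
    """Scale the dose grid so that 95% of the PTV receives 100% of the
    prescription dose, i.e. D95(PTV) = prescription exactly."""
    if prescription_gy <= 0:
        raise ValueError("prescription must be > 0 Gy")
    d95 = dose_at_volume(dose, ptv, 95.0)
    if d95 <= 0:
        raise NormalizationError(
            f"cannot normalize: D95 of '{ptv.roi_name}' is zero"
        )
    return dose.scaled(prescription_gy / d95)


# ---------------------------------------------------------------------------
# clinical per-ROI evaluation (plan protocol table)

#: per-OAR evaluation endpoints and dose constraints, keyed by a
#: case-insensitive ROI name; thresholds in Gy or % as appropriate.
OAR_PROTOCOL: Dict[str, dict] = {
    "breastcon": {"metrics": ["v5"], "constraints": [("V5 < 10%", "v5", 10.0)]},
    "esophagus": {"metrics": ["d_mean"], "constraints": [("Dmean < 25 Gy", "d_mean", 25.0)]},
    "heart": {"metrics": ["d_mean"], "constraints": [("Dmean < 8 Gy", "d_mean", 8.0)]},
    "humeralhead": {"metrics": ["d_mean"], "constraints": [("Dmean < 25 Gy", "d_mean", 25.0)]},
    "lung": {"metrics": ["v5", "v20"],
             "constraints": [("V5 < 60%", "v5", 60.0), ("V20 < 35%", "v20", 35.0)]},
    "spinalcord": {"metrics": ["d_max"], "constraints": [("Dmax < 45 Gy", "d_max", 45.0)]},
    "thyroid": {"metrics": ["d_mean"], "constraints": [("Dmean < 25 Gy", "d_mean", 25.0)]},
}

#: endpoints reported for an OAR whose name is not in the protocol table
DEFAULT_OAR_METRICS = ["d_mean", "d_max"]


def _protocol_for(roi_name: str) -> Optional[dict]:
    key = roi_name.replace("_", "").replace(" ", "").lower()
    return OAR_PROTOCOL.get(key)


@dataclass(frozen=True)
class PlanRoiMetrics:
    """Evaluation-set values for one ROI under one plan."""

    roi_name: str
    role: str  # "target" | "oar"
    d_mean_gy: float
    d_max_gy: float
    d_min_gy: float
    d_at: Dict[float, float] = field(default_factory=dict)   # X% -> Gy
    v_at: Dict[float, float] = field(default_factory=dict)   # Gy -> % volume
    hi: Optional[float] = None
    ci: Optional[float] = None
    conformity_inputs: Optional[Tuple[float, float, float]] = None
    constraints: Dict[str, bool] = field(default_factory=dict)

    def metric(self, key: str) -> float:
        """Look up a metric by short key: d_mean, d_max, d_min, hi, ci,
        v5, v20, d95, d2 ..."""
        simple = {"d_mean": self.d_mean_gy, "d_max": self.d_max_gy,
                  "d_min": self.d_min_gy, "hi": self.hi, "ci": self.ci}
        if key in simple:
            val = simple[key]
            if val is None:
                raise KeyError(f"metric {key!r} not evaluated for {self.roi_name!r}")
            return val
        if key.startswith("v"):
            return self.v_at[float(key[1:])]
        if key.startswith("d"):
            return self.d_at[float(key[1:])]
        raise KeyError(key)


def evaluate_roi(dose: DoseGrid, roi: Mask, role: str,
                 prescription_gy: float,
                 reference_dose_gy: Optional[float] = None) -> PlanRoiMetrics:
    """Compute the protocol evaluation set for one ROI.

    Targets: Dmean/Dmax/Dmin, D2/D5/D95/D98, HI, CI (reference isodose =
    prescription unless overridden) and the target coverage constraints.
    OARs: Dmean/Dmax plus the organ-specific endpoints and constraint
    flags from :data:`OAR_PROTOCOL`.
    """
    if role not in ("target", "oar"):
        raise ValueError(f"role must be 'target' or 'oar', got {role!r}")
    ds = _roi_doses(dose, roi)
    d_mean, d_max, d_min = float(ds.mean()), float(ds.max()), float(ds.min())
    d_at: Dict[float, float] = {}
    v_at: Dict[float, float] = {}
    hi = ci = None
    conf = None
    constraints: Dict[str, bool] = {}

    if role == "target":
        for x in (2.0, 5.0, 95.0, 98.0):
            d_at[x] = dose_at_volume(dose, roi, x)
        hi = homogeneity_index(dose, roi)
        ref = prescription_gy if reference_dose_gy is None else reference_dose_gy
        ci = conformity_index(dose, roi, ref)
        conf = conformity_inputs_mm3(dose, roi, ref)
        constraints["D95 > prescription"] = d_at[95.0] > prescription_gy
        constraints["D2 < 110% prescription"] = d_at[2.0] < 1.10 * prescription_gy
    else:
        proto = _protocol_for(roi.roi_name)
        metrics = proto["metrics"] if proto else DEFAULT_OAR_METRICS
        for key in metrics:
            if key.startswith("v"):
                v_at[float(key[1:])] = volume_at_dose(dose, roi, float(key[1:]))
        if proto:
            for label, key, limit in proto["constraints"]:
                val = {"d_mean": d_mean, "d_max": d_max}.get(key)
                if val is None:
                    val = v_at[float(key[1:])]
                constraints[label] = val < limit

    return PlanRoiMetrics(
        roi_name=roi.roi_name, role=role,
        d_mean_gy=d_mean, d_max_gy=d_max, d_min_gy=d_min,
        d_at=d_at, v_at=v_at, hi=hi, ci=ci,
        conformity_inputs=conf, constraints=constraints,
    )


#: metric keys reported per ROI role in plan-difference tables
TARGET_DELTA_METRICS = ("d_mean", "d_max", "d_min", "hi", "ci")


def _oar_delta_metrics(roi_name: str) -> Tuple[str, ...]:
    proto = _protocol_for(roi_name)
    return tuple(proto["metrics"]) if proto else ("d_mean",)


def _delta_block(m: PlanRoiMetrics, a: PlanRoiMetrics,
                 keys: Sequence[str]) -> Dict[str, Dict[str, float]]:
    return {
        key: {"manual": m.metric(key), "auto": a.metric(key),
              "delta": a.metric(key) - m.metric(key)}
        for key in keys
    }


def ptv_dose_differences(case: Case, evaluate_on: str = "manual"
                         ) -> Dict[str, Dict[str, float]]:
    """ΔDmean/ΔDmax/ΔDmin/ΔHI/ΔCI of the target between the two plans.

    With ``evaluate_on="manual"`` (default) both plans are scored against
    the manual (ground-truth) PTV — the clinically meaningful question of
    what the auto plan delivers to the true target; ``evaluate_on="own"``
    scores each plan on its own PTV instead.
    """
    if evaluate_on not in ("manual", "own"):
        raise ValueError(f"evaluate_on must be 'manual' or 'own', got {evaluate_on!r}")
    ptv_for_auto = case.manual["PTV"] if evaluate_on == "manual" else case.auto["PTV"]
    m = evaluate_roi(case.dose_manual, case.manual["PTV"], "target",
                     case.prescription_gy)
    a = evaluate_roi(case.dose_auto, ptv_for_auto, "target", case.prescription_gy)
    return _delta_block(m, a, TARGET_DELTA_METRICS)


def oar_dose_differences(case: Case, roi_name: str
                         ) -> Dict[str, Dict[str, float]]:
    """Δ of one OAR's protocol endpoint(s) between the two plans
    (always evaluated on the manual contour)."""
    roi = case.manual[roi_name]
    m = evaluate_roi(case.dose_manual, roi, "oar", case.prescription_gy)
    a = evaluate_roi(case.dose_auto, roi, "oar", case.prescription_gy)
    return _delta_block(m, a, _oar_delta_metrics(roi_name))


def dose_differences(case: Case, evaluate_on: str = "manual"
                     ) -> Dict[str, Dict[str, Dict[str, float]]]:
    """Per-ROI dosimetric differences between Auto-plan and Manual-plan:
    the target block from :func:`ptv_dose_differences` plus one block per
    OAR.  Returns ``{roi: {metric: {"manual": v, "auto": v,
    "delta": auto - manual}}}``; swapping the two plans negates every
    delta."""
    out: Dict[str, Dict[str, Dict[str, float]]] = {
        "PTV": ptv_dose_differences(case, evaluate_on)
    }
    for roi_name in case.manual.rois:
        if roi_name == "PTV" or roi_name.upper().startswith("CTV"):
            continue
        out[roi_name] = oar_dose_differences(case, roi_name)
    return out
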