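"""Synthetic thorax cohort generator.

Emulates the study conditions the downstream analysis assumes, without any
patient data:

* an elliptical thorax cross-section carrying a concave, chest-wall-like
  target — a thin wall sector hugging the left-anterior body surface,
  mimicking the post-mastectomy chest-wall CTV ("irregular, concave" and
  bowing around the lung);
* organs at risk of varying size and distance to the target (heart, lung,
  spinal cord, esophagus, contralateral breast, thyroid, humeral head),
  the lung carved around the mediastinal organs as real lungs are;
* smooth random contour perturbations of controllable amplitude standing
  in for auto-segmentation variation (plus optional rigid shifts as
  calibration controls);
* a steep-gradient, PTV-conformal dose model for each plan, normalized so
  95% of the PTV receives 100% of the prescription.

All randomness flows from explicit integer seeds; per-case seeds are
derived from the master seed with :class:`numpy.random.SeedSequence`, so
cohorts are reproducible piecewise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

from .errors import GenerationError
from .geometry import expand_margin, surface_voxels
from .grids import Case, DoseGrid, Mask, StructureSet, VoxelGrid
from .dvh import normalize_to_coverage

#: CTV -> PTV margin in mm (setup error + respiratory motion allowance)
DEFAULT_MARGIN_MM = 5.0
#: prescription in Gy (50 Gy in 25 fractions)
DEFAULT_PRESCRIPTION_GY = 50.0


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class OrganSpec:
    """One OAR primitive.

    ``shape`` is ``"ellipsoid"`` or ``"cylinder_z"`` (vertical cylinder:
    ``radii_mm[0]`` = half-length in z, ``radii_mm[1:]`` = in-plane radii).
    If ``bearing_deg``/``wall_gap_mm`` are set the in-plane center is placed
    along that bearing (degrees from anterior toward the treated side) at
    the stated clearance inside the chest wall; otherwise ``center_mm``
    gives (z absolute, y offset, x offset) relative to the body axis.
    ``carve=True`` clips the organ to the interior clearance of the wall
    and around previously placed organs (used for the lung).
    """

    shape: str
    radii_mm: Tuple[float, float, float]
    center_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    bearing_deg: Optional[float] = None
    wall_gap_mm: float = 3.0
    gap_jitter_mm: float = 0.0
    carve: bool = False


@dataclass(frozen=True)
class AnatomyParams:
    """Thorax geometry: grid, body ellipse, chest-wall sector, organs.

    Angles are measured from the anterior direction (+y) toward the
    treated side; ``laterality`` mirrors everything in x.  ``seed`` drives
    the per-case jitter of sizes and offsets ("very patient-specific"
    geometry); the same seed always yields the same structure set.
    """

    dims: Tuple[int, int, int] = (18, 64, 80)
    spacing_mm: Tuple[float, float, float] = (5.0, 3.0, 3.0)
    origin_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    body_semiaxes_mm: Tuple[float, float] = (82.0, 112.0)  # (ay, ax)
    wall_thickness_mm: float = 10.0
    wall_extent_deg: float = 90.0
    wall_center_deg: float = 40.0
    wall_z_mm: Tuple[float, float] = (15.0, 65.0)
    laterality: str = "left"
    organs: Dict[str, OrganSpec] = field(default_factory=lambda: default_organs())
    jitter: float = 1.0  # 0 disables all anatomical jitter
    split_subtargets: bool = False
    seed: int = 0


def default_organs() -> Dict[str, OrganSpec]:
    """Default OAR layout (sizes in mm, ordered so carved organs come
    after the organs they must wrap around)."""
    return {
        "Heart": OrganSpec("ellipsoid", (22.0, 26.0, 28.0), (37.5, 0.0, 0.0),
                           bearing_deg=25.0, wall_gap_mm=4.0, gap_jitter_mm=1.5),
        "SpinalCord": OrganSpec("cylinder_z", (40.0, 5.0, 5.0), (42.5, -58.0, 0.0)),
        "Esophagus": OrganSpec("cylinder_z", (40.0, 5.0, 5.0), (42.5, -36.0, -8.0)),
        "Breast_con": OrganSpec("ellipsoid", (18.0, 20.0, 26.0), (35.0, 0.0, 0.0),
                                bearing_deg=-50.0, wall_gap_mm=-5.0),
        "Lung": OrganSpec("ellipsoid", (32.0, 58.0, 48.0), (40.0, 0.0, 0.0),
                          bearing_deg=55.0, wall_gap_mm=2.0, carve=True),
        "Thyroid": OrganSpec("ellipsoid", (7.0, 9.0, 13.0), (80.0, 10.0, 0.0)),
        "HumeralHead": OrganSpec("ellipsoid", (12.0, 12.0, 12.0), (80.0, 15.0, 98.0)),
    }


@dataclass(frozen=True)
class PerturbParams:
    """Smooth random contour perturbation emulating auto-segmentation
    variation.

    ``amplitude_mm`` is the RMS magnitude of a Gaussian-correlated random
    displacement field (correlation scale ``correlation_length_mm``);
    ``rigid_shift_mm`` adds a whole-structure translation (z, y, x) — the
    classical setup-error control.  Amplitude 0 with zero shift reproduces
    the input mask exactly.
    """

    amplitude_mm: float = 3.0
    correlation_length_mm: float = 25.0
    rigid_shift_mm: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0


@dataclass(frozen=True)
class DoseModelParams:
    """Distance-based surrogate for an IMRT plan.

    Dose = prescription inside the PTV, falling sigmoidally with the
    signed Euclidean distance to the PTV surface so that it reaches 50% of
    the prescription ``gradient_mm_per_halfdose`` mm outside; a smooth
    multiplicative noise field (sd in Gy, at prescription level) models
    in-target dose inhomogeneity and a mild linear weighting along
    ``asymmetry_axis`` models the tangential-beam direction.  The result
    is renormalized so D95(PTV) equals the prescription exactly.
    """

    prescription_gy: float = DEFAULT_PRESCRIPTION_GY
    gradient_mm_per_halfdose: float = 7.0
    uniformity_noise_sd_gy: float = 0.8
    noise_correlation_mm: float = 12.0
    asymmetry_axis: str = "x"
    asymmetry_weight: float = 0.05
    seed: int = 0


# ---------------------------------------------------------------------------
# anatomy


def _body_radius_mm(ay: float, ax: float, bearing_deg: float) -> float:
    b = math.radians(bearing_deg)
    return 1.0 / math.sqrt((math.sin(b) / ax) ** 2 + (math.cos(b) / ay) ** 2)


def _inplane_radius_mm(ry: float, rx: float, bearing_deg: float) -> float:
    b = math.radians(bearing_deg)
    return math.sqrt((rx * math.sin(b)) ** 2 + (ry * math.cos(b)) ** 2)


def _grids_mm(grid: VoxelGrid, center_yx: Tuple[float, float]
              ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    z, y, x = grid.axis_coordinates()
    zz = z[:, None, None]
    yy = (y - center_yx[0])[None, :, None]
    xx = (x - center_yx[1])[None, None, :]
    return zz, yy, xx


def _organ_mask(grid: VoxelGrid, center_yx: Tuple[float, float],
                spec: OrganSpec, center_zyx: Tuple[float, float, float]
                ) -> np.ndarray:
    zz, yy, xx = _grids_mm(grid, center_yx)
    cz, cy, cx = center_zyx
    rz, ry, rx = spec.radii_mm
    if spec.shape == "ellipsoid":
        return (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2
                + ((xx - cx) / rx) ** 2) <= 1.0
    if spec.shape == "cylinder_z":
        return ((np.abs(zz - cz) <= rz)
                & ((((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2) <= 1.0))
    raise GenerationError(f"unknown organ shape {spec.shape!r}")


def _concavity_ratio(ctv: Mask) -> float:
    pts = ctv.grid.physical_points(np.argwhere(surface_voxels(ctv)))
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:  # degenerate (flat) target
        raise GenerationError(f"target too degenerate for hull test: {exc}") from exc
    return hull.volume / ctv.volume_mm3


def generate_anatomy(params: AnatomyParams, validate: bool = True) -> StructureSet:
    """Generate the manual structure set: chest-wall CTV plus OARs.

    Deterministic given ``params.seed``.  Raises
    :class:`~contourdose.errors.GenerationError` if an organ collides with
    the CTV or another organ, or if the target fails its concavity check.
    """
    rng = np.random.default_rng(params.seed)
    j = params.jitter

    grid = VoxelGrid(params.dims, params.spacing_mm, params.origin_mm)
    nz, ny, nx = grid.dims
    dz, dy, dx = grid.spacing
    center_yx = (grid.origin[1] + dy * (ny - 1) / 2.0,
                 grid.origin[2] + dx * (nx - 1) / 2.0)
    lat = 1.0 if params.laterality == "left" else -1.0

    ay = params.body_semiaxes_mm[0] * (1.0 + j * rng.uniform(-0.06, 0.06))
    ax = params.body_semiaxes_mm[1] * (1.0 + j * rng.uniform(-0.06, 0.06))
    thickness = params.wall_thickness_mm * (1.0 + j * rng.uniform(-0.15, 0.15))
    extent = params.wall_extent_deg + j * rng.uniform(-5.0, 5.0)
    center_ang = lat * (params.wall_center_deg + j * rng.uniform(-5.0, 5.0))

    zz, yy, xx = _grids_mm(grid, center_yx)
    body = ((yy / ay) ** 2 + (xx / ax) ** 2) <= 1.0
    body3 = np.broadcast_to(body, grid.dims)
    depth = ndi.distance_transform_edt(body3, sampling=grid.spacing)

    theta = np.degrees(np.arctan2(xx, yy))  # 0 = anterior, + toward left
    ang_lo, ang_hi = center_ang - extent / 2.0, center_ang + extent / 2.0
    in_sector = (theta >= ang_lo) & (theta <= ang_hi)
    z_lo, z_hi = params.wall_z_mm
    in_z = (zz >= z_lo) & (zz <= z_hi)
    ctv_occ = body3 & (depth <= thickness) & in_sector & in_z
    ctv = Mask(grid, ctv_occ, roi_name="CTV")
    if ctv.is_empty:
        raise GenerationError("generated CTV is empty; enlarge the wall sector")

    rois: Dict[str, Mask] = {"CTV": ctv}
    organ_occs: Dict[str, np.ndarray] = {}
    for name, spec in params.organs.items():
        cz = spec.center_mm[0] + j * rng.uniform(-2.0, 2.0)
        radii = tuple(r * (1.0 + j * rng.uniform(-0.07, 0.07)) for r in spec.radii_mm)
        spec_j = replace(spec, radii_mm=radii)
        if spec.bearing_deg is not None:
            bearing = lat * spec.bearing_deg + j * rng.uniform(-3.0, 3.0)
            gap = spec.wall_gap_mm + j * rng.uniform(-spec.gap_jitter_mm,
                                                     spec.gap_jitter_mm)
            r_c = (_body_radius_mm(ay, ax, bearing) - thickness - gap
                   - _inplane_radius_mm(radii[1], radii[2], bearing))
            b = math.radians(bearing)
            cy, cx = r_c * math.cos(b), r_c * math.sin(b)
        else:
            cy = spec.center_mm[1] + j * rng.uniform(-2.0, 2.0)
            cx = lat * spec.center_mm[2] + j * rng.uniform(-2.0, 2.0)
        occ = _organ_mask(grid, center_yx, spec_j, (cz, cy, cx))

        if spec.carve:
            # wrap around the wall and around previously placed organs,
            # keeping >= 1.5 mm clearance (the lung behaves this way)
            occ &= body3 & (depth > thickness + 1.5)
            for prev in organ_occs.values():
                occ &= ndi.distance_transform_edt(
                    ~prev, sampling=grid.spacing) > 2.0
        if not occ.any():
            raise GenerationError(f"organ {name!r} came out empty")
        if (occ & ctv_occ).any():
            raise GenerationError(
                f"organ {name!r} collides with the CTV; increase its offset or gap"
            )
        for other, prev in organ_occs.items():
            if (occ & prev).any():
                raise GenerationError(
                    f"organs {name!r} and {other!r} overlap; increase their offsets"
                )
        organ_occs[name] = occ
        rois[name] = Mask(grid, occ, roi_name=name)

    if validate:
        ratio = _concavity_ratio(ctv)
        if ratio < 1.1:
            raise GenerationError(
                f"target not concave enough: hull/volume ratio {ratio:.3f} < 1.1"
            )

    if params.split_subtargets:
        rois.update(_split_subtargets(ctv, theta, zz, center_ang, extent,
                                      (z_lo, z_hi)))

    return StructureSet(grid, rois, provenance="manual")


def _split_subtargets(ctv: Mask, theta: np.ndarray, zz: np.ndarray,
                      center_ang: float, extent: float,
                      z_range: Tuple[float, float]) -> Dict[str, Mask]:
    """Partition the chest-wall CTV into the four clinical sub-targets:
    supra/infraclavicular nodes (top band), axillary nodes (lateral upper),
    internal mammary nodes (medial strip), chest wall (remainder)."""
    occ = ctv.occupancy
    z_lo, z_hi = z_range
    sign = 1.0 if center_ang >= 0 else -1.0
    medial_edge = center_ang - sign * extent / 2.0
    lateral_edge = center_ang + sign * extent / 2.0
    rel = sign * (theta - medial_edge)  # 0 at medial edge, grows laterally

    scn = occ & (zz >= z_hi - 0.22 * (z_hi - z_lo))
    aln = occ & ~scn & (rel >= 0.78 * extent) & (zz >= (z_lo + z_hi) / 2.0)
    imn = occ & ~scn & ~aln & (rel <= 0.18 * extent)
    cw = occ & ~scn & ~aln & ~imn
    out = {}
    for name, sub in (("CTV_SCN", scn), ("CTV_ALN", aln),
                      ("CTV_IMN", imn), ("CTV_CW", cw)):
        out[name] = Mask(ctv.grid, sub, roi_name=name)
    return out


# ---------------------------------------------------------------------------
# contour perturbation


def _signed_distance(occ: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Signed Euclidean distance (mm), negative inside the mask."""
    outside = ndi.distance_transform_edt(~occ, sampling=spacing)
    inside = ndi.distance_transform_edt(occ, sampling=spacing)
    return outside - inside


def perturb_mask(m: Mask, params: PerturbParams) -> Mask:
    """Warp a mask with a smooth random displacement field plus a rigid
    shift; deterministic given ``params.seed``."""
    if m.is_empty:
        raise GenerationError(f"cannot perturb empty mask '{m.roi_name}'")
    shift = np.asarray(params.rigid_shift_mm, dtype=float)
    if params.amplitude_mm == 0 and not shift.any():
        return Mask(m.grid, m.occupancy.copy(), roi_name=m.roi_name)
    if params.amplitude_mm < 0:
        raise ValueError("amplitude must be >= 0 mm")

    spacing = np.asarray(m.grid.spacing, dtype=float)
    sdf = _signed_distance(m.occupancy, spacing)

    disp_mm = np.zeros((3,) + m.grid.dims)
    if params.amplitude_mm > 0:
        rng = np.random.default_rng(params.seed)
        sigma_vox = np.maximum(params.correlation_length_mm / spacing, 1e-6)
        for a in range(3):
            disp_mm[a] = ndi.gaussian_filter(
                rng.standard_normal(m.grid.dims), sigma=sigma_vox)
        rms = float(np.sqrt(np.mean(np.sum(disp_mm ** 2, axis=0))))
        if rms > 0:
            disp_mm *= params.amplitude_mm / rms

    coords = np.indices(m.grid.dims, dtype=float)
    sample = [coords[a] + (disp_mm[a] - shift[a]) / spacing[a] for a in range(3)]
    warped = ndi.map_coordinates(sdf, sample, order=1, mode="nearest")
    occ = warped < 0
    if not occ.any():
        raise GenerationError(
            f"perturbation (amplitude {params.amplitude_mm} mm) emptied "
            f"mask '{m.roi_name}'"
        )
    return Mask(m.grid, occ, roi_name=m.roi_name)


# ---------------------------------------------------------------------------
# dose model


def synthetic_dose(ptv: Mask, params: DoseModelParams) -> DoseGrid:
    """Steep-gradient PTV-conformal dose, normalized so D95(PTV) equals
    the prescription exactly."""
    if ptv.is_empty:
        raise GenerationError("cannot build a dose distribution for an empty PTV")
    g = params.gradient_mm_per_halfdose
    if g <= 0:
        raise ValueError("gradient_mm_per_halfdose must be > 0")
    rx = params.prescription_gy
    spacing = np.asarray(ptv.grid.spacing, dtype=float)

    s = _signed_distance(ptv.occupancy, spacing)
    k = math.log(49.0) / g  # dose(surface) = 98% Rx, dose(g outside) = 50% Rx
    expo = np.clip(k * (s - g), -60.0, 60.0)
    dose = rx / (1.0 + np.exp(expo))

    if params.uniformity_noise_sd_gy > 0:
        rng = np.random.default_rng(params.seed)
        sigma_vox = np.maximum(params.noise_correlation_mm / spacing, 1e-6)
        eps = ndi.gaussian_filter(rng.standard_normal(ptv.grid.dims), sigma=sigma_vox)
        sd = float(eps.std())
        if sd > 0:
            dose *= 1.0 + (params.uniformity_noise_sd_gy / rx) * (eps / sd)

    if params.asymmetry_weight:
        axis = {"z": 0, "y": 1, "x": 2}[params.asymmetry_axis]
        c = ptv.grid.axis_coordinates()[axis]
        span = (c[-1] - c[0]) or 1.0
        u_axis = 2.0 * (c - c[0]) / span - 1.0
        shape = [1, 1, 1]
        shape[axis] = -1
        dose *= 1.0 + params.asymmetry_weight * u_axis.reshape(shape)

    dose = np.maximum(dose, 0.0)
    return normalize_to_coverage(DoseGrid(ptv.grid, dose), ptv, rx)


# ---------------------------------------------------------------------------
# cases and cohorts


def generate_case(anatomy: AnatomyParams, perturb: PerturbParams,
                  dose_model: DoseModelParams, case_id: str,
                  margin_mm: float = DEFAULT_MARGIN_MM) -> Case:
    """Build one complete case.

    Manual CTV -> PTV by uniform margin expansion; auto CTV by perturbing
    the manual CTV, expanded with the same margin; one dose grid per plan
    from the same dose-model seed, each conformal to its own PTV.
    """
    manual = generate_anatomy(anatomy)
    ctv_m = manual["CTV"]
    ptv_m = expand_margin(ctv_m, margin_mm).with_name("PTV")
    ctv_a = perturb_mask(ctv_m, perturb)
    ptv_a = expand_margin(ctv_a, margin_mm).with_name("PTV")

    manual_rois = dict(manual.rois)
    manual_rois["PTV"] = ptv_m
    manual_full = StructureSet(manual.grid, manual_rois, provenance="manual")
    auto = StructureSet(manual.grid, {"CTV": ctv_a, "PTV": ptv_a},
                        provenance="auto")

    dose_m = synthetic_dose(ptv_m, dose_model)
    dose_a = synthetic_dose(ptv_a, dose_model)
    return Case(case_id=case_id, manual=manual_full, auto=auto,
                dose_manual=dose_m, dose_auto=dose_a,
                prescription_gy=dose_model.prescription_gy)


def _case_seeds(master_seed: int, index: int) -> Tuple[int, int, int, int]:
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return tuple(int(s) & 0x7FFFFFFF for s in ss.generate_state(4))


def iter_cohort(n: int, master_seed: int,
                anatomy: Optional[AnatomyParams] = None,
                perturb: Optional[PerturbParams] = None,
                dose_model: Optional[DoseModelParams] = None,
                amplitude_range_mm: Tuple[float, float] = (0.5, 10.0),
                ) -> Iterator[Case]:
    """Yield ``n`` cases one at a time (per-case seeds derived from
    ``master_seed``; anatomy jittered case to case; perturbation
    amplitudes drawn uniformly from ``amplitude_range_mm``)."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    anatomy = anatomy or AnatomyParams()
    perturb = perturb or PerturbParams()
    dose_model = dose_model or DoseModelParams()
    lo, hi = amplitude_range_mm
    if lo < 0 or hi < lo:
        raise ValueError(f"invalid amplitude range {amplitude_range_mm}")
    for i in range(n):
        s_anat, s_pert, s_dose, s_amp = _case_seeds(master_seed, i)
        amp = float(np.random.default_rng(s_amp).uniform(lo, hi))
        yield generate_case(
            replace(anatomy, seed=s_anat),
            replace(perturb, amplitude_mm=amp, seed=s_pert),
            replace(dose_model, seed=s_dose),
            case_id=f"case{i:03d}",
        )


def generate_cohort(n: int, master_seed: int, **kwargs) -> List[Case]:
    """Materialize :func:`iter_cohort` as a list."""
    return list(iter_cohort(n, master_seed, **kwargs))
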