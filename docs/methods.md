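# Methods

## Problem and scope

Auto-segmentation of radiotherapy targets is usually scored with purely
geometric metrics (DSC, JI, HD, MDA), but the clinically relevant
question is dosimetric: when a plan is re-optimized on the auto contour,
how much does the dose to the true target and to the organs at risk
change, and which contour-quality metrics predict that change?
`contourdose` implements the metric definitions, the DVH dosimetry, the
cohort correlation machinery, and a synthetic thorax cohort that supplies
the statistical structure the analysis assumes — a concave chest-wall
target under a steep, target-conformal dose gradient with nearby OARs.
It does not implement a segmentation model, an IMRT optimizer, image
registration or resampling: all volumes of a case must arrive
co-registered on one voxel grid, and the package validates but never
resamples.

## Data model and conventions

Arrays are indexed `(z, y, x)` = (slice, row, column), 0-based, with a
voxel-center physical mapping (voxel `(k, j, i)` at
`origin + (k·dz, j·dy, i·dx)` mm). All distances are Euclidean in
physical mm, so the usual CT anisotropy (5 mm slices, finer in-plane) is
handled correctly. Masks are strictly binary; dose is stored in Gy.
Grids must agree exactly in dims and within 1e-6 mm (spacing) / 1e-3 mm
(origin); those tolerances absorb the float32 affines of the NIfTI
container, while the JSON manifest carries the authoritative geometry at
full precision.

## Geometric metrics

DSC and JI are computed on voxel counts (region overlap); HD and MDA on
surfaces. A surface voxel is a foreground voxel with at least one
background face-neighbor (6-connectivity), the grid border counting as
background. Nearest-surface distances come from an exact Euclidean
distance transform of each surface set, sampled at the other set's
surface voxels; the test suite pins this against a brute-force all-pairs
computation to 1e-9 mm. HD is the exact 100th-percentile Hausdorff by
default (a percentile argument provides HD95-style robust variants, never
the default). Comparing two empty masks is an error, not a score:
empty structures are not evaluable, and silently returning 1 or 0 would
poison cohort statistics.

Margin expansion (CTV→PTV, default 5 mm) selects every voxel whose
center lies within the margin of some foreground voxel center, via the
same distance transform; with a margin below the smallest spacing it is
the identity.

## Spatial metrics and the XOR region

RV = V_ROI/V_PTV and DM = MDA(OAR, PTV) summarize each OAR's size and
distance relative to the target. (DM is sometimes loosely called a
"mean Hausdorff distance"; the implementation is exactly the MDA of the
OAR/PTV pair, delegating to the same code path.) The XOR region —
voxels labeled PTV by exactly one of the two contour sets — localizes
the boundary error; its overlap with an OAR is reported both in mm³ and
as a fraction of the OAR volume, since neither normalization is
canonically preferable. The identity DSC = 1 − |XOR|/(|A|+|B|) ties the
XOR analysis to the region metrics and is asserted on random pairs.

## Dosimetry

D_X (dose to the hottest X% of an ROI) is an interpolated quantile of
the ROI's voxel doses (numpy linear interpolation between order
statistics); tests bracket it with a count-based sort-and-scan oracle.
The binned cumulative DVH (default bin 0.01 Gy) exists for reporting
only — all endpoints use exact sorting. Dmax/Dmin are single-voxel
extrema (no 0.03 cc criterion). HI = D5/D95 ≥ 1. CI uses the
prescription isodose as the reference region by default (the natural
choice given the normalization convention below), returns values in
[0, 1], and returns 0 in the limit where the target misses the reference
dose entirely. Plan normalization rescales the dose grid so that 95% of
the PTV receives 100% of the prescription, i.e. D95(PTV) = prescription
exactly (D_X is homogeneous of degree 1 in dose, so the scaling is
exact, not iterative).

Plan differences (Auto − Manual) are computed per ROI. For the target,
both plans are by default evaluated **on the manual PTV** — the
clinically meaningful question of what the auto-optimized plan delivers
to the true target; an `evaluate_on="own"` switch scores each plan on
its own PTV instead, since conventions differ between studies. OARs are
always the manual contours (the auto plan re-optimizes targets only),
each scored with its protocol endpoint: mean dose for heart, esophagus,
thyroid and humeral head; V5/V20 for lung; Dmax for spinal cord; V5 for
the contralateral breast; with the corresponding clinical constraint
flags (heart < 8 Gy, parallel-organ limits, cord < 45 Gy, and the
target coverage rules D95 > prescription, D2 < 110% prescription).

## Cohort statistics

Spearman's rho is Pearson correlation on average ranks. Two-sided
p-values are exact by full permutation enumeration for n ≤ 9 (deterministic
at toy scale) and use the t approximation otherwise; a type-I calibration
test confirms ~5% rejection at the cohort size n = 48. Zero-variance
input raises an error rather than returning NaN; the correlation-matrix
driver skips such pairs and keeps the rest. |rho| is classified into
the conventional bands (0.2/0.4/0.6) with significance tiers at p < 0.05
and p < 0.01; no multiple-testing correction is applied, so the tables
carry raw p-values. Pearson correlation is available as an option for
linear associations. Paired plan comparisons use the paired t-test and
the Wilcoxon signed-rank test (undefined when all differences vanish).

## Synthetic cohort

The generator emulates a post-mastectomy thorax at planning scale:

* **Grid**: 18 × 64 × 80 voxels at (5, 3, 3) mm — 5 mm slices as in
  routine simulation CT, 3 mm in-plane matching a typical dose-grid
  resolution. The modest matrix keeps a full 48-case cohort evaluation
  in seconds-per-case; all geometry is expressed in mm, so finer grids
  are a parameter, not a code change.
* **Body**: an elliptical cylinder (semi-axes 112 × 82 mm — a wide,
  shallow chest). The **CTV** is a 10 mm-thick wall sector hugging the
  left-anterior surface over a 90° arc and 55 mm of z: thin, curved and
  concave (its convex hull exceeds its volume by well over 10%, which
  the generator verifies), like a chest-wall target.
* **OARs**: heart (ellipsoid placed at a controlled 2.5–5.5 mm clearance
  inside the wall along its anatomical bearing), ipsilateral lung
  (a large ellipsoid carved around the wall, heart and mediastinal
  organs, as real lungs wrap around their neighbors), spinal cord and
  esophagus (posterior cylinders), contralateral breast, thyroid and
  humeral head. Pairwise disjointness and CTV clearance are enforced;
  violations raise generation errors rather than being silently fixed.
  Per-case jitter of sizes, offsets and wall geometry emulates
  patient-specific variation.
* **Contour perturbation**: the auto CTV is the manual CTV warped by a
  Gaussian-correlated random displacement field (RMS amplitude in mm,
  correlation length 25 mm) applied to the signed distance function,
  plus an optional rigid shift. Smooth stochastic deformation is the
  default error model because pure translation/rotation/scaling is a
  poor surrogate for observer-style variation; rigid shifts are kept as
  calibration controls. Amplitude 0 with zero shift reproduces the
  input bit-exactly. Default cohort amplitudes are Uniform(0.5, 10) mm,
  spanning PTV-pair DSC ≈ 0.55–1.0 — the range reported for clinical
  DL chest-wall segmentation.
* **Dose model**: dose = prescription × sigmoid of the signed distance
  to the PTV surface (98% of prescription at the surface, 50% at 7 mm
  outside — an IMRT-like gradient), times a smooth ±0.8 Gy
  inhomogeneity field and a mild (5%) linear weighting along the
  tangential axis, then normalized to D95(PTV) = prescription (50 Gy).
  It is distance-based, not beam-physics-based: the analysis only needs
  a steep, PTV-conformal, plan-to-plan-consistent gradient, which is
  precisely the property that makes target-adjacent dose sensitive to
  contour error. Maximum dose stays within 115% of prescription.
* **Seeding**: every random element draws from an explicit integer seed;
  per-case seeds derive from the master seed via `SeedSequence([master,
  case_index])`, so any case is reproducible in isolation.

### What the generator shows — and what it cannot

Passing tests on this cohort demonstrate that the pipeline's mechanics
are correct and that its statistical machinery detects the relationships
the synthetic model builds in: larger contour error monotonically
degrades DSC; ΔHI on the true target grows with (1 − DSC) (strongly
positive Spearman at n = 48 across master seeds); and at matched DSC,
the heart's mean-dose change tracks the heart∩XOR overlap — boundary
error location, not distance or relative volume, drives OAR dose change.
They do **not** validate any particular clinical effect size: real
DL segmentation errors are not Gaussian random fields, real IMRT dose is
not a radial sigmoid, and real anatomies vary far more than the jittered
phantom. Correlation magnitudes from synthetic cohorts should never be
quoted as clinical findings.

### Rigid-shift calibration and the orientation factor

For a closed surface translated rigidly by **t**, each surface patch
sees only the component of the shift along its own normal, so
MDA(A, A + t) ≈ |t| · κ with κ = ⟨|n̂ · t̂|⟩, the surface-average
absolute cosine between normal and shift direction — 0.5 for a sphere,
→ 1 for a thin plate shifted along its normal, ≈ 0.7–0.75 for this
chest-wall PTV shifted along its central normal. Raw MDA therefore
under-reads shift magnitude for any closed shape. The package exposes
κ (`surface_orientation_factor`, normals from the smoothed signed
distance function) computed from the reference contour and the shift
axis alone, and the shift-recovery experiment estimates t̂ = MDA/κ;
regression of t̂ on the true magnitude recovers unity slope within a
few percent. The calibration cohort uses a 2 mm in-plane grid because
3 mm voxels quantize MDA visibly at 2–8 mm shifts; this is a metrology
choice for the calibration experiment, not a change to the study grid.

## Numerical choices and edge cases

* Distance transforms are exact EDTs (`scipy.ndimage`), so the fast
  paths agree with brute force to float precision, not approximately.
* Interpolated D_X vs step-function D_X differ by at most one order
  statistic; the oracle tests assert the bracket rather than equality.
* Degenerate inputs fail loudly: empty-vs-empty masks, zero D95,
  all-zero paired differences and zero-variance correlations raise typed
  errors; the pipeline isolates such failures per ROI and per case and
  records them in the run log and the `failed_rois` field.
* CSV outputs are byte-reproducible for a fixed config and master seed.

## Known limitations

* Surface metrics are voxel-center based; no sub-voxel (mesh) surface
  model, no 2D slice-wise metrics, no added-path-length.
* DICOM-RT ingestion is out of scope; NIfTI + JSON manifest is the
  exchange format, and resampling is the data producer's responsibility.
* The four-sub-target split (CW/SCN/ALN/IMN) is a simple angular/axial
  partition of the wall sector — adequate for exercising per-sub-target
  analyses, not an anatomical model of nodal volumes.
* The Spearman p-value at cohort scale is the standard t approximation;
  exact enumeration is used only for n ≤ 9.
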