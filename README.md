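# contourdose

Geometric **and** dosimetric evaluation of radiotherapy target
auto-segmentation.

A Dice score alone does not tell a physicist whether an auto-delineated
target is safe to plan on: the same DSC can hide boundary errors with very
different dose consequences, especially for concave chest-wall targets
(post-mastectomy breast cancer) surrounded by heart and lung under steep
IMRT dose gradients. `contourdose` implements the full evaluation chain
that links contour quality to dose:

* **Region and surface metrics** for a manual/auto contour pair on a 3D
  voxel grid with anisotropic mm spacing:
  DSC = 2|A∩B|/(|A|+|B|), Jaccard JI = |A∩B|/|A∪B|,
  Hausdorff distance HD(A,B) = max(H(A,B), H(B,A)) with
  H(A,B) = max_a min_b d(a,b), and mean distance to agreement
  MDA = (H_mean(A,B) + H_mean(B,A))/2 — surface distances computed
  exactly via Euclidean distance transforms (brute-force verified).
* **Target-relative spatial metrics** per organ at risk:
  relative volume RV = V_ROI / V_PTV and distance metric
  DM = MDA(OAR, PTV), plus the **XOR boundary-error region**
  (voxels labeled PTV by exactly one contour set) and its per-OAR
  overlap — the quantity that actually drives OAR dose changes.
* **Dosimetry**: cumulative DVHs, D_X / V_X endpoints by exact
  voxel-dose sorting, homogeneity index HI = D5/D95, conformity index
  CI = V_R²/(V_T·V_dose), plan normalization (95% of the PTV receives
  100% of the prescription), per-ROI clinical constraint checks
  (e.g. lung V5 < 60%, V20 < 35%; cord Dmax < 45 Gy; heart mean < 8 Gy)
  and Auto-plan − Manual-plan differences per ROI.
* **Cohort statistics**: two-tailed Spearman correlations (exact
  permutation p for n ≤ 9) between contour metrics and dose differences,
  paired t / Wilcoxon plan comparisons, and the conventional strength
  bands (very weak < 0.2 ≤ weak < 0.4 ≤ moderate < 0.6 ≤ strong).
* **A synthetic thorax cohort generator**: concave chest-wall CTV on an
  elliptical body, seven OARs, CTV→PTV expansion by a uniform 5 mm
  margin, smooth random contour perturbations standing in for
  auto-segmentation variation, and a steep-gradient PTV-conformal dose
  model — so the whole pipeline is testable and reproducible without any
  patient data.

Masks and dose grids travel as NIfTI volumes plus a JSON case manifest;
cohort results come out as CSV tables.

## Worked example

```python
import contourdose as cd

case = cd.generate_case(cd.AnatomyParams(seed=7),
                        cd.PerturbParams(amplitude_mm=4.0, seed=11),
                        cd.DoseModelParams(seed=3), "demo")

g = cd.geometric_report(case.manual["PTV"], case.auto["PTV"])
print(f"DSC={g.dsc:.3f}  JI={g.ji:.3f}  HD={g.hd_mm:.1f} mm  MDA={g.mda_mm:.2f} mm")

sp = cd.spatial_report(case.manual["Heart"], case.manual["PTV"])
print(f"Heart: RV={sp.rv:.2f}  DM={sp.dm_mm:.1f} mm")

diffs = cd.dose_differences(case)
ptv = diffs["PTV"]
print(f"PTV  dHI={ptv['hi']['delta']:+.3f}  dCI={ptv['ci']['delta']:+.3f}  "
      f"dDmean={ptv['d_mean']['delta']:+.2f} Gy")
print(f"Heart dDmean={diffs['Heart']['d_mean']['delta']:+.2f} Gy")
```

prints

```
DSC=0.933  JI=0.874  HD=6.0 mm  MDA=0.87 mm
Heart: RV=0.42  DM=30.6 mm
PTV  dHI=+0.078  dCI=-0.123  dDmean=-0.54 Gy
Heart dDmean=-0.37 Gy
```

Read: a 4 mm RMS contour perturbation leaves the PTV pair at DSC 0.93
with sub-millimetre mean surface error but a 6 mm worst-point error.
Re-optimizing the plan on the perturbed target degrades target-dose
homogeneity on the true PTV (ΔHI +0.078) and conformity (ΔCI −0.123),
while the heart — 31 mm from the target and barely touched by the
boundary error — sees its mean dose change by only 0.4 Gy.

The same analysis runs from the shell over a whole cohort:

```sh
contourdose run --n-cases 48 --seed 1 --out run48
```

which writes `cohort_metrics.csv` (one row per case), `dose_report.csv`
(long-format manual/auto/delta per ROI and metric), `correlations.csv`
(Spearman rho, p, star tier and strength band for every metric pair in
the analysis plan), a run log and an echoed config that reproduces the
run bit-for-bit. `generate`, `evaluate` and `correlate` run the
individual stages against NIfTI cases on disk.

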