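"""End-to-end driver: generate or ingest a cohort, evaluate every case
(geometric, spatial and dosimetric metrics), assemble the cohort table
and run the correlation analysis.

A run is reproducible from its echoed config alone; failures are isolated
at case level (one degenerate structure must not kill a 48-case cohort)
and at ROI level within a case.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import caseio, cohort as cohort_stats, spatial, synth
from .dvh import oar_dose_differences, ptv_dose_differences
from .errors import ContourDoseError
from .geometry import geometric_report
from .grids import Case

logger = logging.getLogger("contourdose")

GEOMETRIC_METRICS = ("dsc", "ji", "hd_mm", "mda_mm")


def evaluate_case_pipeline(case: Case, evaluate_on: str = "manual") -> dict:
    """Per-case metric record: PTV geometric metrics, per-OAR RV/DM and
    XOR overlap, and all plan dose differences.

    ROI-level failures are recorded (``failed_rois`` field, NaN metrics)
    without aborting the remaining ROIs.
    """
    record: dict = {"case_id": case.case_id}
    failed: List[str] = []

    ptv_m, ptv_a = case.manual["PTV"], case.auto["PTV"]
    g = geometric_report(ptv_m, ptv_a)
    record.update(dsc=g.dsc, ji=g.ji, hd_mm=g.hd_mm, mda_mm=g.mda_mm)

    xor = spatial.xor_mask(ptv_a, ptv_m)
    record["xor_volume_mm3"] = xor.volume_mm3

    oar_names = [r for r in case.manual.roi_names
                 if r != "PTV" and not r.upper().startswith("CTV")]
    for name in oar_names:
        oar = case.manual[name]
        try:
            record[f"rv_{name}"] = spatial.relative_volume(oar, ptv_m)
            record[f"dm_{name}"] = spatial.distance_metric(oar, ptv_m)
            mm3, frac = spatial.xor_overlap(oar, xor)
            record[f"xor_mm3_{name}"] = mm3
            record[f"xor_frac_{name}"] = frac
        except ContourDoseError as exc:
            failed.append(name)
            logger.warning("case %s: ROI %s spatial metrics failed: %s",
                           case.case_id, name, exc)
            for key in ("rv", "dm", "xor_mm3", "xor_frac"):
                record[f"{key}_{name}"] = np.nan

    diffs: Dict[str, Dict[str, Dict[str, float]]] = {}
    try:
        diffs["PTV"] = ptv_dose_differences(case, evaluate_on=evaluate_on)
    except ContourDoseError as exc:
        logger.warning("case %s: PTV dose differences failed: %s",
                       case.case_id, exc)
        failed.append("PTV")
    for name in oar_names:
        try:
            diffs[name] = oar_dose_differences(case, name)
        except ContourDoseError as exc:
            logger.warning("case %s: ROI %s dose differences failed: %s",
                           case.case_id, name, exc)
            if name not in failed:
                failed.append(name)
    for roi, metrics in diffs.items():
        for metric, vals in metrics.items():
            record[f"d_{roi}_{metric}"] = vals["delta"]
            record[f"{roi}_{metric}_manual"] = vals["manual"]
            record[f"{roi}_{metric}_auto"] = vals["auto"]

    record["failed_rois"] = ";".join(failed)
    return record


def dose_report_rows(case: Case, evaluate_on: str = "manual") -> List[dict]:
    """Long-format dosimetric rows (case_id, roi, metric, manual, auto,
    delta) for the per-case CSV report."""
    rows = []
    blocks: Dict[str, Dict[str, Dict[str, float]]] = {}
    try:
        blocks["PTV"] = ptv_dose_differences(case, evaluate_on=evaluate_on)
    except ContourDoseError:
        pass
    for name in case.manual.roi_names:
        if name == "PTV" or name.upper().startswith("CTV"):
            continue
        try:
            blocks[name] = oar_dose_differences(case, name)
        except ContourDoseError:
            continue
    for roi, metrics in blocks.items():
        for metric, vals in metrics.items():
            rows.append({"case_id": case.case_id, "roi": roi, "metric": metric,
                         "manual_value": vals["manual"],
                         "auto_value": vals["auto"], "delta": vals["delta"]})
    return rows


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one pipeline run."""

    mode: str = "generate"            # "generate" | "ingest"
    n_cases: int = 48
    master_seed: int = 0
    amplitude_range_mm: Tuple[float, float] = (0.5, 10.0)
    manifests: Tuple[str, ...] = ()   # ingest mode: case.json paths
    evaluate_on: str = "manual"       # PTV delta evaluation structure
    correlation_method: str = "spearman"
    write_cases: bool = False         # generate mode: also save NIfTI cases
    out_dir: str = "contourdose_run"
    log_level: str = "INFO"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        for key in ("amplitude_range_mm", "manifests"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class RunResult:
    out_dir: Path
    cohort: pd.DataFrame
    correlations: pd.DataFrame
    n_failed_cases: int
    exit_code: int


def _correlation_pairs(df: pd.DataFrame) -> List[Tuple[List[str], List[str]]]:
    """The analysis plan: traditional geometric metrics of the PTV pair
    against every dose difference; per-OAR spatial metrics (RV, DM, XOR
    overlap) against that OAR's own dose differences."""
    delta_cols = sorted(c for c in df.columns if c.startswith("d_"))
    pairs: List[Tuple[List[str], List[str]]] = [
        ([m for m in GEOMETRIC_METRICS if m in df.columns], delta_cols)
    ]
    oars = sorted(c[len("rv_"):] for c in df.columns if c.startswith("rv_"))
    for oar in oars:
        x = [c for c in (f"rv_{oar}", f"dm_{oar}", f"xor_frac_{oar}")
             if c in df.columns]
        y = [c for c in delta_cols if c.startswith(f"d_{oar}_")]
        if x and y:
            pairs.append((x, y))
    return pairs


def run(config: RunConfig) -> RunResult:
    """Execute a full pipeline run; deterministic given the master seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    (out / "config_echo.json").write_text(config.to_json())

    records: List[dict] = []
    dose_rows: List[dict] = []
    n_failed = 0
    try:
        if config.mode == "generate":
            cases = synth.iter_cohort(
                config.n_cases, config.master_seed,
                amplitude_range_mm=config.amplitude_range_mm)
        elif config.mode == "ingest":
            if not config.manifests:
                raise ValueError("ingest mode requires a manifest list")
            cases = _iter_manifests(config.manifests)
        else:
            raise ValueError(f"unknown mode {config.mode!r}")

        for case in cases:
            if case is None:      # failed ingest, already logged
                n_failed += 1
                continue
            try:
                records.append(evaluate_case_pipeline(case, config.evaluate_on))
                dose_rows.extend(dose_report_rows(case, config.evaluate_on))
                if config.mode == "generate" and config.write_cases:
                    caseio.save_case(case, out / "cases" / case.case_id)
            except ContourDoseError as exc:
                n_failed += 1
                logger.error("case %s failed: %s", case.case_id, exc)

        df = cohort_stats.build_cohort_table(records) if records else pd.DataFrame()
        results = []
        if len(df) >= 3:
            for x_metrics, y_metrics in _correlation_pairs(df):
                results.extend(cohort_stats.correlation_matrix(
                    df, x_metrics, y_metrics, method=config.correlation_method))
        corr_df = cohort_stats.correlation_frame(results)

        df.to_csv(out / "cohort_metrics.csv", index=False)
        corr_df.to_csv(out / "correlations.csv", index=False)
        pd.DataFrame(dose_rows).to_csv(out / "dose_report.csv", index=False)
        logger.info("evaluated %d cases (%d failed); %d correlations",
                    len(records), n_failed, len(corr_df))
    finally:
        logger.removeHandler(handler)
        handler.close()

    return RunResult(out_dir=out, cohort=df, correlations=corr_df,
                     n_failed_cases=n_failed,
                     exit_code=0 if n_failed == 0 else 1)


def _iter_manifests(manifests: Sequence[str]):
    for path in manifests:
        try:
            yield caseio.load_case(path)
        except (ContourDoseError, OSError) as exc:
            logger.error("manifest %s failed to load: %s", path, exc)
            yield None
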