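"""Cohort-level statistics: Spearman correlations between contour-quality
metrics and dose differences, paired plan comparisons, and the strength
bands used to read correlation tables.

Spearman's rho is Pearson correlation on average ranks (ties handled).
Two-sided p-values are exact (full permutation enumeration) for n <= 9 and
use the standard t approximation otherwise.  No multiple-testing
correction is applied; results carry raw p-values and the conventional
star tiers (p < 0.05, p < 0.01).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError, UndefinedStatisticError

EXACT_PERMUTATION_MAX_N = 9


def _ranks(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v, method="average")


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
    if denom == 0:
        raise UndefinedStatisticError("zero rank variance: correlation undefined")
    return float((rxc @ ryc) / denom)


def _exact_two_sided_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p-value: fraction of the n! pairings with
    |rho| >= |rho_obs| (small tolerance for float ties)."""
    n = len(rx)
    rxc = rx - rx.mean()
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc @ rxc) * np.einsum("ij,ij->i", ryc, ryc))
    rhos = (ryc @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def _tier(p: float) -> str:
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "none"


@dataclass(frozen=True)
class CorrelationResult:
    """One (x, y) correlation with its two-sided p-value and star tier."""

    metric_x: str
    metric_y: str
    rho: float
    p_value: float
    n: int
    significance_tier: str


def spearman(x: Sequence[float], y: Sequence[float],
             name_x: str = "x", name_y: str = "y") -> CorrelationResult:
    """Two-tailed Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise UndefinedStatisticError(f"need n >= 3 samples, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise UndefinedStatisticError("non-finite values in correlation input")
    rx, ry = _ranks(x), _ranks(y)
    rho = _rank_corr(rx, ry)
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_two_sided_p(rx, ry, rho)
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(name_x, name_y, rho, p, n, _tier(p))


def pearson(x: Sequence[float], y: Sequence[float],
            name_x: str = "x", name_y: str = "y") -> CorrelationResult:
    """Two-tailed Pearson correlation (offered as an alternative to
    Spearman for linear associations)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise UndefinedStatisticError(f"need n >= 3 samples, got {x.size}")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(name_x, name_y, float(r), float(p), x.size, _tier(float(p)))


def paired_tests(manual_values: Sequence[float],
                 auto_values: Sequence[float]) -> Tuple[float, float]:
    """Two-sided paired t-test and Wilcoxon signed-rank p-values for the
    manual-vs-auto difference."""
    m = np.asarray(manual_values, dtype=float)
    a = np.asarray(auto_values, dtype=float)
    if m.shape != a.shape or m.ndim != 1:
        raise ValueError("paired samples must be 1-D vectors of equal length")
    if m.size < 3:
        raise UndefinedStatisticError(f"need n >= 3 pairs, got {m.size}")
    diff = a - m
    if np.all(diff == 0):
        raise UndefinedStatisticError(
            "all paired differences are zero: Wilcoxon signed-rank undefined"
        )
    t_p = float(stats.ttest_rel(a, m).pvalue)
    w_p = float(stats.wilcoxon(a, m, zero_method="wilcox", method="auto").pvalue)
    return t_p, w_p


def strength_classification(rho: float) -> str:
    """Map |coefficient| to the conventional strength bands:
    very weak < 0.2 <= weak < 0.4 <= moderate < 0.6 <= strong."""
    r = abs(rho)
    if r > 1 + 1e-12:
        raise ValueError(f"|coefficient| must be <= 1, got {rho}")
    if r < 0.2:
        return "very weak"
    if r < 0.4:
        return "weak"
    if r < 0.6:
        return "moderate"
    return "strong"


def build_cohort_table(records: Iterable[dict]) -> pd.DataFrame:
    """Assemble per-case metric records into a cohort table
    (one row per case, indexed order preserved)."""
    df = pd.DataFrame(list(records))
    if "case_id" not in df.columns:
        raise SchemaError("cohort records must carry a 'case_id' field")
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise SchemaError(f"duplicated case_id values: {dupes}")
    return df


def correlation_matrix(cohort: pd.DataFrame,
                       x_metrics: Sequence[str],
                       y_metrics: Sequence[str],
                       method: str = "spearman") -> List[CorrelationResult]:
    """All pairwise (x, y) correlations over the cohort, ordered by
    (x, y) name.  Pairs whose statistic is undefined (constant column)
    are skipped; unknown metric names raise :class:`SchemaError`."""
    if cohort.empty:
        raise SchemaError("cohort table is empty")
    corr = {"spearman": spearman, "pearson": pearson}.get(method)
    if corr is None:
        raise ValueError(f"unknown correlation method {method!r}")
    for name in list(x_metrics) + list(y_metrics):
        if name not in cohort.columns:
            raise SchemaError(f"metric {name!r} not present in cohort table")
    results: List[CorrelationResult] = []
    for name_x in sorted(x_metrics):
        for name_y in sorted(y_metrics):
            sub = cohort[[name_x, name_y]].dropna()
            try:
                results.append(
                    corr(sub[name_x].to_numpy(), sub[name_y].to_numpy(),
                         name_x=name_x, name_y=name_y)
                )
            except UndefinedStatisticError:
                continue
    return results


def correlation_frame(results: Sequence[CorrelationResult]) -> pd.DataFrame:
    """Long-format correlation table with strength bands, ready for CSV."""
    return pd.DataFrame(
        {
            "metric_x": [r.metric_x for r in results],
            "metric_y": [r.metric_y for r in results],
            "rho": [r.rho for r in results],
            "p_value": [r.p_value for r in results],
            "n": [r.n for r in results],
            "tier": [r.significance_tier for r in results],
            "strength_band": [strength_classification(r.rho) for r in results],
        }
    )
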