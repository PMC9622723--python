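"""Cohort-level orchestration and statistics: per-cell records aggregated
into a table, condition summaries (mean ± SD), Welch two-sample
comparisons with Kolmogorov–Smirnov normality checks, and pairwise linear
correlations with R² and 95% confidence bands.

No multiple-testing correction is applied: raw per-parameter p-values are
reported, and that choice is deliberate and documented.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .model import PARAM_COLUMNS, AnalysisConfig, SingleCellModel, SingleCellResults

logger = logging.getLogger(__name__)


def analyze_cell(
    hologram_path: str | Path,
    spectrum_path: str | Path,
    config: AnalysisConfig | None = None,
    pixel_um: float = 0.1,
    dispersion_coeffs=None,
    mask_path: str | Path | None = None,
    condition: str = "",
) -> SingleCellResults:
    """Process one hologram/spectrum pair from disk into a full record."""
    model = SingleCellModel.from_files(
        hologram_path, spectrum_path, config,
        pixel_um=pixel_um, dispersion_coeffs=dispersion_coeffs,
        mask_path=mask_path,
    )
    results = model.fit()
    if condition:
        results.provenance["condition"] = condition
    return results


def records_to_table(records: list[dict]) -> pd.DataFrame:
    """Assemble per-cell records (dicts from ``to_record``) into the
    cohort table, one row per cell."""
    return pd.DataFrame(records)


def summarize_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition sample mean and SD (ddof=1) for every parameter.

    Returns a tidy frame with columns (condition, parameter, mean, sd, n);
    empty input yields an empty summary.
    """
    cols = [c for c in PARAM_COLUMNS if c in table.columns]
    if table.empty or not cols:
        return pd.DataFrame(columns=["condition", "parameter", "mean", "sd", "n"])
    group_key = table["condition"] if "condition" in table else pd.Series(
        ["all"] * len(table), index=table.index)
    rows = []
    for label, sub in table.groupby(group_key, sort=False):
        for col in cols:
            x = sub[col].dropna()
            rows.append({
                "condition": label,
                "parameter": col,
                "mean": float(x.mean()),
                "sd": float(x.std(ddof=1)) if len(x) > 1 else np.nan,
                "n": int(len(x)),
            })
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Welch unequal-variance t-test per parameter between two conditions,
    plus a per-group Kolmogorov–Smirnov normality p-value."""

    condition_a: str
    condition_b: str
    table: pd.DataFrame  # parameter, means/SDs/n, t, df, p, ks_p_a, ks_p_b


def _ks_normality_p(x: np.ndarray) -> float:
    """KS test of the standardized sample against the standard normal."""
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(stats.kstest((x - x.mean()) / sd, "norm").pvalue)


def _welch_df(x: np.ndarray, y: np.ndarray) -> float:
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    if vx + vy == 0:
        return float(len(x) + len(y) - 2)
    return (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))


def compare_groups(
    table: pd.DataFrame, condition_a: str, condition_b: str
) -> GroupComparison:
    """Two-tailed Welch t-test (Welch–Satterthwaite df) on every parameter."""
    rows = []
    for cond in (condition_a, condition_b):
        if (table["condition"] == cond).sum() < 2:
            raise ValueError(f"need >= 2 cells in condition {cond!r}")
    for col in [c for c in PARAM_COLUMNS if c in table.columns]:
        a = table.loc[table["condition"] == condition_a, col].dropna().to_numpy()
        b = table.loc[table["condition"] == condition_b, col].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"insufficient data for parameter {col!r}")
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({
            "parameter": col,
            "mean_a": a.mean(), "sd_a": a.std(ddof=1), "n_a": len(a),
            "mean_b": b.mean(), "sd_b": b.std(ddof=1), "n_b": len(b),
            "t": float(t), "df": _welch_df(a, b), "p": float(p),
            "ks_p_a": _ks_normality_p(a), "ks_p_b": _ks_normality_p(b),
        })
    return GroupComparison(condition_a, condition_b, pd.DataFrame(rows))


@dataclass
class LineFit:
    """Ordinary least-squares line with R² and a 95% confidence band."""

    slope: float
    intercept: float
    r2: float
    n: int
    x_mean: float
    sxx: float
    mse: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x) + self.intercept

    def confidence_band(self, x: np.ndarray, level: float = 0.95):
        """(lower, upper) 95% confidence band of the fitted mean line."""
        x = np.asarray(x, dtype=float)
        dof = self.n - 2
        tcrit = stats.t.ppf(0.5 + level / 2.0, dof) if dof > 0 else np.nan
        se = np.sqrt(self.mse * (1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx))
        yhat = self.predict(x)
        return yhat - tcrit * se, yhat + tcrit * se


@dataclass
class CorrelationResult:
    param_x: str
    param_y: str
    pooled: LineFit
    groups: dict[str, LineFit]


def _line_fit(x: np.ndarray, y: np.ndarray) -> LineFit:
    if len(x) < 3:
        raise ValueError("need >= 3 points for a line fit")
    if np.var(x) == 0:
        raise ValueError("degenerate x: zero variance")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    mse = float(np.sum(resid**2) / max(len(x) - 2, 1))
    return LineFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r2=float(res.rvalue**2), n=len(x),
        x_mean=float(np.mean(x)), sxx=float(np.sum((x - np.mean(x)) ** 2)),
        mse=mse,
    )


def correlate(
    table: pd.DataFrame,
    param_x: str,
    param_y: str,
    grouping: str | None = "condition",
) -> CorrelationResult:
    """OLS line and R² per condition and pooled across all cells."""
    sub = table[[param_x, param_y] + ([grouping] if grouping and grouping in table else [])].dropna()
    x = sub[param_x].to_numpy(dtype=float)
    y = sub[param_y].to_numpy(dtype=float)
    pooled = _line_fit(x, y)
    groups: dict[str, LineFit] = {}
    if grouping and grouping in sub:
        for label, g in sub.groupby(grouping, sort=False):
            if len(g) >= 3:
                groups[str(label)] = _line_fit(
                    g[param_x].to_numpy(dtype=float), g[param_y].to_numpy(dtype=float))
    return CorrelationResult(param_x, param_y, pooled, groups)


def correlation_table(result: CorrelationResult) -> pd.DataFrame:
    rows = [{
        "group": "pooled", "param_x": result.param_x, "param_y": result.param_y,
        "slope": result.pooled.slope, "intercept": result.pooled.intercept,
        "r2": result.pooled.r2, "n": result.pooled.n,
    }]
    for label, fit in result.groups.items():
        rows.append({
            "group": label, "param_x": result.param_x, "param_y": result.param_y,
            "slope": fit.slope, "intercept": fit.intercept, "r2": fit.r2, "n": fit.n,
        })
    return pd.DataFrame(rows)


class CohortModel:
    """Cohort table in, summary statistics out (model/results idiom)."""

    def __init__(self, table: pd.DataFrame):
        self.table = table

    def fit(self) -> "CohortResults":
        return CohortResults(self.table, summarize_cohort(self.table))


@dataclass
class CohortResults:
    table: pd.DataFrame
    summary_table: pd.DataFrame

    def summary(self) -> str:
        if self.summary_table.empty:
            return "empty cohort"
        wide = self.summary_table.pivot(index="parameter", columns="condition",
                                        values=["mean", "sd"])
        return wide.to_string(float_format=lambda v: f"{v:.4g}")

    def compare(self, condition_a: str, condition_b: str) -> GroupComparison:
        return compare_groups(self.table, condition_a, condition_b)

    def correlate(self, param_x: str, param_y: str,
                  grouping: str | None = "condition") -> CorrelationResult:
        return correlate(self.table, param_x, param_y, grouping)
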