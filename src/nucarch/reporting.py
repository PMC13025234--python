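"""Condition-level statistics: percent change, ANOVA, Sidak, stars.

Per-object morphometric measurements are aggregated per condition ×
timepoint into mean ± SD with a t-based 95 % confidence interval,
percent change relative to the 0-h baseline, and a Sidak-adjusted
p value for each non-baseline timepoint against baseline.  The
comparison design follows the common prism-style layout for imaging
timecourses: a one-way ANOVA across timepoint groups supplies the
pooled error variance, each non-baseline timepoint is contrasted with
baseline by a pooled-variance t test, and the m = (number of
non-baseline timepoints) contrasts are Sidak-corrected
(p_adj = 1 − (1 − p)^m).  Individual cells are not matched across
timepoints (imaging is destructive), so a literal repeated-measures
layout is not applicable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MissingDataError

REPORT_COLUMNS = [
    "condition", "timepoint_h", "metric", "n", "mean", "sd",
    "ci95_low", "ci95_high", "pct_change_vs_0h", "p_adj", "stars",
]


@dataclass(frozen=True)
class CohortSample:
    """Per-object measurements of one metric for one condition ×
    timepoint."""

    condition: str
    timepoint: float
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def percent_change(baseline: float, value: float) -> float:
    """Signed percent change of ``value`` relative to ``baseline``."""
    if baseline == 0:
        raise ValueError("percent change undefined for a zero baseline")
    return (value - baseline) / baseline * 100.0


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed reports;
    banker's rounding would turn 2.5 % into 2 %)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs n >= 2")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiple-comparison adjustment, p_adj = 1 − (1 − p)^m."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(np.clip(1.0 - (1.0 - p) ** m, 0.0, 1.0))


def star_code(p_adj: float) -> str:
    """Significance stars with strict-inequality bins: n.s. at 0.05."""
    if not 0.0 <= p_adj <= 1.0:
        raise ValueError("p_adj must lie in [0, 1]")
    if p_adj < 1e-4:
        return "****"
    if p_adj < 1e-3:
        return "***"
    if p_adj < 1e-2:
        return "**"
    if p_adj < 0.05:
        return "*"
    return "n.s."


def _pooled_contrast_p(groups: dict[float, np.ndarray], baseline_key: float,
                       other_key: float) -> float:
    """Two-sided pooled-variance t test of one group against baseline,
    with the error variance pooled across *all* timepoint groups (the
    ANOVA mean-square error, df = N − k)."""
    all_groups = list(groups.values())
    n_total = sum(len(g) for g in all_groups)
    k = len(all_groups)
    mse = sum(
        (len(g) - 1) * np.var(g, ddof=1) for g in all_groups
    ) / (n_total - k)
    a = groups[baseline_key]
    b = groups[other_key]
    if mse == 0:
        return 1.0 if np.mean(b) == np.mean(a) else 0.0
    t = (np.mean(b) - np.mean(a)) / math.sqrt(mse * (1 / len(a) + 1 / len(b)))
    return float(2.0 * stats.t.sf(abs(t), df=n_total - k))


def ci95(values: np.ndarray) -> tuple[float, float]:
    """t-distribution 95 % confidence interval for the mean."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("confidence interval requires n >= 2")
    m = float(values.mean())
    half = float(stats.t.ppf(0.975, n - 1) * values.std(ddof=1) / math.sqrt(n))
    return m - half, m + half


def build_report(
    samples: pd.DataFrame,
    baseline_timepoint: float = 0.0,
) -> pd.DataFrame:
    """Assemble the condition-level report.

    ``samples`` is long-format with columns ``condition, timepoint_h,
    metric, value`` (one row per measured object).  Every
    condition × metric must include the baseline timepoint; otherwise a
    :class:`~nucarch.errors.MissingDataError` names the offender.
    """
    required = {"condition", "timepoint_h", "metric", "value"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"samples table lacks columns: {sorted(missing)}")
    rows = []
    for (cond, metric), grp in samples.groupby(["condition", "metric"], sort=True):
        groups = {
            float(t): g["value"].to_numpy(dtype=float)
            for t, g in grp.groupby("timepoint_h", sort=True)
        }
        if baseline_timepoint not in groups:
            raise MissingDataError(
                f"no {baseline_timepoint} h baseline for condition "
                f"{cond!r}, metric {metric!r}"
            )
        timepoints = sorted(groups)
        others = [t for t in timepoints if t != baseline_timepoint]
        m_comparisons = len(others)
        base_mean = float(groups[baseline_timepoint].mean())
        for t in timepoints:
            vals = groups[t]
            n = len(vals)
            if n < 2:
                raise ValueError(
                    f"group {cond}/{metric}/{t} h has n < 2; variance-based "
                    "outputs are undefined"
                )
            lo, hi = ci95(vals)
            if t == baseline_timepoint:
                pct = 0.0
                p_adj = np.nan
                stars = ""
            else:
                pct = percent_change(base_mean, float(vals.mean()))
                raw_p = _pooled_contrast_p(groups, baseline_timepoint, t)
                p_adj = sidak_adjust(raw_p, m_comparisons)
                stars = star_code(p_adj)
            rows.append(
                dict(
                    condition=cond,
                    timepoint_h=t,
                    metric=metric,
                    n=n,
                    mean=float(vals.mean()),
                    sd=float(vals.std(ddof=1)),
                    ci95_low=lo,
                    ci95_high=hi,
                    pct_change_vs_0h=pct,
                    p_adj=p_adj,
                    stars=stars,
                )
            )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
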