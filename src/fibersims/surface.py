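"""Surface-deposit statistics: intensity ratios, summaries, wash reports.

Surface insecticide is quantified relatively as the ratio of the analyte
ion intensity (35Cl-) to a matrix reference ion (C4H3- from HDPE) at
each analysed location.  Because surface deposits are patchy, each
specimen is measured at many (typically 20) random locations and the
per-condition spread is summarised as median, mean, sample SD, relative
SD, and a z-based 95% confidence interval for the mean
(mean +/- 1.96 * sd / sqrt(n)).  Wash/regeneration experiments are
reported as the percent change of each condition's mean ratio versus
the same sample's initial condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SpotTable

__all__ = [
    "SummaryStats",
    "ConditionComparison",
    "WashReport",
    "Z_95",
    "intensity_ratio",
    "intensity_ratios",
    "summarize",
    "percent_change",
    "wash_report",
]

#: Two-sided 95% normal quantile used for confidence intervals.
Z_95 = 1.96

#: Preferred display order for conditions in reports.
_CONDITION_ORDER = [
    "initial",
    "washed",
    "incubated_4d",
    "incubated_10d",
    "unpressed",
    "unpressed_sputtered",
    "pressed",
    "pressed_sputtered",
    "other",
]


@dataclass(frozen=True)
class SummaryStats:
    """Descriptive statistics of a set of intensity ratios.

    ``sd``, ``rsd_pct`` and the confidence bounds are NaN when ``n < 2``
    (undefined rather than zero).
    """

    n: int
    median: float
    mean: float
    sd: float
    rsd_pct: float
    ci95_low: float
    ci95_high: float


@dataclass(frozen=True)
class ConditionComparison:
    """Percent change of a condition's mean ratio versus baseline."""

    sample_id: str
    baseline_condition: str
    condition: str
    pct_change_mean: float


def intensity_ratio(analyte_intensity: float, reference_intensity: float) -> float:
    """Analyte/reference intensity ratio for a single location."""
    if reference_intensity <= 0:
        raise ValueError("reference_intensity must be positive")
    return analyte_intensity / reference_intensity


def intensity_ratios(table: SpotTable) -> pd.Series:
    """Per-record intensity ratios, aligned with ``table.df``."""
    df = table.df
    return df["analyte_intensity"] / df["reference_intensity"]


def summarize(ratios, z: float = Z_95) -> SummaryStats:
    """Summarise a sequence of ratios (Table-style descriptive statistics).

    Uses the sample SD (n-1 denominator), the midpoint-rule median, and
    a normal-approximation CI ``mean +/- z * sd / sqrt(n)``.
    """
    x = np.asarray(ratios, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("ratios must be a non-empty 1-D sequence")
    n = int(x.size)
    mean = float(np.mean(x))
    median = float(np.median(x))
    if n >= 2:
        sd = float(np.std(x, ddof=1))
        rsd_pct = 100.0 * sd / mean if mean > 0 else math.nan
        half = z * sd / math.sqrt(n)
        ci_low, ci_high = mean - half, mean + half
    else:
        sd = rsd_pct = ci_low = ci_high = math.nan
    return SummaryStats(
        n=n, median=median, mean=mean, sd=sd, rsd_pct=rsd_pct,
        ci95_low=ci_low, ci95_high=ci_high,
    )


def percent_change(
    base: SummaryStats,
    cond: SummaryStats,
    sample_id: str = "",
    baseline_condition: str = "initial",
    condition: str = "",
) -> ConditionComparison:
    """Percent change of the condition mean relative to the baseline mean."""
    if not base.mean > 0:
        raise ValueError("baseline mean must be positive")
    return ConditionComparison(
        sample_id=sample_id,
        baseline_condition=baseline_condition,
        condition=condition,
        pct_change_mean=100.0 * (cond.mean - base.mean) / base.mean,
    )


@dataclass(frozen=True)
class WashReport:
    """Per-(sample, condition) summaries plus comparisons versus baseline."""

    summaries: dict[tuple[str, str], SummaryStats]
    comparisons: list[ConditionComparison]
    baseline_condition: str

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for (sample, condition), s in self.summaries.items():
            rows.append(
                {
                    "sample_id": sample,
                    "condition": condition,
                    "n": s.n,
                    "median": s.median,
                    "mean": s.mean,
                    "sd": s.sd,
                    "rsd_pct": s.rsd_pct,
                    "ci95_low": s.ci95_low,
                    "ci95_high": s.ci95_high,
                }
            )
        return pd.DataFrame(rows)

    def comparison_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": c.sample_id,
                    "baseline_condition": c.baseline_condition,
                    "condition": c.condition,
                    "pct_change_mean": c.pct_change_mean,
                }
                for c in self.comparisons
            ]
        )

    def __str__(self) -> str:
        lines = ["sample  condition           n  median   mean     sd  rsd%   95% CI"]
        for (sample, condition), s in self.summaries.items():
            lines.append(
                f"{sample:<7} {condition:<18} {s.n:>2}  {s.median:6.2f} {s.mean:6.2f} "
                f"{s.sd:6.2f} {s.rsd_pct:5.1f}  {s.ci95_low:.2f}-{s.ci95_high:.2f}"
            )
        for c in self.comparisons:
            lines.append(
                f"{c.sample_id}: {c.condition} vs {c.baseline_condition}: "
                f"{c.pct_change_mean:+.1f}% change in mean"
            )
        return "\n".join(lines)


def _condition_sort_key(condition: str) -> tuple[int, str]:
    try:
        return (_CONDITION_ORDER.index(condition), condition)
    except ValueError:
        return (len(_CONDITION_ORDER), condition)


def wash_report(table: SpotTable, baseline_condition: str = "initial") -> WashReport:
    """Summarise every (sample, condition) group and compare to baseline.

    Every sample must contain the baseline condition; each non-baseline
    condition yields one :class:`ConditionComparison`.
    """
    df = table.df.copy()
    df["ratio"] = intensity_ratios(table)
    summaries: dict[tuple[str, str], SummaryStats] = {}
    comparisons: list[ConditionComparison] = []
    for sample in sorted(df["sample_id"].astype(str).unique()):
        sub = df[df["sample_id"].astype(str) == sample]
        conditions = sorted(sub["condition"].unique(), key=_condition_sort_key)
        if baseline_condition not in conditions:
            raise ValueError(
                f"sample {sample!r} has no baseline condition {baseline_condition!r}"
            )
        for condition in conditions:
            ratios = sub.loc[sub["condition"] == condition, "ratio"].to_numpy()
            summaries[(sample, condition)] = summarize(ratios)
        base = summaries[(sample, baseline_condition)]
        for condition in conditions:
            if condition == baseline_condition:
                continue
            comparisons.append(
                percent_change(
                    base,
                    summaries[(sample, condition)],
                    sample_id=sample,
                    baseline_condition=baseline_condition,
                    condition=condition,
                )
            )
    return WashReport(
        summaries=summaries,
        comparisons=comparisons,
        baseline_condition=baseline_condition,
    )
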