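"""Study-period labeling and within-period trend models.

The 40-day measurement window decomposes into named calendar periods
(a short baseline, three holiday intervals on days 6-12, 13-19 and 38
onward, and an uninterrupted mitigation period on days 20-37).  Within each
period, each item's linear slope over days is tested with a multilevel
model (random intercept per person) at a strict two-sided alpha of .001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .types import DiaryPanel

__all__ = ["PeriodSpec", "PeriodTrendResult", "label_periods", "fit_period_slope", "fit_all_period_slopes"]


def default_intervals(n_days: int) -> dict[str, tuple[int, int]]:
    """The 40-day study calendar, clamped to shorter panels."""
    base = {
        "baseline": (1, 5),
        "holiday1": (6, 12),
        "holiday2": (13, 19),
        "mitigation": (20, 37),
        "holiday3": (38, n_days),
    }
    return {
        name: (lo, min(hi, n_days))
        for name, (lo, hi) in base.items()
        if lo <= n_days
    }


@dataclass(frozen=True)
class PeriodSpec:
    """Named, non-overlapping day-index intervals (inclusive bounds)."""

    intervals: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        spans = sorted(self.intervals.values())
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            if a2 <= b1:
                raise ValueError("period intervals overlap")
        for name, (lo, hi) in self.intervals.items():
            if lo < 1 or hi < lo:
                raise ValueError(f"bad interval for period {name}: ({lo}, {hi})")

    @classmethod
    def default(cls, n_days: int = 40) -> "PeriodSpec":
        return cls(default_intervals(n_days))

    def label_of(self, day: int) -> str:
        for name, (lo, hi) in self.intervals.items():
            if lo <= day <= hi:
                return name
        return "unassigned"


@dataclass(frozen=True)
class PeriodTrendResult:
    """One item x period slope test."""

    item: str
    period: str
    slope: float
    se: float
    z: float
    p: float
    alpha: float
    n_obs: int

    @property
    def significant(self) -> bool:
        return self.p < self.alpha


def label_periods(panel: DiaryPanel, spec: PeriodSpec) -> pd.DataFrame:
    """Panel data with a ``period`` column (pure function of day index)."""
    for lo, hi in spec.intervals.values():
        if hi > panel.n_days:
            raise ValueError("period interval exceeds panel length")
    df = panel.data.copy()
    df["period"] = [spec.label_of(int(d)) for d in df["day"]]
    return df


def fit_period_slope(
    panel: DiaryPanel,
    item: str,
    period: str,
    spec: PeriodSpec,
    alpha: float = 0.001,
    min_persons: int = 10,
) -> PeriodTrendResult:
    """Within-period linear slope of one item, random intercept per person.

    The model is ``score ~ day`` with a person random intercept, fit by
    REML; the slope's two-sided p comes from the Wald z (normal
    approximation, adequate at hundreds of persons).  Constant data
    degenerate to slope 0 with p = 1.
    """
    lo, hi = spec.intervals[period]
    df = panel.data[(panel.data["day"] >= lo) & (panel.data["day"] <= hi)]
    df = df[["person_id", "day", item]].dropna().rename(columns={item: "score"})
    if df["day"].nunique() < 3:
        raise ValueError(f"{item}/{period}: fewer than 3 distinct days")
    if df["person_id"].nunique() < min_persons:
        raise ValueError(f"{item}/{period}: fewer than {min_persons} persons")
    if np.ptp(df["score"].to_numpy()) == 0:
        return PeriodTrendResult(item, period, 0.0, 0.0, 0.0, 1.0, alpha, len(df))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.filterwarnings("ignore", message=".*covariance.*singular.*")
        md = smf.mixedlm("score ~ day", df, groups=df["person_id"])
        res = md.fit(reml=True, method="lbfgs")
    slope = float(res.fe_params["day"])
    se = float(res.bse_fe["day"])
    z = slope / se if se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z))) if se > 0 else 1.0
    return PeriodTrendResult(item, period, slope, se, z, p, alpha, len(df))


def fit_all_period_slopes(
    panel: DiaryPanel,
    spec: PeriodSpec | None = None,
    alpha: float = 0.001,
    items: list[str] | None = None,
) -> pd.DataFrame:
    """Slope tests for every item x period with enough data; tidy frame."""
    spec = spec or PeriodSpec.default(panel.n_days)
    rows = []
    for item in items or panel.items:
        for period in spec.intervals:
            try:
                r = fit_period_slope(panel, item, period, spec, alpha)
            except ValueError:
                continue
            rows.append(
                {
                    "item": r.item,
                    "period": r.period,
                    "slope": r.slope,
                    "se": r.se,
                    "z": r.z,
                    "p": r.p,
                    "significant": r.significant,
                    "n_obs": r.n_obs,
                }
            )
    return pd.DataFrame(rows)
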