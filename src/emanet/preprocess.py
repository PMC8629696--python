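"""Pre-processing for dynamic network estimation.

Stages, in pipeline order: drop participants below a minimum completed-diary
count, remove a pooled linear (per day) and weekend trend from every item,
center each item within person on that person's own sample mean, and build
the lag-1 design table of consecutive observed days.  Within-person
centering separates within-person dynamics from between-person (person-mean)
structure; detrending removes shared calendar effects that would otherwise
masquerade as dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import DiaryPanel, PanelValidationError

__all__ = [
    "TrendFit",
    "CenteredPanel",
    "CompletionReport",
    "filter_min_completion",
    "fit_trends",
    "detrend",
    "within_person_center",
    "build_lag_pairs",
]


@dataclass(frozen=True)
class CompletionReport:
    """Outcome of the minimum-completion filter."""

    n_total: int
    n_retained: int
    n_excluded: int
    min_days: int
    retained_ids: tuple[str, ...]

    @property
    def retention_percent(self) -> float:
        """Retention as a percentage of the enrolled participants."""
        if self.n_total == 0:
            return 0.0
        return 100.0 * self.n_retained / self.n_total


@dataclass
class TrendFit:
    """Per-item pooled OLS fit of score on day index and a weekend dummy."""

    items: list[str]
    intercept: dict[str, float]
    slope: dict[str, float]
    weekend: dict[str, float]
    se_slope: dict[str, float]
    se_weekend: dict[str, float]
    n_obs: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "intercept": self.intercept,
                "slope_per_day": self.slope,
                "weekend_offset": self.weekend,
                "se_slope": self.se_slope,
                "se_weekend": self.se_weekend,
                "n_obs": self.n_obs,
            }
        ).loc[self.items]


@dataclass
class CenteredPanel:
    """Detrended, within-person-centered panel plus the person means.

    ``panel`` holds centered continuous values; ``person_means`` are each
    person's sample means of the detrended values over observed days (these
    carry the between-person level); ``grand_means`` average the person
    means.
    """

    panel: DiaryPanel
    person_means: pd.DataFrame  # index person_id, columns items
    grand_means: pd.Series
    already_centered: bool = field(default=True, repr=False)

    @property
    def items(self) -> list[str]:
        return self.panel.items


def filter_min_completion(
    panel: DiaryPanel, min_days: int
) -> tuple[DiaryPanel, CompletionReport]:
    """Retain persons with at least ``min_days`` completed diaries.

    A diary counts as completed when the person-day row is present with at
    least one non-missing item.  ``min_days=0`` is the identity filter.
    """
    if not 0 <= min_days <= panel.n_days:
        raise ValueError(f"min_days must lie in [0, {panel.n_days}]")
    counts = panel.completed_days()
    retained = [p for p in panel.persons if counts.get(p, 0) >= min_days]
    report = CompletionReport(
        n_total=panel.n_persons,
        n_retained=len(retained),
        n_excluded=panel.n_persons - len(retained),
        min_days=min_days,
        retained_ids=tuple(retained),
    )
    return panel.subset_persons(retained), report


def fit_trends(panel: DiaryPanel, items: list[str] | None = None) -> TrendFit:
    """Pooled per-item OLS of scores on (day index, weekend dummy).

    One fixed trend per item across all persons and days; the design is
    ``score ~ 1 + day + weekend``.
    """
    items = items or panel.items
    out = TrendFit(list(items), {}, {}, {}, {}, {}, {})
    df = panel.data
    for it in items:
        obs = df[it].notna()
        sub = df.loc[obs]
        if len(sub) < 4:
            raise PanelValidationError(f"item {it}: fewer than 4 observations")
        X = np.column_stack(
            [np.ones(len(sub)), sub["day"].to_numpy(float), sub["weekend"].to_numpy(float)]
        )
        if np.linalg.matrix_rank(X) < 3:
            raise PanelValidationError(
                f"item {it}: rank-deficient trend design (day/weekend collinear)"
            )
        res = sm.OLS(sub[it].to_numpy(float), X).fit()
        out.intercept[it] = float(res.params[0])
        out.slope[it] = float(res.params[1])
        out.weekend[it] = float(res.params[2])
        out.se_slope[it] = float(res.bse[1])
        out.se_weekend[it] = float(res.bse[2])
        out.n_obs[it] = int(len(sub))
    return out


def detrend(panel: DiaryPanel, fit: TrendFit) -> DiaryPanel:
    """Subtract fitted linear and weekend trends from every observation.

    ``value' = value - slope * day - weekend_offset * weekend``; the
    intercept is retained so person means keep their location.  The result
    is a continuous panel (scale bounds dropped); missing stays missing.
    """
    missing = [it for it in panel.items if it not in fit.slope]
    if missing:
        raise PanelValidationError(f"trend fit lacks items: {missing}")
    df = panel.data.copy()
    day = df["day"].to_numpy(float)
    wk = df["weekend"].to_numpy(float)
    for it in panel.items:
        df[it] = df[it].to_numpy(float) - fit.slope[it] * day - fit.weekend[it] * wk
    return DiaryPanel(df, list(panel.items), panel.n_days, panel.day1_weekday, scale=None)


def within_person_center(panel: DiaryPanel, min_obs: int = 2) -> CenteredPanel:
    """Center every item within person on that person's own sample mean.

    Person means are computed over each person's observed days of the
    (detrended) values and are kept: they are the between-subjects level the
    estimator later models.  Persons with fewer than ``min_obs`` observed
    days cannot be centered and raise an error (they should have been
    filtered out).
    """
    df = panel.data
    any_obs = df[panel.items].notna().any(axis=1)
    counts = df.loc[any_obs].groupby("person_id").size()
    thin = sorted(set(panel.persons) - set(counts[counts >= min_obs].index))
    if thin:
        raise PanelValidationError(
            f"persons with fewer than {min_obs} observed days: {thin}"
        )
    means = df.groupby("person_id")[panel.items].mean()
    centered = df.copy()
    centered[panel.items] = df[panel.items] - means.loc[
        df["person_id"], panel.items
    ].to_numpy()
    out_panel = DiaryPanel(
        centered, list(panel.items), panel.n_days, panel.day1_weekday, scale=None
    )
    return CenteredPanel(
        panel=out_panel,
        person_means=means.loc[panel.persons],
        grand_means=means.loc[panel.persons].mean(),
    )


def build_lag_pairs(centered: CenteredPanel) -> pd.DataFrame:
    """Lagged design table for the node-wise regressions.

    One row per (person, day t) where both day t and day t-1 are observed
    for that person.  Columns: ``person_id``, ``day``, ``y_<item>`` (the
    detrended, uncentered outcome at t, i.e. centered value + person mean),
    ``lag_<item>`` (the centered value at t-1) and ``pm_<item>`` (the
    grand-mean-centered person mean).  A missing day breaks the lag chain;
    item-level missing values propagate as NaN and are dropped listwise by
    each node regression.
    """
    items = centered.items
    df = centered.panel.data.sort_values(["person_id", "day"]).reset_index(drop=True)
    if df.empty:
        cols = (
            ["person_id", "day"]
            + [f"y_{it}" for it in items]
            + [f"lag_{it}" for it in items]
            + [f"pm_{it}" for it in items]
        )
        return pd.DataFrame(columns=cols)
    lag = df.groupby("person_id")[items].shift(1)
    prev_day = df.groupby("person_id")["day"].shift(1)
    consecutive = (df["day"] - prev_day) == 1
    pm = centered.person_means
    gm = centered.grand_means
    out = pd.DataFrame({"person_id": df["person_id"], "day": df["day"]})
    pm_rows = pm.loc[df["person_id"], items].to_numpy()
    for i, it in enumerate(items):
        out[f"y_{it}"] = df[it].to_numpy() + pm_rows[:, i]
        out[f"lag_{it}"] = lag[it]
        out[f"pm_{it}"] = pm_rows[:, i] - gm[it]
    return out.loc[consecutive].reset_index(drop=True)
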