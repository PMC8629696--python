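"""Shared data model for diary panels and estimated networks.

The two central containers are :class:`DiaryPanel`, a long-format
person x day table of item scores, and :class:`NetworkSet`, the triple of
networks produced by the multilevel VAR(1) estimator (directed temporal
matrix plus symmetric contemporaneous and between-subjects
partial-correlation matrices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WEEKDAYS",
    "ItemCatalog",
    "DEFAULT_CATALOG",
    "DiaryPanel",
    "NetworkSet",
    "PanelSummary",
    "is_weekend",
    "PanelValidationError",
]

WEEKDAYS = (
    "monday",
    "tuesday",
    "wednesday",
    "thursday",
    "friday",
    "saturday",
    "sunday",
)


class PanelValidationError(ValueError):
    """Raised when a diary panel or network violates its invariants."""


def is_weekend(day_index: int, day1_weekday: str) -> bool:
    """True when ``day_index`` (1-based) falls on Saturday or Sunday.

    ``day1_weekday`` declares the calendar weekday of day 1; the flag is
    periodic with period 7 from there.
    """
    wd = day1_weekday.strip().lower()
    if wd not in WEEKDAYS:
        raise ValueError(f"unknown weekday name: {day1_weekday!r}")
    return (WEEKDAYS.index(wd) + day_index - 1) % 7 >= 5


@dataclass(frozen=True)
class ItemCatalog:
    """Ordered catalog of diary items: (abbreviation, full text, scale bounds)."""

    items: tuple[tuple[str, str, tuple[int, int]], ...]

    def __post_init__(self) -> None:
        abbrevs = [a for a, _, _ in self.items]
        if any(not a for a in abbrevs):
            raise ValueError("item abbreviations must be non-empty")
        if len(set(abbrevs)) != len(abbrevs):
            raise ValueError("item abbreviations must be unique")
        for a, _, (lo, hi) in self.items:
            if lo >= hi:
                raise ValueError(f"bad scale bounds for {a}: ({lo}, {hi})")

    @property
    def abbreviations(self) -> list[str]:
        return [a for a, _, _ in self.items]

    def bounds(self, abbrev: str) -> tuple[int, int]:
        for a, _, b in self.items:
            if a == abbrev:
                return b
        raise KeyError(abbrev)

    def __len__(self) -> int:
        return len(self.items)


def _default_catalog() -> ItemCatalog:
    texts = [
        ("DepMood", "Today, I felt down, depressed or hopeless."),
        ("Anhedonia", "Today, I had little interest or pleasure in doing things."),
        ("Lethargy", "Today, I felt tired or that I had little energy."),
        ("Worthless", "Today, I felt bad about myself or felt like a failure."),
        ("Rumination", "Today, I thought negatively about things that have happened in the past."),
        ("EmoReg", "Today, it has been difficult to cope with my emotions."),
        ("Helpless", "Today, I felt helpless with regard to my problems."),
        ("Lonely", "Today, I felt lonely."),
        ("SleepSat", "Today, I was satisfied with my sleep."),
        ("Productive", "Today, I felt productive or useful."),
        ("Relatedness", "Today, I felt close to other people."),
        ("SufficInfo", "Today, I received enough information on how to deal with the pandemic and its associated protocols."),
        ("IntpConflict", "Today, I argued or had negative discussions with someone."),
        ("InpSocCon", "Today, I spent ... minutes/hours on physical social gatherings."),
        ("DigSocCon", "Today, I spent ... minutes/hours on digital social gatherings."),
        ("SocMedia", "Today, I spent ... minutes/hours scrolling social media just to make the time pass."),
        ("PhysAct", "Today, I spent ... minutes/hours physically exercising."),
    ]
    return ItemCatalog(tuple((a, t, (1, 5)) for a, t in texts))


#: The 17-item daily diary battery (depressive symptoms, psychopathological
#: mechanisms and contextual variables), all on a 1-5 ordinal scale.
DEFAULT_CATALOG = _default_catalog()


@dataclass
class DiaryPanel:
    """Long-format diary panel: one row per (person, day) with item scores.

    ``data`` holds columns ``person_id`` (str), ``day`` (int, 1-based),
    ``weekend`` (bool) and one float column per item (NaN = missing).
    ``scale`` gives inclusive bounds enforced on non-missing values; ``None``
    marks a continuous (e.g. detrended) panel with no bounds.
    """

    data: pd.DataFrame
    items: list[str]
    n_days: int
    day1_weekday: str = "wednesday"
    scale: tuple[float, float] | None = (1, 5)

    def __post_init__(self) -> None:
        required = {"person_id", "day", "weekend", *self.items}
        missing = required - set(self.data.columns)
        if missing:
            raise PanelValidationError(f"panel missing columns: {sorted(missing)}")
        df = self.data
        if df.duplicated(["person_id", "day"]).any():
            dup = df[df.duplicated(["person_id", "day"], keep=False)].iloc[0]
            raise PanelValidationError(
                f"duplicate (person, day): ({dup['person_id']}, {dup['day']})"
            )
        if len(df) and (df["day"].min() < 1 or df["day"].max() > self.n_days):
            raise PanelValidationError(
                f"day indices must lie in [1, {self.n_days}]"
            )
        if self.scale is not None and len(df):
            lo, hi = self.scale
            vals = df[self.items].to_numpy(dtype=float)
            bad = (vals < lo) | (vals > hi)
            if np.any(bad & ~np.isnan(vals)):
                r, c = np.argwhere(bad & ~np.isnan(vals))[0]
                raise PanelValidationError(
                    f"value {vals[r, c]} out of scale [{lo}, {hi}] for item "
                    f"{self.items[c]} at row {df.index[r]}"
                )
        if len(df):
            expect = np.array([is_weekend(int(d), self.day1_weekday) for d in df["day"]])
            if not np.array_equal(expect, df["weekend"].to_numpy(dtype=bool)):
                raise PanelValidationError(
                    "weekend flags inconsistent with day1_weekday="
                    f"{self.day1_weekday!r}"
                )

    @property
    def persons(self) -> list[str]:
        return list(pd.unique(self.data["person_id"]))

    @property
    def n_persons(self) -> int:
        return self.data["person_id"].nunique()

    def values_wide(self, item: str) -> pd.DataFrame:
        """person x day matrix of one item's scores (NaN where missing)."""
        return self.data.pivot(index="person_id", columns="day", values=item)

    def completed_days(self) -> pd.Series:
        """Completed-diary count per person.

        A day counts as completed when its row is present and at least one
        item is non-missing (a submitted, possibly partial, diary).
        """
        any_obs = self.data[self.items].notna().any(axis=1)
        counts = self.data.loc[any_obs].groupby("person_id").size()
        return counts.reindex(self.persons, fill_value=0).astype(int)

    def subset_persons(self, persons: Sequence[str]) -> "DiaryPanel":
        keep = set(persons)
        df = self.data[self.data["person_id"].isin(keep)].reset_index(drop=True)
        return DiaryPanel(df, list(self.items), self.n_days, self.day1_weekday, self.scale)

    def copy(self) -> "DiaryPanel":
        return DiaryPanel(
            self.data.copy(), list(self.items), self.n_days, self.day1_weekday, self.scale
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiaryPanel):
            return NotImplemented
        if self.items != other.items or self.n_days != other.n_days:
            return False
        cols = ["person_id", "day", "weekend", *self.items]
        a = self.data[cols].sort_values(["person_id", "day"]).reset_index(drop=True)
        b = other.data[cols].sort_values(["person_id", "day"]).reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False, atol=0, rtol=0)
        except AssertionError:
            return False
        return True


def _check_symmetric_pc(name: str, m: np.ndarray, n: int) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.shape != (n, n):
        raise PanelValidationError(f"{name} matrix must be {n}x{n}, got {m.shape}")
    if not np.all(np.isfinite(m)):
        raise PanelValidationError(f"{name} matrix contains non-finite entries")
    if not np.allclose(m, m.T, atol=1e-8):
        raise PanelValidationError(f"{name} matrix must be symmetric")
    if not np.allclose(np.diag(m), 0.0, atol=1e-10):
        raise PanelValidationError(f"{name} matrix must have zero diagonal")
    if np.any(np.abs(m) > 1 + 1e-10):
        raise PanelValidationError(f"{name} entries must lie in [-1, 1]")
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return np.clip(m, -1.0, 1.0)


@dataclass
class NetworkSet:
    """The three estimated networks on a shared node order.

    ``temporal[j, k]`` is the fixed (population-average) lag-1 effect of node
    ``k`` at day t-1 on node ``j`` at day t (rows = outcome, columns =
    predictor; the diagonal holds autoregressions).  ``contemporaneous`` and
    ``between`` are symmetric partial-correlation matrices with zero diagonal.
    """

    node_labels: list[str]
    temporal: np.ndarray
    contemporaneous: np.ndarray
    between: np.ndarray
    temporal_se: np.ndarray | None = None
    temporal_p: np.ndarray | None = None
    random_effect_sd: np.ndarray | None = None  # SDs of person-specific temporal slopes
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.node_labels)
        self.temporal = np.asarray(self.temporal, dtype=float)
        if self.temporal.shape != (n, n):
            raise PanelValidationError(
                f"temporal matrix must be {n}x{n}, got {self.temporal.shape}"
            )
        if not np.all(np.isfinite(self.temporal)):
            raise PanelValidationError("temporal matrix contains non-finite entries")
        self.contemporaneous = _check_symmetric_pc(
            "contemporaneous", self.contemporaneous, n
        )
        self.between = _check_symmetric_pc("between", self.between, n)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def reorder(self, labels: Sequence[str]) -> "NetworkSet":
        """Return a copy with nodes permuted into the given label order."""
        idx = [self.node_labels.index(l) for l in labels]
        ix = np.ix_(idx, idx)

        def perm(m):
            return None if m is None else m[ix]

        return NetworkSet(
            list(labels),
            self.temporal[ix],
            self.contemporaneous[ix],
            self.between[ix],
            temporal_se=perm(self.temporal_se),
            temporal_p=perm(self.temporal_p),
            random_effect_sd=perm(self.random_effect_sd),
            meta=dict(self.meta),
        )


@dataclass(frozen=True)
class PanelSummary:
    """Descriptive summary of a diary panel."""

    completed_days: Mapping[str, int]
    item_means: Mapping[str, float]
    item_sds: Mapping[str, float]
    missing_fraction: float
    n_days: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ValueError("missing fraction must lie in [0, 1]")
        if any(c > self.n_days for c in self.completed_days.values()):
            raise ValueError("completed-day count exceeds study length")


def summarize_panel(panel: DiaryPanel) -> PanelSummary:
    """Per-person completion counts, item means/SDs and overall missingness.

    Missingness is the fraction of empty cells among person-days present in
    the panel times the number of items.
    """
    vals = panel.data[panel.items]
    total = vals.size
    miss = float(vals.isna().to_numpy().sum()) / total if total else 0.0
    return PanelSummary(
        completed_days=panel.completed_days().to_dict(),
        item_means=vals.mean().to_dict(),
        item_sds=vals.std(ddof=1).to_dict(),
        missing_fraction=miss,
        n_days=panel.n_days,
    )
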