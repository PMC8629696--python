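"""Reading and writing the diary CSV and network-matrix formats.

Diary CSV layout: header ``person_id, day, <item abbreviations>``; one row
per submitted diary; blank cells are missing.  Networks are written as three
labeled square CSV matrices plus a small key=value metadata file recording
node order and the matrix convention, so a directory round-trips losslessly.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    DiaryPanel,
    ItemCatalog,
    NetworkSet,
    PanelValidationError,
    is_weekend,
)

__all__ = ["read_diary_csv", "write_diary_csv", "write_network_set", "read_network_set"]

_FMT = "%.10g"  # 10 significant digits: bit-stable across round trips


def read_diary_csv(
    path: str | os.PathLike,
    catalog: ItemCatalog,
    day1_weekday: str = "wednesday",
    n_days: int | None = None,
) -> DiaryPanel:
    """Read and validate a long-format diary CSV.

    Parameters
    ----------
    path
        CSV with columns ``person_id``, ``day`` and one column per catalog
        abbreviation.  Empty cells become missing values.
    catalog
        Item catalog declaring column names and scale bounds.
    day1_weekday
        Calendar weekday of day 1; weekend flags (Saturday/Sunday) are
        derived from it.
    n_days
        Study length ``T``; defaults to the maximum day index present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"person_id": str})
    required = ["person_id", "day", *catalog.abbreviations]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelValidationError(f"{path}: missing columns {missing}")
    try:
        df["day"] = df["day"].astype(int)
    except (TypeError, ValueError) as exc:
        raise PanelValidationError(f"{path}: non-integer day index ({exc})") from None
    items = catalog.abbreviations
    for it in items:
        df[it] = pd.to_numeric(df[it], errors="raise")
        lo, hi = catalog.bounds(it)
        bad = df[it].notna() & ((df[it] < lo) | (df[it] > hi))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise PanelValidationError(
                f"{path}: row {row + 2}: value {df[it].iloc[row]} out of scale "
                f"[{lo}, {hi}] for item {it}"
            )
    dup = df.duplicated(["person_id", "day"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise PanelValidationError(
            f"{path}: row {row + 2}: duplicate (person, day) "
            f"({df['person_id'].iloc[row]}, {df['day'].iloc[row]})"
        )
    if n_days is None:
        n_days = int(df["day"].max()) if len(df) else 0
    df["weekend"] = [is_weekend(int(d), day1_weekday) for d in df["day"]]
    cols = ["person_id", "day", "weekend", *items]
    lo_hi = catalog.bounds(items[0])
    return DiaryPanel(df[cols].reset_index(drop=True), items, n_days, day1_weekday, lo_hi)


def write_diary_csv(panel: DiaryPanel, path: str | os.PathLike) -> None:
    """Write a panel back to the diary CSV layout (weekend column omitted)."""
    cols = ["person_id", "day", *panel.items]
    out = panel.data[cols].sort_values(["person_id", "day"])
    out.to_csv(path, index=False, float_format=_FMT)


def _write_matrix(m: np.ndarray, labels: list[str], path: Path) -> None:
    pd.DataFrame(m, index=labels, columns=labels).to_csv(path, float_format=_FMT)


def _read_matrix(path: Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_network_set(net: NetworkSet, directory: str | os.PathLike) -> None:
    """Write the three network matrices plus metadata into ``directory``.

    Files: ``temporal.csv``, ``contemporaneous.csv``, ``between.csv`` (labeled
    square matrices at 10 significant digits), optional ``temporal_se.csv`` /
    ``temporal_p.csv`` / ``random_effect_sd.csv``, and ``metadata.txt``.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    _write_matrix(net.temporal, net.node_labels, d / "temporal.csv")
    _write_matrix(net.contemporaneous, net.node_labels, d / "contemporaneous.csv")
    _write_matrix(net.between, net.node_labels, d / "between.csv")
    for name in ("temporal_se", "temporal_p", "random_effect_sd"):
        m = getattr(net, name)
        if m is not None:
            _write_matrix(m, net.node_labels, d / f"{name}.csv")
    with open(d / "metadata.txt", "w", encoding="utf-8") as fh:
        fh.write("convention=rows are outcome at t, columns are predictor at t-1\n")
        fh.write("temporal=fixed lag-1 coefficients, diagonal autoregressive\n")
        fh.write("contemporaneous=partial correlations of same-day residuals\n")
        fh.write("between=partial correlations of person means\n")
        fh.write("node_order=" + ",".join(net.node_labels) + "\n")
        for k, v in net.meta.items():
            fh.write(f"{k}={v}\n")


def read_network_set(directory: str | os.PathLike) -> NetworkSet:
    """Read a :class:`NetworkSet` previously written by :func:`write_network_set`."""
    d = Path(directory)
    meta: dict[str, str] = {}
    with open(d / "metadata.txt", encoding="utf-8") as fh:
        for line in fh:
            if "=" in line:
                k, v = line.rstrip("\n").split("=", 1)
                meta[k] = v
    temporal, labels = _read_matrix(d / "temporal.csv")
    contemporaneous, _ = _read_matrix(d / "contemporaneous.csv")
    between, _ = _read_matrix(d / "between.csv")
    extra = {}
    for name in ("temporal_se", "temporal_p", "random_effect_sd"):
        p = d / f"{name}.csv"
        if p.exists():
            extra[name] = _read_matrix(p)[0]
    order = meta.pop("node_order", ",".join(labels)).split(",")
    for key in ("convention", "temporal", "contemporaneous", "between"):
        meta.pop(key, None)
    if order != labels:
        raise PanelValidationError("metadata node order disagrees with matrix labels")
    return NetworkSet(labels, temporal, contemporaneous, between, meta=meta, **extra)
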