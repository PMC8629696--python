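import numpy as np
import pandas as pd
import pytest

from emanet import (
    DiaryPanel,
    ItemCatalog,
    NetworkSet,
    is_weekend,
    sample_generative_params,
    simulate_panel,
)


@pytest.fixture
def catalog3() -> ItemCatalog:
    return ItemCatalog(tuple((a, a, (1, 5)) for a in ("A", "B", "C")))


def make_panel(values: dict[str, dict[int, list[float]]], items: list[str],
               n_days: int, day1: str = "wednesday") -> DiaryPanel:
    """Build a panel from {person: {day: [item values]}} (None = missing)."""
    rows = []
    for pid, days in values.items():
        for day, vals in days.items():
            rows.append(
                {"person_id": pid, "day": day, "weekend": is_weekend(day, day1),
                 **{it: (np.nan if v is None else v) for it, v in zip(items, vals)}}
            )
    return DiaryPanel(pd.DataFrame(rows), items, n_days, day1, scale=None)


@pytest.fixture
def tiny_panel() -> DiaryPanel:
    """2 persons x 3 days, 2 items, fully observed."""
    return make_panel(
        {"p1": {1: [2, 3], 2: [4, 3], 3: [3, 3]},
         "p2": {1: [1, 5], 2: [2, 4], 3: [3, 3]}},
        ["A", "B"], 3,
    )


@pytest.fixture
def net3() -> NetworkSet:
    temporal = np.array([[0.5, 0.2, 0.0], [0.0, 0.4, 0.1], [0.3, 0.0, 0.2]])
    contemporaneous = np.array([[0, 0.3, -0.2], [0.3, 0, 0.1], [-0.2, 0.1, 0]])
    between = np.array([[0, 0.25, 0.0], [0.25, 0, -0.15], [0.0, -0.15, 0]])
    return NetworkSet(["A", "B", "C"], temporal, contemporaneous, between)


@pytest.fixture(scope="session")
def small_sim():
    """4-node, 80-person simulated panel with known truth (shared, read-only)."""
    params = sample_generative_params(4, edge_density=0.25, effect_scale=0.15, seed=11)
    panel, truth = simulate_panel(params, 80, 30)
    return params, panel, truth
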