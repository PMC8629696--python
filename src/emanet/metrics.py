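"""Strength centrality for the three networks.

All centralities are raw (unstandardized) sums of absolute edge weights;
autoregressive self-loops are excluded from in/outstrength.  Raw scores are
reported rather than z-standardized ones, which can exaggerate differences
between nearly equal centralities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import NetworkSet

__all__ = ["CentralityTable", "compute_centrality"]


@dataclass
class CentralityTable:
    """Per-node raw strength centralities.

    ``table`` columns: ``outstrength`` and ``instrength`` from the directed
    temporal network (diagonal excluded), ``strength_contemporaneous`` and
    ``strength_between`` from the symmetric networks.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        assert (self.table.to_numpy() >= 0).all()

    @property
    def nodes(self) -> list[str]:
        return list(self.table.index)

    def metric(self, name: str) -> pd.Series:
        return self.table[name]

    def top_nodes(self, metric: str, k: int) -> list[str]:
        """The k nodes with highest centrality on ``metric`` (ties broken by
        catalog order for determinism)."""
        s = self.table[metric]
        order = sorted(range(len(s)), key=lambda i: (-s.iloc[i], i))
        return [s.index[i] for i in order[:k]]


METRICS = (
    "outstrength",
    "instrength",
    "strength_contemporaneous",
    "strength_between",
)


def compute_centrality(net: NetworkSet) -> CentralityTable:
    """Raw strength centralities of a :class:`NetworkSet`.

    With the convention temporal[j, k] = effect of k (t-1) on j (t):
    outstrength(k) = sum_{j != k} |temporal[j, k]| (column sums) and
    instrength(j) = sum_{k != j} |temporal[j, k]| (row sums); strength of a
    symmetric network is the row sum of absolute off-diagonal weights.
    """
    T = np.abs(net.temporal.copy())
    np.fill_diagonal(T, 0.0)
    table = pd.DataFrame(
        {
            "outstrength": T.sum(axis=0),
            "instrength": T.sum(axis=1),
            "strength_contemporaneous": np.abs(net.contemporaneous).sum(axis=1),
            "strength_between": np.abs(net.between).sum(axis=1),
        },
        index=pd.Index(net.node_labels, name="node"),
    )
    return CentralityTable(table)
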