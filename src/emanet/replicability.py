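"""Split-half robustness protocol for the estimated networks.

Four subsamples are re-estimated with the full pipeline: two random halves
of the participants, and two time halves (all participants, first vs second
half of the study days).  Replicability is quantified by Pearson
correlations of vectorized edge weights per network, correlations of
centrality indices per metric, and the fraction of the full-sample
top-central nodes re-identified in each subsample's top set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import METRICS, CentralityTable, compute_centrality
from .preprocess import (
    detrend,
    filter_min_completion,
    fit_trends,
    within_person_center,
)
from .mlvar import fit_mlvar
from .types import DiaryPanel, NetworkSet

__all__ = [
    "ReplicabilityReport",
    "split_participants",
    "split_time",
    "correlate_edges",
    "correlate_centrality",
    "top_node_consistency",
    "run_replication_suite",
]

NETWORK_NAMES = ("temporal", "contemporaneous", "between")


@dataclass
class ReplicabilityReport:
    """Edge and centrality replicability across the four subsamples.

    ``edge_correlations[(split, network)]`` and
    ``centrality_correlations[(split, metric)]`` hold Pearson r between the
    two members of each split pair; ``top_node_consistency`` is the fraction
    of full-sample top-k nodes (per metric) recovered in the subsamples'
    top-k sets.  Temporal edges are vectorized over all directed entries
    including the autoregressive diagonal; symmetric networks over the lower
    triangle.
    """

    edge_correlations: dict[tuple[str, str], float]
    centrality_correlations: dict[tuple[str, str], float]
    top_node_consistency: float
    top_k: int
    seed: int
    networks: dict[str, NetworkSet] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"split": s, "quantity": f"edges_{net}", "r": r}
            for (s, net), r in self.edge_correlations.items()
        ] + [
            {"split": s, "quantity": f"centrality_{m}", "r": r}
            for (s, m), r in self.centrality_correlations.items()
        ]
        return pd.DataFrame(rows)


def split_participants(
    panel: DiaryPanel, seed: int = 0
) -> tuple[DiaryPanel, DiaryPanel]:
    """Random partition of the persons into two near-equal halves."""
    persons = panel.persons
    if len(persons) < 4:
        raise ValueError("need at least 4 persons to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(persons))
    half = (len(persons) + 1) // 2
    ids_a = [persons[i] for i in sorted(perm[:half])]
    ids_b = [persons[i] for i in sorted(perm[half:])]
    return panel.subset_persons(ids_a), panel.subset_persons(ids_b)


def split_time(panel: DiaryPanel) -> tuple[DiaryPanel, DiaryPanel]:
    """First vs second half of the study days, all persons retained.

    Day indices are re-based to 1 within each half so the halves are valid
    stand-alone panels; the weekday of day 1 shifts accordingly to keep
    weekend flags consistent.
    """
    if panel.n_days < 4:
        raise ValueError("need at least 4 days to split the time series")
    t_half = panel.n_days // 2
    from .types import WEEKDAYS

    def carve(lo: int, hi: int) -> DiaryPanel:
        df = panel.data[(panel.data["day"] >= lo) & (panel.data["day"] <= hi)].copy()
        df["day"] = df["day"] - lo + 1
        wd = WEEKDAYS[(WEEKDAYS.index(panel.day1_weekday) + lo - 1) % 7]
        return DiaryPanel(
            df.reset_index(drop=True), list(panel.items), hi - lo + 1, wd, panel.scale
        )

    return carve(1, t_half), carve(t_half + 1, panel.n_days)


def _vectorize(net: NetworkSet, which: str) -> np.ndarray:
    m = getattr(net, which)
    if which == "temporal":
        return m.ravel()  # all directed entries incl. autoregressive diagonal
    return m[np.tril_indices(net.n_nodes, k=-1)]


def correlate_edges(net_a: NetworkSet, net_b: NetworkSet) -> dict[str, float]:
    """Pearson correlation of vectorized edge weights, per network."""
    if net_a.node_labels != net_b.node_labels:
        raise ValueError("networks have different node sets")
    out = {}
    for which in NETWORK_NAMES:
        va, vb = _vectorize(net_a, which), _vectorize(net_b, which)
        out[which] = float(np.corrcoef(va, vb)[0, 1])
    return out


def correlate_centrality(
    tab_a: CentralityTable, tab_b: CentralityTable
) -> dict[str, float]:
    """Pearson correlation across nodes, per centrality metric."""
    if tab_a.nodes != tab_b.nodes:
        raise ValueError("centrality tables have different node sets")
    return {
        m: float(np.corrcoef(tab_a.metric(m), tab_b.metric(m))[0, 1])
        for m in METRICS
    }


def top_node_consistency(
    reference: CentralityTable,
    replicas: list[CentralityTable],
    k: int = 3,
) -> float:
    """Fraction of reference top-k nodes re-identified in the replicas.

    Counted over every (replica, metric, reference-top-node) instance: an
    instance scores when the node is also in that replica's top-k for the
    metric.  Non-decreasing in k; equals 1 at k = n.
    """
    if k < 1 or k > len(reference.nodes):
        raise ValueError("k must lie in [1, n_nodes]")
    hits = total = 0
    for metric in METRICS:
        ref_top = set(reference.top_nodes(metric, k))
        for rep in replicas:
            if rep.nodes != reference.nodes:
                raise ValueError("replica node set differs from reference")
            rep_top = set(rep.top_nodes(metric, k))
            hits += len(ref_top & rep_top)
            total += k
    return hits / total


def _pipeline(
    panel: DiaryPanel, min_days: int, detrend_data: bool = True
) -> NetworkSet:
    filtered, _ = filter_min_completion(panel, min_days)
    if detrend_data:
        filtered = detrend(filtered, fit_trends(filtered))
    centered = within_person_center(filtered)
    return fit_mlvar(centered)


def run_replication_suite(
    panel: DiaryPanel,
    min_days: int = 30,
    seed: int = 0,
    top_k: int = 3,
    detrend_data: bool = True,
) -> ReplicabilityReport:
    """Full-sample fit plus the four subsample re-estimations.

    The minimum-completion criterion is re-applied inside the time halves
    with ``min_days`` scaled proportionally to the half length (rounded),
    since the full-study cutoff would be unattainable on half the days.
    """
    full = _pipeline(panel, min_days, detrend_data)
    ref_cent = compute_centrality(full)

    pa, pb = split_participants(panel, seed=seed)
    ta, tb = split_time(panel)
    scaled = int(round(min_days * ta.n_days / panel.n_days))
    subsets = {
        "participants_a": (pa, min_days),
        "participants_b": (pb, min_days),
        "time_first": (ta, scaled),
        "time_second": (tb, int(round(min_days * tb.n_days / panel.n_days))),
    }
    nets = {"full": full}
    cents = {}
    notes = [f"time-half completion cutoff scaled to {scaled} days"]
    for name, (sub, md) in subsets.items():
        nets[name] = _pipeline(sub, md, detrend_data)
        cents[name] = compute_centrality(nets[name])

    edge_corr = {}
    cent_corr = {}
    for split, (a, b) in {
        "participants": ("participants_a", "participants_b"),
        "time": ("time_first", "time_second"),
    }.items():
        for net_name, r in correlate_edges(nets[a], nets[b]).items():
            edge_corr[(split, net_name)] = r
        for metric, r in correlate_centrality(cents[a], cents[b]).items():
            cent_corr[(split, metric)] = r

    consistency = top_node_consistency(
        ref_cent, [cents[k] for k in subsets], k=top_k
    )
    return ReplicabilityReport(
        edge_correlations=edge_corr,
        centrality_correlations=cent_corr,
        top_node_consistency=consistency,
        top_k=top_k,
        seed=seed,
        networks=nets,
        notes=notes,
    )
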