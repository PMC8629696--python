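"""Data-driven item-redundancy screening.

Before network estimation, candidate item sets are checked for (a) a
positive-definite correlation matrix with no item a near linear combination
of the others, and (b) pairwise redundancy: two items correlating highly
with each other while correlating near-identically with every third item
are likely measuring the same construct.  The pairwise search ("goldbricker"
screen) compares, for each highly correlated pair (A, B) and every third
item C, the dependent overlapping correlations r_AC and r_BC with the
Hittner z-test; a pair is flagged when few of those comparisons differ
significantly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .types import DiaryPanel

__all__ = [
    "MatrixDiagnostics",
    "RedundancyReport",
    "check_correlation_matrix",
    "hittner_test",
    "goldbricker_screen",
]


@dataclass(frozen=True)
class MatrixDiagnostics:
    min_eigenvalue: float
    positive_definite: bool
    linear_combination_items: tuple[str, ...]  # multiple R^2 > 0.999


@dataclass
class RedundancyReport:
    """Per-pair redundancy screen results.

    ``pairs`` columns: item_a, item_b, r_ab, prop_significant (share of
    third items C whose dependent correlations r_AC vs r_BC differ at
    ``alpha``), flagged.  A pair is flagged as potentially redundant when
    r_ab >= r_threshold and prop_significant < proportion_threshold.
    """

    pairs: pd.DataFrame
    r_threshold: float
    alpha: float
    proportion_threshold: float
    n: int

    @property
    def flagged_pairs(self) -> list[tuple[str, str]]:
        f = self.pairs[self.pairs["flagged"]]
        return [tuple(sorted((a, b))) for a, b in zip(f["item_a"], f["item_b"])]


def check_correlation_matrix(
    R: np.ndarray, labels: list[str] | None = None
) -> MatrixDiagnostics:
    """Positive-definiteness and collinearity diagnostics of a correlation matrix.

    An item whose multiple R^2 against the remaining items exceeds 0.999 is
    flagged as (close to) a linear combination of the others.
    """
    R = np.asarray(R, dtype=float)
    n = R.shape[0]
    if R.shape != (n, n) or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be square and symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("correlation matrix must have unit diagonal")
    labels = labels or [f"V{i + 1}" for i in range(n)]
    eigvals = np.linalg.eigvalsh(R)
    min_eig = float(eigvals[0])
    pd_flag = min_eig > 1e-10
    lincomb: list[str] = []
    for j in range(n):
        rest = [k for k in range(n) if k != j]
        Rsub = R[np.ix_(rest, rest)]
        rvec = R[rest, j]
        # multiple R^2 of item j on the others: r' Rsub^{-1} r
        r2 = float(rvec @ np.linalg.lstsq(Rsub, rvec, rcond=None)[0])
        if r2 > 0.999:
            lincomb.append(labels[j])
    return MatrixDiagnostics(min_eig, pd_flag, tuple(lincomb))


def hittner_test(
    r_ac: float, r_bc: float, r_ab: float, n: int
) -> tuple[float, float]:
    """Compare two dependent overlapping correlations (shared variable C).

    Hittner, May & Silver's modification of Dunn & Clark's z: both
    correlations are Fisher-transformed, and the covariance term c is
    evaluated at the backtransformed average of the two Fisher z values
    together with r_ab.  Returns (z, two-sided p); z > 0 when r_ac > r_bc.
    """
    for r in (r_ac, r_bc, r_ab):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 10:
        raise ValueError("need n > 10")
    R = np.array([[1, r_ab, r_ac], [r_ab, 1, r_bc], [r_ac, r_bc, 1]])
    if np.linalg.eigvalsh(R)[0] < -1e-12:
        raise ValueError(
            "correlation triple is not jointly consistent (3x3 matrix not PSD)"
        )
    z_ac = np.arctanh(r_ac)
    z_bc = np.arctanh(r_bc)
    rm = np.tanh(0.5 * (z_ac + z_bc))  # backtransformed average correlation
    c = (r_ab * (1 - 2 * rm**2) - 0.5 * rm**2 * (1 - 2 * rm**2 - r_ab**2)) / (
        (1 - rm**2) ** 2
    )
    z = (z_ac - z_bc) * np.sqrt((n - 3) / (2 - 2 * c))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def _pairwise_correlations(data: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    corr = data.corr(method="pearson")
    n = int(data.notna().all(axis=1).sum())
    return corr, n


def goldbricker_screen(
    data: DiaryPanel | pd.DataFrame,
    r_threshold: float = 0.5,
    alpha: float = 0.05,
    proportion_threshold: float = 0.25,
) -> RedundancyReport:
    """Pairwise redundancy search over all item pairs.

    For every pair (A, B) with r_AB >= ``r_threshold``, the dependent
    correlations r_AC and r_BC are compared for every third item C with the
    Hittner test; the pair is flagged potentially redundant when the
    proportion of significantly different comparisons (p < ``alpha``) falls
    below ``proportion_threshold``.  Correlations are computed on pooled
    person-day observations (complete rows), as the screen runs before the
    multilevel decomposition.
    """
    if isinstance(data, DiaryPanel):
        df = data.data[data.items]
    else:
        df = data
    items = list(df.columns)
    if len(items) < 3:
        raise ValueError("need at least 3 items for third-party comparisons")
    df = df.dropna()
    n = len(df)
    if n < 20:
        raise ValueError(f"need >= 20 complete observations, got {n}")
    R = df.corr(method="pearson")
    rows = []
    for a, b in combinations(items, 2):
        r_ab = float(R.loc[a, b])
        if r_ab < r_threshold:
            continue
        n_sig = 0
        thirds = [c for c in items if c not in (a, b)]
        for c in thirds:
            _, p = hittner_test(float(R.loc[a, c]), float(R.loc[b, c]), r_ab, n)
            n_sig += p < alpha
        prop = n_sig / len(thirds)
        rows.append(
            {
                "item_a": a,
                "item_b": b,
                "r_ab": r_ab,
                "prop_significant": prop,
                "flagged": prop < proportion_threshold,
            }
        )
    pairs = pd.DataFrame(
        rows, columns=["item_a", "item_b", "r_ab", "prop_significant", "flagged"]
    )
    return RedundancyReport(pairs, r_threshold, alpha, proportion_threshold, n)
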