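"""Two-step node-wise multilevel VAR(1) estimator.

Step 1 regresses each node on all nodes' within-person-centered lag-1
values (fixed effects plus person-specific random slopes, mutually
uncorrelated = "orthogonal" estimation, plus a random intercept) and on the
grand-mean-centered person means of the *other* nodes as person-level fixed
predictors.  The lagged fixed effects form the directed temporal network;
the person-mean coefficients, combined node-wise into partial correlations
using the random-intercept variances, form the between-subjects network.

Step 2 regresses each node's step-1 (conditional) residual on the other
nodes' same-day residuals with the same orthogonal random-effect structure;
the coefficients, combined with the step-2 residual variances, form the
symmetric contemporaneous partial-correlation network.

Orthogonal (uncorrelated) random effects are the recommended choice for
networks with more than six nodes: the random-effects covariance is
diagonal, which keeps the number of variance parameters linear in the
number of nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .preprocess import CenteredPanel, build_lag_pairs
from .types import NetworkSet

__all__ = [
    "NodeRegressionFit",
    "ResidualFit",
    "MlvarError",
    "fit_node_step1",
    "fit_node_step2",
    "combine_to_partial_correlation",
    "fit_mlvar",
]


class MlvarError(RuntimeError):
    """Raised when a node-wise regression cannot be fit."""


@dataclass
class NodeRegressionFit:
    """Step-1 fit of one node: temporal and between-subjects coefficients."""

    node: str
    intercept: float
    lag_coef: dict[str, float]  # predictor item -> fixed lag-1 coefficient
    lag_se: dict[str, float]
    lag_p: dict[str, float]
    mean_coef: dict[str, float]  # other items' person-mean coefficients
    mean_se: dict[str, float]
    random_sd: dict[str, float]  # random slope SD per lagged predictor
    intercept_sd: float  # random intercept SD (between-level residual SD)
    resid_sd: float
    residuals: pd.Series  # conditional residuals keyed by (person_id, day)
    n_obs: int
    method: str  # which rung of the fallback ladder converged
    converged: bool = True

    def __post_init__(self) -> None:
        assert all(v >= 0 for v in self.random_sd.values())
        assert self.intercept_sd >= 0 and self.resid_sd >= 0


@dataclass
class ResidualFit:
    """Step-2 fit of one node's residual on the others' same-day residuals."""

    node: str
    coef: dict[str, float]
    se: dict[str, float]
    p: dict[str, float]
    random_sd: dict[str, float]
    resid_sd: float
    n_obs: int
    method: str
    converged: bool = True


def _run_mixed(
    df: pd.DataFrame,
    fe_terms: list[str],
    slope_cols: list[str],
    node: str,
) -> tuple:
    """Fit y ~ fe_terms with orthogonal random effects, walking a fallback ladder.

    Ladder: REML with random intercept + uncorrelated random slopes, then ML,
    then random intercept only (REML).  Returns (result, slope_cols_used,
    method label).
    """
    fe = "y ~ " + (" + ".join(fe_terms) if fe_terms else "1")
    attempts = [
        ("reml-orthogonal", True, slope_cols),
        ("ml-orthogonal", False, slope_cols),
        ("reml-intercept-only", True, []),
    ]
    last_exc: Exception | None = None
    for label, reml, slopes in attempts:
        vcf = {c: f"0 + {c}" for c in slopes}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                # boundary estimates (zero variance components) are expected
                warnings.filterwarnings(
                    "ignore", message=".*covariance.*singular.*"
                )
                warnings.filterwarnings(
                    "ignore", message=".*Random effects covariance is singular.*"
                )
                md = smf.mixedlm(
                    fe, df, groups=df["person_id"], re_formula="1",
                    vc_formula=vcf or None,
                )
                # powell is the backstop for boundary fits (zero variance
                # components), where gradient methods stall
                res = md.fit(reml=reml, method=["lbfgs", "powell"], maxiter=300)
            ok = bool(res.converged) and np.all(np.isfinite(res.fe_params))
            if ok:
                return res, slopes, label
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
    raise MlvarError(
        f"node {node}: mixed model did not converge on any fallback "
        f"(last error: {last_exc})"
    )


def _vcomp_sds(res, slopes: list[str]) -> dict[str, float]:
    names = list(res.model.exog_vc.names) if slopes else []
    sds = {}
    for name, v in zip(names, res.vcomp):
        sds[name] = float(np.sqrt(max(v, 0.0)))
    return {c: sds.get(c, 0.0) for c in slopes}


def fit_node_step1(
    node: str,
    design: pd.DataFrame,
    items: list[str],
    estimator: str = "orthogonal",
    min_persons_warn: int = 20,
) -> NodeRegressionFit:
    """Step-1 multilevel regression for one node.

    ``design`` comes from :func:`emanet.preprocess.build_lag_pairs`.  The
    outcome is the node's detrended value at day t; predictors are all
    nodes' centered lag-1 values (fixed + uncorrelated random slopes) and
    the grand-mean-centered person means of the other nodes (person-level
    fixed effects).  Rows with any missing value are dropped listwise.
    """
    if estimator != "orthogonal":
        raise ValueError(f"unknown estimator: {estimator!r}")
    lag_cols = [f"lag_{it}" for it in items]
    pm_cols = [f"pm_{it}" for it in items if it != node]
    cols = ["person_id", "day", f"y_{node}", *lag_cols, *pm_cols]
    df = design[cols].dropna().rename(columns={f"y_{node}": "y"})
    if df.empty:
        raise MlvarError(f"node {node}: empty design after listwise deletion")
    if df["person_id"].nunique() < min_persons_warn:
        warnings.warn(
            f"node {node}: only {df['person_id'].nunique()} persons; "
            "multilevel estimates may be unstable",
            UserWarning,
            stacklevel=2,
        )
    res, slopes, label = _run_mixed(df, lag_cols + pm_cols, lag_cols, node)
    fe = res.fe_params
    bse = res.bse_fe
    pv = res.pvalues
    slope_sds = _vcomp_sds(res, slopes)
    return NodeRegressionFit(
        node=node,
        intercept=float(fe["Intercept"]),
        lag_coef={it: float(fe[f"lag_{it}"]) for it in items},
        lag_se={it: float(bse[f"lag_{it}"]) for it in items},
        lag_p={it: float(pv[f"lag_{it}"]) for it in items},
        mean_coef={it: float(fe[f"pm_{it}"]) for it in items if it != node},
        mean_se={it: float(bse[f"pm_{it}"]) for it in items if it != node},
        random_sd={it: slope_sds.get(f"lag_{it}", 0.0) for it in items},
        intercept_sd=float(np.sqrt(max(float(res.cov_re.iloc[0, 0]), 0.0))),
        resid_sd=float(np.sqrt(res.scale)),
        residuals=pd.Series(
            np.asarray(res.resid, dtype=float),
            index=pd.MultiIndex.from_frame(df[["person_id", "day"]]),
        ),
        n_obs=len(df),
        method=label,
    )


def fit_node_step2(
    node: str,
    residuals: pd.DataFrame,
    estimator: str = "orthogonal",
) -> ResidualFit:
    """Step-2 multilevel regression of one node's residual on the others'.

    ``residuals`` has one column per node (named by item) indexed by
    (person_id, day); rows with any missing residual have already been
    dropped.  No person-mean predictors enter: residuals are free of
    between-person level by construction.
    """
    if estimator != "orthogonal":
        raise ValueError(f"unknown estimator: {estimator!r}")
    others = [c for c in residuals.columns if c != node]
    df = residuals.rename(columns={node: "y"}).reset_index()
    pred_cols = others
    res, slopes, label = _run_mixed(df, pred_cols, pred_cols, node)
    fe = res.fe_params
    bse = res.bse_fe
    pv = res.pvalues
    return ResidualFit(
        node=node,
        coef={c: float(fe[c]) for c in others},
        se={c: float(bse[c]) for c in others},
        p={c: float(pv[c]) for c in others},
        random_sd={c: _vcomp_sds(res, slopes).get(c, 0.0) for c in others},
        resid_sd=float(np.sqrt(res.scale)),
        n_obs=len(df),
        method=label,
    )


def combine_to_partial_correlation(
    beta_jk: float, beta_kj: float, resid_var_j: float, resid_var_k: float
) -> float:
    """Symmetrize two directional regression coefficients into one edge.

    For a Gaussian graphical model, the regression coefficient of k in j's
    node-wise regression relates to the partial correlation rho_jk via
    rho_jk = beta_jk * sqrt(resid_var_k / resid_var_j); the two directional
    estimates are averaged and clipped to [-1, 1].
    """
    if resid_var_j <= 0 or resid_var_k <= 0:
        raise ValueError("residual variances must be positive")
    rho1 = beta_jk * np.sqrt(resid_var_k / resid_var_j)
    rho2 = beta_kj * np.sqrt(resid_var_j / resid_var_k)
    return float(np.clip(0.5 * (rho1 + rho2), -1.0, 1.0))


def fit_mlvar(
    centered: CenteredPanel,
    estimator: str = "orthogonal",
    and_rule: bool = False,
    alpha: float = 0.05,
) -> NetworkSet:
    """Estimate the temporal, contemporaneous and between-subjects networks.

    Orchestrates step 1 over all nodes (temporal matrix from the fixed
    lagged coefficients; between network from the person-mean coefficients
    combined pairwise using the random-intercept variances), then step 2 on
    the aligned step-1 residuals (contemporaneous network combined likewise
    using the step-2 residual variances).

    ``and_rule=True`` zeroes a symmetric edge unless both directional
    coefficients are significant at ``alpha`` (significance-based pruning;
    off by default, matching full weighted reporting).
    """
    items = centered.items
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 nodes")
    design = build_lag_pairs(centered)
    if design.empty:
        raise MlvarError("no lag pairs: panel has no consecutive observed days")
    step1: dict[str, NodeRegressionFit] = {}
    failures: list[str] = []
    for it in items:
        try:
            step1[it] = fit_node_step1(it, design, items, estimator)
        except MlvarError as exc:
            failures.append(str(exc))
    if failures:
        raise MlvarError(
            f"step 1 failed for {len(failures)} node(s): " + "; ".join(failures)
        )
    temporal = np.zeros((n, n))
    temporal_se = np.zeros((n, n))
    temporal_p = np.ones((n, n))
    random_sd = np.zeros((n, n))
    for j, it_j in enumerate(items):
        f = step1[it_j]
        for k, it_k in enumerate(items):
            temporal[j, k] = f.lag_coef[it_k]
            temporal_se[j, k] = f.lag_se[it_k]
            temporal_p[j, k] = f.lag_p[it_k]
            random_sd[j, k] = f.random_sd[it_k]

    between = np.zeros((n, n))
    for j, k in ((j, k) for j in range(n) for k in range(j + 1, n)):
        it_j, it_k = items[j], items[k]
        var_j = max(step1[it_j].intercept_sd**2, 1e-12)
        var_k = max(step1[it_k].intercept_sd**2, 1e-12)
        edge = combine_to_partial_correlation(
            step1[it_j].mean_coef[it_k], step1[it_k].mean_coef[it_j], var_j, var_k
        )
        if and_rule:
            z_jk = step1[it_j].mean_coef[it_k] / max(step1[it_j].mean_se[it_k], 1e-12)
            z_kj = step1[it_k].mean_coef[it_j] / max(step1[it_k].mean_se[it_j], 1e-12)
            from scipy.stats import norm

            if not (2 * norm.sf(abs(z_jk)) < alpha and 2 * norm.sf(abs(z_kj)) < alpha):
                edge = 0.0
        between[j, k] = between[k, j] = edge

    resid = pd.DataFrame({it: step1[it].residuals for it in items}).dropna()
    step2: dict[str, ResidualFit] = {}
    for it in items:
        try:
            step2[it] = fit_node_step2(it, resid, estimator)
        except MlvarError as exc:
            failures.append(str(exc))
    if failures:
        raise MlvarError(
            f"step 2 failed for {len(failures)} node(s): " + "; ".join(failures)
        )
    contemporaneous = np.zeros((n, n))
    for j, k in ((j, k) for j in range(n) for k in range(j + 1, n)):
        it_j, it_k = items[j], items[k]
        edge = combine_to_partial_correlation(
            step2[it_j].coef[it_k],
            step2[it_k].coef[it_j],
            step2[it_j].resid_sd**2,
            step2[it_k].resid_sd**2,
        )
        if and_rule and not (
            step2[it_j].p[it_k] < alpha and step2[it_k].p[it_j] < alpha
        ):
            edge = 0.0
        contemporaneous[j, k] = contemporaneous[k, j] = edge

    meta = {
        "estimator": estimator,
        "and_rule": and_rule,
        "n_lag_rows": int(len(design)),
        "n_step2_rows": int(len(resid)),
        "step1_methods": ",".join(step1[it].method for it in items),
        "step2_methods": ",".join(step2[it].method for it in items),
    }
    return NetworkSet(
        node_labels=list(items),
        temporal=temporal,
        contemporaneous=contemporaneous,
        between=between,
        temporal_se=temporal_se,
        temporal_p=temporal_p,
        random_effect_sd=random_sd,
        meta=meta,
    )
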