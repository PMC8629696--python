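"""Two-step multilevel estimator: oracles in analytic limits and recovery."""

import numpy as np
import pandas as pd
import pytest

from emanet import (
    GenerativeParams,
    build_lag_pairs,
    combine_to_partial_correlation,
    fit_mlvar,
    fit_node_step1,
    fit_node_step2,
    implied_contemporaneous,
    simulate_panel,
    within_person_center,
)


def no_re_params(n, B, Sw=None, Sb=None, seed=0):
    return GenerativeParams(
        n_items=n, B=B, tau=np.zeros((n, n)),
        Sigma_within=np.eye(n) * 0.36 if Sw is None else Sw,
        mu0=np.full(n, 3.0),
        Sigma_between=np.eye(n) * 0.36 if Sb is None else Sb,
        seed=seed,
    )


def pooled_ols(design: pd.DataFrame, node: str, items: list[str]) -> dict[str, float]:
    """Independent oracle: per-node pooled least squares on the same design."""
    lag = [f"lag_{it}" for it in items]
    pm = [f"pm_{it}" for it in items if it != node]
    df = design[[f"y_{node}", *lag, *pm]].dropna()
    X = np.column_stack([np.ones(len(df)), df[lag + pm].to_numpy()])
    beta, *_ = np.linalg.lstsq(X, df[f"y_{node}"].to_numpy(), rcond=None)
    return dict(zip(["const", *lag, *pm], beta))


@pytest.fixture(scope="module")
def tau_zero_fit():
    n = 4
    B = np.array(
        [[0.3, 0.15, 0.0, 0.0],
         [0.0, 0.25, -0.12, 0.0],
         [0.1, 0.0, 0.3, 0.0],
         [0.0, 0.0, 0.0, 0.2]]
    )
    K = np.array(
        [[2.0, -0.5, 0.0, 0.0],
         [-0.5, 2.0, -0.4, 0.0],
         [0.0, -0.4, 2.0, 0.0],
         [0.0, 0.0, 0.0, 2.0]]
    )
    Sw = np.linalg.inv(K)
    params = no_re_params(n, B, Sw=Sw, seed=31)
    panel, truth = simulate_panel(params, 120, 40)
    centered = within_person_center(panel)
    design = build_lag_pairs(centered)
    net = fit_mlvar(centered)
    return params, truth, centered, design, net


class TestStep1:
    def test_tau_zero_matches_pooled_ols(self, tau_zero_fit):
        params, _, centered, design, net = tau_zero_fit
        items = centered.items
        for j, node in enumerate(items):
            oracle = pooled_ols(design, node, items)
            for k, it in enumerate(items):
                assert net.temporal[j, k] == pytest.approx(
                    oracle[f"lag_{it}"], abs=0.02
                )

    def test_null_truth_gives_null_fixed_effects(self):
        n = 3
        params = no_re_params(n, np.zeros((n, n)), seed=13)
        panel, _ = simulate_panel(params, 150, 40)
        centered = within_person_center(panel)
        design = build_lag_pairs(centered)
        for node in centered.items:
            fit = fit_node_step1(node, design, centered.items)
            for it in centered.items:
                assert abs(fit.lag_coef[it]) < 3 * fit.lag_se[it] + 1e-9

    def test_random_slope_sd_recovery(self):
        # tau recovered within 25% relative error at 300 persons x 40 days
        n = 3
        B = np.eye(n) * 0.3
        params = GenerativeParams(
            n_items=n, B=B, tau=np.full((n, n), 0.12),
            Sigma_within=np.eye(n) * 0.36, mu0=np.full(n, 3.0),
            Sigma_between=np.eye(n) * 0.36, seed=17,
        )
        panel, _ = simulate_panel(params, 300, 40)
        centered = within_person_center(panel)
        design = build_lag_pairs(centered)
        fit = fit_node_step1(centered.items[0], design, centered.items)
        sds = np.array(list(fit.random_sd.values()))
        assert np.all(np.abs(sds - 0.12) / 0.12 < 0.25)


class TestStep2:
    def test_independent_residuals_give_null_coefficients(self):
        rng = np.random.default_rng(5)
        idx = pd.MultiIndex.from_product(
            [[f"p{i}" for i in range(60)], range(1, 31)], names=["person_id", "day"]
        )
        resid = pd.DataFrame(
            rng.standard_normal((len(idx), 3)), index=idx, columns=["A", "B", "C"]
        )
        fit = fit_node_step2("A", resid)
        for c in ("B", "C"):
            assert abs(fit.coef[c]) < 3 * fit.se[c] + 1e-9

    def test_coefficients_match_precision_matrix(self):
        K = np.array([[2.0, -0.6, 0.3], [-0.6, 2.0, -0.5], [0.3, -0.5, 2.0]])
        Sigma = np.linalg.inv(K)
        rng = np.random.default_rng(9)
        idx = pd.MultiIndex.from_product(
            [[f"p{i}" for i in range(200)], range(1, 41)], names=["person_id", "day"]
        )
        x = rng.multivariate_normal(np.zeros(3), Sigma, size=len(idx))
        resid = pd.DataFrame(x, index=idx, columns=["A", "B", "C"])
        fit = fit_node_step2("A", resid)
        # regression implied by the precision matrix: beta_jk = -K[j,k]/K[j,j]
        assert fit.coef["B"] == pytest.approx(-K[0, 1] / K[0, 0], abs=0.03)
        assert fit.coef["C"] == pytest.approx(-K[0, 2] / K[0, 0], abs=0.03)


class TestCombine:
    def test_zero_coefficients_give_zero(self):
        assert combine_to_partial_correlation(0.0, 0.0, 1.0, 2.0) == 0.0

    def test_bivariate_identity(self):
        # standardized bivariate case: both betas equal r, variances 1 - r^2
        r = 0.45
        v = 1 - r**2
        assert combine_to_partial_correlation(r, r, v, v) == pytest.approx(r)

    def test_matches_matrix_inversion_oracle(self):
        rng = np.random.default_rng(2)
        A = rng.standard_normal((4, 4))
        Sigma = A @ A.T + 4 * np.eye(4)
        K = np.linalg.inv(Sigma)
        true_pc = implied_contemporaneous(Sigma)
        x = rng.multivariate_normal(np.zeros(4), Sigma, size=50_000)
        for j in range(4):
            for k in range(j + 1, 4):
                def node_reg(a):
                    rest = [m for m in range(4) if m != a]
                    X = np.column_stack([np.ones(len(x)), x[:, rest]])
                    beta, res, *_ = np.linalg.lstsq(X, x[:, a], rcond=None)
                    rv = float(res[0]) / len(x)
                    return dict(zip(rest, beta[1:])), rv

                bj, vj = node_reg(j)
                bk, vk = node_reg(k)
                edge = combine_to_partial_correlation(bj[k], bk[j], vj, vk)
                assert edge == pytest.approx(true_pc[j, k], abs=0.02)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            combine_to_partial_correlation(0.1, 0.1, 0.0, 1.0)


class TestFitMlvar:
    def test_symmetry_and_zero_diagonal(self, tau_zero_fit):
        *_, net = tau_zero_fit
        np.testing.assert_array_equal(net.contemporaneous, net.contemporaneous.T)
        np.testing.assert_array_equal(net.between, net.between.T)
        assert np.all(np.diag(net.contemporaneous) == 0)
        assert np.all(np.diag(net.between) == 0)

    def test_contemporaneous_recovers_implied_partials(self, tau_zero_fit):
        params, truth, _, _, net = tau_zero_fit
        tril = np.tril_indices(params.n_items, -1)
        est, true = net.contemporaneous[tril], truth.contemporaneous[tril]
        assert np.corrcoef(est, true)[0, 1] > 0.9
        assert np.abs(est - true).max() < 0.12

    def test_node_permutation_conjugates_networks(self):
        n = 3
        params = no_re_params(n, np.array(
            [[0.3, 0.15, 0.0], [0.0, 0.25, -0.1], [0.1, 0.0, 0.3]]
        ), seed=23)
        panel, _ = simulate_panel(params, 60, 25)
        centered = within_person_center(panel)
        net = fit_mlvar(centered)

        perm = [2, 0, 1]
        items = [panel.items[i] for i in perm]
        permuted = panel.copy()
        permuted.items = items
        net_p = fit_mlvar(within_person_center(permuted))
        ix = np.ix_(perm, perm)
        np.testing.assert_allclose(net_p.temporal, net.temporal[ix], atol=1e-3)
        np.testing.assert_allclose(
            net_p.contemporaneous, net.contemporaneous[ix], atol=1e-3
        )
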