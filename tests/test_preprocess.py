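"""Completion filtering, detrending, centering, lag-pair construction."""

import numpy as np
import pandas as pd
import pytest

from emanet import (
    GenerativeParams,
    build_lag_pairs,
    detrend,
    filter_min_completion,
    fit_trends,
    simulate_panel,
    within_person_center,
    PanelValidationError,
)

from conftest import make_panel


def panel_with_counts(counts: dict[str, int], n_days: int = 40):
    vals = {
        pid: {d: [3.0] for d in range(1, c + 1)} for pid, c in counts.items()
    }
    return make_panel(vals, ["A"], n_days)


class TestFilterMinCompletion:
    def test_threshold_is_inclusive(self):
        panel = panel_with_counts({"p29": 29, "p30": 30, "p40": 40})
        kept, report = filter_min_completion(panel, 30)
        assert set(kept.persons) == {"p30", "p40"}
        assert (report.n_retained, report.n_excluded) == (2, 1)

    def test_zero_threshold_is_identity(self):
        panel = panel_with_counts({"a": 5, "b": 17})
        kept, report = filter_min_completion(panel, 0)
        assert kept == panel
        assert report.retention_percent == 100.0

    def test_retention_percent_matches_headline_arithmetic(self):
        # 1368 retained of 1706 enrolled -> 80.19% to two decimals
        panel = panel_with_counts(
            {f"k{i}": 35 for i in range(1368)} | {f"x{i}": 10 for i in range(338)},
            n_days=40,
        )
        _, report = filter_min_completion(panel, 30)
        assert report.n_total == 1706
        assert report.n_retained == 1368
        assert round(report.retention_percent, 2) == 80.19

    def test_monotone_in_min_days(self):
        panel = panel_with_counts({f"p{i}": i for i in range(2, 20)}, n_days=25)
        prev = None
        for m in range(0, 21, 5):
            kept, _ = filter_min_completion(panel, m)
            ids = set(kept.persons)
            if prev is not None:
                assert ids <= prev
            prev = ids


class TestTrends:
    def test_recovers_injected_slope_and_weekend(self):
        n = 2
        p = GenerativeParams(
            n_items=n, B=np.zeros((n, n)), tau=np.zeros((n, n)),
            Sigma_within=np.eye(n) * 0.25, mu0=np.full(n, 3.0),
            Sigma_between=np.eye(n) * 0.25, seed=21,
            trend_slopes=np.array([0.05, 0.0]),
            weekend_effects=np.array([0.3, 0.3]),
        )
        panel, _ = simulate_panel(p, 200, 40)
        fit = fit_trends(panel)
        assert abs(fit.slope["V1"] - 0.05) < 3 * fit.se_slope["V1"]
        assert abs(fit.weekend["V1"] - 0.3) < 3 * fit.se_weekend["V1"]
        assert abs(fit.slope["V2"] - 0.0) < 3 * fit.se_slope["V2"]
        assert abs(fit.weekend["V2"] - 0.3) < 3 * fit.se_weekend["V2"]

    def test_constant_item_has_zero_trend(self):
        panel = make_panel({"p": {d: [4.0] for d in range(1, 11)}}, ["A"], 10)
        fit = fit_trends(panel)
        assert fit.slope["A"] == pytest.approx(0, abs=1e-12)
        assert fit.weekend["A"] == pytest.approx(0, abs=1e-12)
        assert fit.intercept["A"] == pytest.approx(4.0)

    def test_detrend_then_refit_gives_zero_trends(self):
        p = GenerativeParams(
            n_items=1, B=np.array([[0.3]]), tau=np.zeros((1, 1)),
            Sigma_within=np.eye(1) * 0.4, mu0=np.array([3.0]),
            Sigma_between=np.eye(1) * 0.3, seed=5,
            trend_slopes=np.array([0.04]), weekend_effects=np.array([0.25]),
        )
        panel, _ = simulate_panel(p, 50, 40)
        first = fit_trends(panel)
        flat = detrend(panel, first)
        refit = fit_trends(flat)
        assert abs(refit.slope["V1"]) < 1e-10
        assert abs(refit.weekend["V1"]) < 1e-10

    def _week_panel(self):
        return make_panel(
            {"p": {d: [float(2 + d % 3), 3.0] for d in range(1, 8)}}, ["A", "B"], 7
        )

    def test_zero_fit_is_identity(self):
        panel = self._week_panel()
        fit = fit_trends(panel)
        fit.slope = {k: 0.0 for k in fit.slope}
        fit.weekend = {k: 0.0 for k in fit.weekend}
        out = detrend(panel, fit)
        pd.testing.assert_frame_equal(out.data, panel.data, check_dtype=False)

    def test_missing_item_in_fit_rejected(self):
        panel = self._week_panel()
        fit = fit_trends(panel, items=["A"])
        with pytest.raises(PanelValidationError, match="lacks items"):
            detrend(panel, fit)

    def test_all_weekend_design_rejected(self):
        panel = make_panel(
            {"p": {4: [2.0], 5: [3.0], 11: [4.0], 12: [1.0]}}, ["A"], 12
        )
        with pytest.raises(PanelValidationError, match="rank-deficient"):
            fit_trends(panel)


class TestCentering:
    def test_two_value_example(self):
        panel = make_panel({"p": {1: [2.0], 2: [4.0]}}, ["A"], 2)
        c = within_person_center(panel)
        assert list(c.panel.data["A"]) == [-1.0, 1.0]
        assert c.person_means.loc["p", "A"] == 3.0

    def test_centered_values_sum_to_zero_per_person(self, small_sim):
        _, panel, _ = small_sim
        c = within_person_center(panel)
        sums = c.panel.data.groupby("person_id")[c.items].sum()
        assert np.abs(sums.to_numpy()).max() < 1e-8 * panel.n_days

    def test_centering_is_idempotent(self, tiny_panel):
        once = within_person_center(tiny_panel)
        twice = within_person_center(once.panel)
        pd.testing.assert_frame_equal(once.panel.data, twice.panel.data)

    def test_single_day_person_rejected(self):
        panel = make_panel({"p": {1: [2.0]}, "q": {1: [2.0], 2: [3.0]}}, ["A"], 3)
        with pytest.raises(PanelValidationError, match="fewer than 2"):
            within_person_center(panel)


class TestLagPairs:
    def test_gap_breaks_chain(self):
        panel = make_panel(
            {"p": {d: [float(d)] for d in (1, 2, 3, 5)}}, ["A"], 6
        )
        pairs = build_lag_pairs(within_person_center(panel))
        assert sorted(pairs["day"]) == [2, 3]

    def test_complete_person_has_T_minus_1_rows(self):
        panel = make_panel({"p": {d: [float(d % 3)] for d in range(1, 41)}}, ["A"], 40)
        pairs = build_lag_pairs(within_person_center(panel))
        assert len(pairs) == 39

    def test_count_equals_consecutive_adjacencies(self, small_sim):
        _, panel, _ = small_sim
        c = within_person_center(panel)
        pairs = build_lag_pairs(c)
        expected = 0
        for _, g in panel.data.groupby("person_id"):
            days = np.sort(g["day"].to_numpy())
            expected += int(np.sum(np.diff(days) == 1))
        assert len(pairs) == expected

    def test_outcome_is_centered_plus_person_mean(self):
        panel = make_panel({"p": {1: [2.0], 2: [4.0], 3: [3.0]}}, ["A"], 3)
        c = within_person_center(panel)
        pairs = build_lag_pairs(c)
        np.testing.assert_allclose(pairs["y_A"], [4.0, 3.0])
        np.testing.assert_allclose(pairs["lag_A"], [-1.0, 1.0])
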