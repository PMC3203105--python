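"""ICER arithmetic, Monte Carlo uncertainty and the sensitivity grid."""

import math

import numpy as np
import pytest

import pmslt
from pmslt import cea_engine


class TestIcer:
    def test_zero_cost_zero_ratio(self):
        assert cea_engine.icer(0.0, 100.0) == 0.0

    def test_no_health_gain_is_dominated_sentinel(self):
        assert cea_engine.icer(1e6, 0.0) == math.inf
        assert cea_engine.icer(1e6, -5.0) == math.inf

    def test_two_significant_figure_reporting(self):
        assert cea_engine.round_2sf(1.4e9 / 1.1e4) == 130_000
        assert cea_engine.round_2sf(84_321) == 84_000
        assert cea_engine.round_2sf(math.inf) == math.inf

    def test_ratio_of_means_not_mean_of_ratios(self):
        """On skewed draws the two estimators differ; the point estimate must
        be the ratio of means."""
        costs = np.array([100.0, 100.0, 100.0])
        dalys = np.array([0.1, 1.0, 10.0])
        ratio_of_means = costs.mean() / dalys.mean()
        mean_of_ratios = (costs / dalys).mean()
        assert ratio_of_means != pytest.approx(mean_of_ratios, rel=0.5)
        assert cea_engine.icer(costs.mean(), dalys.mean()) == ratio_of_means


class TestBmiUtility:
    def test_zero_utility_unchanged(self):
        assert cea_engine.add_bmi_utility(12.0, 1e6, 0.0) == 12.0

    def test_unit_exposure_year_adds_utility_weight(self):
        assert cea_engine.add_bmi_utility(0.0, 1.0) == pytest.approx(0.017)

    def test_year_one_per_starter_contribution(self, prepared):
        """With a midpoint intra-year exposure of half the 12-month loss, one
        treated male starter contributes 0.017 * (4.45 / 1.78^2) / 2 QALYs
        in the intervention year (undiscounted)."""
        per_starter = 0.017 * (4.45 / 1.78**2) * 0.5
        assert per_starter == pytest.approx(0.0119, abs=2e-4)


class TestPsa:
    def test_degenerate_distributions_collapse_intervals(self, prepared):
        sc = pmslt.ScenarioConfig(drug="sibutramine", loss_se=0.0, regain_rate=0.385)
        # zero out the stochastic components by hand
        eff = sc.weight_effect()
        draws = [
            cea_engine.ParameterDraw(
                loss_kg=eff.loss_at_12m, regain_rate=eff.regain_rate
            )
            for _ in range(3)
        ]
        outs = [cea_engine.evaluate_scenario(prepared, sc, d) for d in draws]
        point = cea_engine.evaluate_scenario(prepared, sc)
        for out in outs:
            assert out.dalys == pytest.approx(point.dalys, rel=1e-12)
            assert out.net_cost("plus_unrelated") == pytest.approx(
                point.net_cost("plus_unrelated"), rel=1e-12
            )

    def test_identical_seeds_identical_results(self, prepared):
        sc = pmslt.ScenarioConfig(drug="orlistat")
        a = cea_engine.run_psa(prepared, sc, n_iter=30, seed=99)
        b = cea_engine.run_psa(prepared, sc, n_iter=30, seed=99)
        assert a.dalys == b.dalys
        assert a.icers == b.icers
        assert a.p_cost_effective == b.p_cost_effective

    def test_interval_orders_and_covers_mean(self, prepared):
        res = cea_engine.run_psa(
            prepared, pmslt.ScenarioConfig(drug="sibutramine"), n_iter=60, seed=5
        )
        mean, lo, hi = res.dalys
        assert lo <= mean <= hi
        for key, (m, l, h) in res.cost_components.items():
            assert l <= m + 1e-9 and m <= h + 1e-9, key

    def test_percentile_interval_covers_deterministic_point(self, prepared):
        """For (near) symmetric input distributions the 95% interval should
        cover the deterministic point estimate for most seeds."""
        point = pmslt.evaluate_scenario(
            prepared, pmslt.ScenarioConfig(drug="sibutramine")
        ).dalys
        covered = 0
        for seed in (11, 12, 13, 14, 15):
            res = cea_engine.run_psa(
                prepared, pmslt.ScenarioConfig(drug="sibutramine"), n_iter=60, seed=seed
            )
            covered += res.dalys[1] <= point <= res.dalys[2]
        assert covered >= 4

    def test_too_few_iterations_rejected(self, prepared):
        with pytest.raises(ValueError):
            cea_engine.run_psa(prepared, pmslt.ScenarioConfig(), n_iter=1)


class TestSensitivityGrid:
    def test_unknown_scenario_key_rejected(self):
        with pytest.raises(ValueError, match="unknown sensitivity"):
            cea_engine.sensitivity_scenario(pmslt.ScenarioConfig(), "nonsense")

    def test_scenario_construction(self):
        base = pmslt.ScenarioConfig(drug="sibutramine")
        assert cea_engine.sensitivity_scenario(base, "regain_halved").regain_scale == 0.5
        assert (
            cea_engine.sensitivity_scenario(base, "permanent_23pct").permanent_fraction
            == 0.23
        )
        assert cea_engine.sensitivity_scenario(base, "discount_0").discount_rate == 0.0
        assert cea_engine.sensitivity_scenario(base, "age_40_49").age_group == (40, 50)

    def test_grid_directions(self, prepared):
        grid = cea_engine.run_sensitivity_grid(
            prepared, pmslt.ScenarioConfig(drug="sibutramine")
        ).set_index("scenario")
        base = grid.loc["base"]
        assert grid.loc["discount_0", "dalys_averted"] > base["dalys_averted"]
        assert grid.loc["discount_0", "icer"] < base["icer"]
        assert grid.loc["regain_halved", "dalys_averted"] > base["dalys_averted"]
        assert grid.loc["regain_halved", "icer"] < base["icer"]
        assert grid.loc["age_20_29", "dalys_averted"] == pytest.approx(0.0, abs=1e-9)
        assert grid.loc["age_20_29", "icer"] == math.inf
        assert (
            grid.loc["disease_free_baseline", "dalys_averted"] >= base["dalys_averted"]
        )
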