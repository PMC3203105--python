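"""Cohort life-table engine: survivorship, disability linkage, DALYs."""

import numpy as np
import pandas as pd
import pytest

import pmslt
from pmslt import cea_engine, multistate_lifetable as mslt


class TestLifeTableCore:
    def test_constant_hazard_life_expectancy_closed_form(self):
        """Half-cycle person-years under constant annual risk q over n years
        equal (1 - q/2) (1 - (1-q)^n) / q (geometric series)."""
        q, n = 0.02, 80
        closed = (1 - q / 2) * (1 - (1 - q) ** n) / q
        assert abs(mslt.life_expectancy(np.full(n, q)) - closed) < 1e-10

    def test_null_intervention_reproduces_reference_table(self, prepared):
        sa = prepared.sex_arrays["male"]
        ref = mslt.simulate_arm(sa)
        null = mslt.simulate_arm(sa, pif_fn=lambda t, idx: 0.0, ref=ref)
        for attr in ("l_start", "q", "L", "disability", "Lw", "C", "mort_d"):
            assert np.array_equal(getattr(ref, attr), getattr(null, attr)), attr

    def test_survivorship_non_increasing(self, prepared):
        sa = prepared.sex_arrays["female"]
        ref = mslt.simulate_arm(sa)
        frame = mslt.lifetable_frame(ref, sa)
        for _, sub in frame.groupby("cohort"):
            assert (np.diff(sub.sort_values("age")["l"].to_numpy()) <= 1e-15).all()
        assert frame["Lw"].le(frame["L"] + 1e-15).all()
        assert frame["d"].between(0, 1).all()

    def test_flow_conservation_each_cycle(self, prepared):
        """living + cumulative deaths == 1 at every age for every cohort."""
        sa = prepared.sex_arrays["male"]
        ref = mslt.simulate_arm(sa)
        deaths = ref.l_start * ref.q
        for c in range(sa.n_cohorts):
            alive = ref.active[:, c]
            l = ref.l_start[alive, c]
            cum_dead = np.concatenate([[0.0], np.cumsum(deaths[alive, c])])[:-1]
            assert np.allclose(l + cum_dead, 1.0, atol=1e-12)

    def test_single_disease_disability_delta_arithmetic(self):
        """A prevalence reduction of 0.01 under weight 0.31 raises Lw at that
        age by 0.0031 * L."""
        d_base, delta_prev, w = 0.10, 0.01, 0.31
        L = 0.95
        lw_ref = L * (1 - d_base)
        lw_int = L * (1 - (d_base - delta_prev * w))
        assert lw_int - lw_ref == pytest.approx(0.0031 * L)


class TestDalysAverted:
    def _toy_tables(self):
        grid = {"sex": "male", "cohort": 20, "age": [20, 21, 22]}
        ref = pd.DataFrame({**grid, "l": 1.0, "m": 0.0, "d": 0.0, "L": 1.0, "Lw": [1.0, 0.9, 0.8]})
        inter = ref.copy()
        inter["Lw"] = [1.0, 0.95, 0.9]
        return ref, inter

    def test_identical_tables_avert_nothing(self):
        ref, _ = self._toy_tables()
        assert mslt.dalys_averted(ref, ref, 0.03) == 0.0

    def test_hand_summed_two_cohort_fixture(self):
        """Spreadsheet-style hand sum: sum_t (Lw_int - Lw_ref) w (1+r)^-t."""
        ref, inter = self._toy_tables()
        r = 0.03
        hand = (0.05 * 100) / 1.03 + (0.1 * 100) / 1.03**2
        got = mslt.dalys_averted(ref, inter, r, cohort_weights={("male", 20): 100})
        assert got == pytest.approx(hand)

    def test_discounting_reduces_future_gains(self):
        ref, inter = self._toy_tables()
        assert mslt.dalys_averted(ref, inter, 0.0) > mslt.dalys_averted(ref, inter, 0.03)

    def test_mismatched_grids_rejected(self):
        ref, inter = self._toy_tables()
        with pytest.raises(ValueError, match="mismatched"):
            mslt.dalys_averted(ref, inter.iloc[:-1], 0.03)

    def test_burden_fraction(self):
        assert mslt.burden_fraction_averted(5.0, 5.0) == 1.0
        assert mslt.burden_fraction_averted(0.0, 5.0) == 0.0
        with pytest.raises(ValueError):
            mslt.burden_fraction_averted(1.0, 0.0)


class TestPipelineProperties:
    def test_zero_disability_weights_and_no_mortality_link_avert_nothing(self, world):
        w2 = pmslt.World(**{k: v.copy() for k, v in world.tables().items()})
        w2.disability_weights["weight"] = 0.0
        w2.disease_epi["case_fatality"] = 0.0
        out = pmslt.evaluate_scenario(
            pmslt.PreparedWorld(w2), pmslt.ScenarioConfig(drug="sibutramine")
        )
        assert out.dalys == pytest.approx(0.0, abs=1e-9)

    def test_uptake_doubling_is_approximately_linear(self, prepared):
        u = 0.2
        lo = pmslt.evaluate_scenario(
            prepared, pmslt.ScenarioConfig(drug="sibutramine", uptake=u)
        )
        hi = pmslt.evaluate_scenario(
            prepared, pmslt.ScenarioConfig(drug="sibutramine", uptake=2 * u)
        )
        assert hi.dalys == pytest.approx(2 * lo.dalys, rel=0.05)

    def test_youngest_cohorts_gain_nothing(self, prepared):
        """Relative risks are 1 below age 35 and the loss is fully regained
        within two years, so 20-29-year-old cohorts see no benefit."""
        out = pmslt.evaluate_scenario(
            prepared, pmslt.ScenarioConfig(drug="sibutramine", age_group=(20, 30))
        )
        assert out.dalys == pytest.approx(0.0, abs=1e-9)

    def test_burden_fraction_magnitude_band(self, prepared, sibutramine_point):
        """A one-year drug course averts a fraction of the total BMI burden
        on the order of a few tenths of a percent."""
        ideal = cea_engine.ideal_burden(prepared)
        frac = mslt.burden_fraction_averted(sibutramine_point.dalys, ideal)
        assert 0.0005 <= frac <= 0.01
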