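"""Relative-risk evaluation and potential impact fractions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmslt import exposure_model as em, risk_engine as re_


class TestRrAt:
    @pytest.mark.parametrize(
        "rr,delta,expected",
        [(1.10, 1.0, 1.10), (1.0, 7.3, 1.0), (1.19, 2.0, 1.4161)],
    )
    def test_log_linear_compounding(self, rr, delta, expected):
        assert re_.rr_at(21.0 + delta, rr) == pytest.approx(expected)

    def test_below_reference_not_floored(self):
        assert re_.rr_at(20.0, 1.10) == pytest.approx(1 / 1.10)

    def test_negative_rr_rejected(self):
        with pytest.raises(ValueError):
            re_.rr_at(25.0, -0.5)


class TestMeanRr:
    def test_unit_rr_gives_unit_mean(self):
        assert re_.mean_rr(em.BmiDistribution(27, 4), 1.0) == pytest.approx(1.0)

    def test_near_point_mass_at_reference(self):
        assert re_.mean_rr(em.BmiDistribution(21.0, 1e-3), 1.10) == pytest.approx(
            1.0, abs=1e-5
        )

    def test_quadrature_matches_lognormal_closed_form(self):
        """E[r^(X-ref)] for X ~ N(mu, s^2) is exp(b(mu-ref) + b^2 s^2/2)."""
        for mu, s, rr in [(27, 4, 1.10), (26.3, 5, 1.04), (24, 3, 1.19)]:
            quad = re_.mean_rr(em.BmiDistribution(mu, s), rr)
            closed = float(re_.mean_rr_normal(mu, s, np.log(rr)))
            assert quad == pytest.approx(closed, rel=1e-4)

    def test_unnormalized_density_rejected(self):
        class Half:
            def pdf(self, x):
                return 0.5 * em.BmiDistribution(27, 4).pdf(x)

        with pytest.raises(ValueError, match="integrates"):
            re_.mean_rr(Half(), 1.1)


class TestPif:
    def test_null_counterfactual_gives_zero(self):
        base = em.BmiDistribution(27, 4)
        assert re_.pif(base, base, 1.10) == pytest.approx(0.0, abs=1e-12)

    def test_unit_rr_gives_zero(self):
        base = em.BmiDistribution(27, 4)
        cf = em.BmiDistribution(25, 4)
        assert re_.pif(base, cf, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_equal_variance_mean_shift_closed_form(self):
        """Unit downward mean shift under rr=1.10: PIF = 1 - 1.10^-1."""
        p = re_.pif(em.BmiDistribution(27, 4), em.BmiDistribution(26, 4), 1.10)
        assert p == pytest.approx(1.0 - 1.10**-1, abs=5e-5)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(ref=st.floats(15.0, 35.0))
    def test_reference_bmi_cancels(self, ref):
        base = em.BmiDistribution(27, 4)
        mix = em.shift_obese_distribution(base, 2.89, 0.4175, 1.64)
        assert re_.pif(base, mix, 1.08, ref_bmi=ref) == pytest.approx(
            re_.pif(base, mix, 1.08, ref_bmi=21.0), abs=1e-9
        )

    def test_mixture_closed_form_matches_quadrature(self):
        base = em.BmiDistribution(26.3, 5.0)
        mix = em.shift_obese_distribution(base, 4.45, 0.4175, 1.64)
        quad = re_.pif(base, mix, 1.10)
        closed = float(
            re_.pif_obese_shift(26.3, 5.0, np.log(1.10), mix.shift, 0.4175)
        )
        assert quad == pytest.approx(closed, abs=5e-5)

    def test_monte_carlo_confirms_mixture_pif(self, rng):
        """1e6-sample Monte Carlo estimate agrees within 3 SE."""
        n = 10**6
        base = em.BmiDistribution(27.0, 4.0)
        mix = em.shift_obese_distribution(base, 4.45, 0.4175, 1.78)
        x = rng.normal(27.0, 4.0, n)
        xs = np.where(
            (x >= 30) & (rng.random(n) < 0.4175), x - mix.shift, x
        )
        rr_b = 1.10 ** (x - 21.0)
        rr_c = 1.10 ** (xs - 21.0)
        mc = 1.0 - rr_c.mean() / rr_b.mean()
        # delta-method SE of the ratio estimator
        ratio = rr_c.mean() / rr_b.mean()
        se = ratio * np.sqrt(
            rr_c.var() / (n * rr_c.mean() ** 2) + rr_b.var() / (n * rr_b.mean() ** 2)
        )
        assert abs(re_.pif(base, mix, 1.10) - mc) < 3 * se

    def test_larger_shift_gives_larger_pif(self):
        base = em.BmiDistribution(27, 4)
        pifs = [
            re_.pif(base, em.shift_obese_distribution(base, kg, 0.4175, 1.78), 1.10)
            for kg in (1.0, 2.89, 4.45)
        ]
        assert pifs == sorted(pifs)
        assert all(p > 0 for p in pifs)

    def test_ideal_closed_form(self):
        base = em.BmiDistribution(27, 4)
        closed = float(re_.pif_to_ideal(27, 4, np.log(1.10)))
        quad = re_.pif(base, em.ideal_distribution(), 1.10)
        assert quad == pytest.approx(closed, abs=5e-5)


class TestRrSchedule:
    def test_ci_to_log_se(self):
        se = float(re_.ln_rr_se_from_ci(1.06, 1.32))
        assert se == pytest.approx((np.log(1.32) - np.log(1.06)) / (2 * 1.96), rel=1e-3)

    def test_expand_rr_by_age_bands(self, world):
        ages = np.arange(20, 101)
        b = re_.expand_rr_by_age(world.rr_table, "diabetes", "male", ages)
        assert np.exp(b[ages < 35]) == pytest.approx(1.0)
        assert np.exp(b[(ages >= 35) & (ages < 45)]) == pytest.approx(1.19)
        assert np.exp(b[(ages >= 45) & (ages < 70)]) == pytest.approx(1.14)
        assert np.exp(b[ages >= 70]) == pytest.approx(1.10)

    def test_all_rr_unity_below_35(self, world):
        ages = np.arange(20, 35)
        for disease in world.rr_table["disease"].unique():
            b = re_.expand_rr_by_age(world.rr_table, disease, "female", ages)
            assert np.allclose(b, 0.0)

    def test_negative_rr_table_rejected(self, world):
        bad = world.rr_table.copy()
        bad.loc[0, "rr"] = -0.5
        with pytest.raises(ValueError):
            re_.validate_rr_table(bad)
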