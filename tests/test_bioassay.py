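"""WHO bioassay statistics: Abbott correction, Wilson CIs, classification, GLM."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vectorpop.bioassay import (
    BioassayRecord,
    classify_resistance,
    fit_binomial_glm,
    mortality,
    newcombe_ci,
    proportion_summary,
    summarize_bioassay,
)


def rec(dead, exposed=100, control_dead=0, control_n=25, **kw):
    base = dict(site="K", subsite="K1", insecticide="deltamethrin 0.05%")
    base.update(kw)
    return BioassayRecord(
        n_exposed=exposed, n_dead=dead, control_n=control_n, control_dead=control_dead, **base
    )


class TestMortality:
    def test_no_correction_below_five_percent_control(self):
        m = mortality(rec(80, control_dead=0))
        assert m.percent_mortality == 80.0 and not m.corrected

    def test_abbott_correction_in_band(self):
        # control 10%: (80 - 10) / 90 * 100 = 77.78
        m = mortality(rec(80, control_dead=2, control_n=20))
        assert m.corrected
        assert m.percent_mortality == pytest.approx(77.7778, abs=1e-3)

    def test_high_control_mortality_invalidates(self):
        m = mortality(rec(80, control_dead=5, control_n=20))  # 25% control
        assert m.status == "invalid"

    def test_abbott_identity_at_zero_control(self):
        for dead in (0, 37, 100):
            m = mortality(rec(dead))
            assert m.percent_mortality == pytest.approx(dead, abs=1e-12)
            assert not m.corrected

    def test_zero_exposed_rejected(self):
        with pytest.raises(ValueError):
            mortality(rec(0, exposed=0))


class TestNewcombeCi:
    def test_zero_successes(self):
        lo, hi = newcombe_ci(0, 100)
        assert lo == 0.0
        assert hi == pytest.approx(0.0370, abs=2e-4)

    def test_full_successes_upper_is_one(self):
        lo, hi = newcombe_ci(100, 100)
        assert hi == 1.0

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 50), st.integers(1, 50))
    def test_reflection_symmetry(self, k, extra):
        n = k + extra
        lo1, hi1 = newcombe_ci(k, n)
        lo2, hi2 = newcombe_ci(n - k, n)
        assert lo1 == pytest.approx(1 - hi2, abs=1e-12)
        assert hi1 == pytest.approx(1 - lo2, abs=1e-12)

    def test_matches_statsmodels_wilson(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(5, 40), (90, 100), (0, 10), (7, 7)]:
            lo, hi = newcombe_ci(k, n)
            slo, shi = proportion_confint(k, n, alpha=0.05, method="wilson")
            assert lo == pytest.approx(slo, abs=1e-10)
            assert hi == pytest.approx(shi, abs=1e-10)

    def test_coverage_near_nominal(self):
        rng = np.random.default_rng(77)
        k = rng.binomial(100, 0.9, size=800)
        cover = np.mean([(newcombe_ci(int(x), 100)[0] <= 0.9 <= newcombe_ci(int(x), 100)[1]) for x in k])
        assert 0.92 <= cover <= 0.98


class TestClassification:
    @pytest.mark.parametrize(
        "m,status",
        [
            (91, "suspected_resistance"),
            (85, "resistant"),
            (100, "susceptible"),
            (89.99, "resistant"),
            (90, "suspected_resistance"),
            (98, "susceptible"),
        ],
    )
    def test_who_thresholds(self, m, status):
        assert classify_resistance(m) == status

    def test_monotone_step_function(self):
        order = {"resistant": 0, "suspected_resistance": 1, "susceptible": 2}
        last = -1
        for m in np.linspace(0, 100, 201):
            rank = order[classify_resistance(float(m))]
            assert rank >= last
            last = rank

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_resistance(101)


class TestGlm:
    def test_two_group_closed_form(self):
        # 90/100 vs 50/100: coefficient log(odds2/odds1), Wald chi2 = (coef/SE)^2
        records = [rec(90, site="A"), rec(50, site="B")]
        fit = fit_binomial_glm(records, design="site")
        coef = fit.coefficients["site[T.B]"]
        assert coef == pytest.approx(-2.1972, abs=1e-4)
        se = math.sqrt(1 / 90 + 1 / 10 + 1 / 50 + 1 / 50)
        chi2 = (math.log((50 / 50) / (90 / 10)) / se) ** 2
        assert fit.wald_chi2["site"] == pytest.approx(chi2, abs=1e-6)
        assert fit.wald_chi2["site"] == pytest.approx(31.95, abs=0.01)

    def test_identical_groups_zero_effect(self):
        records = [rec(70, site="A"), rec(70, site="B")]
        fit = fit_binomial_glm(records, design="site")
        assert fit.coefficients["site[T.B]"] == pytest.approx(0.0, abs=1e-10)
        assert fit.wald_chi2["site"] == pytest.approx(0.0, abs=1e-10)

    def test_wald_equals_coef_over_se_squared(self):
        records = [rec(80, site="A"), rec(60, site="B")]
        fit = fit_binomial_glm(records, design="site")
        z2 = (fit.coefficients["site[T.B]"] / fit.standard_errors["site[T.B]"]) ** 2
        assert fit.wald_chi2["site"] == pytest.approx(z2, abs=1e-8)

    def test_separation_flagged(self):
        records = [rec(100, site="A"), rec(0, site="B")]
        fit = fit_binomial_glm(records, design="site")
        assert not fit.converged
        assert fit.warnings

    def test_parameter_recovery_from_simulation(self):
        from vectorpop.simulate import BioassaySimSpec, simulate_bioassay

        spec = BioassaySimSpec(
            sites=["A", "B"], insecticides=["x", "y"], intercept=1.0,
            site_effects={"B": -0.8}, insecticide_effects={"y": 0.5}, n_exposed=500,
        )
        ests = []
        for s in range(20):
            fit = fit_binomial_glm(simulate_bioassay(spec, seed=500 + s))
            ests.append(
                [
                    fit.coefficients["Intercept"],
                    fit.coefficients["site[T.B]"],
                    fit.coefficients["insecticide[T.y]"],
                ]
            )
        ests = np.array(ests)
        truth = np.array([1.0, -0.8, 0.5])
        mc_se = ests.std(axis=0, ddof=1) / math.sqrt(len(ests))
        assert (np.abs(ests.mean(axis=0) - truth) <= 3 * mc_se).all()


class TestProportionSummary:
    @pytest.mark.parametrize(
        "k,n,expected", [(730, 866, 84.3), (1140, 1382, 82.5), (0, 10, 0.0)]
    )
    def test_field_collection_percentages(self, k, n, expected):
        pct, (lo, hi) = proportion_summary(k, n)
        assert pct == expected
        assert lo <= pct <= hi

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            proportion_summary(0, 0)


class TestSummarize:
    def test_summary_has_ci_and_status(self):
        rows = summarize_bioassay([rec(91), rec(85), rec(100)])
        assert [r.status for r in rows] == [
            "suspected_resistance", "resistant", "susceptible",
        ]
        for r in rows:
            assert r.ci_low <= r.percent_mortality <= r.ci_high
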