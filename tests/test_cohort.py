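import numpy as np
import pytest

from ccm_dcea import (AnnualMortalitySchedule, FixedParams, RegionInputs,
                      ValidationError, incidence_from_prevalence,
                      mortality_at_coverage, pneumonia_decomposition,
                      run_cohort, u5mr_from_rates)
from ccm_dcea.fixtures import national_inputs
from ccm_dcea.life_tables import MAX_AGE


def constant_schedule(q):
    arr = np.full(MAX_AGE, q)
    arr[-1] = 1.0
    return AnnualMortalitySchedule(arr)


def closed_form_le(q):
    """Life years for a constant-q schedule with forced death at the last
    cycle: sum_{a=1..119} (1-q)^a, since the cohort is extinct at 120."""
    r = 1.0 - q
    ages = np.arange(1, MAX_AGE)
    return float((r ** ages).sum())


def closed_form_dly(q, rate):
    r = 1.0 - q
    ages = np.arange(1, MAX_AGE)
    return float((r ** ages * (1 + rate) ** (-ages)).sum())


def no_pneumonia_region(**overrides):
    base = dict(name="inert", q_infant=0.0, q_child=0.0,
                cost_per_treatment=0.0, incidence=0.0, baseline_coverage=0.0)
    base.update(overrides)
    return RegionInputs(**base)


class TestIncidence:
    def test_prevalence_to_annual_episodes(self):
        assert incidence_from_prevalence(0.005, 4.6) == pytest.approx(
            0.3967, abs=5e-5)

    def test_zero_prevalence(self):
        assert incidence_from_prevalence(0.0, 4.6) == 0.0

    def test_inverse_recovers_prevalence(self):
        # published Amhara incidence implies a ~0.57% point prevalence
        prevalence = 0.453 * 4.6 / 365
        assert prevalence == pytest.approx(0.005709, abs=5e-7)
        assert incidence_from_prevalence(prevalence, 4.6) == pytest.approx(
            0.453, abs=1e-12)

    def test_nonpositive_duration_errors(self):
        with pytest.raises(ValidationError):
            incidence_from_prevalence(0.01, 0.0)


class TestU5mrFromRates:
    @pytest.mark.parametrize("qi,qc,expected", [
        (0.0485, 0.0051, 0.06776),   # national rates
        (0.0767, 0.0115, 0.11844),   # highest-mortality region
        (0.0, 0.0, 0.0),
    ])
    def test_values(self, qi, qc, expected):
        assert u5mr_from_rates(qi, qc) == pytest.approx(expected, abs=5e-6)


class TestDecomposition:
    def test_national_infant_year(self, params):
        region = national_inputs()
        q_non, q_pneu = pneumonia_decomposition(0.0485, region, params)
        assert q_pneu == pytest.approx(0.397 * 0.0351 * (1 - 0.7 * 0.33),
                                       abs=1e-12)
        assert q_pneu == pytest.approx(0.010716, abs=5e-6)
        assert q_non == pytest.approx(0.037784, abs=5e-6)
        assert q_non + q_pneu == pytest.approx(0.0485, abs=1e-12)

    def test_zero_incidence(self, params):
        region = national_inputs().with_(incidence=0.0)
        assert pneumonia_decomposition(0.02, region, params) == (0.02, 0.0)

    def test_clamp_when_pneumonia_exceeds_allcause(self, params, caplog):
        region = national_inputs()
        with caplog.at_level("WARNING"):
            q_non, q_pneu = pneumonia_decomposition(0.001, region, params)
        assert q_non == 0.0
        assert q_pneu > 0.001
        assert "National" in caplog.text


class TestMortalityAtCoverage:
    def test_scale_up_drop_matches_delta(self, params):
        region = national_inputs()
        sched = constant_schedule(0.0485)
        out = mortality_at_coverage(sched, region, params, 0.90)
        drop = 0.397 * 0.0351 * 0.70 * (0.90 - 0.33)
        assert drop == pytest.approx(0.005560, abs=5e-7)
        assert sched.q[0] - out.q[0] == pytest.approx(drop, abs=1e-12)
        assert np.array_equal(out.q[5:], sched.q[5:])

    def test_baseline_coverage_is_bitwise_identity(self, params):
        region = national_inputs()
        sched = constant_schedule(0.0485)
        out = mortality_at_coverage(sched, region, params,
                                    region.baseline_coverage)
        assert np.array_equal(out.q, sched.q)

    def test_zero_efficacy_is_identity_at_any_coverage(self):
        params = FixedParams(efficacy=0.0)
        region = national_inputs()
        sched = constant_schedule(0.0485)
        out = mortality_at_coverage(sched, region, params, 0.90)
        assert np.array_equal(out.q, sched.q)

    def test_coverage_out_of_range(self, params):
        with pytest.raises(ValidationError):
            mortality_at_coverage(constant_schedule(0.01), national_inputs(),
                                  params, 1.2)

    def test_monotone_in_coverage_even_when_clamped(self, params):
        # child mortality below the implied pneumonia floor still yields
        # strictly lower mortality at higher coverage
        region = national_inputs().with_(q_child=0.002)
        arr = np.full(MAX_AGE, 0.0485)
        arr[1:5] = 0.002
        arr[-1] = 1.0
        sched = AnnualMortalitySchedule(arr)
        q_low = mortality_at_coverage(sched, region, params, 0.5).q
        q_high = mortality_at_coverage(sched, region, params, 0.9).q
        assert np.all(q_high[:5] < q_low[:5])


class TestRunCohort:
    @pytest.mark.parametrize("q", [0.5, 0.01, 0.1])
    def test_life_expectancy_matches_geometric_closed_form(self, q):
        params = FixedParams(discount_effects=0.0,
                             half_cycle_correction=False)
        res = run_cohort(constant_schedule(q), no_pneumonia_region(),
                         params, 0.0)
        assert res.life_expectancy == pytest.approx(closed_form_le(q),
                                                    abs=1e-9)

    def test_constant_half_life_expectancy_is_one(self):
        params = FixedParams(discount_effects=0.0,
                             half_cycle_correction=False)
        res = run_cohort(constant_schedule(0.5), no_pneumonia_region(),
                         params, 0.0)
        assert res.life_expectancy == pytest.approx(1.0, abs=5e-5)

    def test_discounted_life_years_matches_annuity(self):
        """With no mortality before the forced final death, discounted life
        years are the 119-payment annuity at 3%."""
        params = FixedParams(half_cycle_correction=False)
        res = run_cohort(constant_schedule(0.0), no_pneumonia_region(),
                         params, 0.0)
        v = 1 / 1.03
        expected = (v * (1 - v ** 119)) / (1 - v)
        assert res.life_expectancy == 119.0
        assert res.discounted_life_years == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("q", [0.01, 0.2])
    def test_discounted_matches_closed_form(self, q):
        params = FixedParams(half_cycle_correction=False)
        res = run_cohort(constant_schedule(q), no_pneumonia_region(),
                         params, 0.0)
        assert res.discounted_life_years == pytest.approx(
            closed_form_dly(q, 0.03), abs=1e-9)

    def test_half_cycle_correction_adds_half_year(self):
        region = no_pneumonia_region()
        sched = constant_schedule(0.01)
        on = run_cohort(sched, region, FixedParams(), 0.0)
        off = run_cohort(sched, region,
                         FixedParams(half_cycle_correction=False), 0.0)
        assert on.life_expectancy - off.life_expectancy == pytest.approx(0.5)
        assert (on.discounted_life_years - off.discounted_life_years
                == pytest.approx(0.5))

    def test_treatment_cost_undiscounted_full_survival(self):
        region = no_pneumonia_region(incidence=0.4, cost_per_treatment=100.0)
        # zero CFR: treatment is bought but nobody dies, so S stays 1
        params = FixedParams(discount_costs=0.0, cfr_untreated=0.0)
        res = run_cohort(constant_schedule(0.0), region, params, 0.9)
        assert res.treatment_cost_per_child == pytest.approx(
            5 * 0.4 * 0.9 * 100, abs=1e-9)

    def test_deaths_by_age_conserves_mass(self, cohort_arms):
        for base, tgt in cohort_arms.values():
            assert base.deaths_by_age.sum() == pytest.approx(1.0, abs=1e-9)
            assert tgt.deaths_by_age.sum() == pytest.approx(1.0, abs=1e-9)

    def test_u5mr_is_one_minus_s5(self, cohort_arms):
        for base, tgt in cohort_arms.values():
            assert base.u5mr == pytest.approx(1 - base.survival[5], abs=0)
            assert tgt.u5mr < base.u5mr

    def test_le_strictly_increasing_in_coverage(self, regions, params,
                                                reference_set):
        from ccm_dcea import region_schedule
        region = regions["Oromia"]
        sched = region_schedule(region, reference_set)
        results = [run_cohort(sched, region, params, c)
                   for c in (0.3, 0.5, 0.7, 0.9)]
        les = [r.life_expectancy for r in results]
        dlys = [r.discounted_life_years for r in results]
        u5s = [r.u5mr for r in results]
        assert les == sorted(les) and len(set(les)) == 4
        assert dlys == sorted(dlys) and len(set(dlys)) == 4
        assert u5s == sorted(u5s, reverse=True)

    def test_baseline_coverage_reproduces_schedule_survival(
            self, regions, params, reference_set):
        """Bit-exact identity for regions where no clamping occurs."""
        from ccm_dcea import region_schedule, survival_from_schedule
        for name in ("Addis", "Afar", "Gambela", "Somali"):
            region = regions[name]
            sched = region_schedule(region, reference_set)
            res = run_cohort(sched, region, params, region.baseline_coverage)
            assert np.array_equal(res.survival,
                                  survival_from_schedule(sched))

    def test_discounting_ordering(self, cohort_arms):
        for base, tgt in cohort_arms.values():
            assert base.discounted_life_years < base.life_expectancy

    def test_zero_discount_equality(self):
        params = FixedParams(discount_effects=0.0,
                             half_cycle_correction=False)
        res = run_cohort(constant_schedule(0.02), no_pneumonia_region(),
                         params, 0.0)
        assert res.discounted_life_years == res.life_expectancy
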