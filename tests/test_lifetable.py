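"""Life-table engine: disease recursion, mortality transfer, discounting, oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pamslt.lifetable import (
    DiseaseRates,
    LifetableError,
    StratumPopulation,
    discount,
    period_prevalence,
    recompute_mortality_morbidity,
    run_disease_lifetable,
    simulate_stratum,
)


def markov_power_oracle(incidence, case_fatality, remission, pif=None, init_prev=0.0):
    """Independent oracle: exhaustive matrix powering of the 3-state chain.

    States ordered (susceptible, prevalent, dead); the annual transition
    matrix encodes the fixed within-cycle order: case fatality first, then
    remission, then incidence.
    """
    n = len(incidence)
    pif = np.zeros(n) if pif is None else np.asarray(pif)
    v = np.array([1.0 - init_prev, init_prev, 0.0])
    states = [v.copy()]
    for t in range(n):
        i = incidence[t] * (1.0 - pif[t])
        f, r = case_fatality[t], remission[t]
        M = np.array(
            [
                [1.0 - i, i, 0.0],
                [(1.0 - f) * r, (1.0 - f) * (1.0 - r), f],
                [0.0, 0.0, 1.0],
            ]
        )
        v = v @ M
        states.append(v.copy())
    return np.array(states)


def toy_rates(i=0.1, f=0.0, r=0.0, n=5, dw=0.1):
    return DiseaseRates(
        "toy",
        incidence=np.full(n, i),
        case_fatality=np.full(n, f),
        remission=np.full(n, r),
        disability_weight=dw,
    )


class TestDiscount:
    def test_zero_rate_is_arithmetic_sum(self):
        assert discount([10.0, 20.0, 30.0], 0.0) == 60.0

    def test_single_deferred_value(self):
        assert discount([0.0, 100.0], 0.03) == pytest.approx(97.0874, abs=5e-5)

    def test_base_year_value_undiscounted(self):
        assert discount([123.4], 0.10) == 123.4


class TestDiseaseLifetable:
    def test_no_incidence_means_no_prevalence(self):
        table = run_disease_lifetable(toy_rates(i=0.0, f=0.1, r=0.05))
        assert np.all(table.prevalent == 0.0)

    def test_two_cycle_hand_recursion(self):
        # i=0.1, f=r=0: prevalent after 2 cycles = 1 - 0.9^2 = 0.19
        table = run_disease_lifetable(toy_rates(i=0.1))
        assert table.prevalent[2] == pytest.approx(0.19, abs=1e-15)

    def test_full_prevention_blocks_all_incidence(self):
        table = run_disease_lifetable(toy_rates(i=0.2, f=0.1), pif_eff=np.ones(5))
        assert np.all(table.new_cases == 0.0)
        assert np.all(table.prevalent == 0.0)

    def test_rate_above_one_rejected(self):
        # a strongly negative PIF pushes incidence above 1
        with pytest.raises(LifetableError):
            run_disease_lifetable(toy_rates(i=0.5), pif_eff=np.full(5, -2.0))

    @given(
        i=st.floats(0.0, 0.5),
        f=st.floats(0.0, 0.5),
        r=st.floats(0.0, 0.3),
        init=st.floats(0.0, 0.5),
    )
    def test_state_conservation_and_markov_equivalence(self, i, f, r, init):
        rates = toy_rates(i=i, f=f, r=r, n=8)
        table = run_disease_lifetable(rates, init_prevalence=init)
        assert table.conservation_error() < 1e-10
        oracle = markov_power_oracle(
            rates.incidence, rates.case_fatality, rates.remission, init_prev=init
        )
        np.testing.assert_allclose(table.susceptible, oracle[:, 0], atol=1e-12)
        np.testing.assert_allclose(table.prevalent, oracle[:, 1], atol=1e-12)
        np.testing.assert_allclose(table.dead, oracle[:, 2], atol=1e-12)


class TestRecomputeMortalityMorbidity:
    def test_identical_scenarios_leave_rates_untouched(self):
        q = np.array([0.01, 0.02])
        w = np.array([0.05, 0.06])
        m = np.array([0.004, 0.005])
        pi = np.array([0.1, 0.2])
        q2, w2, clips = recompute_mortality_morbidity(q, w, [(m, m, pi, pi, 0.1)])
        np.testing.assert_array_equal(q2, q)
        np.testing.assert_array_equal(w2, w)
        assert clips == 0

    def test_halved_disease_mortality_transfers_exactly(self):
        q = np.array([0.02])
        w = np.array([0.05])
        m_bau = np.array([0.008])
        m_int = np.array([0.004])
        pi = np.array([0.1])
        q2, _, _ = recompute_mortality_morbidity(q, w, [(m_bau, m_int, pi, pi, 0.1)])
        assert q2[0] == pytest.approx(0.02 - 0.004, abs=1e-15)

    def test_clipping_is_counted(self):
        q = np.array([0.001])
        w = np.array([0.05])
        m_bau = np.array([0.01])
        m_int = np.array([0.0])
        pi = np.array([0.1])
        q2, _, clips = recompute_mortality_morbidity(q, w, [(m_bau, m_int, pi, pi, 0.0)])
        assert clips == 1
        assert q2[0] == 0.0


class TestSimulateStratum:
    def make_pop(self, n=5, q=0.01):
        return StratumPopulation(
            "female", "other", counts=np.full(n, 100.0), mortality=np.full(n, q),
            pyld=np.full(n, 0.05),
        )

    def test_cohorts_extinct_at_terminal_age(self):
        pop = self.make_pop()
        run = simulate_stratum(pop, [toy_rates(n=5)])
        assert np.all(run.survivors[:, -1] == 0.0)
        # cohort with baseline age n-1 dies within its first cycle
        assert run.survivors[-1, 1] == 0.0

    def test_null_pif_reproduces_bau_exactly(self):
        pop = self.make_pop()
        rates = [toy_rates(n=5, f=0.05)]
        bau = simulate_stratum(pop, rates)
        itv = simulate_stratum(
            pop, rates, pif_eff={"toy": np.zeros((5, 5))}, bau=bau
        )
        np.testing.assert_array_equal(itv.qalys, bau.qalys)
        np.testing.assert_array_equal(itv.life_years, bau.life_years)
        assert itv.clip_events == 0

    def test_protective_pif_increases_qalys(self):
        pop = self.make_pop()
        rates = [toy_rates(n=5, f=0.2, dw=0.3)]
        bau = simulate_stratum(pop, rates)
        itv = simulate_stratum(
            pop, rates, pif_eff={"toy": np.full((5, 5), 0.5)}, bau=bau
        )
        assert itv.qalys.sum() > bau.qalys.sum()

    def test_period_prevalence_feeds_initialisation(self):
        rates = toy_rates(i=0.05, f=0.02, r=0.0, n=10)
        pi = period_prevalence(rates)
        assert pi[0] == 0.0
        assert np.all(np.diff(pi) >= -1e-12)  # accumulates with age here


class TestBauInvariance:
    def test_bau_identical_across_intervention_settings(self, bundle):
        from pamslt import InterventionSpec

        out_a = bundle.run_model(InterventionSpec())
        out_b = bundle.run_model(InterventionSpec(effect_met_min=500.0))
        for key in out_a.bau:
            np.testing.assert_array_equal(
                out_a.bau[key].qalys, out_b.bau[key].qalys
            )

    def test_no_clipping_in_default_run(self, bundle):
        from pamslt import InterventionSpec

        out = bundle.run_model(InterventionSpec())
        assert out.clip_events == 0
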