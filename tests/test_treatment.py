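"""MOUD assignment, retention milestones, and treatment-state mechanics."""

import numpy as np
import pytest
from scipy import stats

from opioidsim import (ConfigError, Modality, ModelParams, PopulationParams,
                       TreatmentEpisode, UseState, annual_to_daily_prob,
                       assign_moud, cessation_hazard, end_treatment,
                       init_population, on_treatment_overdose_rate,
                       rate_to_daily_prob, seek_treatment)
from opioidsim.params import TreatmentParams
from opioidsim.population import AgentState
from opioidsim.treatment import cessation_hazard_array


def survival_at(modality, day, params=None):
    """Brute-force survival under the daily piecewise hazard."""
    s = 1.0
    for d in range(day):
        s *= 1.0 - cessation_hazard(modality, d, params)
    return s


class TestSeeking:
    def test_daily_probability(self):
        assert annual_to_daily_prob(0.25) == pytest.approx(
            1.0 - 0.75 ** (1.0 / 365.0), rel=1e-12)

    def test_ineligible_states_never_seek(self, rng):
        for state in (UseState.OPIOID_NAIVE, UseState.PRESCRIBED_PO,
                      UseState.IN_TREATMENT):
            agent = AgentState(agent_id=0, use_state=state)
            assert not any(seek_treatment(agent, TreatmentParams(), rng)
                           for _ in range(50))

    def test_empirical_annual_seeking_fraction(self, rng):
        p = annual_to_daily_prob(0.25)
        frac = (rng.random((3_000, 365)) < p).any(axis=1).mean()
        se = np.sqrt(0.25 * 0.75 / 3_000)
        assert abs(frac - 0.25) < 4 * se


class TestModalityAssignment:
    def test_split_frequencies(self, rng):
        draws = [assign_moud(TreatmentParams(), rng) for _ in range(10_000)]
        counts = np.bincount([int(d) for d in draws], minlength=3)[:3]
        # chi-square goodness of fit against (0.59, 0.38, 0.03)
        gof = stats.chisquare(counts, f_exp=np.array([0.59, 0.38, 0.03]) * 10_000)
        assert gof.pvalue > 0.01
        assert abs(counts[0] - 5_900) < 4 * np.sqrt(10_000 * 0.59 * 0.41)

    def test_degenerate_probs(self, rng):
        params = TreatmentParams(modality_probs=(1.0, 0.0, 0.0))
        assert all(assign_moud(params, rng) == Modality.METHADONE
                   for _ in range(20))

    def test_probs_must_sum_to_one(self, rng):
        with pytest.raises(ConfigError):
            assign_moud(TreatmentParams(modality_probs=(0.6, 0.38, 0.03)), rng)


class TestCessationMilestones:
    def test_buprenorphine_milestones_exact(self):
        # cumulative cessation 0.31 by day 30 and 0.735 by day 365
        assert 1 - survival_at(Modality.BUPRENORPHINE, 30) == \
            pytest.approx(0.31, abs=1e-9)
        assert 1 - survival_at(Modality.BUPRENORPHINE, 365) == \
            pytest.approx(0.735, abs=1e-9)

    def test_naltrexone_milestones_exact(self):
        assert 1 - survival_at(Modality.NALTREXONE, 30) == \
            pytest.approx(0.52, abs=1e-9)
        assert 1 - survival_at(Modality.NALTREXONE, 365) == \
            pytest.approx(0.95, abs=1e-9)

    def test_methadone_one_year_milestone(self):
        assert 1 - survival_at(Modality.METHADONE, 365) == \
            pytest.approx(0.55, abs=1e-9)

    def test_zero_milestones_mean_nobody_ceases(self):
        params = TreatmentParams(cess_methadone_1y=0.0, cess_bupe_1m=0.0,
                                 cess_bupe_1y=0.0)
        assert cessation_hazard(Modality.METHADONE, 10, params) == 0.0
        assert cessation_hazard(Modality.BUPRENORPHINE, 10, params) == 0.0

    def test_out_of_order_milestones_rejected(self):
        with pytest.raises(ConfigError):
            TreatmentParams(cess_bupe_1m=0.8, cess_bupe_1y=0.3).validate()

    def test_simulated_kaplan_meier_matches_milestones(self, rng):
        # 4,000 simulated buprenorphine episodes vs the analytic milestones
        n = 4_000
        mod = np.full(n, Modality.BUPRENORPHINE, dtype=np.int8)
        still = np.ones(n, dtype=bool)
        ceased_by_30 = ceased_by_365 = 0
        for day in range(365):
            h = cessation_hazard_array(mod, np.full(n, day), TreatmentParams())
            cease = still & (rng.random(n) < h)
            still &= ~cease
            if day == 29:
                ceased_by_30 = n - still.sum()
        ceased_by_365 = n - still.sum()
        assert abs(ceased_by_30 / n - 0.31) < 4 * np.sqrt(0.31 * 0.69 / n)
        assert abs(ceased_by_365 / n - 0.735) < 4 * np.sqrt(0.735 * 0.265 / n)

    def test_scalar_and_array_hazards_agree(self):
        for mod in (Modality.METHADONE, Modality.BUPRENORPHINE,
                    Modality.NALTREXONE):
            for day in (0, 29, 30, 200, 400):
                arr = cessation_hazard_array(np.array([mod], dtype=np.int8),
                                             np.array([day]),
                                             TreatmentParams())
                assert cessation_hazard(mod, day) == pytest.approx(
                    float(arr[0]), rel=1e-12)


class TestOnTreatmentRisk:
    def test_modality_rates(self):
        assert on_treatment_overdose_rate(
            TreatmentEpisode(Modality.BUPRENORPHINE, 0, 100)) == 2.08
        assert on_treatment_overdose_rate(
            TreatmentEpisode(Modality.METHADONE, 0, 10)) == 2.0

    def test_naltrexone_window(self):
        recent = TreatmentEpisode(Modality.NALTREXONE, 0, 10)
        late = TreatmentEpisode(Modality.NALTREXONE, 0, 45)
        assert on_treatment_overdose_rate(recent) == 3.85
        assert on_treatment_overdose_rate(late) is None  # window lapsed

    def test_zero_rate_gives_zero_daily_probability(self):
        params = TreatmentParams(od_rate_bupe=0.0)
        rate = on_treatment_overdose_rate(
            TreatmentEpisode(Modality.BUPRENORPHINE, 0, 5), params)
        assert rate_to_daily_prob(rate) == 0.0


class TestEndTreatment:
    def _pop_with_episode(self, prev_state):
        pop = init_population(PopulationParams(
            n_agents=5, chronic_pain_prevalence=0.0,
            initial_oud_prevalence=0.0,
            initial_in_treatment_statewide=0.0), seed=0)
        pop.use_state[0] = UseState.IN_TREATMENT
        pop.prev_state[0] = prev_state
        pop.modality[0] = Modality.BUPRENORPHINE
        pop.tx_days[0] = 40
        pop.tolerance[0] = 80.0
        return pop

    def test_returns_to_most_recent_active_state(self):
        pop = self._pop_with_episode(UseState.HEROIN_FENTANYL)
        end_treatment(pop, 0)
        assert pop.use_state[0] == UseState.HEROIN_FENTANYL

    def test_zero_tolerance_decay_restores_internal_state(self):
        pop = self._pop_with_episode(UseState.DEPENDENT_PO)
        end_treatment(pop, 0, TreatmentParams(tolerance_decay_daily=0.0))
        assert pop.tolerance[0] == 80.0

    def test_without_episode_rejected(self):
        pop = init_population(PopulationParams(
            n_agents=2, chronic_pain_prevalence=0.0,
            initial_oud_prevalence=0.0,
            initial_in_treatment_statewide=0.0), seed=0)
        with pytest.raises(RuntimeError):
            end_treatment(pop, 0)
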