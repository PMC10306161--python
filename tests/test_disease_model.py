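"""Markov disease model: probability conversions, matrix, cohort traces."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ngsbia import (
    STATES,
    STATE_INDEX,
    annual_prob_to_cycle,
    build_transition_matrix,
    competing_split,
    default_parameters,
    pathway_distribution,
    pct_on_targeted,
    period_event_to_cycle,
    run_cohorts,
)
from ngsbia.microsim import random_parameter_set

CYCLES_PER_YEAR = 365.25 / 30.0


class TestAnnualProbToCycle:
    def test_certain_survival_means_no_events(self):
        assert annual_prob_to_cycle(1.0) == 0.0

    def test_chemo_overall_survival(self):
        # oracle: compounding the per-cycle survival over a year recovers OS
        p = annual_prob_to_cycle(0.494)
        assert p == pytest.approx(0.056277, abs=1e-6)
        assert (1.0 - p) ** CYCLES_PER_YEAR == pytest.approx(0.494, abs=1e-12)

    def test_targeted_overall_survival(self):
        p = annual_prob_to_cycle(0.86)
        assert p == pytest.approx(0.012311, abs=1e-6)
        assert (1.0 - p) ** CYCLES_PER_YEAR == pytest.approx(0.86, abs=1e-12)

    def test_zero_survival_rejected(self):
        with pytest.raises(ValueError):
            annual_prob_to_cycle(0.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.01, max_value=1.0))
    def test_compounding_recovers_annual_probability(self, survival):
        p = annual_prob_to_cycle(survival)
        assert (1.0 - p) ** CYCLES_PER_YEAR == pytest.approx(survival, rel=1e-9)


class TestCompetingSplit:
    def test_pfs_equal_os_means_no_progression(self):
        p_prog, p_death = competing_split(0.5, 0.5)
        assert p_prog == 0.0
        assert p_death == pytest.approx(annual_prob_to_cycle(0.5))

    def test_targeted_split(self):
        p_prog, p_death = competing_split(0.40, 0.86)
        assert p_death == pytest.approx(0.012311, abs=1e-6)
        assert p_prog == pytest.approx(0.060186, abs=1e-6)

    def test_chemo_split(self):
        p_prog, p_death = competing_split(0.173, 0.494)
        assert p_death == pytest.approx(0.056277, abs=1e-6)
        # per-cycle PFS-event probability 0.134204 minus the death probability
        assert p_prog == pytest.approx(0.134204 - 0.056277, abs=1e-5)

    def test_pfs_above_os_rejected(self):
        with pytest.raises(Exception):
            competing_split(0.6, 0.5)


class TestTransitionMatrix:
    def test_rows_stochastic_and_dead_absorbing(self, base):
        M = build_transition_matrix(base)
        assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert (M >= 0).all()
        dead = STATE_INDEX["dead"]
        assert M[dead, dead] == 1.0

    def test_no_events_gives_identity_outside_interim(self, base):
        for therapy in base.clinical.os_1yr:
            base.clinical.os_1yr[therapy] = 1.0
            base.clinical.pfs_1yr[therapy] = 1.0
        base.clinical.p_prog_to_nextline_3mo = 0.0
        base.clinical.p_nextline_to_prog_3mo = 0.0
        base.uncertainty = {}
        M = build_transition_matrix(base)
        interim = STATE_INDEX["interim"]
        for i, state in enumerate(STATES):
            if i == interim:
                continue
            assert M[i, i] == pytest.approx(1.0), state
        # interim is a one-cycle bridge: survivors always leave
        assert M[interim, interim] == 0.0

    def test_progression_to_next_line_conversion(self, base):
        # 1 - (1 - 0.48)^(30 / 91.3125), 3 months = a quarter year
        M = build_transition_matrix(base)
        pd_post = annual_prob_to_cycle(0.494)
        expected = (1.0 - pd_post) * period_event_to_cycle(0.48, 365.25 / 4.0)
        assert period_event_to_cycle(0.48, 365.25 / 4.0) == pytest.approx(
            0.193331, abs=1e-6
        )
        assert M[STATE_INDEX["progression"], STATE_INDEX["next_line"]] == pytest.approx(
            expected
        )

    def test_interim_splits_survivors_34_66(self, base):
        for therapy in base.clinical.os_1yr:
            base.clinical.os_1yr[therapy] = 1.0  # no deaths
            base.clinical.pfs_1yr[therapy] = min(
                base.clinical.pfs_1yr[therapy], 1.0
            )
        base.uncertainty = {}
        M = build_transition_matrix(base)
        i = STATE_INDEX["interim"]
        assert M[i, STATE_INDEX["targeted"]] == pytest.approx(0.34)
        assert M[i, STATE_INDEX["progression"]] == pytest.approx(0.66)


class TestRunCohorts:
    def test_total_entering_patients(self, base):
        alloc = pathway_distribution(base, base.scenario_current)
        trace = run_cohorts(base, base.scenario_current, alloc)
        assert trace.total_entered == 2500
        assert trace.n_cohorts == 5
        assert list(trace.entry_cycles) == [0, 13, 25, 37, 49]
        assert trace.n_cycles == 61

    def test_occupancy_constant_without_events(self, base):
        for therapy in base.clinical.os_1yr:
            base.clinical.os_1yr[therapy] = 1.0
            base.clinical.pfs_1yr[therapy] = 1.0
        base.clinical.p_prog_to_nextline_3mo = 0.0
        base.splits.p_interim = 0.0
        base.splits.p_direct_targeted = 1.0
        base.scenario_current.horizon_years = 1
        base.scenario_proposed.horizon_years = 1
        base.uncertainty = {}
        alloc = pathway_distribution(base, base.scenario_current)
        trace = run_cohorts(base, base.scenario_current, alloc)
        for t in range(trace.n_cycles + 1):
            assert np.allclose(trace.occupancy[0, t], trace.occupancy[0, 0])

    def test_pure_death_geometric_decay(self, base):
        import ngsbia.disease_model as dm

        alloc = pathway_distribution(base, base.scenario_current)
        trace = run_cohorts(base, base.scenario_current, alloc)
        # overwrite with a synthetic pure-death chain at p = 0.5 per cycle
        M = np.zeros((8, 8))
        for i in range(8):
            M[i, STATE_INDEX["dead"]] = 0.5
            M[i, i] += 0.5
        M[STATE_INDEX["dead"], STATE_INDEX["dead"]] = 1.0
        occ = trace.occupancy[0, 0].copy()
        alive0 = occ.sum() - occ[STATE_INDEX["dead"]]
        for k in range(1, 6):
            occ = occ @ M
            alive = occ.sum() - occ[STATE_INDEX["dead"]]
            assert alive == pytest.approx(alive0 * 0.5**k)

    def test_conservation_and_dead_monotonicity(self):
        dead = STATE_INDEX["dead"]
        for seed in range(200):
            p = random_parameter_set(seed)
            for scenario in (p.scenario_current, p.scenario_proposed):
                alloc = pathway_distribution(p, scenario)
                trace = run_cohorts(p, scenario, alloc)
                size = scenario.patients_per_year
                for c in range(trace.n_cohorts):
                    t0 = trace.entry_cycles[c]
                    sums = trace.occupancy[c, t0:].sum(axis=1)
                    expected = size - trace.lost_per_cohort[c]
                    assert np.allclose(sums, expected, atol=1e-6), seed
                    deaths = trace.occupancy[c, t0:, dead]
                    assert (np.diff(deaths) >= -1e-12).all(), seed

    def test_targeted_cohort_outlives_chemo_cohort(self, base):
        from ngsbia.testing_pathway import PathwayAllocation

        def single_therapy_alloc(state):
            kwargs = dict(
                mass_targeted_direct=0.0,
                mass_interim=0.0,
                mass_chemo=0.0,
                mass_immuno=0.0,
                mass_chemoimmuno=0.0,
                mass_lost_second_opinion=0.0,
                tests_inhouse=0.0,
                tests_sendout=1.0,
                tests_singlegene=0.0,
                mean_tat=19.06,
            )
            kwargs[f"mass_{state}"] = 1.0
            return PathwayAllocation(**kwargs)

        targeted = run_cohorts(
            base, base.scenario_current, single_therapy_alloc("targeted_direct")
        )
        chemo = run_cohorts(base, base.scenario_current, single_therapy_alloc("chemo"))
        end = targeted.n_cycles
        assert targeted.alive(end) > chemo.alive(end)


class TestPctOnTargeted:
    def test_empty_targeted_state_is_zero(self, base):
        base.testing.p_actionable_tissue = 0.0
        base.testing.p_actionable_blood = 0.0
        base.uncertainty = {}
        alloc = pathway_distribution(base, base.scenario_current)
        trace = run_cohorts(base, base.scenario_current, alloc)
        assert pct_on_targeted(trace) == 0.0
        assert pct_on_targeted(trace, denominator="entered") == 0.0

    def test_cycle_beyond_horizon_rejected(self, base):
        alloc = pathway_distribution(base, base.scenario_current)
        trace = run_cohorts(base, base.scenario_current, alloc)
        with pytest.raises(IndexError):
            pct_on_targeted(trace, at=trace.n_cycles + 1)
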