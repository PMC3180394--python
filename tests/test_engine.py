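import dataclasses

import numpy as np
import pytest

from cgmcea.engine import (
    Arm,
    ArmResult,
    Dominance,
    CEResult,
    build_transition_matrix,
    build_transition_matrices,
    compare_arms,
    discount_factor,
    net_monetary_benefit,
    run_cohort,
    state_annual_cost,
    state_utility,
)
from cgmcea.parameters import build_parameters
from cgmcea.states import State


@pytest.mark.parametrize(
    "rate,t,expected",
    [(0.03, 0, 1.0), (0.03, 1, 0.970874), (0.03, 33, 0.377026), (0.0, 10, 1.0)],
)
def test_discount_factor_closed_form(rate, t, expected):
    assert discount_factor(rate, t) == pytest.approx(expected, abs=5e-7)


def test_discount_factor_rejects_negative_inputs():
    with pytest.raises(ValueError):
        discount_factor(-0.01, 1)
    with pytest.raises(ValueError):
        discount_factor(0.03, -1)


class TestTransitionMatrix:
    def test_smbg_no_complications_row_matches_published_exits(self, params, schedule):
        M = build_transition_matrix(params, Arm.SMBG, 40, schedule)
        row = M[State.NO_COMPLICATIONS]
        assert row[State.RETINOPATHY] == pytest.approx(0.011)
        assert row[State.NEPHROPATHY] == pytest.approx(0.072)
        assert row[State.NEUROPATHY] == pytest.approx(0.035)
        assert row[State.CHD] == pytest.approx(0.031)
        death = row[State.DEATH]
        assert row[State.NO_COMPLICATIONS] == pytest.approx(1 - 0.149 - death)

    def test_cgm_retinopathy_entry_scaled_by_risk_reduction(self, params, schedule):
        M = build_transition_matrix(params, Arm.CGM, 40, schedule)
        assert M[State.NO_COMPLICATIONS, State.RETINOPATHY] == pytest.approx(
            0.011 * (1 - 0.306)
        )
        assert M[State.NO_COMPLICATIONS, State.RETINOPATHY] == pytest.approx(
            0.0076340, abs=5e-8
        )

    def test_zero_risk_reductions_make_arms_identical(self, schedule):
        params = build_parameters(
            rrr_retinopathy=0.0, rrr_nephropathy=0.0, rrr_neuropathy=0.0, rrr_chd=0.0
        )
        ages = np.arange(40, 73)
        smbg = build_transition_matrices(params, Arm.SMBG, ages, schedule)
        cgm = build_transition_matrices(params, Arm.CGM, ages, schedule)
        np.testing.assert_array_equal(smbg, cgm)

    def test_rows_sum_to_one_for_all_ages_and_arms(self, params, schedule):
        ages = np.arange(40, 73)
        for arm in Arm:
            M = build_transition_matrices(params, arm, ages, schedule)
            np.testing.assert_allclose(M.sum(axis=2), 1.0, atol=1e-12, rtol=0)

    def test_chd_back_transitions_reuse_microvascular_values(self, params, schedule):
        M = build_transition_matrix(params, Arm.SMBG, 50, schedule)
        assert M[State.CHD, State.RETINOPATHY_CHD] == pytest.approx(0.028)
        assert M[State.CHD, State.NEPHROPATHY_CHD] == pytest.approx(0.022)
        assert M[State.CHD, State.NEUROPATHY_CHD] == pytest.approx(0.029)

    def test_death_column_is_baseline_times_multiplier(self, params, flat_schedule):
        M = build_transition_matrix(params, Arm.SMBG, 60, flat_schedule)
        np.testing.assert_allclose(M[:12, State.DEATH], 0.01)
        assert M[State.DEATH, State.DEATH] == 1.0


class TestStateCost:
    def test_no_complications_cost_is_the_base_annual_cost(self, params):
        assert state_annual_cost(State.NO_COMPLICATIONS, params, Arm.SMBG) == 6705

    def test_composite_cost_is_sum_of_component_marginals(self, params):
        assert state_annual_cost(State.NEPHROPATHY_CHD, params, Arm.SMBG) == pytest.approx(
            6705 + 20161 + 35271
        )
        assert state_annual_cost(State.NEUROPATHY_CHD, params, Arm.SMBG) == pytest.approx(
            6705 + 25075 + 35271
        )
        assert state_annual_cost(State.RETINOPATHY_CHD, params, Arm.SMBG) == pytest.approx(
            6705 + 4956 + 35271
        )
        assert state_annual_cost(
            State.NEUROPATHY_NEPHROPATHY, params, Arm.SMBG
        ) == pytest.approx(6705 + 25075 + 20161)

    def test_blindness_esrd_lea_carry_single_marginals(self, params):
        assert state_annual_cost(State.BLINDNESS, params, Arm.SMBG) == 6705 + 9912
        assert state_annual_cost(State.ESRD, params, Arm.SMBG) == 6705 + 36370
        assert state_annual_cost(State.LEA, params, Arm.SMBG) == 6705 + 50150

    def test_cgm_annual_cost_added_after_cycle_zero_only(self, params):
        assert state_annual_cost(State.NO_COMPLICATIONS, params, Arm.CGM, cycle=1) == pytest.approx(
            6705 + 4189
        )
        assert state_annual_cost(State.NO_COMPLICATIONS, params, Arm.CGM, cycle=0) == 6705

    def test_death_state_rejected(self, params):
        with pytest.raises(ValueError):
            state_annual_cost(State.DEATH, params, Arm.SMBG)


class TestStateUtility:
    def test_tabulated_utility_at_start_age(self, params):
        assert state_utility(State.NO_COMPLICATIONS, params, 40) == pytest.approx(0.757)

    def test_linear_age_deduction(self, params):
        assert state_utility(State.NO_COMPLICATIONS, params, 50) == pytest.approx(
            0.757 - 10 * 0.0003
        )

    def test_zero_disutility_leaves_utility_unchanged(self):
        params = build_parameters(du_age=0.0)
        for s in (State.CHD, State.ESRD, State.RETINOPATHY):
            assert state_utility(s, params, 70) == params.utilities[s]

    def test_floored_at_zero(self, params):
        p = dataclasses.replace(params, age_disutility_per_year=-0.1)
        assert state_utility(State.ESRD, p, 90) == 0.0


class TestRunCohort:
    def test_cohort_starts_entirely_without_complications(self, params, schedule):
        res = run_cohort(params, Arm.SMBG, schedule)
        assert res.trace.occupancy[0, State.NO_COMPLICATIONS] == 1.0
        assert res.trace.occupancy.shape == (34, 13)

    def test_closed_form_qalys_without_mortality_or_progression(
        self, zero_mortality_schedule
    ):
        probs = {
            name: 0.0
            for name in (
                "p_nocomp_retinopathy", "p_nocomp_nephropathy", "p_nocomp_neuropathy",
                "p_nocomp_chd", "p_retinopathy_blindness", "p_retinopathy_chd",
                "p_nephropathy_esrd", "p_nephropathy_chd", "p_neuropathy_lea",
                "p_neuropathy_nephropathy", "p_neuropathy_chd",
            )
        }
        params = build_parameters(probs, du_age=0.0, discount_rate=0.0)
        res = run_cohort(params, Arm.SMBG, zero_mortality_schedule)
        assert res.discounted_qalys == pytest.approx(33 * 0.757)
        assert res.discounted_qalys == pytest.approx(24.981)
        assert res.discounted_cost == pytest.approx(33 * 6705)
        assert res.life_years == pytest.approx(33.0)

    def test_zero_horizon_accrues_only_the_cgm_initial_cost(self, schedule):
        params = build_parameters(horizon=0)
        smbg = run_cohort(params, Arm.SMBG, schedule)
        cgm = run_cohort(params, Arm.CGM, schedule)
        assert smbg.discounted_cost == smbg.discounted_qalys == 0.0
        assert cgm.discounted_cost == pytest.approx(4809)
        assert cgm.discounted_qalys == 0.0

    def test_negative_horizon_rejected(self, schedule):
        with pytest.raises(ValueError):
            run_cohort(build_parameters(horizon=-1), Arm.SMBG, schedule)

    def test_trace_matches_stepwise_matrix_products(self, params, schedule):
        res = run_cohort(params, Arm.CGM, schedule)
        occ = np.zeros(13)
        occ[State.NO_COMPLICATIONS] = 1.0
        for t in range(1, 34):
            M = build_transition_matrix(params, Arm.CGM, 40 + t - 1, schedule)
            occ = occ @ M
            np.testing.assert_allclose(res.trace.occupancy[t], occ, atol=1e-14)

    def test_discounted_totals_never_exceed_undiscounted(self, params, schedule):
        for arm in Arm:
            res = run_cohort(params, arm, schedule)
            assert res.discounted_cost <= res.undiscounted_cost
            assert res.discounted_qalys <= res.undiscounted_qalys


def _arm_result(arm, cost, qalys):
    from cgmcea.engine import CohortTrace

    trace = CohortTrace(np.zeros((1, 13)))
    return ArmResult(arm, cost, qalys, cost, qalys, 0.0, trace)


class TestCompareArms:
    def test_published_incrementals_reproduce_published_icer(self):
        smbg = _arm_result(Arm.SMBG, 470_583.0, 10.289)
        cgm = _arm_result(Arm.CGM, 470_583.0 + 23_552.0, 10.289 + 0.523)
        ce = compare_arms(smbg, cgm)
        assert ce.icer == pytest.approx(45_033, abs=1.0)
        assert ce.dominance is Dominance.NONE

    def test_cheaper_and_more_effective_is_dominant(self):
        ce = compare_arms(_arm_result(Arm.SMBG, 100.0, 1.0), _arm_result(Arm.CGM, 99.0, 1.1))
        assert ce.dominance is Dominance.INTERVENTION_DOMINANT
        assert ce.icer is None

    def test_costlier_and_less_effective_is_dominated(self):
        ce = compare_arms(_arm_result(Arm.SMBG, 100.0, 1.0), _arm_result(Arm.CGM, 101.0, 0.9))
        assert ce.dominance is Dominance.INTERVENTION_DOMINATED

    def test_identical_arms_yield_no_dominance_and_undefined_icer(self):
        a = _arm_result(Arm.SMBG, 100.0, 1.0)
        b = _arm_result(Arm.CGM, 100.0, 1.0)
        ce = compare_arms(a, b)
        assert ce.delta_cost == ce.delta_effect == 0.0
        assert ce.icer is None
        assert ce.dominance is Dominance.NONE

    def test_equal_effect_different_cost_reports_dominance_by_cost(self):
        ce = compare_arms(_arm_result(Arm.SMBG, 100.0, 1.0), _arm_result(Arm.CGM, 150.0, 1.0))
        assert ce.icer is None
        assert ce.dominance is Dominance.INTERVENTION_DOMINATED


@pytest.mark.parametrize(
    "wtp,expected",
    [(50_000.0, 50_000 * 0.523 - 23_552), (0.0, -23_552.0), (100_000.0, 100_000 * 0.523 - 23_552)],
)
def test_net_monetary_benefit(wtp, expected):
    ce = CEResult(23_552.0, 0.523, 23_552.0 / 0.523, Dominance.NONE)
    assert net_monetary_benefit(wtp, ce) == pytest.approx(expected)
    # spot-check the arithmetic the definition implies
    assert net_monetary_benefit(50_000.0, ce) == pytest.approx(2_598.0, abs=1.0)
    assert net_monetary_benefit(100_000.0, ce) == pytest.approx(28_748.0, abs=1.0)
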