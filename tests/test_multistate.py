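"""Cohort recursion: conservation, closed forms, reactivation identity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from migraine_states.multistate import (CohortState, StepSizeError,
                                        TransitionRates, UndefinedRateError,
                                        initialize_cohort, markov_step,
                                        prevalence_curves,
                                        reactivation_from_gbd, run_cohort)


class TestReactivation:

    def test_uniform_incidence_across_pool(self):
        out = reactivation_from_gbd(0.01, 0.01, S0=80, Ci=20)
        assert out.rate == pytest.approx(0.01)
        assert not out.fallback and not out.clamped

    def test_balance_identity_arithmetic(self):
        out = reactivation_from_gbd(0.02, 0.01, S0=70, Ci=30)
        assert out.rate == pytest.approx((0.02 * 100 - 0.01 * 70) / 30)

    def test_empty_pool_falls_back_to_gbd_incidence(self):
        out = reactivation_from_gbd(0.015, 0.015, S0=100, Ci=0.0)
        assert out.rate == 0.015
        assert out.fallback

    def test_negative_solution_clamped(self):
        out = reactivation_from_gbd(0.001, 0.05, S0=99, Ci=1)
        assert out.rate == 0.0
        assert out.clamped

    def test_zero_pool_undefined(self):
        with pytest.raises(UndefinedRateError):
            reactivation_from_gbd(0.01, 0.01, S0=0.0, Ci=0.0)


class TestMarkovStep:

    def test_zero_rates_only_age_advances(self):
        state = CohortState(30.0, 900.0, 80.0, 20.0)
        nxt = markov_step(state, TransitionRates.constant(), h=0.5)
        assert (nxt.S0, nxt.Ca, nxt.Ci) == (900.0, 80.0, 20.0)
        assert nxt.age == 30.5

    def test_hand_computed_euler_update(self):
        state = CohortState(30.0, 900.0, 80.0, 20.0)
        rates = TransitionRates.constant(i0=0.01, r=0.05, f=0.02)
        nxt = markov_step(state, rates, h=0.01)
        assert nxt.S0 == pytest.approx(899.91)
        assert nxt.Ca == pytest.approx(80.054)
        assert nxt.Ci == pytest.approx(20.036)
        assert nxt.S0 + nxt.Ca + nxt.Ci == pytest.approx(1000.0, abs=1e-9)

    def test_overshooting_step_rejected(self):
        state = CohortState(30.0, 0.0, 100.0, 0.0)
        with pytest.raises(StepSizeError):
            markov_step(state, TransitionRates.constant(r=0.05), h=30.0)

    @given(S0=st.floats(0, 1e5), Ca=st.floats(0, 1e5), Ci=st.floats(0, 1e5),
           i0=st.floats(0, 0.5), r=st.floats(0, 0.5), f=st.floats(0, 0.5))
    @settings(derandomize=True, max_examples=60)
    def test_single_step_conserves_total(self, S0, Ca, Ci, i0, r, f):
        state = CohortState(40.0, S0, Ca, Ci)
        nxt = markov_step(state, TransitionRates.constant(i0, r, f), h=0.01)
        assert nxt.S0 + nxt.Ca + nxt.Ci == pytest.approx(S0 + Ca + Ci,
                                                         abs=1e-6, rel=1e-12)


class TestRunCohort:

    def test_zero_rates_leave_cohort_in_place(self):
        init = CohortState(30.0, 100_000.0, 0.0, 0.0)
        traj = run_cohort(init, TransitionRates.constant(), 30.0, 0.01)
        assert traj.S0[-1] == 100_000.0
        assert traj.Ca[-1] == 0.0

    def test_trajectory_length_and_age_grid(self):
        init = CohortState(30.0, 1000.0, 0.0, 0.0)
        traj = run_cohort(init, TransitionRates.constant(), 30.0, 0.01)
        assert len(traj) == 3001
        assert traj.ages[0] == 30.0
        assert traj.ages[-1] == pytest.approx(60.0, abs=1e-9)

    def test_non_integral_step_count_rejected(self):
        init = CohortState(30.0, 1000.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            run_cohort(init, TransitionRates.constant(), 30.0, 0.007)

    def test_pure_decay_matches_exponential(self):
        """Only remission active: Ca(30y)/N ~ exp(-0.05*30) within 0.5%."""
        init = CohortState(30.0, 0.0, 100_000.0, 0.0)
        traj = run_cohort(init, TransitionRates.constant(r=0.05), 30.0, 0.01)
        assert traj.Ca[-1] / 100_000.0 == pytest.approx(np.exp(-1.5),
                                                        rel=0.005)

    def test_onset_only_matches_survival(self):
        init = CohortState(30.0, 100_000.0, 0.0, 0.0)
        traj = run_cohort(init, TransitionRates.constant(i0=0.02), 20.0, 0.01)
        assert traj.S0[-1] / 100_000.0 == pytest.approx(np.exp(-0.4),
                                                        rel=0.005)

    def test_conservation_and_monotone_never_state(self):
        init = CohortState(30.0, 90_000.0, 8_000.0, 2_000.0)
        rates = TransitionRates.constant(i0=0.01, r=0.05, f=0.02)
        traj = run_cohort(init, rates, 30.0, 0.01)
        totals = traj.S0 + traj.Ca + traj.Ci
        assert np.max(np.abs(totals - 100_000.0)) < 1e-6
        assert (np.diff(traj.S0) <= 0).all()

    def test_halving_step_barely_moves_end_prevalences(self):
        init = CohortState(30.0, 90_000.0, 8_000.0, 2_000.0)
        rates = TransitionRates.constant(i0=0.01, r=0.05, f=0.02)
        end = {}
        for h in (0.01, 0.005):
            traj = run_cohort(init, rates, 30.0, h)
            end[h] = np.array([traj.S0[-1], traj.Ca[-1], traj.Ci[-1]])
        rel = np.abs(end[0.01] - end[0.005]) / end[0.005]
        assert rel.max() < 1e-3

    def test_state_dependent_reactivation_closure(self):
        """f(age, S0, Ci) closures drive inflow consistent with i_gbd."""
        rates = TransitionRates.with_gbd_reactivation(
            i0=lambda a: 0.01, r=lambda a: 0.0, i_gbd=lambda a: 0.01)
        init = CohortState(30.0, 90_000.0, 8_000.0, 2_000.0)
        traj = run_cohort(init, rates, 10.0, 0.01)
        # uniform incidence, no remission inflow: the no-active pool decays
        pool = traj.S0 + traj.Ci
        assert pool[-1] == pytest.approx(pool[0] * np.exp(-0.01 * 10),
                                         rel=0.02)


class TestPrevalenceCurves:

    def test_zero_rate_trajectory_is_all_never(self):
        init = CohortState(30.0, 1000.0, 0.0, 0.0)
        traj = run_cohort(init, TransitionRates.constant(), 5.0, 0.01)
        curves = prevalence_curves(traj)
        assert (curves["p0"] == 1.0).all()
        assert (curves["p_a"] == 0.0).all()

    def test_rows_sum_to_one(self):
        init = CohortState(30.0, 90_000.0, 8_000.0, 2_000.0)
        rates = TransitionRates.constant(i0=0.01, r=0.05, f=0.02)
        curves = prevalence_curves(run_cohort(init, rates, 30.0, 0.01))
        total = curves[["p0", "p_a", "p_i"]].sum(axis=1)
        assert np.max(np.abs(total - 1.0)) < 1e-12

    def test_pure_decay_complement(self):
        init = CohortState(30.0, 0.0, 100_000.0, 0.0)
        traj = run_cohort(init, TransitionRates.constant(r=0.05), 30.0, 0.01)
        curves = prevalence_curves(traj)
        assert curves["p_a"].iloc[-1] == pytest.approx(np.exp(-1.5), rel=0.005)
        assert curves["p_i"].iloc[-1] == pytest.approx(1 - np.exp(-1.5),
                                                       rel=0.005)
        assert curves["p0"].iloc[-1] == 0.0


class _Baseline:
    def __init__(self, p0):
        self._p0 = p0

    def p0(self, age, sex):
        return self._p0


class _Surface:
    def __init__(self, p):
        self._p = p

    def predict(self, age, year):
        return self._p


class TestInitializeCohort:

    def test_complement_split(self):
        state, flagged = initialize_cohort(_Baseline(0.78), _Surface(0.2),
                                           30.0, 1990.0, 100_000.0, "female")
        assert (state.S0, state.Ca, state.Ci) == (78_000.0, 20_000.0, 2_000.0)
        assert not flagged

    def test_inconsistent_inputs_floored_and_flagged(self):
        state, flagged = initialize_cohort(_Baseline(0.85), _Surface(0.2),
                                           30.0, 1990.0, 100_000.0, "female")
        assert flagged
        assert state.Ci == 0.0
        assert state.S0 == pytest.approx(80_000.0)
        assert state.N == pytest.approx(100_000.0)
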