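"""Metropolis dynamics, chaotic search, equilibrium detection, full runs."""
import math

import numpy as np
import pytest

from cmqa.chaos import ChaosState
from cmqa.engine import (
    EnergyBudget,
    EquilibriumWindow,
    SolutionState,
    chaotic_local_search,
    dep_converged,
    dep_intercept,
    dep_slope,
    metropolis_sweep,
    run,
    run_ap,
    run_cmqa,
    run_csa,
    run_mqa_dep,
    run_mqp,
)
from cmqa.landscapes import CallableLandscape
from cmqa.schedule import ScheduleParams, TemperatureRange, initial_temperature, tune_temperatures


def _state_at(angles, energy_fn):
    angles = np.asarray(angles, dtype=float)
    e = energy_fn(angles)
    return SolutionState(S_i=angles, E_i=e, S_min=angles.copy(), E_min=e)


class TestMetropolisSweep:
    def test_hot_limit_accepts_everything(self, planted4, rng):
        state = _state_at(planted4.random_conformation(rng), planted4.energy)
        metropolis_sweep(state, T=1e12, L=10_000, rng=rng, energy=planted4.energy)
        assert state.n_accept / state.n_propose > 0.999

    def test_cold_limit_rejects_all_uphill(self, planted4, rng):
        # start at the optimum of a trap-free landscape: every move is uphill
        state = _state_at(planted4.sigma_star, planted4.energy)
        metropolis_sweep(state, T=1e-12, L=5_000, rng=rng, energy=planted4.energy)
        assert state.n_accept == 0
        assert state.E_min == 0.0

    def test_acceptance_matches_boltzmann(self, rng):
        # every proposal deteriorates by exactly dZ relative to the current state
        dZ = 1.7
        state = _state_at([0.0], lambda a: 0.0)
        energy = lambda a: state.E_i + dZ  # noqa: E731
        T = initial_temperature(dZ, 0.9)
        metropolis_sweep(state, T=T, L=10_000, rng=rng, energy=energy)
        se = math.sqrt(0.9 * 0.1 / 10_000)
        assert abs(state.n_accept / state.n_propose - 0.9) < 3 * se

    def test_running_minimum_updates(self, planted4, rng):
        start = planted4.random_conformation(rng)
        state = _state_at(start, planted4.energy)
        e0 = state.E_i
        metropolis_sweep(state, T=1.0, L=2_000, rng=rng, energy=planted4.energy)
        assert state.E_min <= e0
        assert planted4.energy(state.S_min) == pytest.approx(state.E_min)


class TestChaoticLocalSearch:
    def test_zero_iterations_is_identity(self, rng):
        s = np.array([1.0, 2.0])
        out, e, _ = chaotic_local_search(
            s, 0, ChaosState(seed=0), rng, lambda a: 0.0, E_min=0.0
        )
        np.testing.assert_array_equal(out, s)
        assert e == 0.0

    def test_greedy_never_worsens_at_any_step(self, planted19, rng):
        start = planted19.random_conformation(rng)
        e0 = planted19.energy(start)
        log = []
        _, e_final, _ = chaotic_local_search(
            start, 100, ChaosState(seed=4), rng, planted19.energy,
            E_min=e0, step_log=log,
        )
        assert e_final <= e0
        assert all(b <= a for a, b in zip([e0] + log, log))

    def test_descends_convex_valley(self, rng):
        # replayed greedy chain on E = (sigma - 10)^2 from sigma = 100
        ls = CallableLandscape(1, lambda a: (a[0] - 10.0) ** 2)
        start = np.array([100.0])
        out, e_final, _ = chaotic_local_search(
            start, 200, ChaosState(amplitude=90.0, seed=6), rng, ls.energy,
            E_min=ls.energy(start),
        )
        assert e_final < ls.energy(start)
        assert e_final == pytest.approx(ls.energy(out))


class TestDepRegression:
    def test_constant_window(self):
        e = [4.2] * 10
        assert dep_slope(e) == pytest.approx(0.0, abs=1e-12)
        assert dep_intercept(e) == pytest.approx(4.2)

    def test_exact_line(self):
        x = np.arange(20.0)
        assert dep_slope(x) == pytest.approx(1.0, abs=1e-9)
        assert dep_intercept(2 * x + 5) == pytest.approx(5.0, abs=1e-9)
        assert dep_slope(2 * x + 5) == pytest.approx(2.0, abs=1e-9)

    def test_matches_general_least_squares(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 101))
            e = rng.normal(size=n) * rng.uniform(0.1, 100)
            slope_ref, intercept_ref = np.polyfit(np.arange(n), e, 1)
            assert abs(dep_slope(e) - slope_ref) < 1e-9
            assert abs(dep_intercept(e) - intercept_ref) < 1e-9

    def test_minimizes_residual_sum_of_squares(self, rng):
        e = rng.normal(size=30)
        x = np.arange(30.0)
        a, b = dep_slope(e), dep_intercept(e)
        rss = np.sum((e - (a * x + b)) ** 2)
        for _ in range(100):
            da, db = rng.normal(scale=0.05, size=2)
            assert rss <= np.sum((e - ((a + da) * x + (b + db))) ** 2) + 1e-12

    @pytest.mark.parametrize("n", [0, 1, 2])
    def test_short_windows_rejected(self, n):
        with pytest.raises(ValueError):
            dep_slope(np.zeros(n))

    def test_convergence_predicate(self):
        w = EquilibriumWindow(n=5, epsilon=0.5)
        for e in [3.0, 3.0, 3.0]:
            w.append(e)
        assert not dep_converged(w)  # under-filled: never errors, never fires
        for e in [3.0, 3.0]:
            w.append(e)
        assert dep_converged(w)
        ramp = EquilibriumWindow(n=5, epsilon=0.5)
        for e in range(5):
            ramp.append(float(e))
        assert not dep_converged(ramp)  # unit slope >= 0.5


class TestPhases:
    def test_mqp_cls_cadence_and_minimum(self, planted19, rng):
        params = ScheduleParams().validate()
        # explicit range deep enough for two full quenching subphases
        temps = TemperatureRange(T0=40.0, Tf=1e-5, T_threshold=3.2e-5, T_fa=2e-5)
        energy = EnergyBudget(planted19.energy)
        state, T, trace = run_mqp(
            planted19, params, temps, ChaosState(seed=9), rng, energy
        )
        assert T <= temps.T_threshold
        # tau squares below its cutoff on every 7th cycle
        assert trace.cls_cycles == [6, 13]
        assert state.E_min <= trace.energy[0]
        # quenching cools at least as fast as geometric, so it needs at most
        # the geometric cycle count to cross the threshold
        assert trace.n_cycles <= math.ceil(
            math.log(temps.T_threshold / temps.T0) / math.log(params.alpha_quenching)
        )

    def test_ap_dep_fires_immediately_on_constant_energy(self, constant_landscape, rng):
        temps = TemperatureRange(T0=1.0, Tf=1e-3, T_threshold=0.5, T_fa=0.5)
        state = _state_at([0.0, 0.0, 0.0], constant_landscape.energy)
        state, trace = run_ap(
            state, 0.5, temps, ScheduleParams(), rng, constant_landscape.energy,
            L=5, dep_window=5, dep_epsilon=1e-6,
        )
        assert trace.dep_trigger_cycle == 4  # first full window, slope exactly 0

    def test_ap_cycle_count_without_dep(self, planted4, rng):
        params = ScheduleParams(alpha_annealing=0.9)
        temps = TemperatureRange(T0=10.0, Tf=0.05, T_threshold=1.0, T_fa=0.5)
        state = _state_at(planted4.random_conformation(rng), planted4.energy)
        state, trace = run_ap(
            state, temps.T_threshold, temps, params, rng, planted4.energy,
            L=5, dep_enabled=False,
        )
        expected = math.ceil(math.log(temps.Tf / temps.T_threshold) / math.log(0.9))
        assert trace.n_cycles == expected


class TestFullRuns:
    def test_replay_is_bitwise_identical(self, planted4):
        a = run_cmqa(planted4, seed=11)
        b = run_cmqa(planted4, seed=11)
        assert a.trace.energy == b.trace.energy
        assert a.best_energy == b.best_energy
        np.testing.assert_array_equal(a.best_conformation, b.best_conformation)

    def test_e_min_non_increasing_all_variants(self, planted4):
        for variant in ("cmqa", "mqa_dep", "csa"):
            res = run(planted4, variant=variant, seed=3)
            assert np.all(np.diff(res.trace.e_min) <= 0)
            assert res.best_energy == min(res.trace.e_min)

    def test_mqa_dep_equals_cmqa_without_cls(self, planted4):
        a = run_cmqa(planted4, seed=5, m_chaot=0)
        b = run_mqa_dep(planted4, seed=5)
        assert a.trace.energy == b.trace.energy
        assert a.best_energy == b.best_energy

    def test_cls_consumes_extra_evaluations(self, planted19):
        a = run_cmqa(planted19, seed=2)
        b = run_mqa_dep(planted19, seed=2)
        assert b.n_evals < a.n_evals

    def test_csa_matches_ap_from_t0(self, planted4):
        res = run_csa(planted4, seed=8)
        assert res.trace.mqp_end_cycle == 0
        assert res.trace.dep_trigger_cycle is None
        assert np.all(np.diff(res.trace.temperature) < 0)

    def test_budget_cap_is_respected(self, planted19):
        res = run_cmqa(planted19, seed=1, max_evals=3000)
        assert res.n_evals <= 3000

    def test_ap_only_improves_on_mqp(self, planted19, rng):
        full = run_cmqa(planted19, seed=4)
        mqp_end = full.trace.mqp_end_cycle
        assert min(full.trace.e_min) <= full.trace.e_min[mqp_end - 1]
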