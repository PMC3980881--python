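"""The three-phase annealer and its baselines.

A run is organised as

    multiquenching phase (MQP)  ->  annealing phase (AP)  ->  equilibrium stop

MQP cools with the quadratic quenching law; each time the tau parameter has
squared its way below its cutoff, a chaotic local search (CLS) greedily
refines the best-so-far conformation, tau resets, and a new quenching subphase
begins, until the crossover temperature T_threshold.  AP is classical
simulated annealing with geometric cooling; once the temperature falls below
the arming point T_fa, the end-of-cycle energies stream into a fixed-size
window and the run stops early when the least-squares slope of that window is
flat (dynamical equilibrium), or otherwise at Tf.

Two baselines share every proposal/acceptance rule: classical SA (``csa``,
single geometric phase, no CLS, no equilibrium stop) and the multiquenching
variant without the chaotic search (``mqa_dep``, M_chaot = 0).

Randomness is split into two substreams spawned from the run seed: the main
stream drives tuning, the initial conformation and all Metropolis proposals;
the chaos state owns the second and supplies everything the CLS consumes.
Because of the split, CMQA and the mqa_dep baseline see *identical* Metropolis
streams at a shared seed — a common-random-numbers design that turns the
variant comparison into a controlled experiment.
"""
from __future__ import annotations

import time
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .chaos import ChaosState, chaotic_perturb
from .landscapes import Landscape
from .moves import uniform_perturb
from .schedule import (
    ScheduleParams,
    TemperatureRange,
    geometric_next,
    quench_next,
    tune_temperatures,
    update_tau,
)

VARIANTS = ("cmqa", "mqa_dep", "csa")


class EnergyBudget:
    """Counting wrapper around a landscape's energy; optionally capped."""

    def __init__(self, fn, max_evals: Optional[int] = None):
        self._fn = fn
        self.calls = 0
        self.max_evals = max_evals

    def __call__(self, angles: np.ndarray) -> float:
        self.calls += 1
        return float(self._fn(angles))

    @property
    def exhausted(self) -> bool:
        return self.max_evals is not None and self.calls >= self.max_evals


def _is_exhausted(energy) -> bool:
    return bool(getattr(energy, "exhausted", False))


@dataclass
class SolutionState:
    """Current / best-so-far solutions and their energies."""

    S_i: np.ndarray
    E_i: float
    S_min: np.ndarray
    E_min: float
    n_accept: int = 0
    n_propose: int = 0


def metropolis_sweep(
    state: SolutionState,
    T: float,
    L: int,
    rng: np.random.Generator,
    energy,
) -> SolutionState:
    """Run L Metropolis proposals at fixed temperature T (in place).

    Each proposal redraws one uniformly chosen torsion on (-180, 180]; moves
    with dE < 0 are accepted outright, others with probability exp(-dE/T)
    (a tie dE = 0 always passes, exp(0) = 1).  The running minimum is updated
    whenever an accepted state improves it.
    """
    if L < 1:
        raise ValueError("L must be at least 1")
    if T <= 0:
        raise ValueError("temperature must be positive")
    for _ in range(L):
        if _is_exhausted(energy):
            break
        S_j = uniform_perturb(state.S_i, rng)
        E_j = energy(S_j)
        dE = E_j - state.E_i
        state.n_propose += 1
        if dE < 0 or rng.random() < np.exp(-dE / T):
            state.S_i, state.E_i = S_j, E_j
            state.n_accept += 1
            if E_j < state.E_min:
                state.S_min, state.E_min = S_j.copy(), E_j
    return state


def chaotic_local_search(
    S_min: np.ndarray,
    M_chaot: int,
    chaos: ChaosState,
    rng: np.random.Generator,
    energy,
    E_min: Optional[float] = None,
    step_log: Optional[list] = None,
) -> Tuple[np.ndarray, float, ChaosState]:
    """Greedy chaotic refinement of the best-so-far conformation.

    Applies M_chaot chaotic perturbations, keeping a proposal only when it
    strictly improves the best energy; the returned energy can never exceed
    the input energy.  The caller's current Metropolis state is untouched
    (the save/restore of the surrounding solution happens at the call site by
    construction, since only S_min is passed in).
    """
    if M_chaot < 0:
        raise ValueError("M_chaot must be non-negative")
    if E_min is None and M_chaot > 0:
        E_min = energy(S_min)
    S, E = S_min, E_min
    for _ in range(M_chaot):
        if _is_exhausted(energy):
            break
        S_j, chaos = chaotic_perturb(S, chaos, rng)
        E_j = energy(S_j)
        if E_j < E:
            S, E = S_j, E_j
        if step_log is not None:
            step_log.append(E)
    return S, (E if E is not None else E_min), chaos


# ---------------------------------------------------------------------------
# dynamical-equilibrium stopping rule


def dep_slope(energies) -> float:
    """Least-squares slope of energies against cycle index 0..n-1.

    Closed form for equally spaced abscissae:
        a = (12 * sum(x_i E_i) - 6 (n-1) * sum(E_i)) / (n^3 - n).
    """
    e = np.asarray(energies, dtype=float)
    n = e.size
    if n < 3:
        raise ValueError(f"need at least 3 points; got {n}")
    x = np.arange(n, dtype=float)
    return float((12.0 * np.dot(x, e) - 6.0 * (n - 1) * e.sum()) / (n**3 - n))


def dep_intercept(energies) -> float:
    """Least-squares intercept for abscissae 0..n-1 (general two-parameter form)."""
    e = np.asarray(energies, dtype=float)
    n = e.size
    if n < 3:
        raise ValueError(f"need at least 3 points; got {n}")
    x = np.arange(n, dtype=float)
    sx, sxx = x.sum(), np.dot(x, x)
    denom = n * sxx - sx * sx
    return float((e.sum() * sxx - sx * np.dot(x, e)) / denom)


@dataclass
class EquilibriumWindow:
    """Streaming window of the last n end-of-cycle energies."""

    n: int = 30
    epsilon: float = 1e-3
    energies: deque = field(init=False)

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("window must hold at least 3 points")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        self.energies = deque(maxlen=self.n)

    def append(self, e: float) -> None:
        self.energies.append(float(e))

    @property
    def full(self) -> bool:
        return len(self.energies) == self.n

    @property
    def slope(self) -> Optional[float]:
        if len(self.energies) < 3:
            return None
        return dep_slope(self.energies)


def dep_converged(window: EquilibriumWindow) -> bool:
    """True once the window is full and its fitted slope is within epsilon of flat."""
    if not window.full:
        return False
    return abs(dep_slope(window.energies)) < window.epsilon


# ---------------------------------------------------------------------------
# phases


@dataclass
class Trace:
    """Per-cycle records of a run."""

    energy: List[float] = field(default_factory=list)
    e_min: List[float] = field(default_factory=list)
    acceptance: List[float] = field(default_factory=list)
    temperature: List[float] = field(default_factory=list)
    cls_cycles: List[int] = field(default_factory=list)
    mqp_end_cycle: Optional[int] = None
    dep_trigger_cycle: Optional[int] = None

    def record(self, state: SolutionState, T: float, proposed: int, accepted: int) -> None:
        self.energy.append(state.E_i)
        self.e_min.append(state.E_min)
        self.acceptance.append(accepted / proposed if proposed else 0.0)
        self.temperature.append(T)

    @property
    def n_cycles(self) -> int:
        return len(self.energy)


def _init_state(landscape: Landscape, rng: np.random.Generator, energy) -> SolutionState:
    S = landscape.random_conformation(rng)
    E = energy(S)
    return SolutionState(S_i=S, E_i=E, S_min=S.copy(), E_min=E)


def run_mqp(
    landscape: Landscape,
    params: ScheduleParams,
    temps: TemperatureRange,
    chaos: ChaosState,
    rng: np.random.Generator,
    energy,
    L: Optional[int] = None,
    m_chaot: Optional[int] = None,
    state: Optional[SolutionState] = None,
    trace: Optional[Trace] = None,
) -> Tuple[SolutionState, float, Trace]:
    """Multiquenching phase: quench cooling with embedded chaotic searches.

    Returns the solution state, the temperature at exit (<= T_threshold) and
    the trace.  M_chaot defaults to the instance dimension m; the CLS draws
    its index choices from the chaos state's own substream.
    """
    params.validate()
    L = L if L is not None else 10 * landscape.m
    m_chaot = m_chaot if m_chaot is not None else landscape.m
    state = state if state is not None else _init_state(landscape, rng, energy)
    trace = trace if trace is not None else Trace()
    T = temps.T0
    tau = params.tau0
    while T > temps.T_threshold and not _is_exhausted(energy):
        before_p, before_a = state.n_propose, state.n_accept
        metropolis_sweep(state, T, L, rng, energy)
        trace.record(state, T, state.n_propose - before_p, state.n_accept - before_a)
        tau = update_tau(tau)
        if tau < params.tau_final:
            tau = params.tau0
            if m_chaot > 0:
                state.S_min, state.E_min, chaos = chaotic_local_search(
                    state.S_min, m_chaot, chaos, chaos.rng, energy, E_min=state.E_min
                )
                trace.cls_cycles.append(trace.n_cycles - 1)
        T = quench_next(T, params.alpha_quenching, tau)
    trace.mqp_end_cycle = trace.n_cycles
    return state, T, trace


def run_ap(
    state: SolutionState,
    T: float,
    temps: TemperatureRange,
    params: ScheduleParams,
    rng: np.random.Generator,
    energy,
    L: int,
    dep_window: int = 30,
    dep_epsilon: float = 1e-3,
    dep_enabled: bool = True,
    trace: Optional[Trace] = None,
) -> Tuple[SolutionState, Trace]:
    """Annealing phase: geometric cooling with the equilibrium stopping rule.

    Below the arming temperature T_fa every cycle's end energy feeds the
    least-squares window; the phase stops early when the fitted slope is flat,
    otherwise at Tf.
    """
    params.validate()
    trace = trace if trace is not None else Trace()
    window = EquilibriumWindow(n=dep_window, epsilon=dep_epsilon)
    while T > temps.Tf and not _is_exhausted(energy):
        before_p, before_a = state.n_propose, state.n_accept
        metropolis_sweep(state, T, L, rng, energy)
        trace.record(state, T, state.n_propose - before_p, state.n_accept - before_a)
        if dep_enabled and T <= temps.T_fa:
            window.append(state.E_i)
            if dep_converged(window):
                trace.dep_trigger_cycle = trace.n_cycles - 1
                break
        T = geometric_next(T, params.alpha_annealing)
    return state, trace


# ---------------------------------------------------------------------------
# full runs


@dataclass
class RunResult:
    """Everything needed to report and to replay one run."""

    variant: str
    seed: int
    best_energy: float
    best_conformation: np.ndarray
    trace: Trace
    temperatures: TemperatureRange
    n_evals: int
    wall_time_s: float
    config: Dict = field(default_factory=dict)
    drmsd: Optional[float] = None

    def to_dict(self) -> Dict:
        return {
            "variant": self.variant,
            "seed": self.seed,
            "best_energy": self.best_energy,
            "best_conformation": [float(x) for x in self.best_conformation],
            "energy_trace": list(self.trace.energy),
            "e_min_trace": list(self.trace.e_min),
            "acceptance_trace": list(self.trace.acceptance),
            "temperature_trace": list(self.trace.temperature),
            "cls_cycles": list(self.trace.cls_cycles),
            "mqp_end_cycle": self.trace.mqp_end_cycle,
            "dep_trigger_cycle": self.trace.dep_trigger_cycle,
            "temperatures": {
                "T0": self.temperatures.T0,
                "Tf": self.temperatures.Tf,
                "T_threshold": self.temperatures.T_threshold,
                "T_fa": self.temperatures.T_fa,
            },
            "n_evals": self.n_evals,
            "wall_time_s": self.wall_time_s,
            "config": self.config,
            "drmsd": self.drmsd,
        }


def run(
    landscape: Landscape,
    variant: str = "cmqa",
    seed: int = 0,
    params: Optional[ScheduleParams] = None,
    chaos_map: str = "M3",
    chaos_x0: float = 0.7,
    chaos_amplitude: float = 90.0,
    chaos_guard: float = 1e-6,
    L: Optional[int] = None,
    m_chaot: Optional[int] = None,
    dep_window: int = 30,
    dep_epsilon: float = 1e-3,
    max_evals: Optional[int] = None,
    config_snapshot: Optional[Dict] = None,
) -> RunResult:
    """Execute one full run of a variant; a pure function of (inputs, seed)."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    params = (params if params is not None else ScheduleParams()).validate()
    t_start = time.perf_counter()
    main_ss, chaos_ss = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(main_ss)
    chaos = ChaosState(
        chaotic_map=chaos_map,
        x=chaos_x0,
        amplitude=chaos_amplitude,
        guard=chaos_guard,
        seed=chaos_ss,
    )
    energy = EnergyBudget(landscape.energy, max_evals)
    temps = tune_temperatures(landscape, params, rng)
    L_eff = L if L is not None else 10 * landscape.m

    if variant == "csa":
        state = _init_state(landscape, rng, energy)
        trace = Trace()
        csa_temps = TemperatureRange(
            T0=temps.T0, Tf=temps.Tf, T_threshold=temps.T0, T_fa=temps.T_fa
        )
        state, trace = run_ap(
            state, temps.T0, csa_temps, params, rng, energy, L_eff,
            dep_enabled=False, trace=trace,
        )
        trace.mqp_end_cycle = 0
    else:
        mc = 0 if variant == "mqa_dep" else m_chaot
        state, T, trace = run_mqp(
            landscape, params, temps, chaos, rng, energy, L=L_eff, m_chaot=mc
        )
        state, trace = run_ap(
            state, T, temps, params, rng, energy, L_eff,
            dep_window=dep_window, dep_epsilon=dep_epsilon, trace=trace,
        )

    return RunResult(
        variant=variant,
        seed=seed,
        best_energy=state.E_min,
        best_conformation=state.S_min.copy(),
        trace=trace,
        temperatures=temps,
        n_evals=energy.calls,
        wall_time_s=time.perf_counter() - t_start,
        config=dict(config_snapshot) if config_snapshot else {},
    )


def run_cmqa(landscape: Landscape, seed: int = 0, **kwargs) -> RunResult:
    """Full three-phase run with chaotic local search."""
    return run(landscape, variant="cmqa", seed=seed, **kwargs)


def run_mqa_dep(landscape: Landscape, seed: int = 0, **kwargs) -> RunResult:
    """Multiquenching + equilibrium stop, chaotic search disabled (M_chaot = 0)."""
    return run(landscape, variant="mqa_dep", seed=seed, **kwargs)


def run_csa(landscape: Landscape, seed: int = 0, **kwargs) -> RunResult:
    """Classical simulated annealing baseline: one geometric phase, no CLS/DEP."""
    return run(landscape, variant="csa", seed=seed, **kwargs)
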