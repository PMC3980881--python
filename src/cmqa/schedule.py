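"""Cooling schedules and analytic tuning of the temperature range.

Two cooling laws are used.  The annealing phase cools geometrically,

    T_{k+1} = alpha * T_k ,          0.7 <= alpha < 1,

while the multiquenching phase cools quadratically faster,

    T_{k+1} = alpha_q * (1 - tau) * T_k ,    tau <- tau**2 each cycle,

so that early cycles quench brutally (tau near 1) and the law relaxes to the
geometric one as tau squares its way to zero.

The temperature range is tuned analytically from the Boltzmann acceptance
probability P(dZ) = exp(-dZ/T): the initial temperature is the one at which
the *maximal* observed deterioration dZ_max is accepted with a target hot
probability, and the final temperature the one at which the *minimal*
deterioration dZ_min survives only with a target cold probability:

    T0 = -dZ_max / ln(P_hot),    Tf = -dZ_min / ln(P_cold).

Deteriorations are estimated by a short uniform random walk on the landscape.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .moves import uniform_perturb


class ConfigurationError(ValueError):
    """A schedule parameter violates its documented range."""


class DegenerateLandscapeError(RuntimeError):
    """No deteriorating move was found while tuning the temperature range."""


# ---------------------------------------------------------------------------
# cooling laws


def _check_alpha(alpha: float, name: str = "alpha") -> None:
    if not (0.7 <= alpha < 1.0):
        raise ConfigurationError(f"{name} must lie in [0.7, 1); got {alpha}")


def geometric_next(T: float, alpha: float) -> float:
    """One geometric cooling step alpha*T."""
    if T <= 0:
        raise ConfigurationError(f"temperature must be positive; got {T}")
    _check_alpha(alpha)
    return alpha * T


def quench_next(T: float, alpha_q: float, tau: float) -> float:
    """One quenching step alpha_q*(1-tau)*T; equals the geometric step at tau=0."""
    if T <= 0:
        raise ConfigurationError(f"temperature must be positive; got {T}")
    _check_alpha(alpha_q, "alpha_quenching")
    if not (0.0 <= tau < 1.0):
        raise ConfigurationError(f"tau must lie in [0, 1); got {tau}")
    return alpha_q * (1.0 - tau) * T


def update_tau(tau: float) -> float:
    """Square tau; repeated updates converge to zero from any tau in (0, 1)."""
    if not (0.0 < tau < 1.0):
        raise ConfigurationError(f"tau must lie in (0, 1); got {tau}")
    return tau * tau


# ---------------------------------------------------------------------------
# analytic temperature tuning


def acceptance_probability(dZ: float, T: float) -> float:
    """Boltzmann acceptance probability exp(-dZ/T) for a deterioration dZ >= 0."""
    if T <= 0:
        raise ConfigurationError(f"temperature must be positive; got {T}")
    if dZ < 0:
        raise ValueError(f"deterioration must be non-negative; got {dZ}")
    return math.exp(-dZ / T)


def initial_temperature(dZmax: float, P: float) -> float:
    """Temperature at which the maximal deterioration is accepted with probability P."""
    if dZmax <= 0:
        raise ValueError(f"dZmax must be positive; got {dZmax}")
    if not (0.0 < P < 1.0):
        raise ValueError(f"P must lie strictly in (0, 1); got {P}")
    return -dZmax / math.log(P)


def final_temperature(dZmin: float, P: float) -> float:
    """Temperature at which the minimal deterioration is accepted with probability P."""
    if dZmin <= 0:
        raise ValueError(f"dZmin must be positive; got {dZmin}")
    if not (0.0 < P < 1.0):
        raise ValueError(f"P must lie strictly in (0, 1); got {P}")
    return -dZmin / math.log(P)


def estimate_deteriorations(
    landscape, n_samples: int, rng: np.random.Generator, n_walks: int = 10
) -> Tuple[float, float]:
    """Estimate (dZ_max, dZ_min) by uniform random walks from random starts.

    Performs ``n_samples`` single-variable uniform perturbations spread over
    ``n_walks`` independent walks, records every positive energy change, and
    returns the largest and smallest one.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    n_walks = max(1, min(n_walks, n_samples))
    per_walk = -(-n_samples // n_walks)  # ceil
    dmax, dmin = -math.inf, math.inf
    taken = 0
    for _ in range(n_walks):
        current = landscape.random_conformation(rng)
        e_cur = landscape.energy(current)
        for _ in range(per_walk):
            if taken >= n_samples:
                break
            nxt = uniform_perturb(current, rng)
            e_nxt = landscape.energy(nxt)
            d = e_nxt - e_cur
            if d > 0:
                dmax = max(dmax, d)
                dmin = min(dmin, d)
            current, e_cur = nxt, e_nxt
            taken += 1
    if not math.isfinite(dmax):
        raise DegenerateLandscapeError(
            "no deteriorating move found while tuning the temperature range; "
            "the landscape may be constant — retry with a larger n_samples"
        )
    return dmax, dmin


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class ScheduleParams:
    """Cooling-schedule parameters.

    alpha_quenching / alpha_annealing are the temperature decrement factors of
    the quenching and annealing phases, both restricted to [0.7, 1).  tau0 and
    tau_final control when a quenching subphase hands over to the chaotic
    local search (tau squares each cycle; the handover fires when it drops
    below tau_final).  p_hot / p_cold are the target acceptance probabilities
    that define T0 and Tf; t_threshold_frac places the quenching->annealing
    crossover at t_threshold_frac*T0, and t_fa_frac arms the equilibrium
    detector at t_fa_frac*Tf.
    """

    alpha_quenching: float = 0.85
    alpha_annealing: float = 0.95
    tau0: float = 0.90
    tau_final: float = 0.0009
    p_hot: float = 0.95
    p_cold: float = 0.01
    t_threshold_frac: float = 1e-3
    t_fa_frac: float = 10.0
    tune_samples: Optional[int] = None  # default 100*m at tuning time

    def validate(self) -> "ScheduleParams":
        _check_alpha(self.alpha_quenching, "alpha_quenching")
        _check_alpha(self.alpha_annealing, "alpha_annealing")
        if not (0.0 < self.tau_final < self.tau0 < 1.0):
            raise ConfigurationError(
                f"need 0 < tau_final < tau0 < 1; got tau0={self.tau0}, "
                f"tau_final={self.tau_final}"
            )
        for name in ("p_hot", "p_cold"):
            p = getattr(self, name)
            if not (0.0 < p < 1.0):
                raise ConfigurationError(f"{name} must lie strictly in (0, 1); got {p}")
        if not (0.0 < self.t_threshold_frac < 1.0):
            raise ConfigurationError(
                f"t_threshold_frac must lie in (0, 1); got {self.t_threshold_frac}"
            )
        if self.t_fa_frac <= 1.0:
            raise ConfigurationError(
                f"t_fa_frac must exceed 1 (T_fa above Tf); got {self.t_fa_frac}"
            )
        if self.tune_samples is not None and self.tune_samples < 2:
            raise ConfigurationError("tune_samples must be at least 2")
        return self


@dataclass
class TemperatureRange:
    """The tuned temperatures, ordered 0 < Tf < T_fa <= T_threshold < T0."""

    T0: float
    Tf: float
    T_threshold: float
    T_fa: float

    def validate(self) -> "TemperatureRange":
        if not (0.0 < self.Tf < self.T_fa <= self.T_threshold < self.T0):
            raise ConfigurationError(
                "temperatures must satisfy 0 < Tf < T_fa <= T_threshold < T0; got "
                f"T0={self.T0:g}, T_threshold={self.T_threshold:g}, "
                f"T_fa={self.T_fa:g}, Tf={self.Tf:g}"
            )
        return self


def tune_temperatures(
    landscape, params: ScheduleParams, rng: np.random.Generator
) -> TemperatureRange:
    """Tune (T0, Tf, T_threshold, T_fa) for one landscape.

    The equilibrium-detector arming temperature T_fa is clamped below
    T_threshold when the tuned landscape would place it above.
    """
    params.validate()
    n = params.tune_samples if params.tune_samples is not None else 100 * landscape.m
    dmax, dmin = estimate_deteriorations(landscape, n, rng)
    T0 = initial_temperature(dmax, params.p_hot)
    Tf = final_temperature(dmin, params.p_cold)
    T_threshold = params.t_threshold_frac * T0
    T_fa = min(params.t_fa_frac * Tf, T_threshold)
    return TemperatureRange(T0=T0, Tf=Tf, T_threshold=T_threshold, T_fa=T_fa).validate()
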