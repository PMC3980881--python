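"""Chaotic drivers for the local-search phase.

Four sine maps with singularities at the ends of the unit interval supply the
perturbation signal of the chaotic local search.  Each map takes x in (0, 1)
(excluding the singular points) to a value in [-1, 1]:

    M1: f(x) = sin(1/x)
    M2: f(x) = sin( (1/x) * (1/(1-x)) )
    M3: f(x) = sin( (100/x) * (1/(1-x)) )
    M4: f(x) = sin(1/x) * sin(5/(1-x))

Near a singularity the maps oscillate with unbounded frequency, which is what
makes the driven search explore erratically.  How the map is *iterated* is a
choice of this package: the next iterate is |f(x)| folded back into the guarded
interval, with a deterministic re-seed from the state's own random substream
whenever the fold lands inside a guard band or on a fixed point.  This gives a
bounded, fully reproducible driver.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Tuple

import numpy as np

from .moves import wrap_angle_deg


class ChaosDomainError(ValueError):
    """Raised when a chaotic map is evaluated at or too near a singular point."""


class ChaoticMap(Enum):
    """The four chaotic functions, in display order."""

    M1 = "M1"
    M2 = "M2"
    M3 = "M3"
    M4 = "M4"

    @property
    def singularities(self) -> Tuple[float, ...]:
        return (0.0,) if self is ChaoticMap.M1 else (0.0, 1.0)


def eval_chaotic_map(chaotic_map: ChaoticMap, x: float, guard: float = 1e-6) -> float:
    """Evaluate one chaotic function at x.

    Parameters
    ----------
    chaotic_map : which of the four maps to evaluate.
    x : point in the map's open domain.
    guard : exclusion radius around the singular points; evaluation closer
        than this is rejected (never silently clamped).

    Returns
    -------
    f(x), always in [-1, 1].
    """
    for s in chaotic_map.singularities:
        if abs(x - s) < guard:
            raise ChaosDomainError(
                f"{chaotic_map.value} is singular at x={s}; got x={x!r} "
                f"within guard radius {guard}"
            )
    if chaotic_map is ChaoticMap.M1:
        return math.sin(1.0 / x)
    if chaotic_map is ChaoticMap.M2:
        return math.sin(1.0 / (x * (1.0 - x)))
    if chaotic_map is ChaoticMap.M3:
        return math.sin(100.0 / (x * (1.0 - x)))
    return math.sin(1.0 / x) * math.sin(5.0 / (1.0 - x))


@dataclass
class ChaosState:
    """Mutable state of the iterated chaotic driver.

    Attributes
    ----------
    chaotic_map : which map drives the iteration.
    x : current iterate, kept strictly inside (guard, 1-guard).
    amplitude : maximal angular perturbation in degrees; a driver output y
        moves one torsion by y*amplitude.
    guard : exclusion radius around singular points (and around 0/1 for the
        folded iterate).
    seed : seed of the dedicated re-seeding substream.  Two states built with
        identical (map, x0, amplitude, guard, seed) replay identically.
    """

    chaotic_map: ChaoticMap = ChaoticMap.M3
    x: float = 0.7
    amplitude: float = 90.0
    guard: float = 1e-6
    seed: int = 0
    rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if isinstance(self.chaotic_map, str):
            self.chaotic_map = ChaoticMap(self.chaotic_map)
        if not (self.guard < self.x < 1.0 - self.guard):
            raise ChaosDomainError(
                f"initial iterate x0={self.x} must lie in ({self.guard}, {1 - self.guard})"
            )
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        self.rng = np.random.default_rng(self.seed)


def advance_chaos(state: ChaosState) -> Tuple[ChaosState, float]:
    """Advance the driver one step.

    Returns the (mutated) state and the raw map output y in [-1, 1].  The next
    iterate is |y| folded into (guard, 1-guard); degenerate folds (guard-band
    landings, fixed points) are re-seeded from the state's substream, so the
    sequence is still a pure function of the initial state.
    """
    y = eval_chaotic_map(state.chaotic_map, state.x, state.guard)
    x_new = abs(y)
    degenerate = (
        not (state.guard < x_new < 1.0 - state.guard)
        or x_new == state.x
        or any(abs(x_new - s) < state.guard for s in state.chaotic_map.singularities)
    )
    if degenerate:
        x_new = float(state.rng.uniform(state.guard, 1.0 - state.guard))
    state.x = x_new
    return state, y


def chaotic_perturb(
    angles: np.ndarray, state: ChaosState, rng: np.random.Generator
) -> Tuple[np.ndarray, ChaosState]:
    """Apply one chaotic perturbation to a conformation.

    Exactly one variable index j (uniform via ``rng``) changes:
    sigma'_j = wrap(sigma_j + y*amplitude) with y from :func:`advance_chaos`.
    """
    if angles.size == 0:
        raise ValueError("cannot perturb an empty conformation")
    j = int(rng.integers(angles.size))
    state, y = advance_chaos(state)
    out = angles.copy()
    out[j] = wrap_angle_deg(angles[j] + y * state.amplitude)
    return out, state
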