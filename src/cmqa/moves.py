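"""Angle conventions and elementary proposal moves.

All dihedral angles live in degrees on the half-open interval (-180, 180].
"""
from __future__ import annotations

import math

import numpy as np


def wrap_angle_deg(angle: float) -> float:
    """Wrap an angle in degrees onto (-180, 180].

    The upper endpoint is kept and the lower one excluded, so 180 stays 180
    and -180 maps to 180 (the same physical torsion).
    """
    r = math.fmod(angle + 180.0, 360.0)
    if r <= 0.0:
        r += 360.0
    return r - 180.0


def random_angle_deg(rng: np.random.Generator) -> float:
    """Draw one angle uniformly on (-180, 180]."""
    u = float(rng.uniform(-180.0, 180.0))
    return 180.0 if u == -180.0 else u


def random_conformation(m: int, rng: np.random.Generator) -> np.ndarray:
    """Draw m independent uniform angles, one per dihedral variable."""
    return np.array([random_angle_deg(rng) for _ in range(m)], dtype=float)


def uniform_perturb(angles: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Redraw one uniformly chosen variable fresh on (-180, 180].

    This is the Metropolis proposal: a full-range redraw rather than a bounded
    delta, so any value of the chosen torsion is reachable in one move.
    """
    if angles.size == 0:
        raise ValueError("cannot perturb an empty conformation")
    j = int(rng.integers(angles.size))
    out = angles.copy()
    out[j] = random_angle_deg(rng)
    return out
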