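"""Objective landscapes over dihedral-angle vectors.

The annealer only needs a dimension ``m`` and an ``energy`` callable over a
vector of m angles in degrees; everything else (protein or synthetic) hides
behind this surface.  The planted landscape is the validation workhorse: a
separable sum of cosine wells with a *certified* global minimum of exactly 0
at a known conformation, optionally decorated with shallower secondary wells
("traps") on selected coordinates.
"""
from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .moves import random_conformation


class Landscape(abc.ABC):
    """Abstract objective over conformations of ``m`` dihedral variables."""

    m: int

    @abc.abstractmethod
    def energy(self, angles: np.ndarray) -> float:
        """Energy of one conformation (angles in degrees)."""

    def random_conformation(self, rng: np.random.Generator) -> np.ndarray:
        return random_conformation(self.m, rng)


@dataclass
class PlantedLandscape(Landscape):
    """Separable cosine landscape with a known global minimum.

    Per coordinate i, with delta_i the angular offset from the planted optimum
    sigma*_i (in radians),

        v_i(delta) = depth * (1 - cos delta) * g_i(delta)

    where g_i = 1 for plain coordinates and, for trap coordinates,

        g_i(delta) = 1 - f * ((1 + cos(delta - s_i)) / 2)**q

    dips around a shifted centre s_i, carving a secondary local minimum while
    keeping v_i >= (1-f) * depth * (1 - cos delta) > 0 away from delta = 0.
    The total energy is the sum over coordinates, so the global minimum is
    exactly 0, attained only at sigma*.
    """

    m: int
    sigma_star: np.ndarray
    depth: float = 1.0
    trap_coords: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    trap_shifts_deg: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))
    trap_depth_frac: float = 0.8
    trap_sharpness: int = 6

    def __post_init__(self) -> None:
        self.sigma_star = np.asarray(self.sigma_star, dtype=float)
        self.trap_coords = np.asarray(self.trap_coords, dtype=int)
        self.trap_shifts_deg = np.asarray(self.trap_shifts_deg, dtype=float)
        if self.m < 1:
            raise ValueError("m must be at least 1")
        if self.sigma_star.shape != (self.m,):
            raise ValueError("sigma_star must have shape (m,)")
        if self.trap_coords.shape != self.trap_shifts_deg.shape:
            raise ValueError("trap coordinates and shifts must align")
        if not (0.0 <= self.trap_depth_frac < 1.0):
            raise ValueError("trap_depth_frac must lie in [0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        self._certify()

    # -- energy -------------------------------------------------------------

    def energy(self, angles: np.ndarray) -> float:
        delta = np.deg2rad(np.asarray(angles, dtype=float) - self.sigma_star)
        base = self.depth * (1.0 - np.cos(delta))
        if self.trap_coords.size:
            d = delta[self.trap_coords] - np.deg2rad(self.trap_shifts_deg)
            dip = self.trap_depth_frac * ((1.0 + np.cos(d)) / 2.0) ** self.trap_sharpness
            base[self.trap_coords] *= 1.0 - dip
        return float(base.sum())

    # -- certification ------------------------------------------------------

    def _coordinate_profile(self, i: int, grid_deg: np.ndarray) -> np.ndarray:
        delta = np.deg2rad(grid_deg)
        v = self.depth * (1.0 - np.cos(delta))
        hits = np.nonzero(self.trap_coords == i)[0]
        if hits.size:
            s = np.deg2rad(self.trap_shifts_deg[hits[0]])
            dip = self.trap_depth_frac * ((1.0 + np.cos(delta - s)) / 2.0) ** self.trap_sharpness
            v *= 1.0 - dip
        return v

    def _certify(self) -> None:
        """Verify at construction that the planted optimum is the global minimum.

        The landscape is separable, so a dense per-coordinate scan suffices:
        each profile must be zero only at delta=0 and, for trap coordinates,
        must show a strictly positive interior local minimum (the trap).
        """
        if self.energy(self.sigma_star) != 0.0:
            raise RuntimeError("planted optimum does not evaluate to zero")
        grid = np.arange(-179.9, 180.05, 0.1)
        for i in range(self.m):
            v = self._coordinate_profile(i, grid)
            if v.min() < 0.0:
                raise RuntimeError(f"coordinate {i} dips below zero; traps too deep")
            nonzero = v[np.abs(grid) > 0.2]
            if nonzero.min() <= 0.0:
                raise RuntimeError(f"coordinate {i} has a spurious zero away from the optimum")
        for t, i in enumerate(self.trap_coords):
            v = self._coordinate_profile(int(i), grid)
            interior = (np.abs(grid) > 30.0)
            dv = np.diff(v)
            # a sign change - to + away from the optimum marks the trap minimum
            local_min = np.nonzero((dv[:-1] < 0) & (dv[1:] > 0) & interior[1:-1])[0]
            if local_min.size == 0:
                raise RuntimeError(
                    f"trap {t} on coordinate {int(i)} produced no secondary local minimum"
                )

    def descent_check(self, n_random: int = 10_000, seed: int = 0) -> bool:
        """Independent spot check: random sampling plus descent from trap centres.

        Returns True when every probed point has strictly positive energy
        (the planted optimum excepted).
        """
        from scipy.optimize import minimize

        rng = np.random.default_rng(seed)
        samples = rng.uniform(-180.0, 180.0, size=(n_random, self.m))
        for s in samples:
            if not np.allclose(s, self.sigma_star) and self.energy(s) <= 0.0:
                return False
        for i, shift in zip(self.trap_coords, self.trap_shifts_deg):
            x0 = self.sigma_star.copy()
            x0[int(i)] = self.sigma_star[int(i)] + shift
            res = minimize(self.energy, x0, method="Nelder-Mead")
            if res.fun <= 0.0 and not np.allclose(res.x, self.sigma_star, atol=1e-3):
                return False
        return True


def planted_landscape(
    m: int,
    sigma_star: Optional[Sequence[float]] = None,
    depth: float = 1.0,
    n_traps: int = 5,
    rng: Optional[np.random.Generator] = None,
    trap_depth_frac: float = 0.8,
    trap_sharpness: int = 6,
) -> PlantedLandscape:
    """Build a planted landscape, drawing unspecified pieces from ``rng``.

    The optimum location (when not given), the trapped coordinates and the
    trap centres are drawn deterministically from the generator, so the same
    seed always yields the same landscape.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    if n_traps > m:
        raise ValueError("cannot place more traps than coordinates")
    rng = rng if rng is not None else np.random.default_rng(0)
    if sigma_star is None:
        sigma_star = rng.uniform(-180.0, 180.0, size=m)
    coords = rng.choice(m, size=n_traps, replace=False) if n_traps else np.array([], int)
    signs = rng.choice([-1.0, 1.0], size=n_traps)
    shifts = signs * rng.uniform(100.0, 160.0, size=n_traps)
    return PlantedLandscape(
        m=m,
        sigma_star=np.asarray(sigma_star, dtype=float),
        depth=depth,
        trap_coords=np.sort(coords),
        trap_shifts_deg=shifts,
        trap_depth_frac=trap_depth_frac,
        trap_sharpness=trap_sharpness,
    )


class CallableLandscape(Landscape):
    """Adapter wrapping an arbitrary energy callable as a landscape."""

    def __init__(self, m: int, fn):
        self.m = m
        self._fn = fn

    def energy(self, angles: np.ndarray) -> float:
        return float(self._fn(np.asarray(angles, dtype=float)))
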