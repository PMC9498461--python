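"""Whale optimization algorithm over a box-bounded continuous domain.

A population of N candidate solutions ("whales") is updated for T_max
iterations by three moves borrowed from humpback foraging:

* encircling the best-so-far solution X_p:
      D = |C * X_p - X|,  X <- X_p - A * D
* a logarithmic bubble-net spiral around X_p:
      D' = |X_p - X|,     X <- D' * exp(b*l) * cos(2*pi*l) + X_p
* a global search around a randomly chosen whale X_rand:
      D" = |C * X_rand - X|,  X <- X_rand - A * D"

with A = 2*a*r1 - a and C = 2*r2, r1, r2 ~ U(0,1) element-wise, and the
control parameter a decaying linearly from 2 to 0 so the swarm shifts from
exploration (|A| >= 1, random-whale search) to exploitation (|A| < 1,
encircling).  Each whale flips a coin p per iteration between the spiral
(p >= 0.5) and the encircle/search pair (p < 0.5); within the latter the
exploitation/exploration choice is made per dimension from |A|.  Positions
are clamped to the bounds; minimization convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["WoaConfig", "WoaResult", "optimize",
           "step_encircle", "step_spiral", "step_search"]


@dataclass
class WoaConfig:
    """Search-space and run-length parameters for the whale optimizer."""

    pop_size: int = 30
    max_iters: int = 100
    b: float = 1.0  # spiral shape constant
    lo: np.ndarray | float = -1.0
    hi: np.ndarray | float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2 or self.max_iters < 1 or self.b <= 0:
            raise ValueError("invalid WOA configuration")

    def bounds(self, dim: int) -> tuple[np.ndarray, np.ndarray]:
        lo = np.broadcast_to(np.asarray(self.lo, dtype=float), (dim,)).copy()
        hi = np.broadcast_to(np.asarray(self.hi, dtype=float), (dim,)).copy()
        if np.any(lo >= hi):
            raise ValueError("bounds must satisfy lo < hi element-wise")
        return lo, hi


@dataclass
class WoaResult:
    """Best solution found and the per-iteration best-fitness trace."""

    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray = field(default_factory=lambda: np.array([]))


def step_encircle(X: np.ndarray, X_p: np.ndarray, A: np.ndarray,
                  C: np.ndarray) -> np.ndarray:
    """Shrinking-encircling move toward the best solution."""
    D = np.abs(C * X_p - X)
    return X_p - A * D


def step_spiral(X: np.ndarray, X_p: np.ndarray, b: float, l: np.ndarray) -> np.ndarray:
    """Logarithmic-spiral move around the best solution."""
    D = np.abs(X_p - X)
    return D * np.exp(b * l) * np.cos(2 * np.pi * l) + X_p


def step_search(X: np.ndarray, X_rand: np.ndarray, A: np.ndarray,
                C: np.ndarray) -> np.ndarray:
    """Exploratory move around a randomly selected whale."""
    D = np.abs(C * X_rand - X)
    return X_rand - A * D


def _evaluate(objective, positions: np.ndarray) -> np.ndarray:
    fit = np.empty(positions.shape[0])
    for i, x in enumerate(positions):
        v = float(objective(x))
        if not np.isfinite(v):
            warnings.warn("objective returned non-finite value; candidate rejected")
            v = np.inf
        fit[i] = v
    return fit


def optimize(objective, dim: int, config: WoaConfig = WoaConfig()) -> WoaResult:
    """Minimize ``objective`` over a ``dim``-dimensional box.

    Deterministic for a fixed config (including the seed).  The best-fitness
    history is non-increasing because the incumbent is only replaced by a
    strictly better candidate.
    """
    lo, hi = config.bounds(dim)
    rng = np.random.default_rng(config.seed)
    X = rng.uniform(lo, hi, size=(config.pop_size, dim))
    fitness = _evaluate(objective, X)
    best_idx = int(np.argmin(fitness))
    best_pos, best_fit = X[best_idx].copy(), float(fitness[best_idx])
    history = [best_fit]

    for t in range(config.max_iters):
        a = 2.0 * (1.0 - t / config.max_iters)
        for i in range(config.pop_size):
            r1 = rng.uniform(size=dim)
            r2 = rng.uniform(size=dim)
            A = 2.0 * a * r1 - a
            C = 2.0 * r2
            p = rng.uniform()
            if p >= 0.5:
                l = rng.uniform(-1.0, 1.0, size=dim)
                X[i] = step_spiral(X[i], best_pos, config.b, l)
            else:
                j = int(rng.integers(config.pop_size))
                exploit = np.abs(A) < 1.0  # per-dimension phase choice
                enc = step_encircle(X[i], best_pos, A, C)
                srch = step_search(X[i], X[j], A, C)
                X[i] = np.where(exploit, enc, srch)
            np.clip(X[i], lo, hi, out=X[i])
        fitness = _evaluate(objective, X)
        it_best = int(np.argmin(fitness))
        if fitness[it_best] < best_fit:
            best_fit = float(fitness[it_best])
            best_pos = X[it_best].copy()
        history.append(best_fit)

    return WoaResult(best_pos, best_fit, np.asarray(history))
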