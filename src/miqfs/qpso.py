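"""Quantum-behaved particle swarm optimization (QPSO) over a box.

QPSO keeps only particle positions (no velocities). Each particle is drawn
from a quantum well centered on a stochastic attractor between its personal
best and the global best; the well width is proportional to the distance to
``mbest`` (the mean of all personal bests) scaled by a contraction-expansion
coefficient that decays linearly from 1.0 to 0.5 over the run. The optimizer
minimizes natively; maximization is handled by negating the objective.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

_U_EPS = 1e-12  # guard for ln(1/u)


@dataclass
class Swarm:
    positions: np.ndarray          # (N, D)
    fitness: np.ndarray            # (N,)
    pbest: np.ndarray              # (N, D)
    pbest_fitness: np.ndarray      # (N,)
    gbest: np.ndarray              # (D,)
    gbest_fitness: float
    bounds: np.ndarray             # (D, 2)
    t: int
    t_max: int
    rng: np.random.Generator = field(repr=False, default=None)

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dims(self) -> int:
        return self.positions.shape[1]


@dataclass
class OptimResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # per-iteration gbest fitness, length t_max


def _as_bounds(bounds) -> np.ndarray:
    b = np.asarray(bounds, dtype=float)
    if b.ndim != 2 or b.shape[1] != 2:
        raise ValueError("bounds must be a sequence of (min, max) pairs")
    if np.any(b[:, 0] >= b[:, 1]):
        raise ValueError("each bound must satisfy min < max")
    return b


def _evaluate(objective: Callable, positions: np.ndarray) -> np.ndarray:
    out = np.empty(positions.shape[0])
    for i, p in enumerate(positions):
        v = float(objective(p))
        if not np.isfinite(v):
            warnings.warn("objective returned a non-finite value; "
                          "treating as +inf", stacklevel=3)
            v = np.inf
        out[i] = v
    return out


def init_swarm(objective: Callable, bounds, n_particles: int,
               t_max: int, seed: int | None = None) -> Swarm:
    """Uniformly sample the swarm inside the box and set the initial bests."""
    b = _as_bounds(bounds)
    if n_particles < 2:
        raise ValueError("the swarm needs at least 2 particles")
    if t_max < 1:
        raise ValueError("t_max must be positive")
    rng = np.random.default_rng(seed)
    positions = b[:, 0] + (b[:, 1] - b[:, 0]) * rng.random(
        (n_particles, b.shape[0]))
    fitness = _evaluate(objective, positions)
    k = int(np.argmin(fitness))
    return Swarm(positions=positions, fitness=fitness,
                 pbest=positions.copy(), pbest_fitness=fitness.copy(),
                 gbest=positions[k].copy(), gbest_fitness=float(fitness[k]),
                 bounds=b, t=0, t_max=t_max, rng=rng)


def contraction_coefficient(t: int, t_max: int) -> float:
    """Linearly decaying step-size control: 1.0 at t = 0, 0.5 at t = t_max."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if not 0 <= t <= t_max:
        raise ValueError(f"iteration t={t} outside [0, {t_max}]")
    return 0.5 + 0.5 * (t_max - t) / t_max


def qpso_step(swarm: Swarm, objective: Callable) -> Swarm:
    """Advance the swarm one generation (in place; the swarm is returned).

    Per particle i and dimension j: attractor
    ``P = phi * pbest + (1 - phi) * gbest`` with ``phi ~ U(0,1)``; the new
    position is ``P -/+ alpha * |mbest - x| * ln(1/u)``, the sign chosen by
    an independent ``r ~ U(0,1)`` (minus when ``r >= 0.5``). Positions are
    clamped to the bounds, then personal and global bests are updated on
    strict improvement.
    """
    if swarm.t >= swarm.t_max:
        raise ValueError("swarm already reached t_max iterations")
    shape = swarm.positions.shape
    rng = swarm.rng
    phi = rng.random(shape)
    u = np.maximum(rng.random(shape), _U_EPS)
    r = rng.random(shape)

    attractor = phi * swarm.pbest + (1.0 - phi) * swarm.gbest
    mbest = swarm.pbest.mean(axis=0)
    alpha = contraction_coefficient(swarm.t, swarm.t_max)
    spread = alpha * np.abs(mbest - swarm.positions) * np.log(1.0 / u)
    sign = np.where(r >= 0.5, -1.0, 1.0)
    new_pos = attractor + sign * spread
    np.clip(new_pos, swarm.bounds[:, 0], swarm.bounds[:, 1], out=new_pos)

    swarm.positions = new_pos
    swarm.fitness = _evaluate(objective, new_pos)

    improved = swarm.fitness < swarm.pbest_fitness
    swarm.pbest[improved] = new_pos[improved]
    swarm.pbest_fitness[improved] = swarm.fitness[improved]
    k = int(np.argmin(swarm.pbest_fitness))
    if swarm.pbest_fitness[k] < swarm.gbest_fitness:
        swarm.gbest = swarm.pbest[k].copy()
        swarm.gbest_fitness = float(swarm.pbest_fitness[k])
    swarm.t += 1
    return swarm


def optimize(objective: Callable, bounds, n_particles: int = 200,
             t_max: int = 200, seed: int | None = None,
             sense: str = "minimize") -> OptimResult:
    """Run QPSO for ``t_max`` generations and return the best point found.

    ``sense="maximize"`` negates the objective internally; the returned
    fitness and history are reported on the caller's scale (so the history is
    non-increasing when minimizing and non-decreasing when maximizing).
    """
    if sense not in ("minimize", "maximize"):
        raise ValueError("sense must be 'minimize' or 'maximize'")
    flip = -1.0 if sense == "maximize" else 1.0
    inner = (lambda p: flip * objective(p)) if flip < 0 else objective
    swarm = init_swarm(inner, bounds, n_particles, t_max, seed)
    history = np.empty(t_max)
    for t in range(t_max):
        qpso_step(swarm, inner)
        history[t] = swarm.gbest_fitness
    return OptimResult(best_position=swarm.gbest.copy(),
                       best_fitness=flip * swarm.gbest_fitness,
                       history=flip * history)
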