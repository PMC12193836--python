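"""Canonical Grey Wolf Optimizer.

A population of ``n_agents`` candidate solutions ("wolves") is steered by
its three best members (alpha, beta, delta).  Each iteration every wolf
moves to the mean of three points obtained by encircling each leader:

    D_l = | C x_l - x |,   X_l = x_l - A D_l,   x <- (X_a + X_b + X_d) / 3

with per-coordinate random coefficients A in [-a, a] and C in [0, 2],
where the exploration radius a shrinks linearly from 2 to 0 over the
iteration budget.  Used both as the baseline optimizer and as the
substrate the Levy-enhanced variant builds on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "GWOConfig",
    "WolfPack",
    "OptResult",
    "linear_a",
    "sample_coefficients",
    "leader_update",
    "gwo_optimize",
]


@dataclass
class GWOConfig:
    """Run configuration for the canonical optimizer.

    Bounds are scalar and apply to every coordinate.  ``clamp=False``
    disables the post-move box projection (exploration may then leave the
    stated domain; useful only for studying unbounded escape artefacts).
    """

    dim: int
    lower: float = -100.0
    upper: float = 100.0
    n_agents: int = 30
    max_iter: int = 500
    seed: int = 0
    clamp: bool = True

    def validate(self) -> None:
        if self.n_agents < 3:
            raise ValueError("n_agents must be >= 3 (three leaders must exist)")
        if not self.lower < self.upper:
            raise ValueError("lower bound must be strictly below upper bound")
        if self.dim < 1 or self.max_iter < 1:
            raise ValueError("dim and max_iter must be positive")


@dataclass
class WolfPack:
    """Positions and fitnesses of the pack at one iteration."""

    positions: np.ndarray
    fitness: np.ndarray
    t: int = 0

    @property
    def leader_indices(self) -> np.ndarray:
        """Indices of alpha, beta, delta; ties break by lower agent index."""
        return np.argsort(self.fitness, kind="stable")[:3]

    @property
    def alpha(self) -> tuple[np.ndarray, float]:
        i = self.leader_indices[0]
        return self.positions[i], float(self.fitness[i])

    @property
    def beta(self) -> tuple[np.ndarray, float]:
        i = self.leader_indices[1]
        return self.positions[i], float(self.fitness[i])

    @property
    def delta(self) -> tuple[np.ndarray, float]:
        i = self.leader_indices[2]
        return self.positions[i], float(self.fitness[i])


@dataclass
class OptResult:
    """Outcome of one optimizer run with its per-iteration trace."""

    best_position: np.ndarray
    best_fitness: float
    curve: np.ndarray
    n_evals: int
    seed: int
    meta: dict = field(default_factory=dict)


def linear_a(t: int, t_max: int) -> float:
    """Exploration radius 2 (1 - t / Tmax), decaying linearly to 0."""
    if not 0 <= t <= t_max:
        raise ValueError(f"iteration t={t} outside [0, {t_max}]")
    return 2.0 * (1.0 - t / t_max)


def sample_coefficients(
    a: float, rng: np.random.Generator, dim: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the encircling coefficients A = 2 a r1 - a and C = 2 r2."""
    if a < 0:
        raise ValueError("a must be non-negative")
    r1 = rng.random(dim)
    r2 = rng.random(dim)
    return 2.0 * a * r1 - a, 2.0 * r2


def leader_update(
    x: np.ndarray,
    leaders: Sequence[np.ndarray],
    a: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Move one wolf toward the mean of its three leader-encircling points."""
    x = np.asarray(x, dtype=float)
    parts = []
    for lead in leaders:
        A, C = sample_coefficients(a, rng, x.size)
        D = np.abs(C * lead - x)
        parts.append(lead - A * D)
    return np.mean(parts, axis=0)


def _evaluate(objective: Callable, x: np.ndarray) -> float:
    v = float(objective(x))
    return v if np.isfinite(v) else np.inf


def _init_pack(objective: Callable, cfg: GWOConfig, rng: np.random.Generator) -> WolfPack:
    positions = cfg.lower + rng.random((cfg.n_agents, cfg.dim)) * (cfg.upper - cfg.lower)
    fitness = np.array([_evaluate(objective, p) for p in positions])
    return WolfPack(positions=positions, fitness=fitness, t=0)


def _sweep(
    pack: WolfPack, a: float, cfg: GWOConfig, rng: np.random.Generator
) -> np.ndarray:
    """Synchronous leader update of the whole pack (one iteration's moves).

    All wolves reference the same leader snapshot; draws are one block per
    iteration so the canonical and enhanced engines consume identical
    stream prefixes.
    """
    leaders = pack.positions[pack.leader_indices]  # (3, dim)
    r = rng.random((cfg.n_agents, 2, 3, cfg.dim))
    A = 2.0 * a * r[:, 0] - a
    C = 2.0 * r[:, 1]
    D = np.abs(C * leaders[None] - pack.positions[:, None, :])
    new = np.mean(leaders[None] - A * D, axis=1)
    if cfg.clamp:
        np.clip(new, cfg.lower, cfg.upper, out=new)
    return new


def gwo_optimize(
    objective: Callable,
    config: GWOConfig,
    _hooks: Optional[Callable] = None,
) -> OptResult:
    """Run the canonical optimizer; deterministic given ``config.seed``.

    ``_hooks(pack, t, rng, best_pos, best_fit)`` is an internal extension
    point called after each sweep (the enhanced variant injects its extra
    moves there); it receives the elitist best-so-far and must return the
    number of objective evaluations it performed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pack = _init_pack(objective, config, rng)
    n_evals = config.n_agents

    best_idx = int(np.argmin(pack.fitness))
    best_fit = float(pack.fitness[best_idx])
    best_pos = pack.positions[best_idx].copy()
    curve = np.empty(config.max_iter)

    for t in range(config.max_iter):
        pack.t = t
        a = linear_a(t, config.max_iter)
        pack.positions = _sweep(pack, a, config, rng)
        pack.fitness = np.array([_evaluate(objective, p) for p in pack.positions])
        n_evals += config.n_agents

        if _hooks is not None:
            n_evals += _hooks(pack, t, rng, best_pos, best_fit)

        i = int(np.argmin(pack.fitness))
        if pack.fitness[i] < best_fit:
            best_fit = float(pack.fitness[i])
            best_pos = pack.positions[i].copy()
        curve[t] = best_fit

    return OptResult(
        best_position=best_pos,
        best_fitness=best_fit,
        curve=curve,
        n_evals=n_evals,
        seed=config.seed,
    )
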