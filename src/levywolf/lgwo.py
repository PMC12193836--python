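"""Levy-enhanced Grey Wolf Optimizer (LGWO).

Extends the canonical optimizer with five ingredients, all under greedy
acceptance (a candidate replaces an incumbent only if its fitness is
better):

* an arctan-decayed weight factor
  ``O = ((Tmax - 2)/Tmax) (ws - (ws - we) (2/pi) arctan(a + b t))^2``
  that shrinks from ~0.6 toward ``((Tmax-2)/Tmax) we^2`` as iterations
  accumulate;
* Levy-flight position adjustments of the non-leader wolves, switched on
  permanently once the best fitness first stagnates, using
  Mantegna-sampled heavy-tailed steps;
* each iteration, a Levy jump around the incumbent best away from the
  worst wolf, ``x_new = x_best + O L (x_best - x_worst)``, and an
  opposition-based candidate ``x_new = ub + lb - L x_best``;
* each iteration, per-wolf drift ``x + L (x_best - x)`` and contraction
  ``O x`` moves, plus a Harris-Hawks-style mutation pair applied with
  probability ``pp`` per wolf.

The contraction move is what drives the exact-zero finishes on the
origin-centred benchmark functions: once progress stalls near the
optimum, repeated greedy multiplication by ``O < 1`` collapses the best
position geometrically until it underflows to 0.0 in double precision.

With ``mutation_prob = 0`` and the stagnation window at least as long as
the run (which disables the whole escape suite), the enhanced optimizer
consumes exactly the same random stream as the canonical one and is
bitwise identical to it on shared seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .gwo import GWOConfig, OptResult, WolfPack, _evaluate, gwo_optimize
from .levy import LevyParams, levy_step

__all__ = [
    "LGWOConfig",
    "StagnationState",
    "weight_factor",
    "levy_restart",
    "greedy_levy_update",
    "opposition",
    "drift_update",
    "contraction_update",
    "hho_mutation",
    "lgwo_optimize",
]


@dataclass
class LGWOConfig(GWOConfig):
    """Enhanced-optimizer configuration.

    ``ws``/``we`` are the start/end values of the weight-factor bracket,
    ``a_const``/``b_const`` its arctan offset and slope.  ``literal_weight``
    switches the bracket to the literal ``arctan(.) * 2 pi`` reading
    (study only; it oscillates far outside [we, ws]).  Stagnation is
    declared when the best fitness improves by less than
    ``stagnation_tol * max(1, |previous best|)`` over
    ``stagnation_window`` consecutive iterations.
    """

    ws: float = 1.5
    we: float = 0.1
    a_const: float = 1.0
    b_const: float = 0.01
    beta_levy: float = 1.5
    levy_scale: float = 0.01
    mutation_prob: float = 0.1
    stagnation_window: int = 5
    stagnation_tol: float = 1e-12
    literal_weight: bool = False

    def validate(self) -> None:
        super().validate()
        if not 0.0 < self.we < self.ws:
            raise ValueError("require 0 < we < ws")
        if not 0.0 <= self.mutation_prob <= 1.0:
            raise ValueError("mutation_prob must be a probability")
        if self.stagnation_window < 1:
            raise ValueError("stagnation_window must be >= 1")


@dataclass
class StagnationState:
    """Sliding window over recent best fitnesses with its trigger flag."""

    window: int
    tol: float = 1e-12
    best_history: list = None
    triggered: bool = False

    def __post_init__(self):
        if self.best_history is None:
            self.best_history = []

    def update(self, best_fitness: float) -> bool:
        """Record the iteration's best fitness; return the trigger state.

        Triggered iff the window is full and the improvement from the
        oldest to the newest entry is below ``tol * max(1, |oldest|)`` —
        a relative-improvement test whose denominator is floored at 1 so
        it remains meaningful when the best fitness is below machine
        scale.
        """
        self.best_history.append(float(best_fitness))
        if len(self.best_history) > self.window + 1:
            del self.best_history[: -self.window - 1]
        if len(self.best_history) < self.window + 1:
            self.triggered = False
        else:
            old, new = self.best_history[0], self.best_history[-1]
            self.triggered = (old - new) < self.tol * max(1.0, abs(old))
        return self.triggered


def weight_factor(t: int, cfg: LGWOConfig) -> float:
    """Arctan-decayed weight factor O(t).

    The arctan is normalised by 2/pi so the bracket decays monotonically
    from near ``ws`` toward ``we``; the literal ``* 2 pi`` reading is kept
    behind ``cfg.literal_weight`` for study.
    """
    inner = np.arctan(cfg.a_const + cfg.b_const * t)
    inner = inner * (2.0 * np.pi) if cfg.literal_weight else inner * (2.0 / np.pi)
    bracket = cfg.ws - (cfg.ws - cfg.we) * inner
    return float((cfg.max_iter - 2.0) / cfg.max_iter * bracket**2)


def levy_restart(
    x: np.ndarray,
    x_alpha: np.ndarray,
    rng: np.random.Generator,
    cfg: LGWOConfig,
) -> np.ndarray:
    """Heavy-tailed displacement ``scale * step (.) (x - x_alpha)``.

    Per-coordinate Levy draws; the caller adds the displacement to the
    wolf's position and clamps to bounds.
    """
    params = LevyParams(beta=cfg.beta_levy, scale=cfg.levy_scale)
    step = levy_step(rng, params, x.size)
    return cfg.levy_scale * step * (x - x_alpha)


def greedy_levy_update(
    x_best: np.ndarray, x_worst: np.ndarray, O: float, L: float
) -> np.ndarray:
    """Candidate ``x_best + O L (x_best - x_worst)`` (greedy at call site)."""
    return x_best + O * L * (x_best - x_worst)


def opposition(x_best: np.ndarray, cfg: LGWOConfig, L: float) -> np.ndarray:
    """Opposition-based candidate ``ub + lb - L x_best`` per coordinate."""
    return cfg.upper + cfg.lower - L * x_best


def drift_update(x: np.ndarray, x_best: np.ndarray, L: float) -> np.ndarray:
    """Drift toward the best: ``x + L (x_best - x)``."""
    return x + L * (x_best - x)


def contraction_update(x: np.ndarray, O: float) -> np.ndarray:
    """Geometric contraction ``O x`` per coordinate."""
    return O * x


def hho_mutation(
    x: np.ndarray,
    x_r: np.ndarray,
    x_best: np.ndarray,
    x_mean: np.ndarray,
    cfg: LGWOConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Harris-Hawks-style mutation pair.

    ``x3 = x_r - r1 |x_r - 2 r2 x|`` perturbs around a random pack mate;
    ``x4 = (x_best - x_mean) - r3 ((ub - lb) r4 + lb)`` jumps relative to
    the pack centroid with a full-range random offset.  Every ``rand`` is
    an independent scalar uniform(0,1) draw, the Harris-Hawks convention
    (each occurrence shared across coordinates).
    """
    r1, r2, r3, r4 = rng.random(4)
    x3 = x_r - r1 * np.abs(x_r - 2.0 * r2 * x)
    x4 = (x_best - x_mean) - r3 * ((cfg.upper - cfg.lower) * r4 + cfg.lower)
    return x3, x4


def _clamp(x: np.ndarray, cfg: LGWOConfig) -> np.ndarray:
    if cfg.clamp:
        return np.clip(x, cfg.lower, cfg.upper)
    return x


def lgwo_optimize(objective: Callable, config: LGWOConfig) -> OptResult:
    """Run the enhanced optimizer; deterministic given ``config.seed``."""
    config.validate()
    levy_params = LevyParams(beta=config.beta_levy, scale=config.levy_scale)
    stag = StagnationState(window=config.stagnation_window, tol=config.stagnation_tol)

    # The escape suite (Levy restarts, best-wolf Levy/opposition jumps,
    # per-wolf drift/contraction) is enabled as a whole only when the
    # stagnation window fits inside the budget; a window >= max_iter
    # disables it, reducing the optimizer to the canonical sweep (plus
    # mutation when mutation_prob > 0).
    escape_enabled = config.stagnation_window < config.max_iter

    def scalar_levy() -> float:
        return float(levy_step(rng_box[0], levy_params, 1)[0])

    rng_box = [None]

    def hooks(
        pack: WolfPack,
        t: int,
        rng: np.random.Generator,
        best_pos: np.ndarray,
        best_fit: float,
    ) -> int:
        rng_box[0] = rng
        extra = 0

        if escape_enabled:
            # Elitist greedy retention: if the sweep washed the incumbent
            # best out of the pack, re-seat it in the worst wolf's slot so
            # the superior solution is retained as the optimal choice.
            if best_fit < float(np.min(pack.fitness)):
                wi = int(np.argmax(pack.fitness))
                pack.positions[wi] = best_pos.copy()
                pack.fitness[wi] = best_fit

            cur_best = min(best_fit, float(np.min(pack.fitness)))
            triggered = stag.update(cur_best)
            O = weight_factor(t, config)

            if triggered:
                # Levy-flight adjustment of the non-leader wolves.
                leaders = set(pack.leader_indices.tolist())
                alpha_pos = pack.positions[pack.leader_indices[0]].copy()
                for i in range(pack.positions.shape[0]):
                    if i in leaders:
                        continue
                    disp = levy_restart(pack.positions[i], alpha_pos, rng, config)
                    pack.positions[i] = _clamp(pack.positions[i] + disp, config)
                    pack.fitness[i] = _evaluate(objective, pack.positions[i])
                    extra += 1

            # Levy jump and opposition candidates for the incumbent best.
            bi = int(np.argmin(pack.fitness))
            wi = int(np.argmax(pack.fitness))
            cand = _clamp(
                greedy_levy_update(pack.positions[bi], pack.positions[wi], O, scalar_levy()),
                config,
            )
            f = _evaluate(objective, cand)
            extra += 1
            if f < pack.fitness[bi]:
                pack.positions[bi], pack.fitness[bi] = cand, f

            cand = _clamp(opposition(pack.positions[bi], config, scalar_levy()), config)
            f = _evaluate(objective, cand)
            extra += 1
            if f < pack.fitness[bi]:
                pack.positions[bi], pack.fitness[bi] = cand, f

            # Per-wolf drift and contraction moves, greedily accepted.
            x_best = pack.positions[int(np.argmin(pack.fitness))].copy()
            for i in range(pack.positions.shape[0]):
                x1 = _clamp(drift_update(pack.positions[i], x_best, scalar_levy()), config)
                x2 = _clamp(contraction_update(pack.positions[i], O), config)
                f1 = _evaluate(objective, x1)
                f2 = _evaluate(objective, x2)
                extra += 2
                if f1 < pack.fitness[i] and f1 <= f2:
                    pack.positions[i], pack.fitness[i] = x1, f1
                elif f2 < pack.fitness[i]:
                    pack.positions[i], pack.fitness[i] = x2, f2

        # Harris-Hawks-style mutation, every iteration, probability pp per wolf.
        if config.mutation_prob > 0.0:
            n = pack.positions.shape[0]
            x_best = pack.positions[int(np.argmin(pack.fitness))].copy()
            x_mean = pack.positions.mean(axis=0)
            for i in range(n):
                q = rng.random()
                if q >= config.mutation_prob:
                    continue
                j = int(rng.integers(n - 1))
                if j >= i:
                    j += 1
                x3, x4 = hho_mutation(
                    pack.positions[i], pack.positions[j], x_best, x_mean, config, rng
                )
                x3, x4 = _clamp(x3, config), _clamp(x4, config)
                f3 = _evaluate(objective, x3)
                f4 = _evaluate(objective, x4)
                extra += 2
                if f3 < pack.fitness[i] and f3 <= f4:
                    pack.positions[i], pack.fitness[i] = x3, f3
                elif f4 < pack.fitness[i]:
                    pack.positions[i], pack.fitness[i] = x4, f4

        return extra

    result = gwo_optimize(objective, config, _hooks=hooks)
    result.meta["optimizer"] = "lgwo"
    return result
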