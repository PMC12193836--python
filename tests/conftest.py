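import dataclasses

import numpy as np
import pytest

from levywolf import benchmarks
from levywolf.lgwo import LGWOConfig, lgwo_optimize
from levywolf.synthetic_data import fixtures


@pytest.fixture(scope="session")
def fixture_tables():
    return fixtures()


@pytest.fixture(scope="session")
def lgwo_protocol():
    """Run the full repeated-run protocol once per function and cache it.

    30 agents, 500 iterations, seeds 1..30, clamped bounds, default
    enhancement parameters — the configuration of the benchmark study.
    """
    cache = {}

    def run(fid: str, n_runs: int = 30) -> np.ndarray:
        key = (fid, n_runs)
        if key not in cache:
            fn = benchmarks.get_function(fid)
            finals = np.empty(n_runs)
            for k, seed in enumerate(range(1, n_runs + 1)):
                cfg = LGWOConfig(
                    dim=fn.dim,
                    lower=fn.lower,
                    upper=fn.upper,
                    n_agents=30,
                    max_iter=500,
                    seed=seed,
                )
                noise_rng = np.random.default_rng(seed + 10_000_019) if fn.noisy else None
                objective = benchmarks.make_objective(fn, noise_rng)
                finals[k] = lgwo_optimize(objective, cfg).best_fitness
            cache[key] = finals
        return cache[key]

    return run


class CyclingRng:
    """Deterministic stand-in for a Generator: cycles through given uniforms."""

    def __init__(self, values):
        self.values = list(values)
        self.i = 0

    def random(self, size=None):
        if size is None:
            v = self.values[self.i % len(self.values)]
            self.i += 1
            return v
        out = np.array([self.random() for _ in range(int(np.prod(size)))])
        return out.reshape(size)


@pytest.fixture
def cycling_rng():
    return CyclingRng
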