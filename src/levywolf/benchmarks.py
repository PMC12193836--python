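"""Registry of the 18 benchmark objectives used to exercise the optimizers.

The suite is the classic mix of unimodal (f1-f6), high-dimensional
multimodal (f7-f11) and fixed-dimension multimodal (f12-f18) test
functions: sphere, Schwefel problems 2.22/1.2/2.21, Rosenbrock, noisy
quartic, Schwefel, Rastrigin, Ackley, Griewank, a penalized function,
Shekel's foxholes, Kowalik, six-hump camel, Branin, Goldstein-Price and
the Hartmann 3-/6-dimensional families.  Each entry carries its
dimension, a scalar per-coordinate box bound pair and the literature
value of the global minimum.

Only f6 is stochastic (an additive uniform[0,1) noise term); its
evaluator draws from a caller-supplied random stream so that runs remain
reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = [
    "BenchmarkFunction",
    "FUNCTION_IDS",
    "get_function",
    "evaluate",
    "make_objective",
    "registry_json",
    "known_minimizer",
]


@dataclass(frozen=True)
class BenchmarkFunction:
    """A benchmark objective with box bounds and known global minimum."""

    id: str
    name: str
    dim: int
    lower: float
    upper: float
    known_optimum: float
    noisy: bool = False
    _evaluator: Optional[Callable] = None

    def __call__(self, x: np.ndarray, rng: Optional[np.random.Generator] = None) -> float:
        return evaluate(self, x, rng)


def _f1(x):
    return float(np.sum(x * x))


def _f2(x):
    ax = np.abs(x)
    return float(np.sum(ax) + np.prod(ax))


def _f3(x):
    return float(np.sum(np.cumsum(x) ** 2))


def _f4(x):
    # printed garbled in the source table; standard Schwefel 2.21 max|x_i|
    return float(np.max(np.abs(x)))


def _f5(x):
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2))


def _f6(x, rng):
    i = np.arange(1, x.size + 1)
    noise = rng.random() if rng is not None else 0.0
    return float(np.sum(i * x**4) + noise)


def _f7(x):
    return float(-np.sum(x * np.sin(np.sqrt(np.abs(x)))))


def _f8(x):
    return float(np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x) + 10.0))


def _f9(x):
    n = x.size
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x * x) / n))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / n)
        + 20.0
        + math.e
    )


def _f10(x):
    i = np.arange(1, x.size + 1)
    return float(np.sum(x * x) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0)


def _penalty(x, a, k, m):
    out = np.zeros_like(x)
    hi = x > a
    lo = x < -a
    out[hi] = k * (x[hi] - a) ** m
    out[lo] = k * (-x[lo] - a) ** m
    return np.sum(out)


def _f11(x):
    term = (
        np.sin(3.0 * np.pi * x[0]) ** 2
        + np.sum((x[:-1] - 1.0) ** 2 * (1.0 + np.sin(3.0 * np.pi * x[1:]) ** 2))
        + (x[-1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * x[-1]) ** 2)
    )
    return float(0.1 * term + _penalty(x, 5.0, 100.0, 4.0))


# Shekel's foxholes grid (25 holes on {-32,-16,0,16,32}^2); standard constants.
_FOXHOLES_A = np.array(
    [
        np.tile([-32.0, -16.0, 0.0, 16.0, 32.0], 5),
        np.repeat([-32.0, -16.0, 0.0, 16.0, 32.0], 5),
    ]
)


def _f12(x):
    j = np.arange(1, 26)
    denom = j + np.sum((x[:, None] - _FOXHOLES_A) ** 6, axis=0)
    return float(1.0 / (1.0 / 500.0 + np.sum(1.0 / denom)))


# Kowalik's 11 calibration points; standard constants.
_KOWALIK_A = np.array(
    [0.1957, 0.1947, 0.1735, 0.1600, 0.0844, 0.0627, 0.0456, 0.0342, 0.0323, 0.0235, 0.0246]
)
_KOWALIK_B = 1.0 / np.array([0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0])


def _f13(x):
    b = _KOWALIK_B
    model = x[0] * (b * b + b * x[1]) / (b * b + b * x[2] + x[3])
    return float(np.sum((_KOWALIK_A - model) ** 2))


def _f14(x):
    x1, x2 = x
    return float(
        4.0 * x1**2 - 2.1 * x1**4 + x1**6 / 3.0 + x1 * x2 - 4.0 * x2**2 + 4.0 * x2**4
    )


def _f15(x):
    x1, x2 = x
    return float(
        (x2 - 5.1 / (4.0 * np.pi**2) * x1**2 + 5.0 / np.pi * x1 - 6.0) ** 2
        + 10.0 * (1.0 - 1.0 / (8.0 * np.pi)) * np.cos(x1)
        + 10.0
    )


def _f16(x):
    x1, x2 = x
    a = 1.0 + (x1 + x2 + 1.0) ** 2 * (
        19.0 - 14.0 * x1 + 3.0 * x1**2 - 14.0 * x2 + 6.0 * x1 * x2 + 3.0 * x2**2
    )
    b = 30.0 + (2.0 * x1 - 3.0 * x2) ** 2 * (
        18.0 - 32.0 * x1 + 12.0 * x1**2 + 48.0 * x2 - 36.0 * x1 * x2 + 27.0 * x2**2
    )
    return float(a * b)


# Hartmann family; standard constants.
_H3_A = np.array([[3.0, 10.0, 30.0], [0.1, 10.0, 35.0], [3.0, 10.0, 30.0], [0.1, 10.0, 35.0]])
_H3_P = np.array(
    [
        [0.3689, 0.1170, 0.2673],
        [0.4699, 0.4387, 0.7470],
        [0.1091, 0.8732, 0.5547],
        [0.0381, 0.5743, 0.8828],
    ]
)
_H_C = np.array([1.0, 1.2, 3.0, 3.2])
_H6_A = np.array(
    [
        [10.0, 3.0, 17.0, 3.5, 1.7, 8.0],
        [0.05, 10.0, 17.0, 0.1, 8.0, 14.0],
        [3.0, 3.5, 1.7, 10.0, 17.0, 8.0],
        [17.0, 8.0, 0.05, 10.0, 0.1, 14.0],
    ]
)
_H6_P = np.array(
    [
        [0.1312, 0.1696, 0.5569, 0.0124, 0.8283, 0.5886],
        [0.2329, 0.4135, 0.8307, 0.3736, 0.1004, 0.9991],
        [0.2348, 0.1451, 0.3522, 0.2883, 0.3047, 0.6650],
        [0.4047, 0.8828, 0.8732, 0.5743, 0.1091, 0.0381],
    ]
)


def _f17(x):
    return float(-np.sum(_H_C * np.exp(-np.sum(_H3_A * (x - _H3_P) ** 2, axis=1))))


def _f18(x):
    return float(-np.sum(_H_C * np.exp(-np.sum(_H6_A * (x - _H6_P) ** 2, axis=1))))


_REGISTRY: dict[str, BenchmarkFunction] = {}


def _register(fid, name, dim, lower, upper, optimum, evaluator, noisy=False):
    _REGISTRY[fid] = BenchmarkFunction(
        id=fid,
        name=name,
        dim=dim,
        lower=float(lower),
        upper=float(upper),
        known_optimum=float(optimum),
        noisy=noisy,
        _evaluator=evaluator,
    )


_register("f1", "sphere", 30, -100, 100, 0.0, _f1)
_register("f2", "schwefel_2_22", 30, -10, 10, 0.0, _f2)
_register("f3", "schwefel_1_2", 30, -100, 100, 0.0, _f3)
_register("f4", "schwefel_2_21", 30, -100, 100, 0.0, _f4)
_register("f5", "rosenbrock", 30, -30, 30, 0.0, _f5)
_register("f6", "noisy_quartic", 30, -1.28, 1.28, 0.0, _f6, noisy=True)
_register("f7", "schwefel", 30, -500, 500, -12569.4866, _f7)
_register("f8", "rastrigin", 30, -5.12, 5.12, 0.0, _f8)
_register("f9", "ackley", 30, -32, 32, 0.0, _f9)
_register("f10", "griewank", 30, -600, 600, 0.0, _f10)
_register("f11", "penalized", 30, -50, 50, 0.0, _f11)
_register("f12", "shekel_foxholes", 2, -65, 65, 0.998004, _f12)
_register("f13", "kowalik", 4, -5, 5, 3.0749e-4, _f13)
_register("f14", "six_hump_camel", 2, -5, 5, -1.031628, _f14)
_register("f15", "branin", 2, -5, 5, 0.397887, _f15)
_register("f16", "goldstein_price", 2, -2, 2, 3.0, _f16)
_register("f17", "hartmann_3", 3, 0, 1, -3.86278, _f17)
_register("f18", "hartmann_6", 6, 0, 1, -3.32237, _f18)

FUNCTION_IDS = tuple(_REGISTRY)

# Literature global minimizers (used by tests; f6 omitted: noisy).
_MINIMIZERS: dict[str, np.ndarray] = {
    "f1": np.zeros(30),
    "f2": np.zeros(30),
    "f3": np.zeros(30),
    "f4": np.zeros(30),
    "f5": np.ones(30),
    "f7": np.full(30, 420.9687),
    "f8": np.zeros(30),
    "f9": np.zeros(30),
    "f10": np.zeros(30),
    "f11": np.ones(30),
    "f12": np.array([-32.0, -32.0]),
    "f13": np.array([0.192833, 0.190836, 0.123117, 0.135766]),
    "f14": np.array([0.08984201, -0.7126564]),
    "f15": np.array([np.pi, 2.275]),
    "f16": np.array([0.0, -1.0]),
    "f17": np.array([0.114614, 0.555649, 0.852547]),
    "f18": np.array([0.20169, 0.150011, 0.476874, 0.275332, 0.311652, 0.6573]),
}


def get_function(fid: str) -> BenchmarkFunction:
    """Look up a benchmark function by identifier (``f1`` .. ``f18``)."""
    try:
        return _REGISTRY[fid]
    except KeyError:
        raise KeyError(f"unknown benchmark function id: {fid!r}") from None


def known_minimizer(fid: str) -> np.ndarray:
    """Literature global minimizer for a non-noisy function."""
    return _MINIMIZERS[fid].copy()


def evaluate(
    fn: BenchmarkFunction, x: np.ndarray, rng: Optional[np.random.Generator] = None
) -> float:
    """Evaluate ``fn`` at a vector of length ``fn.dim``.

    For the noisy quartic (f6) the additive uniform[0,1) term is drawn
    from ``rng``; omitting the stream drops the noise term.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (fn.dim,):
        raise ValueError(f"{fn.id} expects a vector of length {fn.dim}, got shape {x.shape}")
    if not np.isfinite(x).all():
        raise ValueError("input vector contains non-finite values")
    if fn.noisy:
        return fn._evaluator(x, rng)
    return fn._evaluator(x)


def make_objective(fn: BenchmarkFunction, rng: Optional[np.random.Generator] = None) -> Callable:
    """Bind a benchmark to an ``objective(x) -> float`` closure.

    Skips the public shape/finiteness validation in the returned hot-path
    callable; optimizer engines only ever feed in-bounds vectors of the
    right length.
    """
    if fn.noisy:
        ev = fn._evaluator
        return lambda x: ev(x, rng)
    return fn._evaluator


def registry_json() -> str:
    """Machine-readable dump of the registry (id, name, dim, bounds, optimum)."""
    rows = [
        {
            "id": f.id,
            "name": f.name,
            "dim": f.dim,
            "lower": f.lower,
            "upper": f.upper,
            "known_optimum": f.known_optimum,
            "noisy": f.noisy,
        }
        for f in _REGISTRY.values()
    ]
    return json.dumps(rows, indent=2)
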