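"""Levy-stable step sampling via the Mantegna construction.

Heavy-tailed steps ``u / |v|^(1/beta)`` with ``u ~ N(0, sigma_u^2)`` and
``v ~ N(0, 1)`` approximate a symmetric Levy-stable law with tail index
``beta``; the closed-form scale

    sigma_u = [ Gamma(1+beta) sin(pi beta / 2)
                / (Gamma((1+beta)/2) beta 2^((beta-1)/2)) ]^(1/beta)

makes the ratio's tail decay as |s|^(-1-beta).  The stagnation-escape
moves of the enhanced optimizer draw their jump lengths from this
sampler.  ``gamma``/``mu`` are the scale and location parameters of the
underlying Levy density and are carried for documentation; the sampler
realizes the standardised law.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma

__all__ = ["LevyParams", "mantegna_sigma", "levy_step"]


def mantegna_sigma(beta: float) -> float:
    """Mantegna normal-numerator scale for tail index ``beta`` in (0, 2].

    ``beta = 2`` is degenerate (sin(pi) = 0 gives sigma_u = 0, a Gaussian
    collapse); it is accepted here but rejected by the sampler.
    """
    if not 0.0 < beta <= 2.0:
        raise ValueError(f"beta must be in (0, 2], got {beta}")
    num = _gamma(1.0 + beta) * np.sin(np.pi * beta / 2.0)
    den = _gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return float((num / den) ** (1.0 / beta))


@dataclass(frozen=True)
class LevyParams:
    """Parameters of the Levy step sampler.

    ``scale`` is the overall step multiplier applied by callers (the 0.01
    of the optimizer's escape move); ``sigma_u`` is derived from ``beta``.
    """

    beta: float = 1.5
    scale: float = 0.01
    gamma: float = 1.0
    mu: float = 0.0
    sigma_u: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma_u", mantegna_sigma(self.beta))


def levy_step(rng: np.random.Generator, params: LevyParams, count: int) -> np.ndarray:
    """Draw ``count`` Levy steps ``u / |v|^(1/beta)``.

    The sign comes from the normal numerator ``u``; the denominator uses
    ``|v|`` before the fractional power so negative draws stay real.
    Deterministic given the generator state.
    """
    if params.beta >= 2.0:
        raise ValueError("sampling requires beta < 2 (beta = 2 is the degenerate Gaussian case)")
    if count < 1:
        raise ValueError("count must be positive")
    u = rng.normal(0.0, params.sigma_u, size=count)
    v = rng.normal(0.0, 1.0, size=count)
    return u / np.abs(v) ** (1.0 / params.beta)
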