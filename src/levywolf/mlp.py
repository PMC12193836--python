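"""Single-hidden-layer sigmoid network and its hybrid training loop.

The network maps a feature vector through one sigmoid hidden layer and a
sigmoid output unit,

    Y_n = f( sum_m  w_nm f( sum_l v_ml X_l + theta_v_m ) + theta_w_n ),
    f(x) = 1 / (1 + exp(-x)),

and all of its weights and biases live in one flat real vector with the
layout ``[v (h x i), theta_v (h), w (o x h), theta_w (o)]``.  A
metaheuristic (the Levy-enhanced or the canonical grey wolf optimizer)
searches this vector globally against the mean-squared training error;
plain full-batch gradient descent (classical backpropagation) then
refines the incumbent locally.  For binary prognosis tasks the network
has a single output unit and class 1 is predicted where the output meets
the decision threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from scipy.special import expit

from .data import LabeledTable
from .gwo import GWOConfig, OptResult, gwo_optimize
from .lgwo import LGWOConfig, lgwo_optimize

__all__ = [
    "NetworkShape",
    "n_params",
    "sigmoid",
    "decode",
    "forward",
    "fitness",
    "bp_refine",
    "train",
    "predict",
]


@dataclass(frozen=True)
class NetworkShape:
    """Layer sizes: inputs ``n_in``, hidden units ``n_hidden``, outputs ``n_out``."""

    n_in: int
    n_hidden: int = 6
    n_out: int = 1

    def __post_init__(self):
        if min(self.n_in, self.n_hidden, self.n_out) < 1:
            raise ValueError("all layer sizes must be positive")


def n_params(shape: NetworkShape) -> int:
    """Length of the flat parameter vector: h*i + h + o*h + o."""
    h, i, o = shape.n_hidden, shape.n_in, shape.n_out
    return h * i + h + o * h + o


def sigmoid(x):
    """Logistic function 1/(1+exp(-x)), stable for large |x|."""
    return expit(x)


def decode(params: np.ndarray, shape: NetworkShape):
    """Split a flat vector into (V, theta_v, W, theta_w); views, no copy."""
    params = np.asarray(params, dtype=float)
    if params.shape != (n_params(shape),):
        raise ValueError(
            f"parameter vector must have length {n_params(shape)}, got {params.shape}"
        )
    h, i, o = shape.n_hidden, shape.n_in, shape.n_out
    k = 0
    V = params[k : k + h * i].reshape(h, i)
    k += h * i
    tv = params[k : k + h]
    k += h
    W = params[k : k + o * h].reshape(o, h)
    k += o * h
    tw = params[k : k + o]
    return V, tv, W, tw


def encode(V, tv, W, tw) -> np.ndarray:
    """Inverse of :func:`decode`; exact round trip."""
    return np.concatenate([np.ravel(V), np.ravel(tv), np.ravel(W), np.ravel(tw)])


def forward(params: np.ndarray, shape: NetworkShape, X: np.ndarray) -> np.ndarray:
    """Network outputs for each row of ``X``; an (n, n_out) matrix in (0,1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != shape.n_in:
        raise ValueError(f"X has {X.shape[1]} columns, network expects {shape.n_in}")
    V, tv, W, tw = decode(params, shape)
    H = expit(X @ V.T + tv)
    return expit(H @ W.T + tw)


def fitness(
    params: np.ndarray,
    shape: NetworkShape,
    data: LabeledTable,
    loss: str = "mse",
) -> float:
    """Training error of the network on ``data`` (to be minimized).

    ``mse`` (default) is the classical squared-error loss on the sigmoid
    output against the 0/1 labels; ``cross_entropy`` is the Bernoulli
    log-loss alternative.
    """
    if data.n_samples == 0:
        raise ValueError("data must be nonempty")
    Y = forward(params, shape, data.features)
    y = data.labels.reshape(-1, 1).astype(float)
    if loss == "mse":
        return float(np.mean((Y - y) ** 2))
    if loss == "cross_entropy":
        eps = 1e-12
        Yc = np.clip(Y, eps, 1.0 - eps)
        return float(-np.mean(y * np.log(Yc) + (1.0 - y) * np.log(1.0 - Yc)))
    raise ValueError(f"unknown loss: {loss!r}")


def _gradient(params, shape, X, y, loss):
    V, tv, W, tw = decode(params, shape)
    H = expit(X @ V.T + tv)
    Y = expit(H @ W.T + tw)
    n, o = Y.shape
    if loss == "mse":
        dZ = (Y - y) * Y * (1.0 - Y) * (2.0 / (n * o))
    else:  # cross_entropy; sigmoid + log-loss cancels to a linear residual
        dZ = (Y - y) / (n * o)
    gW = dZ.T @ H
    gtw = dZ.sum(axis=0)
    dH = (dZ @ W) * H * (1.0 - H)
    gV = dH.T @ X
    gtv = dH.sum(axis=0)
    return encode(gV, gtv, gW, gtw)


def bp_refine(
    params: np.ndarray,
    shape: NetworkShape,
    data: LabeledTable,
    lr: float = 0.5,
    epochs: int = 500,
    loss: str = "mse",
) -> np.ndarray:
    """Full-batch gradient descent on the training error.

    Returns a refined copy of the parameter vector; ``lr = 0`` or
    ``epochs = 0`` returns the input unchanged.
    """
    if lr < 0:
        raise ValueError("learning rate must be non-negative")
    p = np.asarray(params, dtype=float).copy()
    if lr == 0.0 or epochs == 0:
        return p
    X = data.features
    y = data.labels.reshape(-1, 1).astype(float)
    for _ in range(epochs):
        p -= lr * _gradient(p, shape, X, y, loss)
    return p


def train(
    data: LabeledTable,
    shape: NetworkShape,
    opt_cfg: Union[GWOConfig, LGWOConfig],
    optimizer: Optional[str] = None,
    refine: tuple[float, int] = (0.5, 500),
    loss: str = "mse",
) -> tuple[np.ndarray, OptResult]:
    """Hybrid training: global metaheuristic search, then local refinement.

    ``opt_cfg.dim`` must equal the parameter count for ``shape``; the
    optimizer is chosen by ``optimizer`` ('lgwo' or 'gwo'; default
    'lgwo' when ``opt_cfg`` is an :class:`LGWOConfig`).  ``refine`` is the
    (learning rate, epochs) pair of the gradient-descent stage; pass
    ``(0, 0)`` to disable it.  Features are used as given — callers are
    expected to scale them to [0, 1] (the sklearn estimator wrapper does
    this automatically).
    """
    want = n_params(shape)
    if opt_cfg.dim != want:
        raise ValueError(f"opt_cfg.dim={opt_cfg.dim} but the network needs {want} parameters")
    if optimizer is None:
        optimizer = "lgwo" if isinstance(opt_cfg, LGWOConfig) else "gwo"

    objective: Callable = lambda p: fitness(p, shape, data, loss=loss)
    if optimizer == "lgwo":
        result = lgwo_optimize(objective, opt_cfg)
    elif optimizer == "gwo":
        result = gwo_optimize(objective, opt_cfg)
    else:
        raise ValueError(f"unknown optimizer: {optimizer!r}")

    params = result.best_position.copy()
    lr, epochs = refine
    if lr > 0 and epochs > 0:
        params = bp_refine(params, shape, data, lr=lr, epochs=epochs, loss=loss)
    return params, result


def predict(
    params: np.ndarray,
    shape: NetworkShape,
    X: np.ndarray,
    threshold: float = 0.5,
) -> np.ndarray:
    """Threshold the network output: label 1 where output >= threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    return (forward(params, shape, X)[:, 0] >= threshold).astype(int)
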