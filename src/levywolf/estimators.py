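"""scikit-learn compatible wrappers around the hybrid trainer and selector.

:class:`GreyWolfMLPClassifier` packages the full training recipe — per
column min-max scaling to [0, 1], metaheuristic weight search inside the
[-1, 1] box, gradient-descent refinement, sigmoid-output thresholding —
behind the usual ``fit`` / ``predict`` / ``predict_proba`` surface so it
composes with pipelines and model selection.  :class:`PearsonTopK` is
the matching transformer for correlation-based top-k feature selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .data import LabeledTable
from .feature_selection import rank_features
from .gwo import GWOConfig
from .lgwo import LGWOConfig
from .mlp import NetworkShape, forward, n_params, train

__all__ = ["GreyWolfMLPClassifier", "PearsonTopK", "save_model", "load_model"]


class GreyWolfMLPClassifier(ClassifierMixin, BaseEstimator):
    """Single-hidden-layer sigmoid network trained by a grey-wolf search.

    Parameters
    ----------
    optimizer : 'lgwo' or 'gwo'
        Levy-enhanced or canonical grey wolf optimizer for the global
        weight search.
    n_hidden : int
        Hidden-layer width (default 6).
    n_agents, n_iterations : int
        Pack size and iteration budget of the search (defaults 5 and 30,
        the network-training configuration).
    weight_bound : float
        Search box half-width; weights are confined to
        [-weight_bound, weight_bound].
    refine_lr, refine_epochs : float, int
        Learning rate and epoch count of the backpropagation refinement
        stage; set ``refine_epochs=0`` to disable.
    threshold : float
        Output threshold mapping the sigmoid score to class 1 (ties to
        positive).
    loss : 'mse' or 'cross_entropy'
        Training error minimized by both stages.
    ws, we, a_const, b_const, beta_levy, levy_scale, mutation_prob,
    stagnation_window :
        Enhancement parameters, forwarded to the optimizer ('lgwo' only).
    random_state : int or None
        Seed for the whole run.
    """

    def __init__(
        self,
        optimizer: str = "lgwo",
        n_hidden: int = 6,
        n_agents: int = 5,
        n_iterations: int = 30,
        weight_bound: float = 1.0,
        refine_lr: float = 0.5,
        refine_epochs: int = 500,
        threshold: float = 0.5,
        loss: str = "mse",
        ws: float = 1.5,
        we: float = 0.1,
        a_const: float = 1.0,
        b_const: float = 0.01,
        beta_levy: float = 1.5,
        levy_scale: float = 0.01,
        mutation_prob: float = 0.1,
        stagnation_window: int = 5,
        random_state=None,
    ):
        self.optimizer = optimizer
        self.n_hidden = n_hidden
        self.n_agents = n_agents
        self.n_iterations = n_iterations
        self.weight_bound = weight_bound
        self.refine_lr = refine_lr
        self.refine_epochs = refine_epochs
        self.threshold = threshold
        self.loss = loss
        self.ws = ws
        self.we = we
        self.a_const = a_const
        self.b_const = b_const
        self.beta_levy = beta_levy
        self.levy_scale = levy_scale
        self.mutation_prob = mutation_prob
        self.stagnation_window = stagnation_window
        self.random_state = random_state

    def _make_config(self, dim: int, seed: int):
        common = dict(
            dim=dim,
            lower=-self.weight_bound,
            upper=self.weight_bound,
            n_agents=self.n_agents,
            max_iter=self.n_iterations,
            seed=seed,
        )
        if self.optimizer == "lgwo":
            return LGWOConfig(
                ws=self.ws,
                we=self.we,
                a_const=self.a_const,
                b_const=self.b_const,
                beta_levy=self.beta_levy,
                levy_scale=self.levy_scale,
                mutation_prob=self.mutation_prob,
                stagnation_window=self.stagnation_window,
                **common,
            )
        if self.optimizer == "gwo":
            return GWOConfig(**common)
        raise ValueError(f"unknown optimizer: {self.optimizer!r}")

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError(
                f"binary classifier requires exactly 2 classes, got {self.classes_.size}"
            )
        y01 = (y == self.classes_[1]).astype(int)
        self.n_features_in_ = X.shape[1]

        # min-max scale features to [0, 1]; constant columns map to 0
        self.data_min_ = X.min(axis=0)
        rng_ = X.max(axis=0) - self.data_min_
        self.data_range_ = np.where(rng_ == 0, 1.0, rng_)
        Xs = (X - self.data_min_) / self.data_range_

        if self.random_state is None:
            seed = int(np.random.default_rng().integers(2**31))
        else:
            seed = int(self.random_state)

        self.shape_ = NetworkShape(n_in=X.shape[1], n_hidden=self.n_hidden, n_out=1)
        cfg = self._make_config(n_params(self.shape_), seed)
        data = LabeledTable(features=Xs, labels=y01)
        self.params_, self.opt_result_ = train(
            data,
            self.shape_,
            cfg,
            optimizer=self.optimizer,
            refine=(self.refine_lr, self.refine_epochs),
            loss=self.loss,
        )
        self.curve_ = self.opt_result_.curve
        return self

    def _scores(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        Xs = (X - self.data_min_) / self.data_range_
        return forward(self.params_, self.shape_, Xs)[:, 0]

    def predict_proba(self, X) -> np.ndarray:
        p1 = self._scores(X)
        return np.column_stack([1.0 - p1, p1])

    def decision_function(self, X) -> np.ndarray:
        return self._scores(X)

    def predict(self, X) -> np.ndarray:
        hard = (self._scores(X) >= self.threshold).astype(int)
        return self.classes_[hard]


class PearsonTopK(TransformerMixin, BaseEstimator):
    """Select the k features most correlated (|Pearson r|) with the label."""

    def __init__(self, k: int = 30):
        self.k = k

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        table = LabeledTable(
            features=X, labels=(y == np.unique(y)[-1]).astype(int)
        )
        ranking, _ = rank_features(table, min(self.k, X.shape[1]))
        self.ranking_ = ranking
        name_to_idx = {n: i for i, n in enumerate(table.feature_names)}
        self.selected_idx_ = np.array([name_to_idx[n] for n in ranking.names])
        self.scores_ = ranking.importances
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "selected_idx_")
        X = check_array(X)
        return X[:, self.selected_idx_]


def save_model(clf: GreyWolfMLPClassifier, path) -> None:
    """Serialize a fitted classifier (shape, scaling, flat weights) to JSON."""
    import json

    check_is_fitted(clf, "params_")
    payload = {
        "shape": {
            "n_in": clf.shape_.n_in,
            "n_hidden": clf.shape_.n_hidden,
            "n_out": clf.shape_.n_out,
        },
        "data_min": clf.data_min_.tolist(),
        "data_range": clf.data_range_.tolist(),
        "params": clf.params_.tolist(),
        "classes": clf.classes_.tolist(),
        "threshold": clf.threshold,
        "optimizer": clf.optimizer,
        "seed": clf.opt_result_.seed,
        "hyperparameters": clf.get_params(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_model(path) -> GreyWolfMLPClassifier:
    """Restore a classifier saved by :func:`save_model` (ready to predict)."""
    import json

    with open(path) as fh:
        payload = json.load(fh)
    clf = GreyWolfMLPClassifier(**payload["hyperparameters"])
    clf.shape_ = NetworkShape(**payload["shape"])
    clf.params_ = np.asarray(payload["params"], dtype=float)
    clf.data_min_ = np.asarray(payload["data_min"], dtype=float)
    clf.data_range_ = np.asarray(payload["data_range"], dtype=float)
    clf.classes_ = np.asarray(payload["classes"])
    clf.n_features_in_ = clf.shape_.n_in
    return clf
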