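"""Gradient-free conv-net classifier trained by the improved grey wolf
optimizer.

:class:`IGWOConvNetClassifier` is a scikit-learn estimator: ``fit``
standardizes the inputs, then lets IGWO search the parameter box
``[-weight_bound, weight_bound]^P`` of the compact conv net
(:mod:`pulmopt.network`) with the training-set cross-entropy as the
objective; no backpropagation is involved.  ``predict`` takes the argmax
of the softmax output, breaking ties toward the lowest class index.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .network import NetworkSpec, cross_entropy_loss, forward, parameter_count
from .optim.core import Bounds, OptResult
from .optim.gwo import IGWOConfig, LeaderWeights, igwo_minimize

__all__ = ["IGWOConvNetClassifier", "save_model", "load_model"]


class IGWOConvNetClassifier(ClassifierMixin, BaseEstimator):
    """Tabular conv-net classifier with population-search training.

    Parameters
    ----------
    n_filters, kernel_size, hidden_units
        Conv-net architecture (see :class:`pulmopt.network.NetworkSpec`);
        the number of output classes is taken from ``y`` at fit time.
    weight_bound
        Half-width B of the search box ``[-B, B]`` for every network
        parameter.  ``B = 0`` degenerates to the all-zero network, which
        predicts the uniform distribution.
    pop_size, iterations, leader_weights, sigma0, sigma_min, p_sc
        IGWO settings (see :class:`pulmopt.optim.gwo.IGWOConfig`).
    scale
        Standardize features with training-set mean/sd before the net
        (constant columns map to zeros).
    random_state
        Seed for the optimizer run; fit is deterministic given it.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels.
    params_ : ndarray
        Best parameter vector found.
    norm_stats_ : dict
        Frozen batch-norm statistics of the training set under
        ``params_``.
    optimizer_result_ : OptResult
        Full training trace; its best fitness equals the training
        cross-entropy of ``params_``.
    """

    def __init__(
        self,
        n_filters: int = 4,
        kernel_size: int = 3,
        hidden_units: int = 8,
        weight_bound: float = 1.0,
        pop_size: int = 30,
        iterations: int = 300,
        leader_weights: tuple[float, float, float] = (0.5, 0.3, 0.2),
        sigma0: float | None = None,
        sigma_min: float | None = None,
        p_sc: float = 0.3,
        scale: bool = True,
        random_state: int | None = None,
    ):
        self.n_filters = n_filters
        self.kernel_size = kernel_size
        self.hidden_units = hidden_units
        self.weight_bound = weight_bound
        self.pop_size = pop_size
        self.iterations = iterations
        self.leader_weights = leader_weights
        self.sigma0 = sigma0
        self.sigma_min = sigma_min
        self.p_sc = p_sc
        self.scale = scale
        self.random_state = random_state

    def fit(self, X, y) -> "IGWOConvNetClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y must have the same number of rows")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("invalid labels: need at least 2 classes")
        self.n_features_in_ = X.shape[1]

        if self.scale:
            self.feature_means_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.feature_stds_ = np.where(sd == 0.0, 1.0, sd)
        else:
            self.feature_means_ = np.zeros(X.shape[1])
            self.feature_stds_ = np.ones(X.shape[1])
        Xs = (X - self.feature_means_) / self.feature_stds_

        self.spec_ = NetworkSpec(
            n_filters=self.n_filters,
            kernel_size=self.kernel_size,
            hidden_units=self.hidden_units,
            n_classes=int(self.classes_.size),
        )
        n_params = parameter_count(self.spec_, self.n_features_in_)

        if self.weight_bound < 0:
            raise ValueError("weight_bound must be >= 0")
        if self.weight_bound == 0:
            # degenerate box: the only feasible network is all-zero
            self.params_ = np.zeros(n_params)
            self.optimizer_result_ = OptResult(
                best_position=self.params_.copy(),
                best_fitness=cross_entropy_loss(self.params_, self.spec_, Xs, y_idx),
                trace=np.array(
                    [cross_entropy_loss(self.params_, self.spec_, Xs, y_idx)]
                ),
                iterations=0,
                n_evaluations=1,
                seed=self.random_state,
            )
        else:
            bounds = Bounds.cube(-self.weight_bound, self.weight_bound, n_params)
            config = IGWOConfig(
                pop_size=self.pop_size,
                iterations=self.iterations,
                weights=LeaderWeights(*self.leader_weights),
                sigma0=self.sigma0,
                sigma_min=self.sigma_min,
                p_sc=self.p_sc,
                seed=self.random_state,
            )

            def objective(params: np.ndarray) -> float:
                return cross_entropy_loss(params, self.spec_, Xs, y_idx)

            result = igwo_minimize(objective, bounds, config)
            self.params_ = result.best_position
            self.optimizer_result_ = result

        _, self.norm_stats_ = forward(self.params_, self.spec_, Xs)
        return self

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have {self.n_features_in_} columns, got {X.shape}"
            )
        return (X - self.feature_means_) / self.feature_stds_

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        probs, _ = forward(self.params_, self.spec_, self._transform(X), self.norm_stats_)
        return probs

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]

    def training_loss(self) -> float:
        """Cross-entropy of ``params_`` on the (standardized) training set,
        as recorded by the optimizer."""
        check_is_fitted(self, "optimizer_result_")
        return float(self.optimizer_result_.best_fitness)


def save_model(model: IGWOConvNetClassifier, path: str | Path) -> None:
    """Serialize a fitted model to JSON."""
    check_is_fitted(model, "params_")
    payload = {
        "spec": {
            "n_filters": model.spec_.n_filters,
            "kernel_size": model.spec_.kernel_size,
            "hidden_units": model.spec_.hidden_units,
            "n_classes": model.spec_.n_classes,
        },
        "params": model.params_.tolist(),
        "classes": model.classes_.tolist(),
        "n_features_in": model.n_features_in_,
        "feature_means": model.feature_means_.tolist(),
        "feature_stds": model.feature_stds_.tolist(),
        "norm_stats": {
            "mean": np.asarray(model.norm_stats_["mean"]).tolist(),
            "var": np.asarray(model.norm_stats_["var"]).tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> IGWOConvNetClassifier:
    """Rebuild a fitted model from :func:`save_model` output."""
    payload = json.loads(Path(path).read_text())
    spec = payload["spec"]
    model = IGWOConvNetClassifier(
        n_filters=spec["n_filters"],
        kernel_size=spec["kernel_size"],
        hidden_units=spec["hidden_units"],
    )
    model.spec_ = NetworkSpec(**spec)
    model.params_ = np.asarray(payload["params"], dtype=float)
    model.classes_ = np.asarray(payload["classes"])
    model.n_features_in_ = int(payload["n_features_in"])
    model.feature_means_ = np.asarray(payload["feature_means"], dtype=float)
    model.feature_stds_ = np.asarray(payload["feature_stds"], dtype=float)
    model.norm_stats_ = {
        "mean": np.asarray(payload["norm_stats"]["mean"], dtype=float),
        "var": np.asarray(payload["norm_stats"]["var"], dtype=float),
    }
    return model
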