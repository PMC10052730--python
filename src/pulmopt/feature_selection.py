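"""Wrapper feature selection driven by Tasmanian Devil Optimization.

The selector searches the continuous box ``[0, 1]^d``; a position is
binarized with a 0.5 threshold into a feature mask, scored by

    alpha * (stratified k-fold error of a 1-NN reference classifier on
             the masked features)  +  (1 - alpha) * (selected / d)

so ``alpha`` trades predictive error against sparsity.  An empty mask is
assigned a fitness of 2.0, worse than any feasible value.  Fold
assignments are fixed per fit and mask fitnesses are memoized, so the
search is deterministic given the seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .optim.core import Bounds
from .optim.tdo import TDOConfig, tdo_minimize

__all__ = ["FeatureMask", "TDOFeatureSelector", "tdo_select_features"]

_EMPTY_MASK_PENALTY = 2.0


@dataclass
class FeatureMask:
    """Boolean feature subset plus the continuous position it came from."""

    selected: np.ndarray
    position: np.ndarray
    feature_names: list[str] | None = None

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    def to_json(self) -> str:
        names = (
            self.feature_names
            if self.feature_names is not None
            else [str(i) for i in range(self.selected.size)]
        )
        return json.dumps(
            {
                "selected": [n for n, s in zip(names, self.selected) if s],
                "position": [float(v) for v in self.position],
            }
        )


class TDOFeatureSelector(SelectorMixin, BaseEstimator):
    """Select diagnosis-relevant feature columns with a TDO wrapper search.

    Parameters
    ----------
    alpha
        Weight of the cross-validated 1-NN error in the fitness
        (``1 - alpha`` weights the selected-fraction sparsity term).
    cv_folds
        Stratified folds of the wrapper evaluation.
    pop_size, iterations, p_explore
        TDO search settings.
    random_state
        Seed; the whole fit is deterministic given it.

    Attributes
    ----------
    support_ : bool ndarray of shape (d,)
        Selected columns (never empty).
    position_ : ndarray
        Continuous position the support was thresholded from.
    best_fitness_ : float
        Fitness of the returned mask.
    """

    def __init__(
        self,
        alpha: float = 0.9,
        cv_folds: int = 3,
        pop_size: int = 20,
        iterations: int = 60,
        p_explore: float = 0.5,
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.cv_folds = cv_folds
        self.pop_size = pop_size
        self.iterations = iterations
        self.p_explore = p_explore
        self.random_state = random_state

    def fit(self, X, y) -> "TDOFeatureSelector":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be a 2-D matrix with at least 2 columns")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("invalid labels: need at least 2 classes")
        n, d = X.shape
        if n < self.cv_folds * classes.size:
            raise ValueError(
                "too few samples: need n >= cv_folds * number of classes"
            )
        self.n_features_in_ = d

        alpha = self.alpha
        constant = np.all(X == X[0], axis=0)
        if constant.all():
            warnings.warn(
                "all feature columns are constant; selection falls back to "
                "the sparsity term only",
                UserWarning,
                stacklevel=2,
            )
            alpha = 0.0

        seed_seq = np.random.SeedSequence(self.random_state)
        fold_seed, search_seed = (
            int(s) for s in seed_seq.generate_state(2) % (2**31)
        )
        if alpha > 0:
            skf = StratifiedKFold(
                n_splits=self.cv_folds, shuffle=True, random_state=fold_seed
            )
            folds = list(skf.split(X, y_idx))
        else:
            folds = []

        cache: dict[bytes, float] = {}

        def cv_error(mask: np.ndarray) -> float:
            errors = []
            Xm = X[:, mask]
            for train, test in folds:
                knn = KNeighborsClassifier(n_neighbors=1)
                knn.fit(Xm[train], y_idx[train])
                errors.append(1.0 - knn.score(Xm[test], y_idx[test]))
            return float(np.mean(errors))

        def fitness(position: np.ndarray) -> float:
            mask = position > 0.5
            key = mask.tobytes()
            if key in cache:
                return cache[key]
            k = int(mask.sum())
            if k == 0:
                value = _EMPTY_MASK_PENALTY
            else:
                value = (1.0 - alpha) * k / d
                if alpha > 0:
                    value += alpha * cv_error(mask)
            cache[key] = value
            return value

        config = TDOConfig(
            pop_size=self.pop_size,
            iterations=self.iterations,
            p_explore=self.p_explore,
            seed=search_seed,
        )
        result = tdo_minimize(fitness, Bounds.cube(0.0, 1.0, d), config)

        mask = result.best_position > 0.5
        if not mask.any():
            # pathological: keep the strongest single coordinate
            mask[int(np.argmax(result.best_position))] = True
        self.support_ = mask
        self.position_ = result.best_position
        self.best_fitness_ = float(result.best_fitness)
        self.optimizer_result_ = result
        return self

    def _get_support_mask(self) -> np.ndarray:
        return self.support_

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "support_")


def tdo_select_features(
    X,
    y,
    alpha: float = 0.9,
    cv_folds: int = 3,
    config: TDOConfig | None = None,
    feature_names: list[str] | None = None,
) -> FeatureMask:
    """Functional front-end to :class:`TDOFeatureSelector`."""
    kwargs: dict = {"alpha": alpha, "cv_folds": cv_folds}
    if config is not None:
        kwargs.update(
            pop_size=config.pop_size,
            iterations=config.iterations,
            p_explore=config.p_explore,
            random_state=config.seed,
        )
    selector = TDOFeatureSelector(**kwargs).fit(X, y)
    return FeatureMask(
        selected=selector.support_,
        position=selector.position_,
        feature_names=feature_names,
    )
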