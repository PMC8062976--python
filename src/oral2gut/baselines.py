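"""Comparison predictors: Random Forest regression and a stochastic mocker.

The Random Forest baseline fits one regression forest per stool family on
the same standardized oral features and percent targets as the network;
its raw predictions go through the same clip-and-rescale closure (but no
bias correction). The stochastic baseline ignores the oral data entirely:
it draws each family uniformly within the [min, max] range observed in the
training stool table and closes the draw to a composition — a floor any
informative predictor must beat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor

from .io_tables import FamilyTable
from .postprocess import clip_and_rescale


@dataclass
class StochasticRange:
    """Per-family [min, max] percent abundance observed in training stool."""

    families: list[str]
    minima: np.ndarray
    maxima: np.ndarray

    def __post_init__(self) -> None:
        self.minima = np.asarray(self.minima, dtype=float)
        self.maxima = np.asarray(self.maxima, dtype=float)
        if not (len(self.families) == len(self.minima) == len(self.maxima)):
            raise ValueError("one (min, max) pair per family required")
        if np.any(self.minima > self.maxima):
            raise ValueError("min > max for some family")
        if np.any(self.minima < 0) or np.any(self.maxima > 100):
            raise ValueError("ranges must lie within [0, 100]")

    @classmethod
    def from_table(cls, train: FamilyTable) -> "StochasticRange":
        return cls(
            list(train.families),
            train.values.min(axis=0),
            train.values.max(axis=0),
        )


def stochastic_profiles(
    ranges: StochasticRange,
    n_samples: int,
    seed: int,
    sample_ids: Sequence[str] | None = None,
) -> FamilyTable:
    """Mock stool profiles: uniform draws within the training ranges, closed."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(
        ranges.minima, ranges.maxima, size=(n_samples, len(ranges.families))
    )
    if sample_ids is None:
        sample_ids = [f"mock_{i}" for i in range(n_samples)]
    return clip_and_rescale(draws, ranges.families, sample_ids)


class RandomForestBaseline(RegressorMixin, BaseEstimator):
    """Per-family random forests on the standardized oral features.

    ``multi_output=True`` switches to a single multi-output forest.
    Predictions are closed to compositions by clip-and-rescale.
    """

    def __init__(
        self, n_trees: int = 500, seed: int = 0, multi_output: bool = False
    ):
        self.n_trees = n_trees
        self.seed = seed
        self.multi_output = multi_output

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "RandomForestBaseline":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must have the same number of rows")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.multi_output:
            self.forests_ = [
                RandomForestRegressor(
                    n_estimators=self.n_trees, random_state=self.seed
                ).fit(X, Y)
            ]
        else:
            self.forests_ = [
                RandomForestRegressor(
                    n_estimators=self.n_trees, random_state=self.seed + j
                ).fit(X, Y[:, j])
                for j in range(Y.shape[1])
            ]
        self.n_outputs_ = Y.shape[1]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        if self.multi_output:
            return self.forests_[0].predict(X)
        return np.column_stack([f.predict(X) for f in self.forests_])


def random_forest_predict(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_test: np.ndarray,
    families: Sequence[str],
    sample_ids: Sequence[str],
    n_trees: int = 500,
    seed: int = 0,
    multi_output: bool = False,
) -> FamilyTable:
    """Fit the forest baseline and return closed test-set predictions."""
    model = RandomForestBaseline(
        n_trees=n_trees, seed=seed, multi_output=multi_output
    ).fit(X_train, Y_train)
    raw = model.predict(X_test)
    return clip_and_rescale(raw, families, sample_ids)
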