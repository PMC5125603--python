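"""Random-forest variable-importance feature selection.

A random forest is fit to the labelled windows, per-feature importance scores
are collected, and every feature whose score is at or above the arithmetic
mean of all scores is retained.  The ">= mean" rule keeps ties at the mean.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import SelectorMixin
from sklearn.inspection import permutation_importance
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import FeatureDataset

__all__ = [
    "ImportanceResult",
    "RFImportanceSelector",
    "compute_importance",
    "select_above_mean",
    "apply_selection",
]


@dataclasses.dataclass(frozen=True)
class ImportanceResult:
    """Per-feature importance scores and the above-mean selection.

    ``selected`` is always the sorted set {i : scores[i] >= mean_score}; it is
    nonempty whenever there is at least one feature, because the maximum score
    is never below the mean.
    """

    scores: np.ndarray
    mean_score: float
    selected: tuple[int, ...]
    rf_params: dict

    def __post_init__(self):
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))


class RFImportanceSelector(SelectorMixin, BaseEstimator):
    """Select features whose forest importance is at or above the mean score.

    Parameters
    ----------
    n_estimators : int, default=500
        Trees in the forest (``ntree``).
    max_features : int or None, default=None
        Candidate features per split (``mtry``); ``None`` means
        ``floor(sqrt(p))``.
    n_repeats : int, default=1
        Number of independently seeded forests; scores are averaged.
    importance : {"impurity", "permutation"}, default="impurity"
        Importance measure.  Mean decrease in impurity is the default;
        permutation importance on the training data is available behind the
        flag.
    random_state : int or None
        Seed for the forest(s); pass an int for reproducible selections.

    Attributes
    ----------
    scores_ : ndarray of shape (p,)
        Averaged importance scores, all >= 0.
    mean_score_ : float
    support_ : ndarray of bool, shape (p,)
        ``scores_ >= mean_score_``.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        max_features: int | None = None,
        n_repeats: int = 1,
        importance: str = "impurity",
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.n_repeats = n_repeats
        self.importance = importance
        self.random_state = random_state

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        if X.shape[0] < 2:
            raise ValueError("need at least two windows to score importances")
        if len(np.unique(y)) < 2:
            raise ValueError("importance undefined for a single-class y")
        if self.importance not in ("impurity", "permutation"):
            raise ValueError(f"unknown importance measure {self.importance!r}")
        p = X.shape[1]
        mtry = self.max_features
        if mtry is None:
            mtry = max(1, int(np.floor(np.sqrt(p))))
        rng = np.random.default_rng(self.random_state)
        scores = np.zeros(p)
        for _ in range(max(1, self.n_repeats)):
            seed = int(rng.integers(0, 2**31 - 1))
            forest = RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_features=mtry,
                random_state=seed,
                n_jobs=1,
            ).fit(X, y)
            if self.importance == "impurity":
                scores += forest.feature_importances_
            else:
                perm = permutation_importance(
                    forest, X, y, n_repeats=5, random_state=seed, n_jobs=1
                )
                # permutation importances can dip below zero by chance
                scores += np.clip(perm.importances_mean, 0.0, None)
        scores /= max(1, self.n_repeats)
        self.scores_ = scores
        self.mean_score_ = float(scores.mean())
        self.support_ = scores >= self.mean_score_
        self.mtry_ = mtry
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def to_result(self) -> ImportanceResult:
        check_is_fitted(self, "support_")
        return ImportanceResult(
            scores=self.scores_.copy(),
            mean_score=self.mean_score_,
            selected=tuple(int(i) for i in np.flatnonzero(self.support_)),
            rf_params={
                "ntree": self.n_estimators,
                "mtry": self.mtry_,
                "seed": self.random_state,
                "n_repeats": self.n_repeats,
                "importance": self.importance,
            },
        )


def compute_importance(
    dataset: FeatureDataset,
    ntree: int = 500,
    mtry: int | None = None,
    seed: int | None = None,
    n_repeats: int = 1,
    importance: str = "impurity",
) -> ImportanceResult:
    """Score every feature with a seeded random forest and apply the
    above-mean retention rule."""
    if seed is None:
        raise ValueError("seed is required: forest importances are run-dependent")
    selector = RFImportanceSelector(
        n_estimators=ntree,
        max_features=mtry,
        n_repeats=n_repeats,
        importance=importance,
        random_state=seed,
    ).fit(dataset.X, dataset.y)
    return selector.to_result()


def select_above_mean(scores) -> tuple[int, ...]:
    """Indices i with scores[i] >= mean(scores) — pure arithmetic, no data."""
    if isinstance(scores, ImportanceResult):
        scores = scores.scores
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no scores to select from")
    return tuple(int(i) for i in np.flatnonzero(scores >= scores.mean()))


def apply_selection(dataset: FeatureDataset, indices: Sequence[int]) -> FeatureDataset:
    """Restrict a dataset to the selected columns (row count unchanged)."""
    return dataset.subset_columns(np.asarray(sorted(indices), dtype=int))
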