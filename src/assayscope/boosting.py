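"""Masked multitask gradient-boosted trees.

A squared-error gradient-boosting ensemble over scikit-learn decision trees
with one output column per task and an observation mask: masked entries
contribute nothing to the fit (each boosting round fits each task's tree on
that task's observed residuals only), which is what sparse multitask target
matrices require.  Single-task fitting is the one-column, full-mask case of
the same code path.

Early stopping monitors masked R² on an internal holdout carved from the
training rows; the realized tree count is the best iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.tree import DecisionTreeRegressor

from .errors import DomainError, ParameterError


@dataclass
class BoostingSpec:
    """Hyperparameters of the boosting ensemble."""

    max_trees: int = 1000
    learning_rate: float = 0.1
    min_points_per_leaf: int = 50
    max_depth: int = 8
    subsample: float = 0.8
    early_stopping_rounds: int = 20
    validation_fraction: float = 0.1
    loss: str = "squared_error"

    def __post_init__(self):
        if min(self.max_trees, self.learning_rate, self.min_points_per_leaf,
               self.max_depth) <= 0:
            raise ParameterError("boosting parameters must be positive")
        if not 0 < self.subsample <= 1:
            raise ParameterError("subsample must be in (0, 1]")


def masked_r2(y_true: np.ndarray, y_pred: np.ndarray, mask: np.ndarray) -> float:
    """R² = 1 - SSE/SST over observed (mask == 1) entries only."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    obs = np.asarray(mask, dtype=bool)
    yt, yp = y_true[obs], y_pred[obs]
    if yt.size < 2:
        raise DomainError("masked R² needs at least 2 observed entries")
    sst = float(np.sum((yt - yt.mean()) ** 2))
    if sst == 0:
        raise DomainError("masked R² undefined: observed targets have zero variance")
    return 1.0 - float(np.sum((yt - yp) ** 2)) / sst


class MaskedBoostingModel:
    """Gradient-boosted tree ensemble with a masked multitask squared loss.

    Fitted attributes: ``n_trees_`` (realized rounds after early stopping),
    ``base_`` (per-task mean of observed training targets),
    ``trees_[round][task]`` (``None`` when a task had no observed rows), and
    ``feature_importances_`` (cumulative squared-error reduction per
    feature over all used trees).
    """

    def __init__(self, spec: BoostingSpec | None = None):
        self.spec = spec or BoostingSpec()

    def fit(self, X: np.ndarray, Y: np.ndarray, mask: np.ndarray | None = None,
            seed: int = 0) -> "MaskedBoostingModel":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, n_tasks = Y.shape
        mask = np.ones_like(Y, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
        if mask.shape != Y.shape:
            raise ParameterError("mask shape must match target shape")
        if not np.isfinite(Y[mask]).all():
            raise DomainError("observed targets must be finite")

        empty = np.nonzero(mask.sum(axis=0) == 0)[0]
        if empty.size:
            warnings.warn(f"tasks {empty.tolist()} have no observed values and are dropped")
            keep = mask.sum(axis=0) > 0
            Y, mask = Y[:, keep], mask[:, keep]
            n_tasks = Y.shape[1]
        self.task_index_ = np.arange(n_tasks)

        spec = self.spec
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_val = max(1, int(round(spec.validation_fraction * n)))
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
        if fit_idx.size == 0:
            raise ParameterError("not enough rows for an early-stopping holdout")

        self.base_ = np.array([
            Y[mask[:, t], t].mean() if mask[fit_idx, t].sum() == 0
            else Y[fit_idx, t][mask[fit_idx, t]].mean()
            for t in range(n_tasks)])
        pred = np.tile(self.base_, (n, 1))

        self.trees_: list[list[DecisionTreeRegressor | None]] = []
        self._gain = np.zeros(X.shape[1])
        gains_per_round: list[np.ndarray] = []

        best_score, best_round, rounds_since_best = -np.inf, -1, 0
        monitor = mask[val_idx].sum() >= 2 and np.ptp(Y[val_idx][mask[val_idx]]) > 0

        for r in range(spec.max_trees):
            round_trees: list[DecisionTreeRegressor | None] = []
            round_gain = np.zeros(X.shape[1])
            for t in range(n_tasks):
                rows = fit_idx[mask[fit_idx, t]]
                tree_seed = int(rng.integers(0, 2**31 - 1))
                if rows.size < 2:
                    round_trees.append(None)
                    continue
                if spec.subsample < 1.0:
                    k = max(1, int(round(spec.subsample * rows.size)))
                    rows = rng.choice(rows, size=k, replace=False)
                residual = Y[rows, t] - pred[rows, t]
                tree = DecisionTreeRegressor(
                    criterion="squared_error", max_depth=spec.max_depth,
                    min_samples_leaf=spec.min_points_per_leaf, random_state=tree_seed)
                tree.fit(X[rows], residual)
                pred[:, t] += spec.learning_rate * tree.predict(X)
                round_gain += (tree.tree_.compute_feature_importances(normalize=False)
                               * rows.size)
                round_trees.append(tree)
            self.trees_.append(round_trees)
            gains_per_round.append(round_gain)

            if monitor:
                try:
                    score = masked_r2(Y[val_idx], pred[val_idx], mask[val_idx])
                except DomainError:
                    score = -np.inf
                if score > best_score or best_round < 0:
                    best_score, best_round, rounds_since_best = score, r, 0
                else:
                    rounds_since_best += 1
                    if rounds_since_best >= spec.early_stopping_rounds:
                        break
            else:
                best_round = r

        self.n_trees_ = best_round + 1
        self.trees_ = self.trees_[: self.n_trees_]
        self._gain = np.sum(gains_per_round[: self.n_trees_], axis=0) if self.n_trees_ else np.zeros(X.shape[1])
        self.n_tasks_ = n_tasks
        self.validation_score_ = best_score if monitor else None
        return self

    @property
    def feature_importances_(self) -> np.ndarray:
        """Cumulative squared-error reduction attributed to each feature."""
        return self._gain

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        pred = np.tile(self.base_, (X.shape[0], 1))
        for round_trees in self.trees_:
            for t, tree in enumerate(round_trees):
                if tree is not None:
                    pred[:, t] += self.spec.learning_rate * tree.predict(X)
        return pred


def train_single_task(features: np.ndarray, y: np.ndarray,
                      spec: BoostingSpec | None = None, seed: int = 0) -> MaskedBoostingModel:
    """Fit a single-task boosting model (1-column full-mask case)."""
    y = np.asarray(y, dtype=float)
    if not np.isfinite(y).all():
        raise DomainError("targets must be finite")
    return MaskedBoostingModel(spec).fit(features, y[:, None], None, seed=seed)


def train_multitask(features: np.ndarray, Y: np.ndarray, mask: np.ndarray,
                    spec: BoostingSpec | None = None, seed: int = 0) -> MaskedBoostingModel:
    """Fit a masked multitask boosting model (one output per task)."""
    return MaskedBoostingModel(spec).fit(features, Y, mask, seed=seed)
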