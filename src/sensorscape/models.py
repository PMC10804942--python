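"""Gradient-boosted tree models on sensor profiles.

Two scikit-learn-compatible estimators wrap the boosting backend (LightGBM):
:class:`SensorProfileClassifier` for multiclass ecosystem/condition prediction
and :class:`SensorProfileRegressor` for continuous physical parameters.  The
surrounding functions implement the evaluation protocol: a stratified 70/20/10
train/test/validation split, exhaustive grid search over learning rate, tree
depth and L2 leaf regularisation selected on the validation set, and a report
with accuracy (or R^2), per-class F1 and a complete confusion matrix.  The
headline metric is always measured on the held-out test set.

The backend contract is deliberately narrow — fit, predict, per-class raw
scores and tree-structure attributions — so any gradient-boosted tree library
providing those could be substituted.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier, LGBMRegressor
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.metrics import f1_score, r2_score
from sklearn.model_selection import train_test_split

from .profile import SensorProfileMatrix

logger = logging.getLogger(__name__)

def _predict_quietly(fn, X, **kwargs):
    # the backend auto-names ndarray columns at fit time, which trips
    # sklearn's feature-name consistency warning on every ndarray predict
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="X does not have valid feature names")
        return fn(X, **kwargs)


_BACKEND_FIXED = dict(
    n_jobs=1,
    deterministic=True,
    force_row_wise=True,
    verbosity=-1,
)


@dataclass
class SplitSpec:
    """Train/test/validation fractions (default 70/20/10) and split policy."""

    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be three positive numbers")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


@dataclass
class ModelConfig:
    """Task, loss/metric convention and the hyperparameter grid.

    Classification uses a multiclass log-loss with accuracy as the selection
    metric; regression uses squared error with R^2 for selection.  Grid axes
    follow the usual boosted-tree knobs: learning rate, tree depth and L2 leaf
    regularisation.
    """

    task: str = "multiclass"
    grid: Mapping[str, Sequence] = field(
        default_factory=lambda: {
            "learning_rate": [0.1],
            "depth": [6],
            "l2_leaf_reg": [3.0],
        }
    )
    n_estimators: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("multiclass", "regression"):
            raise ValueError("task must be 'multiclass' or 'regression'")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("every grid axis must be nonempty")


class SensorProfileClassifier(BaseEstimator, ClassifierMixin):
    """Multiclass gradient-boosted classifier over sensor-profile features.

    Parameters mirror the tuned knobs: ``learning_rate``, ``depth`` (per-tree
    depth limit), ``l2_leaf_reg`` (L2 regularisation on leaf values) and
    ``n_estimators``.  ``min_child_samples`` defaults low because profile
    corpora at desk scale are small.  Fitted attributes: ``classes_``,
    ``feature_names_``, ``booster_``.
    """

    def __init__(
        self,
        learning_rate: float = 0.1,
        depth: int = 6,
        l2_leaf_reg: float = 3.0,
        n_estimators: int = 200,
        min_child_samples: int = 5,
        random_state: int = 0,
    ):
        self.learning_rate = learning_rate
        self.depth = depth
        self.l2_leaf_reg = l2_leaf_reg
        self.n_estimators = n_estimators
        self.min_child_samples = min_child_samples
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training labels contain a single class")
        # objective resolves to multiclass log-loss (binary special case for
        # two classes) inside the backend
        self._model = LGBMClassifier(
            learning_rate=self.learning_rate,
            max_depth=self.depth,
            num_leaves=min(2**self.depth, 64),
            reg_lambda=self.l2_leaf_reg,
            n_estimators=self.n_estimators,
            min_child_samples=self.min_child_samples,
            random_state=self.random_state,
            **_BACKEND_FIXED,
        )
        self._model.fit(np.asarray(X, dtype=float), y)
        self.classes_ = self._model.classes_
        self.feature_names_ = [str(c) for c in getattr(X, "columns", range(np.asarray(X).shape[1]))]
        self.booster_ = self._model.booster_
        return self

    def predict(self, X) -> np.ndarray:
        return _predict_quietly(self._model.predict, np.asarray(X, dtype=float))

    def predict_proba(self, X) -> np.ndarray:
        return _predict_quietly(self._model.predict_proba, np.asarray(X, dtype=float))

    def raw_scores(self, X) -> np.ndarray:
        """Pre-softmax per-class margins, shape (n_samples, n_classes)."""
        return self.booster_.predict(np.asarray(X, dtype=float), raw_score=True)


class SensorProfileRegressor(BaseEstimator, RegressorMixin):
    """Gradient-boosted regressor for continuous physical parameters."""

    def __init__(
        self,
        learning_rate: float = 0.1,
        depth: int = 6,
        l2_leaf_reg: float = 3.0,
        n_estimators: int = 200,
        min_child_samples: int = 5,
        random_state: int = 0,
    ):
        self.learning_rate = learning_rate
        self.depth = depth
        self.l2_leaf_reg = l2_leaf_reg
        self.n_estimators = n_estimators
        self.min_child_samples = min_child_samples
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y, dtype=float)
        if np.allclose(y, y[0]):
            raise ValueError("regression target is constant")
        self._model = LGBMRegressor(
            learning_rate=self.learning_rate,
            max_depth=self.depth,
            num_leaves=min(2**self.depth, 64),
            reg_lambda=self.l2_leaf_reg,
            n_estimators=self.n_estimators,
            min_child_samples=self.min_child_samples,
            random_state=self.random_state,
            **_BACKEND_FIXED,
        )
        self._model.fit(np.asarray(X, dtype=float), y)
        self.feature_names_ = [str(c) for c in getattr(X, "columns", range(np.asarray(X).shape[1]))]
        self.booster_ = self._model.booster_
        return self

    def predict(self, X) -> np.ndarray:
        return _predict_quietly(self._model.predict, np.asarray(X, dtype=float))

    def raw_scores(self, X) -> np.ndarray:
        return self.predict(X)


def split(labels: pd.Series, spec: SplitSpec | None = None) -> tuple[list, list, list]:
    """Deterministic (seeded) 70/20/10 split of the index of ``labels``.

    Returns (train, test, validation) id lists — disjoint and exhaustive.
    When stratified, every class needs >= 3 members so each part can receive
    its share.
    """
    spec = spec or SplitSpec()
    ids = np.asarray(labels.index)
    y = labels.to_numpy()
    strat = None
    if spec.stratified:
        counts = pd.Series(y).value_counts()
        too_small = counts.index[counts < 3]
        if len(too_small):
            raise ValueError(f"class too small to stratify: {too_small[0]!r} ({counts[too_small[0]]} samples)")
        strat = y
    f_train, f_test, f_val = spec.fractions
    train_ids, rest_ids, _, rest_y = train_test_split(
        ids, y, train_size=f_train, random_state=spec.seed, stratify=strat
    )
    strat_rest = rest_y if spec.stratified else None
    test_ids, val_ids = train_test_split(
        rest_ids,
        train_size=f_test / (f_test + f_val),
        random_state=spec.seed,
        stratify=strat_rest,
    )
    return list(train_ids), list(test_ids), list(val_ids)


@dataclass
class EvalReport:
    """Held-out performance: headline metric, per-class F1 and confusion matrix.

    The confusion matrix covers the full label set (union of training classes
    and test labels), including all-zero rows, so its row sums equal per-class
    test counts and its trace over the total equals the accuracy.
    """

    accuracy: float
    f1: pd.Series
    confusion: pd.DataFrame
    best_params: dict | None = None
    unseen_labels: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1": {str(k): float(v) for k, v in self.f1.items()},
            "best_params": self.best_params,
            "unseen_labels": list(self.unseen_labels),
        }


def train_classifier(X: pd.DataFrame, y: pd.Series, cfg: ModelConfig) -> SensorProfileClassifier:
    """Fit a classifier with the first grid point of ``cfg`` (no search)."""
    params = {k: v[0] for k, v in cfg.grid.items()}
    model = SensorProfileClassifier(
        n_estimators=cfg.n_estimators, random_state=cfg.seed, **params
    )
    return model.fit(X, y)


def train_regressor(X: pd.DataFrame, y: pd.Series, cfg: ModelConfig) -> SensorProfileRegressor:
    params = {k: v[0] for k, v in cfg.grid.items()}
    model = SensorProfileRegressor(
        n_estimators=cfg.n_estimators, random_state=cfg.seed, **params
    )
    return model.fit(X, y)


def grid_search(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_val: pd.DataFrame,
    y_val: pd.Series,
    cfg: ModelConfig,
):
    """Exhaustive Cartesian grid search selected on the validation metric.

    Ties are broken by first-in-grid order (strictly-greater wins), making the
    selection deterministic.  Returns ``(best_params, fitted model)`` where the
    model is trained on the training rows only.
    """
    axes = list(cfg.grid)
    best_score = -np.inf
    best_params: dict | None = None
    best_model = None
    for combo in itertools.product(*(cfg.grid[a] for a in axes)):
        params = dict(zip(axes, combo))
        if cfg.task == "multiclass":
            model = SensorProfileClassifier(
                n_estimators=cfg.n_estimators, random_state=cfg.seed, **params
            ).fit(X_train, y_train)
            score = float(np.mean(model.predict(X_val) == np.asarray(y_val)))
        else:
            model = SensorProfileRegressor(
                n_estimators=cfg.n_estimators, random_state=cfg.seed, **params
            ).fit(X_train, y_train)
            score = r2_score(np.asarray(y_val, dtype=float), model.predict(X_val))
        logger.info("grid point %s -> validation %s %.4f", params, cfg.task, score)
        if score > best_score:
            best_score, best_params, best_model = score, params, model
    logger.info("selected %s (validation score %.4f)", best_params, best_score)
    return best_params, best_model


def evaluate(model: SensorProfileClassifier, X_test: pd.DataFrame, y_test: pd.Series,
             best_params: dict | None = None) -> EvalReport:
    """Test-set accuracy, per-class F1 and a complete confusion matrix."""
    y_true = np.asarray(y_test)
    if len(y_true) == 0:
        raise ValueError("empty test set")
    y_pred = model.predict(X_test)
    trained = [str(c) for c in model.classes_]
    unseen = sorted(set(map(str, y_true)) - set(trained))
    if unseen:
        logger.warning("test labels never seen in training: %s", unseen)
    label_set = sorted(set(trained) | set(map(str, y_true)))
    accuracy = float(np.mean(y_pred.astype(str) == y_true.astype(str)))
    f1 = pd.Series(
        f1_score(y_true.astype(str), y_pred.astype(str), labels=label_set, average=None, zero_division=0),
        index=label_set,
        name="f1",
    )
    confusion = pd.crosstab(
        pd.Categorical(y_true.astype(str), categories=label_set),
        pd.Categorical(y_pred.astype(str), categories=label_set),
        dropna=False,
    )
    confusion.index = pd.Index(label_set, name="true")
    confusion.columns = pd.Index(label_set, name="predicted")
    return EvalReport(accuracy, f1, confusion, best_params, unseen)


def evaluate_r2(model: SensorProfileRegressor, X_test: pd.DataFrame, y_test) -> float:
    """Coefficient of determination R^2 = 1 - SS_res/SS_tot on held-out rows."""
    return float(r2_score(np.asarray(y_test, dtype=float), model.predict(X_test)))


def feature_set_comparison(
    m: SensorProfileMatrix,
    alternative: SensorProfileMatrix,
    cfg: ModelConfig,
    label_field: str = "ecosystem",
    split_spec: SplitSpec | None = None,
) -> dict[str, EvalReport]:
    """Train the same model on cluster features vs an alternative feature set.

    The split, seed and hyperparameters are identical across the pair; only the
    columns differ, so any accuracy gap is attributable to feature resolution.
    """
    if list(m.values.index) != list(alternative.values.index):
        raise ValueError("feature matrices must cover the same rows in the same order")
    labels = m.meta[label_field]
    train_ids, test_ids, val_ids = split(labels, split_spec)
    out: dict[str, EvalReport] = {}
    for name, matrix in (("clusters", m), ("alternative", alternative)):
        X = matrix.values
        best, model = grid_search(
            X.loc[train_ids], labels.loc[train_ids], X.loc[val_ids], labels.loc[val_ids], cfg
        )
        out[name] = evaluate(model, X.loc[test_ids], labels.loc[test_ids], best)
    return out
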