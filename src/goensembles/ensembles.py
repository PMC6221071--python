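"""Heterogeneous ensembles over a base-classifier prediction matrix.

Three families combine the bag-averaged scores of the base classifiers:

* **mean aggregation** — unsupervised row-wise average;
* **stacking** — a meta-classifier trained on the held-out base scores
  (any of the eight meta roster slots);
* **CES** — Caruana-style greedy forward ensemble selection *with
  replacement*: starting from an empty ensemble, repeatedly add the base
  classifier (duplicates allowed) whose addition maximizes the selection
  metric of the multiset-mean score, stopping when no candidate strictly
  improves it.

All three consume a prediction matrix whose columns follow the fixed base
roster order and produce scores in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import learners
from .evaluation import fmax
from .learners import LearnerSpec, TrainedLearner

Metric = Callable[[np.ndarray, np.ndarray], float]


def fmax_metric(scores: np.ndarray, labels: np.ndarray) -> float:
    """Default CES selection metric: F_max of the candidate ensemble."""
    return fmax(scores, labels).fmax


def auc_metric(scores: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, scores))


@dataclass(frozen=True)
class CesTrace:
    """Accepted CES steps: (base name added, selection metric after adding)."""

    steps: tuple[tuple[str, float], ...]

    @property
    def multiset(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.steps)

    @property
    def final_metric(self) -> float:
        return self.steps[-1][1]


@dataclass
class EnsembleModel:
    """A fitted ensemble: mean, stacking:<meta>, or ces."""

    method: str
    roster: tuple[str, ...]
    meta_model: TrainedLearner | None = None
    multiset: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        kind = self.method.split(":")[0]
        if kind not in ("mean", "stacking", "ces"):
            raise ValueError(f"unknown ensemble method {self.method!r}")


def _check_columns(matrix: pd.DataFrame, roster: Sequence[str]) -> pd.DataFrame:
    if list(matrix.columns) == list(roster):
        return matrix
    if set(matrix.columns) != set(roster):
        missing = set(roster) - set(matrix.columns)
        extra = set(matrix.columns) - set(roster)
        raise ValueError(
            f"prediction-matrix columns do not match the fitted roster: "
            f"missing {sorted(missing)}, extra {sorted(extra)}"
        )
    return matrix[list(roster)]


def mean_ensemble(matrix: pd.DataFrame) -> np.ndarray:
    """Row-wise arithmetic mean of the base scores."""
    if matrix.shape[1] < 1:
        raise ValueError("prediction matrix needs at least one column")
    return matrix.to_numpy(dtype=float).mean(axis=1)


def fit_mean(matrix: pd.DataFrame) -> EnsembleModel:
    return EnsembleModel(method="mean", roster=tuple(matrix.columns))


def fit_stacking(
    meta_spec: LearnerSpec,
    meta_matrix: pd.DataFrame,
    labels: np.ndarray,
) -> EnsembleModel:
    """Fit a stacking meta-classifier on held-out base scores."""
    if meta_spec.role != "meta":
        raise ValueError(f"stacking requires a meta-role spec, got role={meta_spec.role!r}")
    model = learners.fit(meta_spec, meta_matrix, np.asarray(labels))
    return EnsembleModel(
        method=f"stacking:{meta_spec.name}",
        roster=tuple(meta_matrix.columns),
        meta_model=model,
    )


def ces_select(
    meta_matrix: pd.DataFrame,
    labels: np.ndarray,
    metric: Metric = fmax_metric,
    max_iter: int = 100,
) -> tuple[EnsembleModel, CesTrace]:
    """Greedy forward ensemble selection with replacement.

    Every base column remains a candidate at every iteration, so the
    selected multiset may contain duplicates (which act as weights in the
    multiset mean).  The first accepted step is the single best base;
    subsequent steps require strict improvement of the selection metric.
    Ties break to the lowest roster index.  ``max_iter`` is a safety cap.
    """
    if meta_matrix.shape[1] < 1:
        raise ValueError("prediction matrix needs at least one column")
    y = np.asarray(labels)
    columns = list(meta_matrix.columns)
    X = meta_matrix.to_numpy(dtype=float)
    current_sum = np.zeros(X.shape[0])
    current_metric = -np.inf
    steps: list[tuple[str, float]] = []
    for _ in range(max_iter):
        size = len(steps)
        best_j, best_metric = None, current_metric
        for j, name in enumerate(columns):
            cand = (current_sum + X[:, j]) / (size + 1)
            value = metric(cand, y)
            if value > best_metric:
                best_j, best_metric = j, value
        if best_j is None:
            break
        current_sum = current_sum + X[:, best_j]
        current_metric = best_metric
        steps.append((columns[best_j], float(best_metric)))
    trace = CesTrace(steps=tuple(steps))
    model = EnsembleModel(method="ces", roster=tuple(columns), multiset=trace.multiset)
    return model, trace


def ensemble_score(model: EnsembleModel, matrix: pd.DataFrame) -> np.ndarray:
    """Score a prediction matrix with a fitted ensemble; output in [0, 1]."""
    matrix = _check_columns(matrix, model.roster)
    kind = model.method.split(":")[0]
    if kind == "mean":
        return mean_ensemble(matrix)
    if kind == "ces":
        if not model.multiset:
            raise ValueError("CES model has an empty multiset")
        cols = [matrix[name].to_numpy(dtype=float) for name in model.multiset]
        return np.mean(cols, axis=0)
    assert model.meta_model is not None
    return learners.score(model.meta_model, matrix)
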