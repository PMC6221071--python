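"""Uniform contract over the base- and meta-classifier rosters.

Twelve base-classifier slots and eight stacking meta-classifier slots are
exposed by short conventional names (NB, LR, SGD, VP, AB, DT, LB, RT, RF,
RIPPER, PART, KNN for bases; NB, AB, DT, LB, KNN, LR, SGD, RF for metas).
Each slot maps to the closest scikit-learn algorithm; the rule-induction
slots (RIPPER, PART), for which scikit-learn has no native learner, are
served by decision-tree surrogates with rule-learner-like capacity
controls.  The contract — not the vendor implementation — is normative:
every slot is fit on a feature matrix plus binary labels and returns
scores in [0, 1] interpretable as confidence of the positive class.

Learners whose native output is a margin (hinge-loss SGD, perceptrons)
are min-max squashed to [0, 1] using the margin range observed on their
own training data, so all slots share a common score scale for
thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression, Perceptron, SGDClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

#: Fixed roster orders; all downstream prediction matrices use these.
BASE_ROSTER: tuple[str, ...] = (
    "NB", "LR", "SGD", "VP", "AB", "DT", "LB", "RT", "RF", "RIPPER", "PART", "KNN",
)
META_ROSTER: tuple[str, ...] = ("NB", "AB", "DT", "LB", "KNN", "LR", "SGD", "RF")

#: Slots whose estimator cannot consume scipy sparse input.
_DENSE_ONLY = {"NB"}
#: Slots without predict_proba whose decision margins are squashed.
_MARGIN_SLOTS = {"SGD", "VP"}


@dataclass(frozen=True)
class LearnerSpec:
    """A named algorithm slot with optional hyperparameter overrides."""

    name: str
    role: str = "base"  # "base" or "meta"
    hyperparameters: tuple[tuple[str, Any], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        roster = BASE_ROSTER if self.role == "base" else META_ROSTER
        if self.role not in ("base", "meta"):
            raise ValueError(f"role must be 'base' or 'meta', got {self.role!r}")
        if self.name not in roster:
            raise ValueError(
                f"unknown {self.role} learner {self.name!r}; roster: {roster}"
            )

    @property
    def hyperparameter_dict(self) -> dict[str, Any]:
        return dict(self.hyperparameters)

    def with_seed(self, seed: int) -> "LearnerSpec":
        return LearnerSpec(self.name, self.role, self.hyperparameters, seed)


@dataclass
class TrainedLearner:
    """A fitted slot plus the metadata needed to score safely."""

    spec: LearnerSpec
    estimator: BaseEstimator
    feature_names: tuple[str, ...]
    margin_range: tuple[float, float] | None = None


def _make_estimator(spec: LearnerSpec, n_features: int = 0) -> BaseEstimator:
    name, seed = spec.name, spec.seed
    hp = spec.hyperparameter_dict
    builders = {
        "NB": lambda: GaussianNB(),
        "LR": lambda: LogisticRegression(max_iter=1000),
        "SGD": lambda: SGDClassifier(random_state=seed),
        "VP": lambda: Perceptron(random_state=seed),
        "AB": lambda: AdaBoostClassifier(random_state=seed),
        "DT": lambda: DecisionTreeClassifier(random_state=seed),
        # random feature subsampling per split keeps boosting tractable on
        # the 8000-column k-mer space; narrow matrices use exhaustive splits
        "LB": lambda: GradientBoostingClassifier(
            max_features="sqrt" if n_features > 1000 else None, random_state=seed
        ),
        "RT": lambda: DecisionTreeClassifier(splitter="random", random_state=seed),
        "RF": lambda: RandomForestClassifier(random_state=seed),
        "RIPPER": lambda: DecisionTreeClassifier(
            criterion="entropy", max_depth=5, min_samples_leaf=5, random_state=seed
        ),
        "PART": lambda: DecisionTreeClassifier(
            criterion="entropy", min_samples_leaf=10, random_state=seed
        ),
        "KNN": lambda: KNeighborsClassifier(),
    }
    est = builders[name]()
    if hp:
        est.set_params(**hp)
    return est


def roster_specs(role: str = "base", seed: int = 0) -> list[LearnerSpec]:
    """Default specs for the full roster of the given role."""
    roster = BASE_ROSTER if role == "base" else META_ROSTER
    return [LearnerSpec(name=name, role=role, seed=seed) for name in roster]


def _as_matrix(features) -> np.ndarray | sparse.spmatrix:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy()
    if sparse.issparse(features):
        return features
    return np.asarray(features)


def _prepare(X, spec: LearnerSpec):
    """Choose the estimator-facing representation of the feature matrix.

    k-mer matrices are mostly zeros; sparse input speeds up tree and
    linear learners considerably without changing their output.  Slots
    whose estimator requires dense input get a dense view either way.
    """
    if sparse.issparse(X):
        return X.toarray() if spec.name in _DENSE_ONLY else X
    if spec.name in _DENSE_ONLY or X.shape[1] < 64:
        return X
    density = np.count_nonzero(X) / max(X.size, 1)
    if density < 0.25:
        return sparse.csr_matrix(X)
    return X


def fit(
    spec: LearnerSpec,
    features,
    labels: np.ndarray,
) -> TrainedLearner:
    """Fit one slot on a (bag-restricted) feature matrix.

    ``features`` may be a DataFrame, ndarray or scipy sparse matrix.
    Deterministic given (spec, data, seed).  Raises on single-class input
    and on label/row count mismatch.
    """
    X = _as_matrix(features)
    y = np.asarray(labels)
    if len(y) != X.shape[0]:
        raise ValueError(f"labels length {len(y)} != feature rows {X.shape[0]}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(
            f"learner {spec.name}: training data contains a single class ({classes.tolist()})"
        )
    if isinstance(features, pd.DataFrame):
        feature_names = tuple(map(str, features.columns))
    else:
        feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    est = _make_estimator(spec, n_features=X.shape[1])
    Xfit = _prepare(X, spec)
    est.fit(Xfit, y)
    margin_range = None
    if not hasattr(est, "predict_proba"):
        margins = est.decision_function(Xfit)
        margin_range = (float(np.min(margins)), float(np.max(margins)))
    return TrainedLearner(spec=spec, estimator=est, feature_names=feature_names, margin_range=margin_range)


def score(model: TrainedLearner, features) -> np.ndarray:
    """Score rows with a trained slot; output is in [0, 1] per row.

    Probabilistic learners report the positive-class probability; margin
    learners report the training-range min-max squash of their decision
    function, clipped to [0, 1] (a constant margin scores 0.5).
    """
    if isinstance(features, pd.DataFrame):
        names = tuple(map(str, features.columns))
        if names != model.feature_names:
            missing = set(model.feature_names) - set(names)
            extra = set(names) - set(model.feature_names)
            raise ValueError(
                f"feature mismatch for {model.spec.name}: missing {sorted(missing)[:5]}, "
                f"extra {sorted(extra)[:5]}"
            )
    X = _as_matrix(features)
    if X.shape[0] == 0:
        return np.zeros(0, dtype=float)
    if X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"feature count mismatch for {model.spec.name}: "
            f"got {X.shape[1]}, trained on {len(model.feature_names)}"
        )
    est = model.estimator
    Xs = _prepare(X, model.spec)
    if hasattr(est, "predict_proba"):
        proba = est.predict_proba(Xs)
        pos_col = int(np.where(est.classes_ == np.max(est.classes_))[0][0])
        out = proba[:, pos_col]
    else:
        margins = np.asarray(est.decision_function(Xs), dtype=float)
        lo, hi = model.margin_range
        if hi - lo <= 0:
            out = np.full(len(margins), 0.5)
        else:
            out = (margins - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0)
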