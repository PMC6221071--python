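"""Nested cross-validation for training base classifiers and ensembles.

Supervised ensembles require two rounds of training, so a single CV loop
would let the meta-layer see data its base classifiers trained on.  The
nested scheme avoids that: the dataset is split into *outer* folds; each
outer-train set is split again into *inner* folds; base classifiers are
trained on balanced bags of the inner-train sets and predict the inner
tests; those held-out predictions, collected across the inner folds, form
the meta matrix on which the ensembles are trained; everything is finally
scored on the untouched outer-test set.  Outer-test scores are pooled
across folds into one score vector per method before computing F_max.

Every unit of work (classifier x bag x inner fold; ensemble x outer fold)
is a pure function of its declared inputs, so units may be executed in
any order or in parallel (joblib threads) with bit-identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy import sparse
from sklearn.model_selection import StratifiedKFold

from . import learners
from .datasets import LabeledTermDataset
from .ensembles import (
    CesTrace,
    EnsembleModel,
    ces_select,
    ensemble_score,
    fit_mean,
    fit_stacking,
    fmax_metric,
)
from .evaluation import DeltaFmax, FmaxResult, delta_fmax, fmax
from .learners import BASE_ROSTER, META_ROSTER, LearnerSpec

logger = logging.getLogger(__name__)

#: Recorder signature for leak-audit instrumentation: (context, row indices).
FitRecorder = Callable[[dict, np.ndarray], None]


@dataclass(frozen=True)
class NestedSplit:
    """Outer folds and, per outer fold, inner folds of the outer-train set.

    All index tuples hold absolute row positions into the dataset.
    """

    outer_folds: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    inner_folds: tuple[tuple[tuple[tuple[int, ...], tuple[int, ...]], ...], ...]
    seed: int


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the per-term training/evaluation pipeline."""

    n_bags: int = 10
    k_outer: int = 5
    k_inner: int = 5
    base_roster: tuple[str, ...] = BASE_ROSTER
    meta_roster: tuple[str, ...] = META_ROSTER
    include_mean: bool = True
    include_ces: bool = True
    ces_max_iter: int = 100
    seed: int = 0
    n_jobs: int = 1
    fit_recorder: FitRecorder | None = None


@dataclass
class TermPipelineResult:
    """Pooled outer-test scores and evaluation for one term."""

    term_id: str
    protein_ids: tuple[str, ...]
    labels: np.ndarray
    scores: pd.DataFrame  # rows = proteins, columns = methods
    fmax_results: dict[str, FmaxResult]
    deltas: list[DeltaFmax]
    best_base: tuple[str, float]
    ces_traces: list[CesTrace]

    @property
    def fmax_by_method(self) -> dict[str, float]:
        return {name: res.fmax for name, res in self.fmax_results.items()}


def ensemble_method_names(config: PipelineConfig) -> list[str]:
    names: list[str] = []
    if config.include_mean:
        names.append("Mean")
    names.extend(f"{meta}.S" for meta in config.meta_roster)
    if config.include_ces:
        names.append("CES")
    return names


def make_nested_splits(
    labels: np.ndarray,
    k_outer: int = 5,
    k_inner: int = 5,
    seed: int = 0,
) -> NestedSplit:
    """Stratified two-level splits, deterministic given the seed.

    Outer tests partition the dataset; inner tests partition each
    outer-train set; fold sizes differ by at most one.  Raises when any
    (outer or inner) test fold would contain zero positives.
    """
    y = np.asarray(labels).astype(int)
    n = len(y)
    if not (n >= k_outer >= 2):
        raise ValueError(f"need n >= k_outer >= 2, got n={n}, k_outer={k_outer}")
    if k_inner < 2:
        raise ValueError(f"need k_inner >= 2, got {k_inner}")
    outer = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed)
    outer_folds = []
    inner_folds = []
    X_dummy = np.zeros((n, 1))
    for fold_i, (train, test) in enumerate(outer.split(X_dummy, y)):
        for part, which in ((train, "outer-train"), (test, "outer-test")):
            if y[part].sum() == 0:
                raise ValueError(
                    f"{which} fold {fold_i} contains zero positives; use fewer folds"
                )
        inner_seed = (seed * 1009 + fold_i + 1) % (2**31)
        inner = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=inner_seed)
        fold_inner = []
        for j, (itrain, itest) in enumerate(inner.split(np.zeros((len(train), 1)), y[train])):
            if y[train[itest]].sum() == 0:
                raise ValueError(
                    f"inner-test fold {j} of outer fold {fold_i} contains zero "
                    f"positives; use fewer folds"
                )
            fold_inner.append((tuple(train[itrain]), tuple(train[itest])))
        outer_folds.append((tuple(train), tuple(test)))
        inner_folds.append(tuple(fold_inner))
    return NestedSplit(outer_folds=tuple(outer_folds), inner_folds=tuple(inner_folds), seed=seed)


def assemble_meta_matrix(
    outer_train: Sequence[int],
    inner_results: Sequence[tuple[Sequence[int], Mapping[str, np.ndarray]]],
    roster: Sequence[str],
    protein_ids: Sequence[str],
) -> pd.DataFrame:
    """Collect inner-test bag-averaged scores into the meta-training matrix.

    ``inner_results`` holds, per inner fold, the held-out row indices and a
    mapping base-classifier name -> score vector aligned to those rows.
    The result has one row per outer-train protein (in outer-train order)
    and one column per roster entry.
    """
    outer_train = list(outer_train)
    values = pd.DataFrame(
        np.full((len(outer_train), len(roster)), np.nan),
        index=outer_train,
        columns=list(roster),
    )
    seen: set[int] = set()
    for test_idx, scores_by_name in inner_results:
        test_idx = list(test_idx)
        dup = seen.intersection(test_idx)
        if dup:
            raise ValueError(f"rows {sorted(dup)[:5]} appear in more than one inner test fold")
        seen.update(test_idx)
        for name in roster:
            if name not in scores_by_name:
                raise ValueError(
                    f"missing scores for classifier {name!r} on rows {test_idx[:5]}"
                )
            values.loc[test_idx, name] = np.asarray(scores_by_name[name], dtype=float)
    if values.isna().any().any():
        rows = values.index[values.isna().any(axis=1)].tolist()
        raise ValueError(f"meta matrix has unscored rows: {rows[:10]}")
    values.index = [protein_ids[i] for i in outer_train]
    return values


def _unit_seed(*key: int) -> int:
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0] % (2**31))


def _balanced_bags(
    pos_idx: np.ndarray,
    neg_idx: np.ndarray,
    n_bags: int,
    seed_key: tuple[int, ...],
) -> list[np.ndarray]:
    """Index-level balanced bags: all positives + sampled negatives each."""
    if len(pos_idx) < 1:
        raise ValueError("cannot build bags without positives")
    if len(neg_idx) < len(pos_idx):
        raise ValueError(
            f"fewer negatives ({len(neg_idx)}) than positives ({len(pos_idx)}) in the "
            f"training split; consider under-sampling the positive class instead"
        )
    bags = []
    for b in range(n_bags):
        rng = np.random.default_rng(list(seed_key) + [b])
        sampled = rng.choice(len(neg_idx), size=len(pos_idx), replace=False)
        bags.append(np.concatenate([pos_idx, neg_idx[np.sort(sampled)]]))
    return bags


def _fit_score_unit(
    spec: LearnerSpec,
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    context: dict,
    train_indices: np.ndarray,
    recorder: FitRecorder | None,
) -> np.ndarray:
    if recorder is not None:
        recorder(context, np.asarray(train_indices))
    model = learners.fit(spec, X_train, y_train)
    return learners.score(model, X_test)


def run_term_pipeline(
    dataset: LabeledTermDataset,
    features: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
) -> TermPipelineResult:
    """Train and evaluate all methods for one term under nested CV.

    Per outer fold: bags and base learners are built from the outer-train
    set only; ensembles are fitted on the inner-CV meta matrix; base
    classifiers are refit on full outer-train bags for outer-test scoring
    (same training budget as the ensembles' inputs); everything is scored
    on the outer test.  Scores are pooled across outer folds into one
    vector per method, from which F_max and Delta F_max are computed.
    """
    members = dataset.positives | dataset.negatives
    missing = members - set(features.index)
    if missing:
        raise ValueError(
            f"term {dataset.term_id}: proteins missing from the feature matrix: "
            f"{sorted(missing)[:5]}"
        )
    ids = tuple(pid for pid in features.index if pid in members)
    X = features.loc[list(ids)]
    # one sparse copy, sliced per unit: row slicing on CSR is far cheaper
    # than repeated DataFrame fancy indexing at 8000 columns
    X_csr = sparse.csr_matrix(X.to_numpy())
    y = np.array([1 if pid in dataset.positives else 0 for pid in ids])
    n = len(ids)

    split = make_nested_splits(y, config.k_outer, config.k_inner, config.seed)
    base_names = list(config.base_roster)
    ens_names = ensemble_method_names(config)
    method_scores: dict[str, np.ndarray] = {
        name: np.full(n, np.nan) for name in base_names + ens_names
    }
    ces_traces: list[CesTrace] = []
    parallel = Parallel(n_jobs=config.n_jobs, prefer="threads")

    for fold_i, (outer_train, outer_test) in enumerate(split.outer_folds):
        outer_train_arr = np.asarray(outer_train)
        outer_test_arr = np.asarray(outer_test)

        # ---- inner stage: held-out base predictions over outer-train ----
        tasks = []
        task_meta = []  # (kind, inner_j, bag_b, base_name)
        for inner_j, (itrain, itest) in enumerate(split.inner_folds[fold_i]):
            itrain_arr = np.asarray(itrain)
            itest_arr = np.asarray(itest)
            pos_idx = itrain_arr[y[itrain_arr] == 1]
            neg_idx = itrain_arr[y[itrain_arr] == 0]
            bags = _balanced_bags(
                pos_idx, neg_idx, config.n_bags, (config.seed, 0, fold_i, inner_j)
            )
            for b, bag in enumerate(bags):
                for s, name in enumerate(base_names):
                    spec = LearnerSpec(
                        name=name,
                        role="base",
                        seed=_unit_seed(config.seed, 0, fold_i, inner_j, b, s),
                    )
                    context = {
                        "term": dataset.term_id, "stage": "inner-base",
                        "outer_fold": fold_i, "inner_fold": inner_j,
                        "bag": b, "classifier": name,
                    }
                    tasks.append(delayed(_fit_score_unit)(
                        spec, X_csr[bag], y[bag], X_csr[itest_arr],
                        context, bag, config.fit_recorder,
                    ))
                    task_meta.append(("inner", inner_j, b, name))

        # ---- outer stage base units: refit on full outer-train bags ----
        pos_idx = outer_train_arr[y[outer_train_arr] == 1]
        neg_idx = outer_train_arr[y[outer_train_arr] == 0]
        outer_bags = _balanced_bags(
            pos_idx, neg_idx, config.n_bags, (config.seed, 1, fold_i)
        )
        for b, bag in enumerate(outer_bags):
            for s, name in enumerate(base_names):
                spec = LearnerSpec(
                    name=name, role="base",
                    seed=_unit_seed(config.seed, 1, fold_i, b, s),
                )
                context = {
                    "term": dataset.term_id, "stage": "outer-base",
                    "outer_fold": fold_i, "bag": b, "classifier": name,
                }
                tasks.append(delayed(_fit_score_unit)(
                    spec, X_csr[bag], y[bag], X_csr[outer_test_arr],
                    context, bag, config.fit_recorder,
                ))
                task_meta.append(("outer", -1, b, name))

        results = parallel(tasks)

        # bag-average inner predictions per (inner fold, classifier)
        inner_acc: dict[tuple[int, str], list[np.ndarray]] = {}
        outer_acc: dict[str, list[np.ndarray]] = {name: [] for name in base_names}
        for (kind, inner_j, b, name), scores in zip(task_meta, results):
            if kind == "inner":
                inner_acc.setdefault((inner_j, name), []).append(scores)
            else:
                outer_acc[name].append(scores)
        inner_results = []
        for inner_j, (_, itest) in enumerate(split.inner_folds[fold_i]):
            scores_by_name = {
                name: np.mean(inner_acc[(inner_j, name)], axis=0) for name in base_names
            }
            inner_results.append((list(itest), scores_by_name))
        meta_matrix = assemble_meta_matrix(
            outer_train, inner_results, base_names, ids
        )
        meta_labels = y[outer_train_arr]

        outer_matrix = pd.DataFrame(
            {name: np.mean(outer_acc[name], axis=0) for name in base_names},
            index=[ids[i] for i in outer_test_arr],
        )[base_names]

        for name in base_names:
            method_scores[name][outer_test_arr] = outer_matrix[name].to_numpy()

        # ---- ensemble stage ----
        def record_ensemble(method: str) -> None:
            if config.fit_recorder is not None:
                config.fit_recorder(
                    {
                        "term": dataset.term_id, "stage": "ensemble",
                        "outer_fold": fold_i, "classifier": method,
                    },
                    outer_train_arr,
                )

        if config.include_mean:
            record_ensemble("Mean")
            model = fit_mean(meta_matrix)
            method_scores["Mean"][outer_test_arr] = ensemble_score(model, outer_matrix)
        for s, meta_name in enumerate(config.meta_roster):
            spec = LearnerSpec(
                name=meta_name, role="meta",
                seed=_unit_seed(config.seed, 2, fold_i, s),
            )
            record_ensemble(f"{meta_name}.S")
            model = fit_stacking(spec, meta_matrix, meta_labels)
            method_scores[f"{meta_name}.S"][outer_test_arr] = ensemble_score(model, outer_matrix)
        if config.include_ces:
            record_ensemble("CES")
            model, trace = ces_select(
                meta_matrix, meta_labels, metric=fmax_metric, max_iter=config.ces_max_iter
            )
            ces_traces.append(trace)
            method_scores["CES"][outer_test_arr] = ensemble_score(model, outer_matrix)

    scores_df = pd.DataFrame(method_scores, index=list(ids))
    if scores_df.isna().any().any():
        raise RuntimeError("internal error: some proteins were never scored on an outer test")
    fmax_results = {name: fmax(scores_df[name].to_numpy(), y) for name in scores_df.columns}
    deltas = delta_fmax(
        {k: v.fmax for k, v in fmax_results.items()},
        base_names,
        ens_names,
        term_id=dataset.term_id,
    )
    best = max(base_names, key=lambda nm: fmax_results[nm].fmax)
    return TermPipelineResult(
        term_id=dataset.term_id,
        protein_ids=ids,
        labels=y,
        scores=scores_df,
        fmax_results=fmax_results,
        deltas=deltas,
        best_base=(best, fmax_results[best].fmax),
        ces_traces=ces_traces,
    )
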