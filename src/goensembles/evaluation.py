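"""Threshold-free evaluation and statistical comparison of predictors.

The headline metric is F_max: the maximum F-measure (harmonic mean of
precision and recall) over all binarization thresholds of a score vector,
the measure recommended by the CAFA assessments for protein function
prediction.  Thresholds are the observed unique score values, predictions
at exactly the threshold count as positive, and ties in the maximum
resolve to the smallest achieving threshold.

Method comparison across many GO terms uses average ranks: Friedman's
chi-square test (with tie correction) for overall differences, the
Nemenyi critical difference CD = q_alpha * sqrt(m(m+1)/(6N)) for post-hoc
grouping, and the Wilcoxon signed-rank test for paired per-stratum
comparisons of Delta F_max.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class FmaxResult:
    """F_max, the smallest threshold achieving it, and the full P/R curve."""

    fmax: float
    threshold: float
    curve: tuple[tuple[float, float, float, float], ...]  # (tau, P, R, F)


@dataclass(frozen=True)
class DeltaFmax:
    """F_max difference of one ensemble method vs the best base classifier."""

    term_id: str
    method: str
    delta: float


@dataclass(frozen=True)
class RankComparison:
    methods: tuple[str, ...]
    n_datasets: int
    rank_matrix: pd.DataFrame  # methods x datasets, 1 = best, ties averaged
    average_ranks: pd.Series
    statistic: float
    p_value: float
    alpha: float
    critical_difference: float
    groups: tuple[tuple[str, ...], ...]


def fmax(scores: np.ndarray, labels: np.ndarray) -> FmaxResult:
    """Maximum F-measure over all unique score thresholds.

    At threshold tau, rows scoring >= tau are predicted positive;
    P = TP/(TP+FP), R = TP/(TP+FN), F = 2PR/(P+R) (0 when P+R = 0).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError(f"scores and labels differ in length: {scores.shape} vs {labels.shape}")
    if scores.size == 0:
        raise ValueError("empty score vector")
    if np.min(scores) < 0 or np.max(scores) > 1:
        raise ValueError("scores must lie in [0, 1]")
    y = labels.astype(int)
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("no positive labels; F_max is undefined")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y[order]
    cum_tp = np.cumsum(y_sorted)
    # last index of each distinct score value in the descending sort
    boundary = np.nonzero(np.diff(s_sorted) != 0)[0]
    last = np.concatenate([boundary, [len(s_sorted) - 1]])
    tp = cum_tp[last].astype(float)
    predicted = (last + 1).astype(float)
    precision = tp / predicted
    recall = tp / n_pos
    denom = precision + recall
    f_values = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    thresholds = s_sorted[last]  # strictly decreasing
    best_f = float(np.max(f_values))
    # ties -> smallest achieving threshold (last position in descending order)
    best_idx = len(f_values) - 1 - int(np.argmax(f_values[::-1]))
    curve = tuple(
        (float(t), float(p), float(r), float(f))
        for t, p, r, f in zip(thresholds[::-1], precision[::-1], recall[::-1], f_values[::-1])
    )
    return FmaxResult(fmax=best_f, threshold=float(thresholds[best_idx]), curve=curve)


def prevalence_baseline(prevalence: float) -> float:
    """F at the all-positive threshold: 2*pi/(1+pi) for prevalence pi.

    This is the F_max attained by any uninformative (constant-threshold)
    scoring, and a lower bound for F_max in general.
    """
    return 2 * prevalence / (1 + prevalence)


def delta_fmax(
    fmax_by_method: Mapping[str, float],
    base_names: Sequence[str],
    ensemble_names: Sequence[str],
    term_id: str = "",
) -> list[DeltaFmax]:
    """Delta F_max per ensemble = ensemble F_max - best base F_max."""
    missing = [m for m in list(base_names) + list(ensemble_names) if m not in fmax_by_method]
    if missing:
        raise KeyError(f"missing F_max for methods: {missing}")
    best_base = max(fmax_by_method[b] for b in base_names)
    return [
        DeltaFmax(term_id=term_id, method=m, delta=float(fmax_by_method[m] - best_base))
        for m in ensemble_names
    ]


def wilcoxon_signed_rank(deltas: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired differences.

    Zeros are removed first.  The exact null distribution is used for
    n <= 25 samples without tied absolute values; otherwise the normal
    approximation with tie correction.
    """
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero; signed-rank test is degenerate")
    ranks_ties = len(np.unique(np.abs(d))) < d.size
    if d.size <= 25 and not ranks_ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=False)
    return float(res.pvalue)


def _nemenyi_q(alpha: float, m: int) -> float:
    """Critical value of the Nemenyi test (studentized range / sqrt(2))."""
    return float(stats.studentized_range.ppf(1 - alpha, m, np.inf) / math.sqrt(2))


def friedman_nemenyi(
    table: pd.DataFrame,
    alpha: float = 0.05,
) -> RankComparison:
    """Rank-based comparison of methods (rows) across datasets (columns).

    Ranks are per dataset, 1 = best (largest value), ties averaged.  The
    Friedman chi-square statistic uses the tie-corrected form; the Nemenyi
    critical difference is q_alpha * sqrt(m(m+1)/(6N)).  Methods are
    grouped into maximal sets whose average ranks all lie within CD of
    each other ("statistically equivalent" cliques).
    """
    if table.isna().any().any():
        cells = [(str(r), str(c)) for r, c in zip(*np.where(table.isna().to_numpy()))]
        raise ValueError(f"missing cells in comparison table: {cells[:10]}")
    m, n = table.shape
    if m < 3:
        raise ValueError(f"need at least 3 methods, got {m}")
    if n < 2:
        raise ValueError(f"need at least 2 datasets, got {n}")

    values = table.to_numpy(dtype=float)
    # rank within each dataset: 1 = best = largest value, ties averaged
    ranks = np.apply_along_axis(lambda col: stats.rankdata(-col), 0, values)
    rank_df = pd.DataFrame(ranks, index=table.index, columns=table.columns)
    avg_ranks = rank_df.mean(axis=1)

    # Friedman chi-square with tie correction
    ties = 0.0
    for j in range(n):
        _, counts = np.unique(values[:, j], return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (m * (m * m - 1) * n)
    rank_sums = ranks.sum(axis=1)
    ssbn = float(np.sum(rank_sums**2))
    numerator = 12.0 / (m * n * (m + 1)) * ssbn - 3.0 * n * (m + 1)
    if c <= 0:
        statistic, p_value = 0.0, 1.0
    else:
        statistic = numerator / c
        p_value = float(stats.chi2.sf(statistic, m - 1))

    cd = _nemenyi_q(alpha, m) * math.sqrt(m * (m + 1) / (6.0 * n))

    order = avg_ranks.sort_values(kind="stable").index.tolist()
    sorted_ranks = avg_ranks.loc[order].to_numpy()
    groups: list[tuple[str, ...]] = []
    for i in range(len(order)):
        j = i
        while j + 1 < len(order) and sorted_ranks[j + 1] - sorted_ranks[i] < cd:
            j += 1
        group = tuple(order[i:j + 1])
        if not any(set(group) <= set(g) for g in groups):
            groups.append(group)

    return RankComparison(
        methods=tuple(map(str, table.index)),
        n_datasets=n,
        rank_matrix=rank_df,
        average_ranks=avg_ranks,
        statistic=float(statistic),
        p_value=float(p_value),
        alpha=alpha,
        critical_difference=float(cd),
        groups=tuple(groups),
    )


def stratify_by_level(
    deltas: Iterable[DeltaFmax],
    levels: Mapping[str, int],
) -> dict[int, dict]:
    """Group Delta F_max records by GO-term level and test each stratum.

    Returns, per level: the delta vector, its mean, and the Wilcoxon
    signed-rank p-value (``None`` with a reason when fewer than two
    non-zero deltas make the test inapplicable).
    """
    by_level: dict[int, list[float]] = {}
    for rec in deltas:
        if rec.term_id not in levels:
            raise KeyError(f"term {rec.term_id!r} has no level assigned")
        by_level.setdefault(levels[rec.term_id], []).append(rec.delta)
    out: dict[int, dict] = {}
    for level in sorted(by_level):
        vec = np.asarray(by_level[level], dtype=float)
        nonzero = vec[vec != 0]
        entry: dict = {"deltas": vec, "mean": float(vec.mean()), "n": int(vec.size)}
        if nonzero.size < 2:
            entry["p_value"] = None
            entry["reason"] = "fewer than 2 non-zero deltas"
        else:
            entry["p_value"] = wilcoxon_signed_rank(vec)
        out[level] = entry
    return out
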