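import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from goensembles.evaluation import (
    DeltaFmax,
    delta_fmax,
    fmax,
    friedman_nemenyi,
    prevalence_baseline,
    stratify_by_level,
    wilcoxon_signed_rank,
)


def brute_force_fmax(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Independent oracle: scan every unique threshold explicitly."""
    best_f, best_t = -1.0, None
    for tau in sorted(set(scores), reverse=True):
        pred = scores >= tau
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        if f >= best_f:  # >= so that ties resolve to the smallest threshold
            best_f, best_t = f, tau
    return best_f, best_t


class TestFmax:
    def test_perfect_separation(self):
        res = fmax(np.array([0.9, 0.1]), np.array([1, 0]))
        assert res.fmax == 1.0 and res.threshold == 0.9

    def test_three_threshold_example(self):
        res = fmax(np.array([0.6, 0.4, 0.5]), np.array([1, 1, 0]))
        assert res.fmax == pytest.approx(0.8)
        assert res.threshold == pytest.approx(0.4)

    def test_constant_scores_hit_prevalence_baseline(self):
        labels = np.array([1] * 3 + [0] * 7)
        res = fmax(np.full(10, 0.5), labels)
        assert res.fmax == pytest.approx(prevalence_baseline(0.3))

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(300):
            n = int(rng.integers(2, 200))
            scores = np.round(rng.random(n), 3)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                labels[0] = 1
            res = fmax(scores, labels)
            bf_f, bf_t = brute_force_fmax(scores, labels)
            assert res.fmax == pytest.approx(bf_f, abs=1e-12)
            assert res.threshold == pytest.approx(bf_t, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(100)
        labels = rng.integers(0, 2, size=100)
        labels[0] = 1
        f1 = fmax(scores, labels).fmax
        f2 = fmax(scores**3, labels).fmax  # strictly monotone on [0, 1]
        assert f1 == pytest.approx(f2)

    def test_never_below_all_positive_baseline(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 80))
            labels = rng.integers(0, 2, size=n)
            labels[0] = 1
            scores = rng.random(n)
            pi = labels.mean()
            assert fmax(scores, labels).fmax >= prevalence_baseline(pi) - 1e-12

    def test_curve_satisfies_f_definition(self, rng):
        scores = np.round(rng.random(50), 2)
        labels = rng.integers(0, 2, size=50)
        labels[0] = 1
        res = fmax(scores, labels)
        for tau, p, r, f in res.curve:
            expected = 2 * p * r / (p + r) if p + r else 0.0
            assert f == pytest.approx(expected)
        assert res.fmax == pytest.approx(max(pt[3] for pt in res.curve))

    def test_input_validation(self):
        with pytest.raises(ValueError, match="no positive"):
            fmax(np.array([0.5]), np.array([0]))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fmax(np.array([1.5]), np.array([1]))
        with pytest.raises(ValueError, match="length"):
            fmax(np.array([0.5, 0.5]), np.array([1]))


class TestDeltaFmax:
    def test_simple_difference(self):
        table = {"b1": 0.80, "e1": 0.82}
        (d,) = delta_fmax(table, ["b1"], ["e1"], term_id="T")
        assert d.delta == pytest.approx(0.02)

    def test_copy_of_best_base_gives_zero(self):
        table = {"b1": 0.8, "b2": 0.7, "e1": 0.8}
        (d,) = delta_fmax(table, ["b1", "b2"], ["e1"])
        assert d.delta == 0.0

    def test_max_over_bases(self):
        table = {"b1": 0.8, "b2": 0.75, "e1": 0.7, "e2": 0.9}
        deltas = {d.method: d.delta for d in delta_fmax(table, ["b1", "b2"], ["e1", "e2"])}
        assert deltas["e1"] == pytest.approx(-0.1)
        assert deltas["e2"] == pytest.approx(0.1)

    def test_missing_method_raises(self):
        with pytest.raises(KeyError, match="e1"):
            delta_fmax({"b1": 0.8}, ["b1"], ["e1"])


class TestWilcoxon:
    def test_perfectly_balanced_pair(self):
        assert wilcoxon_signed_rank([0.3, -0.3]) == pytest.approx(1.0)

    def test_six_concordant_signs_exact(self):
        """Exact enumeration over all 2^6 sign assignments gives p = 2/64."""
        p = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
        # independent oracle: enumerate the null distribution of W+
        stats_all = [
            sum(r for r, s in zip([1, 2, 3, 4, 5, 6], signs) if s)
            for signs in itertools.product([0, 1], repeat=6)
        ]
        observed = 21
        p_oracle = np.mean([s >= observed for s in stats_all]) * 2
        assert p == pytest.approx(p_oracle) == pytest.approx(2 / 64)

    def test_large_sample_matches_reference(self, rng):
        d = rng.normal(0.1, 1.0, size=30)
        p = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, alternative="two-sided", method="approx", correction=False).pvalue
        assert p == pytest.approx(ref, abs=1e-8)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([0.0, 0.0])


class TestFriedmanNemenyi:
    def _random_table(self, rng, m=4, n=10):
        return pd.DataFrame(
            rng.random((m, n)),
            index=[f"M{i}" for i in range(m)],
            columns=[f"D{j}" for j in range(n)],
        )

    def test_uniform_winner_has_rank_one(self, rng):
        table = self._random_table(rng)
        table.loc["M0"] = 10.0  # strictly best everywhere
        res = friedman_nemenyi(table)
        assert res.average_ranks["M0"] == 1.0

    def test_complete_ties_give_p_one(self):
        table = pd.DataFrame(np.ones((4, 6)), index=list("ABCD"))
        res = friedman_nemenyi(table)
        assert res.p_value == 1.0
        assert (res.average_ranks == 2.5).all()

    def test_statistic_matches_scipy_reference(self, rng):
        for _ in range(20):
            m, n = int(rng.integers(3, 8)), int(rng.integers(3, 15))
            table = self._random_table(rng, m, n)
            res = friedman_nemenyi(table)
            ref = stats.friedmanchisquare(*[table.iloc[i].to_numpy() for i in range(m)])
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-8)

    def test_nemenyi_q_matches_published_table(self):
        # studentized range / sqrt(2) at alpha = 0.05 (Demsar's q_alpha values)
        from goensembles.evaluation import _nemenyi_q

        known = {2: 1.960, 3: 2.343, 5: 2.728, 10: 3.164}
        for m, q in known.items():
            assert _nemenyi_q(0.05, m) == pytest.approx(q, abs=2e-3)

    def test_cd_formula(self, rng):
        table = self._random_table(rng, m=5, n=12)
        res = friedman_nemenyi(table, alpha=0.05)
        from goensembles.evaluation import _nemenyi_q

        expected = _nemenyi_q(0.05, 5) * np.sqrt(5 * 6 / (6 * 12))
        assert res.critical_difference == pytest.approx(expected)

    def test_rank_rows_sum_to_m_m_plus_1_over_2(self, rng):
        table = self._random_table(rng, m=6, n=9)
        table.iloc[0, :3] = table.iloc[1, :3]  # inject ties
        res = friedman_nemenyi(table)
        sums = res.rank_matrix.sum(axis=0)
        assert np.allclose(sums, 6 * 7 / 2)

    def test_missing_cells_rejected(self):
        table = pd.DataFrame(np.ones((3, 4)))
        table.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            friedman_nemenyi(table)

    def test_group_structure_is_contiguous_in_rank_order(self, rng):
        table = self._random_table(rng, m=5, n=8)
        res = friedman_nemenyi(table)
        order = list(res.average_ranks.sort_values().index)
        for group in res.groups:
            positions = sorted(order.index(m) for m in group)
            assert positions == list(range(positions[0], positions[-1] + 1))


class TestStratifyByLevel:
    def test_level_means_and_grouping(self):
        deltas = [
            DeltaFmax("t1", "E", 0.1), DeltaFmax("t2", "E", 0.2),
            DeltaFmax("t3", "E", 0.3), DeltaFmax("t4", "E", 0.4),
        ]
        levels = {"t1": 1, "t2": 1, "t3": 2, "t4": 2}
        out = stratify_by_level(deltas, levels)
        assert out[1]["mean"] == pytest.approx(0.15)
        assert out[2]["mean"] == pytest.approx(0.35)

    def test_single_term_level_is_untestable(self):
        out = stratify_by_level([DeltaFmax("t1", "E", 0.1)], {"t1": 3})
        assert out[3]["p_value"] is None

    def test_missing_level_raises(self):
        with pytest.raises(KeyError, match="t9"):
            stratify_by_level([DeltaFmax("t9", "E", 0.1)], {})

    def test_planted_monotone_increase_is_recovered(self, rng):
        deltas, levels = [], {}
        for level in range(1, 5):
            for i in range(10):
                tid = f"L{level}_{i}"
                deltas.append(DeltaFmax(tid, "E", level * 0.05 + rng.normal(0, 0.005)))
                levels[tid] = level
        out = stratify_by_level(deltas, levels)
        means = [out[lv]["mean"] for lv in sorted(out)]
        assert means == sorted(means)
        assert all(out[lv]["p_value"] < 0.05 for lv in sorted(out))
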