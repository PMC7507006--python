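"""Differential screen statistics: exact rank-sum, BH, clustering, group test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from ppcet.differential import (
    benjamini_hochberg,
    cut_columns,
    differential_screen,
    meta_profile_group_test,
    rank_sum_pvalues,
    wilcoxon_rank_sum,
    zscore_and_cluster,
)


def enumeration_pvalue(x, y):
    """Brute-force two-sided rank-sum p: enumerate all label assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n1, n2 = len(x), len(y)
    m = n1 * n2

    def u_stat(xs, ys):
        return sum(1.0 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_stat(x, y)
    crit = min(u_obs, m - u_obs)
    hits = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n1 + n2) if i not in idx]
        u = u_stat(xs, ys)
        total += 1
        if min(u, m - u) <= crit + 1e-9:
            hits += 1
    return hits / total


class TestWilcoxonRankSum:
    def test_textbook_separation(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_all_identical_values_give_p_one(self):
        assert wilcoxon_rank_sum([5.0] * 4, [5.0] * 3) == 1.0

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.normal(size=6), rng.normal(size=9)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(wilcoxon_rank_sum(y, x))

    @pytest.mark.parametrize("n1,n2", [(1, 3), (2, 2), (3, 3), (4, 4), (3, 5), (4, 6), (2, 8)])
    def test_exact_matches_enumeration_for_every_rank_configuration(self, n1, n2):
        # p depends only on the rank split, so iterating all C(n, n1)
        # tie-free arrangements covers all tie-free inputs of this shape
        n = n1 + n2
        for idx in itertools.combinations(range(n), n1):
            vals = np.arange(1.0, n + 1)
            x = vals[list(idx)]
            y = np.delete(vals, list(idx))
            assert wilcoxon_rank_sum(x, y) == pytest.approx(
                enumeration_pvalue(x, y), abs=1e-12
            )

    def test_ties_use_corrected_normal_approximation(self, rng):
        x = np.round(rng.normal(size=30), 1)
        y = np.round(rng.normal(0.5, size=30), 1)
        expect = stats.mannwhitneyu(x, y, method="asymptotic").pvalue
        assert wilcoxon_rank_sum(x, y) == pytest.approx(expect, rel=1e-9)

    def test_large_samples_match_scipy_asymptotic(self, rng):
        x, y = rng.normal(size=40), rng.normal(0.3, size=35)
        expect = stats.mannwhitneyu(x, y, method="asymptotic").pvalue
        assert wilcoxon_rank_sum(x, y) == pytest.approx(expect, rel=1e-9)

    def test_vectorized_rows_match_scalar_calls(self, rng):
        X = rng.normal(size=(20, 8))
        Y = rng.normal(size=(20, 10))
        p_vec = rank_sum_pvalues(X, Y)
        for i in range(20):
            assert p_vec[i] == pytest.approx(wilcoxon_rank_sum(X[i], Y[i]), abs=1e-12)


class TestBenjaminiHochberg:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_degenerate_cases(self):
        np.testing.assert_allclose(benjamini_hochberg([1.0, 1.0]), [1.0, 1.0])
        np.testing.assert_allclose(benjamini_hochberg([0.37]), [0.37])
        assert benjamini_hochberg([]).size == 0

    def test_matches_hand_formula_on_random_vectors(self, rng):
        def hand_bh(p):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p, kind="stable")
            q_sorted = p[order] * m / np.arange(1, m + 1)
            q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
            q = np.empty(m)
            q[order] = np.minimum(q_sorted, 1.0)
            return q

        for _ in range(100):
            p = rng.random(int(rng.integers(1, 50)))
            np.testing.assert_allclose(benjamini_hochberg(p), hand_bh(p), atol=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30), st.randoms())
    def test_order_invariance(self, p, pyrandom):
        perm = list(range(len(p)))
        pyrandom.shuffle(perm)
        q = benjamini_hochberg(p)
        q_perm = benjamini_hochberg([p[i] for i in perm])
        np.testing.assert_allclose([q_perm[perm.index(i)] for i in range(len(p))], q, atol=1e-12)


def _toy_matrix(rng, n_genes=40, n1=6, n2=6, shift_genes=()):
    cols = [f"P{i}" for i in range(n1)] + [f"N{i}" for i in range(n2)]
    labels = pd.Series(["pCR"] * n1 + ["non-pCR"] * n2, index=cols)
    vals = rng.gamma(5.0, 1.0, size=(n_genes, n1 + n2))
    for g in shift_genes:
        vals[g, :n1] *= 4.0
    df = pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)], columns=cols)
    return df, labels


class TestDifferentialScreen:
    def test_label_swap_inverts_fold_change_only(self, rng):
        df, labels = _toy_matrix(rng, shift_genes=(0, 1))
        swapped = labels.map({"pCR": "non-pCR", "non-pCR": "pCR"})
        a = differential_screen(df, labels)
        b = differential_screen(df, swapped)
        np.testing.assert_allclose(b["fold_change"], 1.0 / a["fold_change"], rtol=1e-9)
        np.testing.assert_allclose(b["p_value"], a["p_value"], atol=1e-12)
        np.testing.assert_allclose(b["fdr"], a["fdr"], atol=1e-12)
        pd.testing.assert_series_equal(a["passes"], b["passes"])

    def test_column_duplication_never_increases_p(self, rng):
        df, labels = _toy_matrix(rng, n_genes=25, shift_genes=(0,))
        dup = pd.concat([df, df.add_suffix("_dup", axis=1)], axis=1)
        dup_labels = pd.concat([labels, labels.set_axis(labels.index + "_dup")])
        a = differential_screen(df, labels)
        b = differential_screen(dup, dup_labels)
        assert (b["p_value"] <= a["p_value"] + 1e-12).all()

    def test_one_empty_group_rejected(self, rng):
        df, labels = _toy_matrix(rng)
        with pytest.raises(ValueError, match="non-empty"):
            differential_screen(df, labels.map(lambda _: "pCR"))

    def test_pass_rule_is_two_sided(self, rng):
        df, labels = _toy_matrix(rng, n_genes=30, n1=8, n2=8)
        df.iloc[0, :8] *= 20.0  # strong enrichment in pCR
        df.iloc[1, :8] /= 20.0  # strong depletion in pCR
        rec = differential_screen(df, labels)
        assert rec.loc["g0", "passes"] and rec.loc["g1", "passes"]
        assert rec.loc["g0", "fold_change"] > 1.5 > 1 / 1.5 > rec.loc["g1", "fold_change"]


class TestZScoreCluster:
    def test_zscore_row_values(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["a", "b"], columns=["x", "y", "z"]
        )
        zm = zscore_and_cluster(df)
        np.testing.assert_allclose(zm.z.loc["a"], [-1.0, 0.0, 1.0])
        np.testing.assert_allclose(zm.z.loc["b"], 0.0)
        assert zm.constant_genes == ["b"]

    def test_identical_samples_are_adjacent_leaves(self, rng):
        vals = rng.normal(size=(10, 4))
        vals[:, 3] = vals[:, 0]
        df = pd.DataFrame(vals, index=[f"g{i}" for i in range(10)], columns=list("abcd"))
        zm = zscore_and_cluster(df)
        order = zm.col_order
        assert abs(order.index("a") - order.index("d")) == 1

    def test_block_structure_recovers_groups_at_k2(self, rng):
        df, labels = _toy_matrix(rng, n_genes=30, shift_genes=tuple(range(15)))
        zm = zscore_and_cluster(df)
        found = cut_columns(zm, 2)
        truth = (labels == "pCR").astype(int)
        assert adjusted_rand_score(truth[found.index], found) == 1.0


class TestMetaProfileGroupTest:
    def _profiles(self, base, delta, n=4):
        rows = {}
        for i in range(n):
            rows[f"P{i}"] = base
            rows[f"N{i}"] = base + delta
        labels = pd.Series({f"P{i}": "pCR" for i in range(n)} | {f"N{i}": "non-pCR" for i in range(n)})
        return pd.DataFrame.from_dict(rows, orient="index"), labels

    def test_identical_group_profiles_give_p_one(self, rng):
        base = rng.random(2000)
        prof, labels = self._profiles(base, 0.0)
        assert meta_profile_group_test(prof, labels) == 1.0

    def test_constant_shift_detected_by_offset_unit_at_full_flank(self, rng):
        base = rng.random(2000)
        prof, labels = self._profiles(base, -0.05)
        assert meta_profile_group_test(prof, labels, unit="offset-means") < 1e-6

    def test_constant_shift_detected_by_sample_means_default(self, rng):
        base = rng.random(2000)
        prof, labels = self._profiles(base, -0.5)
        p = meta_profile_group_test(prof, labels)
        assert 0 < p < 0.05

    def test_requires_two_samples_per_group(self, rng):
        prof, labels = self._profiles(rng.random(100), 0.1, n=1)
        with pytest.raises(ValueError, match=">= 2 samples"):
            meta_profile_group_test(prof, labels)
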