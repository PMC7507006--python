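"""LOOCV SVM panels, ROC/AUC, DeLong statistics, panel search."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ppcet.classifier import (
    auc_ci,
    chronological_split,
    compare_auc,
    confusion_metrics,
    evaluate_scores,
    loocv_scores,
    operating_point,
    panel_search,
    roc_auc,
)


def pairwise_auc(scores, y):
    """O(n^2) Mann-Whitney oracle with ties counted 1/2."""
    pos = [s for s, l in zip(scores, y) if l == 1]
    neg = [s for s, l in zip(scores, y) if l == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def _labels(y):
    return pd.Series(["pCR" if v else "non-pCR" for v in y])


class TestChronologicalSplit:
    def test_fraction_and_ordering(self, make_sample):
        recs = [make_sample(f"S{i:02d}", "pCR" if i % 2 else "non-pCR", day=i) for i in range(20)]
        split = chronological_split(recs, 0.7)
        assert len(split.training) == 14 and len(split.validation) == 6
        assert split.training == [f"S{i:02d}" for i in range(14)]

    def test_equal_dates_tie_break_by_sample_id(self, make_sample):
        recs = [make_sample(sid, "pCR" if i % 2 else "non-pCR", day=0) for i, sid in
                enumerate(["D", "C", "B", "A", "F", "E", "H", "G"])]
        split = chronological_split(recs, 0.5)
        assert split.training == ["A", "B", "C", "D"]

    def test_degenerate_fraction_rejected(self, make_sample):
        recs = [make_sample(f"S{i}", "pCR" if i % 2 else "non-pCR", day=i) for i in range(10)]
        with pytest.raises(ValueError):
            chronological_split(recs, 1.0)

    def test_cohort_with_too_few_of_a_label_rejected(self, make_sample):
        recs = [make_sample(f"S{i}", "pCR" if i < 9 else "non-pCR", day=i) for i in range(10)]
        with pytest.raises(ValueError, match="< 2"):
            chronological_split(recs, 0.7)


class TestLoocv:
    def test_separable_case_gives_perfect_auc(self, rng):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        x = pd.DataFrame({"f": y + rng.normal(0, 0.01, 8)})
        scores = loocv_scores(x, _labels(y).set_axis(x.index))
        _, auc = roc_auc(scores, _labels(y).set_axis(x.index))
        assert auc == 1.0

    def test_scores_match_fold_by_fold_oracle(self, rng):
        y = np.array([0, 1, 0, 1, 0, 1])
        x = pd.DataFrame(rng.normal(size=(6, 3)))
        got = loocv_scores(x, _labels(y).set_axis(x.index))
        for i in range(6):
            mask = np.ones(6, bool)
            mask[i] = False
            sc = StandardScaler().fit(x.to_numpy()[mask])
            clf = SVC(kernel="linear", C=1.0).fit(sc.transform(x.to_numpy()[mask]), y[mask])
            expect = clf.decision_function(sc.transform(x.to_numpy()[~mask]))[0]
            assert got.iloc[i] == pytest.approx(expect, abs=1e-9)

    def test_fold_model_independent_of_its_held_out_sample(self, rng):
        # corrupt sample 3's features: its own fold's model must be the one
        # fitted on the *uncorrupted* other samples, applied to the corrupt row
        y = np.array([0, 1] * 5)
        x = pd.DataFrame(rng.normal(size=(10, 2)))
        corrupted = x.copy()
        corrupted.iloc[3] = 50.0
        got = loocv_scores(corrupted, _labels(y).set_axis(x.index))
        mask = np.arange(10) != 3
        sc = StandardScaler().fit(x.to_numpy()[mask])
        clf = SVC(kernel="linear", C=1.0).fit(sc.transform(x.to_numpy()[mask]), y[mask])
        expect = clf.decision_function(sc.transform(corrupted.to_numpy()[~mask]))[0]
        assert got.iloc[3] == pytest.approx(expect, abs=1e-9)

    def test_permuted_labels_give_chance_level_mean_auc(self, rng):
        x = pd.DataFrame(rng.normal(size=(20, 3)))
        aucs = []
        for _ in range(20):
            y = rng.permutation([0] * 10 + [1] * 10)
            lab = _labels(y).set_axis(x.index)
            scores = loocv_scores(x, lab)
            aucs.append(roc_auc(scores, lab)[1])
        # LOOCV is conservatively biased under the null (per-fold refitting
        # anti-correlates held-out scores with labels); the leakage-relevant
        # direction is optimism, which must be absent
        assert np.mean(aucs) < 0.5 + 0.12
        assert np.mean(aucs) > 0.15


class TestRocAuc:
    def test_perfect_and_tied_conventions(self):
        lab = _labels([0, 0, 1, 1])
        assert roc_auc(pd.Series([1, 2, 3, 4]), lab)[1] == 1.0
        assert roc_auc(pd.Series([2.0] * 4), lab)[1] == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 51))
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[:2] = [0, 1]
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        _, auc = roc_auc(pd.Series(scores), _labels(y))
        assert auc == pytest.approx(pairwise_auc(scores, y), abs=1e-12)

    def test_label_swap_antisymmetry(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = pd.Series(rng.normal(size=30))
        a = roc_auc(s, _labels(y))[1]
        b = roc_auc(s, _labels(1 - y))[1]
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(pd.Series([1.0, 2.0]), _labels([1, 1]))


class TestDeLong:
    def test_ci_contains_point_estimate(self, rng):
        y = np.array([0] * 15 + [1] * 15)
        s = pd.Series(rng.normal(size=30) + y)
        (lo, hi), degenerate = auc_ci(s, _labels(y))
        _, auc = roc_auc(s, _labels(y))
        assert lo <= auc <= hi and not degenerate

    def test_perfect_separation_collapses_interval(self):
        y = [0] * 5 + [1] * 5
        s = pd.Series(np.arange(10, dtype=float))
        (lo, hi), degenerate = auc_ci(s, _labels(y))
        assert (lo, hi) == (1.0, 1.0) and degenerate

    def test_identical_classifiers_give_p_one(self, rng):
        y = np.array([0] * 10 + [1] * 10)
        s = pd.Series(rng.normal(size=20) + y)
        assert compare_auc(s, s, _labels(y)) == 1.0

    def test_opposed_perfect_classifiers_strongly_rejected(self):
        y = np.array([0] * 10 + [1] * 10)
        s = pd.Series(np.arange(20, dtype=float) + np.random.default_rng(0).normal(0, 0.01, 20))
        assert compare_auc(s, -s, _labels(y)) < 0.01

    def test_null_p_values_roughly_uniform(self, rng):
        y = np.array([0] * 12 + [1] * 12)
        lab = _labels(y)
        ps = []
        for _ in range(300):
            a = pd.Series(rng.normal(size=24))
            b = pd.Series(rng.normal(size=24))
            ps.append(compare_auc(a, b, lab))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestOperatingPoint:
    def test_perfect_separation_metrics(self):
        y = _labels([0, 0, 1, 1])
        s = pd.Series([0.1, 0.2, 0.8, 0.9])
        roc, _ = roc_auc(s, y)
        thr, sens, spec = operating_point(roc)
        assert (sens, spec) == (1.0, 1.0)
        assert confusion_metrics(s, y, thr) == (1.0, 1.0, 1.0)

    def test_all_tied_scores_pick_specificity(self):
        y = _labels([0, 0, 1, 1])
        s = pd.Series([0.5] * 4)
        roc, _ = roc_auc(s, y)
        thr, sens, spec = operating_point(roc)
        assert spec == 1.0 and sens == 0.0  # J = 0 everywhere; tiebreak to specificity

    def test_matches_exhaustive_threshold_scan(self, rng):
        y = np.array([0, 1, 0, 1, 1, 0])
        s = pd.Series(rng.normal(size=6))
        roc, _ = roc_auc(s, _labels(y))
        thr, sens, spec = operating_point(roc)
        best = -1.0
        for t in np.r_[s.to_numpy(), s.max() + 1]:
            se, sp, _ = confusion_metrics(s, _labels(y), t)
            best = max(best, se + sp - 1)
        assert sens + spec - 1 == pytest.approx(best)


class TestPanelSearch:
    def _features(self, rng, y, n_noise=4):
        cols = {"good": y + rng.normal(0, 0.05, len(y))}
        for i in range(n_noise):
            cols[f"n{i}"] = rng.normal(size=len(y))
        return pd.DataFrame(cols)

    def test_single_separating_gene_selected(self, rng):
        y = np.array([0, 1] * 6)
        feats = self._features(rng, y)
        res = panel_search(list(feats.columns), feats, _labels(y).set_axis(feats.index),
                           max_panel_size=2, pool_size=5)
        assert res.best.panel == ("good",)
        assert res.best.auc == 1.0

    def test_enumeration_count_contract(self, rng):
        y = np.array([0, 1] * 6)
        feats = self._features(rng, y)
        res = panel_search(list(feats.columns), feats, _labels(y).set_axis(feats.index),
                           max_panel_size=2, pool_size=5)
        assert res.n_evaluated == math.comb(5, 1) + math.comb(5, 2) == 15
        assert res.exhaustive

    def test_greedy_fallback_respects_budget(self, rng):
        y = np.array([0, 1] * 8)
        feats = self._features(rng, y, n_noise=7)
        res = panel_search(list(feats.columns), feats, _labels(y).set_axis(feats.index),
                           max_panel_size=3, pool_size=8, enumeration_budget=10)
        assert not res.exhaustive
        assert "good" in res.best.panel

    def test_empty_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            panel_search([], pd.DataFrame(), _labels([0, 1]))


class TestEvaluateScores:
    def test_metrics_schema(self, rng):
        y = np.array([0] * 8 + [1] * 8)
        s = pd.Series(rng.normal(size=16) + 2 * y)
        ev = evaluate_scores(s, _labels(y), "training", ["g1"])
        m = ev.metrics()
        assert set(m) == {"cohort", "panel", "auc", "auc_ci", "sensitivity",
                          "specificity", "accuracy", "n_pos", "n_neg"}
        assert m["n_pos"] == m["n_neg"] == 8
        assert ev.auc_ci[0] <= ev.auc <= ev.auc_ci[1]
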