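import numpy as np
import pytest

from ironsift.selection import (SelectionResult, indval_scores, select_indval,
                                select_multiple_ttest, select_presence_absence,
                                select_random_forest)
from ironsift.permanova import _distinct_labelings
from ironsift.tables import OTUTable


def _table(counts, otu_ids=None):
    counts = np.asarray(counts)
    return OTUTable(
        [f"s{i}" for i in range(counts.shape[0])],
        otu_ids or [f"Otu{j}" for j in range(counts.shape[1])],
        counts,
    )


class TestIndval:
    def test_perfect_indicator_scores_100(self):
        # OTU0 in every group-a sample, absent from group b
        t = _table([[5, 5], [7, 3], [0, 9], [0, 9]])
        labels = ["a", "a", "b", "b"]
        scores = indval_scores(t, labels)
        assert scores[0] == pytest.approx(100.0)

    def test_worked_arithmetic(self):
        # group1 counts (2,2,0), group2 (2,0,0), equal library sizes via a
        # filler OTU: A1 = 2/3, B1 = 2/3, IndVal = 400/9
        counts = np.array([
            [2, 8], [2, 8], [0, 10],   # group 1
            [2, 8], [0, 10], [0, 10],  # group 2
        ])
        t = _table(counts, ["target", "filler"])
        scores = indval_scores(t, ["g1"] * 3 + ["g2"] * 3)
        assert scores[0] == pytest.approx(400.0 / 9.0)

    def test_exact_permutation_matches_enumeration(self):
        rng = np.random.default_rng(0)
        t = _table(rng.integers(0, 30, size=(6, 5)) + 1)
        labels = ["a", "a", "a", "b", "b", "b"]
        sel = select_indval(t, labels, exact=True, alpha=1.1)
        # independent oracle: definitional IndVal over all labelings
        rel = t.counts / t.counts.sum(axis=1, keepdims=True)
        presence = t.counts >= 1

        def iv(codes):
            codes = np.asarray(codes)
            out = np.zeros(t.n_otus)
            for j in range(t.n_otus):
                best = 0.0
                for g in (0, 1):
                    mean_g = rel[codes == g, j].mean()
                    mean_h = rel[codes != g, j].mean()
                    a = mean_g / (mean_g + mean_h) if mean_g + mean_h > 0 else 0.0
                    b = presence[codes == g, j].mean()
                    best = max(best, a * b * 100.0)
                out[j] = best
            return out

        codes = np.array([0, 0, 0, 1, 1, 1])
        obs = iv(codes)
        perms = list(_distinct_labelings(codes))
        exceed = np.zeros(t.n_otus)
        for perm in perms:
            exceed += iv(perm) >= obs
        expected_p = exceed / len(perms)
        assert sel.params["n_permutations"] == len(perms) == 20
        # alpha > 1 selects every OTU, exposing all IndVal scores
        for j, otu in enumerate(t.otu_ids):
            assert sel.scores[otu] == pytest.approx(obs[j])
        # selection decision at a real alpha matches the oracle p after BH
        from ironsift.stats import bh_adjust
        for alpha in (0.2, 0.5, 0.8):
            expected = {t.otu_ids[j]
                        for j in np.flatnonzero(bh_adjust(expected_p) < alpha)}
            got = set(select_indval(t, labels, exact=True,
                                    alpha=alpha).selected_otus)
            assert got == expected

    def test_deterministic(self, planted_cohort_factory):
        t, m, _ = planted_cohort_factory(0)
        labels = m.column_for(t.sample_ids, "timepoint")
        s1 = select_indval(t, labels, n_permutations=199, seed=4)
        s2 = select_indval(t, labels, n_permutations=199, seed=4)
        assert s1.selected_otus == s2.selected_otus
        assert s1.scores == s2.scores

    def test_column_order_invariance(self):
        rng = np.random.default_rng(1)
        t = _table(rng.integers(0, 50, size=(8, 10)))
        labels = ["a"] * 4 + ["b"] * 4
        perm = rng.permutation(t.n_otus)
        tp = t.select_otus([t.otu_ids[j] for j in perm])
        s1 = select_indval(t, labels, n_permutations=99, seed=0)
        s2 = select_indval(tp, labels, n_permutations=99, seed=0)
        assert set(s1.selected_otus) == set(s2.selected_otus)

    def test_single_group_errors(self):
        t = _table([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="2 classes"):
            select_indval(t, ["a", "a"])


class TestPresenceAbsence:
    def test_full_to_zero_selected(self):
        counts = np.vstack([np.tile([3, 5], (5, 1)), np.tile([0, 5], (5, 1))])
        t = _table(counts)
        sel = select_presence_absence(t, ["B14"] * 5 + ["LI7"] * 5)
        assert sel.selected_otus == ["Otu0"]
        assert sel.scores["Otu0"] == pytest.approx(1.0)

    def test_weak_prevalence_shift_not_selected(self):
        # 3/5 vs 2/5: neither side is "> half vs zero"
        g1 = np.array([[1], [1], [1], [0], [0]])
        g2 = np.array([[1], [1], [0], [0], [0]])
        t = _table(np.vstack([g1, g2]))
        sel = select_presence_absence(t, ["a"] * 5 + ["b"] * 5)
        assert sel.selected_otus == []

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(3)
        t = _table(rng.integers(0, 2, size=(10, 40)) * rng.integers(1, 9, (10, 40)))
        labels = ["a"] * 5 + ["b"] * 5
        sel = select_presence_absence(t, labels)
        expected = set()
        for j, otu in enumerate(t.otu_ids):
            pa = np.mean(t.counts[:5, j] >= 1)
            pb = np.mean(t.counts[5:, j] >= 1)
            if (pa > 0.5 and pb <= 0.0) or (pb > 0.5 and pa <= 0.0):
                expected.add(otu)
        assert set(sel.selected_otus) == expected

    def test_direction_symmetric(self):
        counts = np.vstack([np.tile([0, 5], (5, 1)), np.tile([3, 5], (5, 1))])
        t = _table(counts)
        sel = select_presence_absence(t, ["B14"] * 5 + ["LI7"] * 5)
        assert sel.selected_otus == ["Otu0"]


class TestMultipleTtest:
    def test_identical_values_never_selected(self):
        t = _table(np.tile([10, 20, 30], (8, 1)))
        sel = select_multiple_ttest(t, ["a"] * 4 + ["b"] * 4)
        assert sel.selected_otus == []

    def test_constant_zero_otu_skipped(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 50, size=(8, 4))
        counts[:, 2] = 0
        t = _table(counts)
        sel = select_multiple_ttest(t, ["a"] * 4 + ["b"] * 4, alpha=1.0)
        assert "Otu2" not in sel.scores

    def test_bonferroni_subset_of_bh(self, planted_cohort_factory):
        t, m, _ = planted_cohort_factory(1)
        labels = m.column_for(t.sample_ids, "timepoint")
        subjects = m.column_for(t.sample_ids, "mouse_id")
        bonf = select_multiple_ttest(t, labels, correction="bonferroni",
                                     paired=True, subjects=subjects)
        bh = select_multiple_ttest(t, labels, correction="bh",
                                   paired=True, subjects=subjects)
        assert set(bonf.selected_otus) <= set(bh.selected_otus)

    def test_paired_requires_subjects(self):
        t = _table(np.ones((4, 2), dtype=int))
        with pytest.raises(ValueError, match="subjects"):
            select_multiple_ttest(t, ["a", "a", "b", "b"], paired=True)

    def test_recall_on_planted_cohorts(self, planted_cohort_factory):
        recalls = []
        for seed in range(10):
            t, m, g = planted_cohort_factory(seed)
            labels = m.column_for(t.sample_ids, "timepoint")
            subjects = m.column_for(t.sample_ids, "mouse_id")
            sel = select_multiple_ttest(t, labels, correction="bonferroni",
                                        alpha=0.05, paired=True,
                                        subjects=subjects)
            hits = len(set(sel.selected_otus) & g.sensitive_otus)
            recalls.append(hits / len(g.sensitive_otus))
        assert np.mean(recalls) >= 0.8

    def test_column_order_invariance(self):
        rng = np.random.default_rng(5)
        t = _table(rng.integers(0, 60, size=(10, 20)))
        labels = ["a"] * 5 + ["b"] * 5
        perm = rng.permutation(t.n_otus)
        tp = t.select_otus([t.otu_ids[j] for j in perm])
        s1 = select_multiple_ttest(t, labels, alpha=0.5)
        s2 = select_multiple_ttest(tp, labels, alpha=0.5)
        assert set(s1.selected_otus) == set(s2.selected_otus)


class TestRandomForest:
    def test_deterministic(self, planted_cohort_factory):
        t, m, _ = planted_cohort_factory(2)
        labels = m.column_for(t.sample_ids, "timepoint")
        kw = dict(n_trees=50, importance_null_reps=5, n_repeats=1, seed=42)
        s1 = select_random_forest(t, labels, **kw)
        s2 = select_random_forest(t, labels, **kw)
        assert s1.selected_otus == s2.selected_otus
        assert s1.scores == s2.scores
        assert s1.params["threshold"] == s2.params["threshold"]

    def test_single_class_errors(self):
        t = _table(np.ones((4, 3), dtype=int))
        with pytest.raises(ValueError, match="2 classes"):
            select_random_forest(t, ["a"] * 4)

    def test_small_class_errors(self):
        t = _table(np.ones((3, 3), dtype=int))
        with pytest.raises(ValueError, match="at least 2 samples"):
            select_random_forest(t, ["a", "a", "b"])

    def test_top_k_mode(self, planted_cohort_factory):
        t, m, g = planted_cohort_factory(3)
        labels = m.column_for(t.sample_ids, "timepoint")
        sel = select_random_forest(t, labels, n_trees=300, top_k=5, seed=0)
        assert sel.n_selected == 5
        # strong planted signal: fixed-size selection should hit the truth
        assert len(set(sel.selected_otus) & g.sensitive_otus) >= 4

    def test_recall_and_precision_on_planted_cohorts(self, planted_cohort_factory):
        recalls, precisions = [], []
        for seed in range(8):
            t, m, g = planted_cohort_factory(seed + 100)
            labels = m.column_for(t.sample_ids, "timepoint")
            sel = select_random_forest(t, labels, n_trees=300,
                                       importance_null_reps=19, seed=seed)
            chosen = set(sel.selected_otus)
            tp = len(chosen & g.sensitive_otus)
            recalls.append(tp / len(g.sensitive_otus))
            precisions.append(tp / len(chosen) if chosen else 1.0)
        assert np.mean(recalls) >= 0.8
        assert np.mean(precisions) >= 0.8

    def test_scores_cover_selection(self, planted_cohort_factory):
        t, m, _ = planted_cohort_factory(4)
        labels = m.column_for(t.sample_ids, "timepoint")
        sel = select_random_forest(t, labels, n_trees=100,
                                   importance_null_reps=5, n_repeats=1, seed=1)
        assert set(sel.selected_otus) == set(sel.scores)


def test_selection_result_requires_scores():
    with pytest.raises(ValueError, match="without scores"):
        SelectionResult(method="x", selected_otus=["a"], scores={})
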