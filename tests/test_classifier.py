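"""Overlap percentage, random splits, <OP> scoring and ROC evaluation."""

import numpy as np
import pandas as pd
import pytest

import modprog as mp
from modprog.classifier import PipelineParams


class TestOverlapPercentage:
    def test_identical_sets(self):
        assert mp.overlap_percentage({"x", "y", "z"}, {"x", "y", "z"}) == 1.0

    def test_disjoint_sets(self):
        assert mp.overlap_percentage({"x", "y"}, {"z", "w"}) == 0.0

    def test_half_overlap(self):
        assert mp.overlap_percentage({"x", "y", "z"}, {"y", "z", "w"}) == 0.5

    def test_both_empty_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert mp.overlap_percentage(set(), set()) == 0.0

    def test_symmetric_and_one_iff_equal(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = set(rng.choice(20, size=rng.integers(1, 10), replace=False).tolist())
            b = set(rng.choice(20, size=rng.integers(1, 10), replace=False).tolist())
            assert mp.overlap_percentage(a, b) == mp.overlap_percentage(b, a)
            assert (mp.overlap_percentage(a, b) == 1.0) == (a == b)


class TestRandomSplit:
    def _labels(self, n_non, n_rec):
        names = [f"n{i}" for i in range(n_non)] + [f"r{i}" for i in range(n_rec)]
        return names, pd.Series(
            ["non_recurrent"] * n_non + ["recurrent"] * n_rec, index=names
        )

    def test_even_split(self):
        names, labels = self._labels(10, 10)
        split = mp.random_split(names, labels, seed=0)
        for half in (split.half_1, split.half_2):
            assert sum(labels[s] == "recurrent" for s in half) == 5
            assert sum(labels[s] == "non_recurrent" for s in half) == 5
        assert set(split.half_1) | set(split.half_2) == set(names)
        assert not set(split.half_1) & set(split.half_2)

    def test_odd_counts_extra_goes_to_half_1(self):
        names, labels = self._labels(9, 8)
        split = mp.random_split(names, labels, seed=3)
        assert sum(labels[s] == "non_recurrent" for s in split.half_1) == 5
        assert sum(labels[s] == "recurrent" for s in split.half_1) == 4

    def test_same_seed_same_halves(self):
        names, labels = self._labels(8, 8)
        assert mp.random_split(names, labels, 7) == mp.random_split(names, labels, 7)

    def test_small_class_rejected(self):
        names, labels = self._labels(3, 8)
        with pytest.raises(ValueError, match="non_recurrent"):
            mp.random_split(names, labels, 0)


class TestRocAndMetrics:
    def _scores(self, pairs):
        return [mp.PredictionScore(sample_id=s, components={}, score=v)
                for s, v in pairs]

    def test_perfect_separation(self):
        labels = pd.Series({"r1": "recurrent", "r2": "recurrent",
                            "n1": "non_recurrent", "n2": "non_recurrent"})
        rep = mp.roc_and_metrics(
            self._scores([("r1", 0.9), ("r2", 0.8), ("n1", 0.2), ("n2", 0.1)]), labels
        )
        assert rep.auc == 1.0 and rep.accuracy == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0

    def test_constant_scores_give_half_auc(self):
        labels = pd.Series({"r1": "recurrent", "n1": "non_recurrent",
                            "r2": "recurrent", "n2": "non_recurrent"})
        rep = mp.roc_and_metrics(self._scores([(s, 0.5) for s in labels.index]), labels)
        assert rep.auc == pytest.approx(0.5)

    def test_auc_equals_concordant_pair_fraction(self):
        # brute force: pairs (rec, non) with rec > non: 3 of 4 -> AUC 0.75
        labels = pd.Series({"r1": "recurrent", "r2": "recurrent",
                            "n1": "non_recurrent", "n2": "non_recurrent"})
        scores = [("r1", 0.9), ("r2", 0.8), ("n1", 0.85), ("n2", 0.1)]
        concordant = sum(rv > nv for rs, rv in scores[:2] for ns, nv in scores[2:])
        rep = mp.roc_and_metrics(self._scores(scores), labels)
        assert rep.auc == pytest.approx(concordant / 4) == pytest.approx(0.75)

    def test_roc_monotone(self):
        rng = np.random.default_rng(0)
        labels = pd.Series({f"s{i}": ("recurrent" if i % 2 else "non_recurrent")
                            for i in range(20)})
        rep = mp.roc_and_metrics(
            self._scores([(f"s{i}", float(rng.random())) for i in range(20)]), labels
        )
        assert (rep.roc_points["fpr"].diff().dropna() >= 0).all()
        assert (rep.roc_points["tpr"].diff().dropna() >= 0).all()

    def test_single_class_is_an_error(self):
        labels = pd.Series({"r1": "recurrent", "r2": "recurrent"})
        with pytest.raises(ValueError):
            mp.roc_and_metrics(self._scores([("r1", 1.0), ("r2", 0.0)]), labels)


@pytest.fixture(scope="module")
def cohort_bits(small_cohort):
    ds = small_cohort.dataset
    rec = ds.samples_with_label("recurrent")
    non = ds.samples_with_label("non_recurrent")
    train = rec[:8] + non[:8]
    tests = rec[8:12] + non[8:12]
    return ds, small_cohort.sets, small_cohort.ppi, train, tests


class TestPredictScore:
    def test_deterministic_given_seed(self, cohort_bits):
        ds, sets, ppi, train, tests = cohort_bits
        params = PipelineParams(n_splits=1, n_grid=(5, 10), mode="rank_only")
        s1 = mp.predict_score(tests[0], ds, train, sets, ppi, params, base_seed=4)
        s2 = mp.predict_score(tests[0], ds, train, sets, ppi, params, base_seed=4)
        assert s1.score == s2.score
        assert s1.components == s2.components

    def test_full_mode_runs_and_is_deterministic(self, cohort_bits):
        ds, sets, ppi, train, tests = cohort_bits
        params = PipelineParams(n_splits=1, n_grid=(5,), mode="full")
        s1 = mp.predict_score(tests[0], ds, train, sets, ppi, params, base_seed=4)
        s2 = mp.predict_score(tests[0], ds, train, sets, ppi, params, base_seed=4)
        assert s1.score == s2.score
        assert np.isfinite(s1.score) and s1.score >= 0

    def test_training_overlap_rejected(self, cohort_bits):
        ds, sets, ppi, train, _ = cohort_bits
        with pytest.raises(ValueError):
            mp.predict_score(train[0], ds, train, sets, ppi)

    def test_constant_expression_gives_identity_score(self):
        """If rankings cannot change (all-tied data), every component is
        OP_new/OP_old = 1 and the score is exactly 1."""
        samples = [f"r{i}" for i in range(5)] + [f"n{i}" for i in range(5)] + ["x"]
        labels = pd.Series(["recurrent"] * 5 + ["non_recurrent"] * 5 + ["unlabeled"],
                           index=samples)
        rng = np.random.default_rng(1)
        base = rng.normal(size=(6, 1))
        values = pd.DataFrame(np.tile(base, (1, 11)),
                              index=[f"G{i}" for i in range(6)], columns=samples)
        ds = mp.ExpressionDataset(values=values, labels=labels)
        sets = mp.GeneSetCollection(sets={"S1": [f"G{i}" for i in range(6)]})
        ppi = mp.InteractionNetwork(
            edges={frozenset((f"G{i}", f"G{i+1}")) for i in range(5)}
        )
        params = PipelineParams(n_splits=2, n_grid=(1, 2), mode="rank_only")
        with pytest.warns(UserWarning):  # zero-variance genes
            score = mp.predict_score("x", ds, samples[:10], sets, ppi, params, 0)
        assert score.score == pytest.approx(1.0)

    def test_score_invariant_to_gene_row_order(self, cohort_bits):
        ds, sets, ppi, train, tests = cohort_bits
        params = PipelineParams(n_splits=1, n_grid=(5,), mode="rank_only")
        s1 = mp.predict_score(tests[0], ds, train, sets, ppi, params, base_seed=2)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n_genes)
        ds2 = mp.ExpressionDataset(values=ds.values.iloc[perm], labels=ds.labels)
        s2 = mp.predict_score(tests[0], ds2, train, sets, ppi, params, base_seed=2)
        assert s1.score == pytest.approx(s2.score, abs=1e-12)


class TestEvaluators:
    def test_leave_one_out_count_contract(self, small_cohort):
        ds = small_cohort.dataset
        keep = (ds.samples_with_label("recurrent")[:5]
                + ds.samples_with_label("non_recurrent")[:5])
        sub = ds.subset_samples(keep)
        params = PipelineParams(n_splits=1, n_grid=(5,), mode="rank_only")
        rep = mp.leave_one_out(sub, small_cohort.sets, small_cohort.ppi, params, 0)
        assert len(rep.scores) == 10
        assert rep.protocol == "LOO"

    def test_loo_needs_five_per_class(self, small_cohort):
        ds = small_cohort.dataset
        keep = (ds.samples_with_label("recurrent")[:4]
                + ds.samples_with_label("non_recurrent")[:6])
        with pytest.raises(ValueError):
            mp.leave_one_out(ds.subset_samples(keep), small_cohort.sets,
                             small_cohort.ppi)

    def test_fixed_train_counts_and_summary_order(self, small_cohort):
        ds, sets, ppi = small_cohort.dataset, small_cohort.sets, small_cohort.ppi
        params = PipelineParams(n_splits=1, n_grid=(5,), mode="rank_only")
        reports, summary = mp.fixed_train_validation(
            ds, sets, ppi, train_size=16, n_repeats=2, params=params, base_seed=1
        )
        assert len(reports) == 2
        for metric, s in summary.items():
            assert s["min"] <= s["mean"] <= s["max"]

    def test_fixed_train_too_large_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            mp.fixed_train_validation(
                small_cohort.dataset, small_cohort.sets, small_cohort.ppi,
                train_size=24,
            )
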