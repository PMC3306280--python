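"""Enrichment fractions, Fisher tests, permutation controls, Grubbs, frequencies."""

import math

import numpy as np
import pandas as pd
import pytest

import modprog as mp
from modprog.community import Module, ModulePartition
from modprog.ranking import ModuleScore, RankedModules
from modprog.classifier import PipelineParams


def hypergeom_tail_oracle(universe: int, k_mut: int, m: int, x: int) -> float:
    """P(X >= x) by direct combinatorial enumeration."""
    total = math.comb(universe, m)
    return sum(
        math.comb(k_mut, i) * math.comb(universe - k_mut, m - i)
        for i in range(x, min(k_mut, m) + 1)
    ) / total


class TestKnownGeneFraction:
    def test_direct_fraction(self):
        cat = mp.GeneCatalog(genes={"a", "b"})
        assert mp.known_gene_fraction({"a", "b", "c", "d"}, cat) == 0.5

    def test_disjoint_and_subset(self):
        cat = mp.GeneCatalog(genes={"a", "b"})
        assert mp.known_gene_fraction({"c", "d"}, cat) == 0.0
        assert mp.known_gene_fraction({"a", "b"}, cat) == 1.0

    def test_empty_top_rejected(self):
        with pytest.raises(ValueError):
            mp.known_gene_fraction(set(), mp.GeneCatalog(genes={"a"}))


class TestTtestGeneControl:
    def _ds(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(30, 40))
        vals[:5, :20] += 3.0
        cols = [f"a{i}" for i in range(20)] + [f"b{i}" for i in range(20)]
        labels = pd.Series(["recurrent"] * 20 + ["non_recurrent"] * 20, index=cols)
        return mp.ExpressionDataset(
            values=pd.DataFrame(vals, index=[f"G{i}" for i in range(30)], columns=cols),
            labels=labels,
        )

    def test_m_equals_total_returns_all(self):
        ds = self._ds()
        out = mp.ttest_gene_control(ds, ds.samples_with_label("recurrent"),
                                    ds.samples_with_label("non_recurrent"), 30)
        assert out == set(ds.gene_ids)

    def test_zero_m_returns_empty(self):
        ds = self._ds()
        assert mp.ttest_gene_control(ds, ds.samples_with_label("recurrent"),
                                     ds.samples_with_label("non_recurrent"), 0) == set()

    def test_planted_genes_occupy_the_top(self):
        ds = self._ds()
        top5 = mp.ttest_gene_control(ds, ds.samples_with_label("recurrent"),
                                     ds.samples_with_label("non_recurrent"), 5)
        assert top5 == {f"G{i}" for i in range(5)}


class TestMutatedModuleTest:
    def test_two_of_two_in_small_universe(self):
        # C(2,2)C(2,0)/C(4,2) = 1/6
        cat = mp.GeneCatalog(genes={"A", "B"}, annotation="mutated_gene")
        mod = Module(set_id="S", genes=("A", "B"))
        p = mp.mutated_module_test(mod, cat, {"A", "B", "C", "D"})
        assert p == pytest.approx(1 / 6, abs=1e-12)

    def test_no_mutated_genes_gives_one(self):
        cat = mp.GeneCatalog(genes={"Z"}, annotation="mutated_gene")
        mod = Module(set_id="S", genes=("A", "B"))
        assert mp.mutated_module_test(mod, cat, {"A", "B", "C", "Z"}) <= 1.0
        cat2 = mp.GeneCatalog(genes={"Q"}, annotation="mutated_gene")
        assert mp.mutated_module_test(mod, cat2, {"A", "B", "C", "D", "Q"}) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        u = int(rng.integers(4, 25))
        genes = [f"g{i}" for i in range(u)]
        k_mut = int(rng.integers(0, u + 1))
        m = int(rng.integers(2, u + 1))
        mutated = set(genes[:k_mut]) or {"none"}
        module_genes = list(rng.choice(genes, size=m, replace=False))
        cat = mp.GeneCatalog(genes=mutated, annotation="mutated_gene")
        x = len(set(module_genes) & mutated)
        p = mp.mutated_module_test(module_genes, cat, genes)
        assert p == pytest.approx(hypergeom_tail_oracle(u, len(set(genes) & mutated),
                                                        m, x), abs=1e-10)


def _ranked_with_mm(n_top_mm=5, n_rest_mm=9, n_top=10, n_rest=90):
    """100 two-gene modules; MM modules have both genes mutated."""
    universe, mutated, modules = [], set(), []
    gi = 0
    flags = [True] * n_top_mm + [False] * (n_top - n_top_mm) \
        + [True] * n_rest_mm + [False] * (n_rest - n_rest_mm)
    for is_mm in flags:
        g1, g2 = f"g{gi}", f"g{gi+1}"
        gi += 2
        universe += [g1, g2]
        if is_mm:
            mutated |= {g1, g2}
        modules.append(Module(set_id=f"S{gi}", genes=(g1, g2)))
    universe += [f"pad{i}" for i in range(200)]
    entries = [ModuleScore(module=m, k=2, sds=float(100 - i), p_value=i / 1000)
               for i, m in enumerate(modules)]
    return RankedModules(entries=entries), mp.GeneCatalog(
        genes=mutated or {"pad0"}, annotation="mutated_gene"), set(universe)


class TestMmEnrichmentRatio:
    def test_hand_computed_ratio(self):
        ranked, cat, universe = _ranked_with_mm()
        res = mp.mm_enrichment_ratio(ranked, cat, universe, N=10)
        assert res.ratio == pytest.approx(5.0)
        assert res.observed_fraction == 0.5
        assert res.control_fractions["rest_modules"] == pytest.approx(0.1)
        assert 0.0 <= res.p_value <= 1.0

    def test_requires_more_than_n_modules(self):
        ranked, cat, universe = _ranked_with_mm()
        with pytest.raises(ValueError):
            mp.mm_enrichment_ratio(ranked, cat, universe, N=100)

    def test_null_fisher_p_super_uniform(self):
        """Random mutation flags over a fixed ranking: P(p < 0.05) stays near
        or below nominal (the test is conservative)."""
        ranked, _, universe = _ranked_with_mm(0, 0)
        genes = sorted(universe)
        rng = np.random.default_rng(0)
        hits = 0
        n_runs = 300
        for _ in range(n_runs):
            mutated = set(np.array(genes)[rng.random(len(genes)) < 0.15])
            cat = mp.GeneCatalog(genes=mutated or {"pad0"}, annotation="mutated_gene")
            res = mp.mm_enrichment_ratio(ranked, cat, universe, N=10)
            hits += res.p_value < 0.05
        assert hits / n_runs <= 0.07


class TestLabelPermutationControl:
    def _labels(self, n=10):
        names = [f"r{i}" for i in range(n)] + [f"n{i}" for i in range(n)]
        return pd.Series(["recurrent"] * n + ["non_recurrent"] * n, index=names)

    def test_identity_statistic_reproduced_exactly(self):
        labels = self._labels()
        stat = lambda lab: float((lab == "recurrent").sum())
        out = mp.label_permutation_control(stat, labels, n_perm=10, seed=0)
        assert out["observed"] == 10.0
        assert np.all(out["null"] == 10.0)  # class sizes preserved
        assert out["p_value"] == 1.0

    def test_observed_above_all_null(self):
        labels = self._labels()
        reference = labels.copy()
        stat = lambda lab: float((lab == reference).all())
        out = mp.label_permutation_control(stat, labels, n_perm=99, seed=1)
        assert out["observed"] == 1.0
        # add-one rule: (0+1)/(99+1) when no permutation reproduces the labels
        assert out["p_value"] == pytest.approx((int((out["null"] >= 1.0).sum()) + 1) / 100)

    def test_zero_permutations_rejected(self):
        with pytest.raises(ValueError):
            mp.label_permutation_control(lambda lab: 0.0, self._labels(), 0, 0)


class TestGrubbs:
    def test_observed_at_null_mean_not_an_outlier(self):
        assert mp.grubbs_outlier_test([1.0, 1.1, 0.9, 1.05, 0.95], 1.0) > 0.5

    def test_strictly_decreasing_in_observed(self):
        null = [1.0, 1.1, 0.9, 1.05, 0.95]
        ps = [mp.grubbs_outlier_test(null, obs) for obs in (1.2, 1.5, 2.0, 3.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_extreme_outlier_is_significant(self):
        null = list(np.random.default_rng(0).normal(1.0, 0.05, size=30))
        assert mp.grubbs_outlier_test(null, 2.0) < 0.006

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            mp.grubbs_outlier_test([1.0, 1.0], 1.0)
        with pytest.raises(ValueError):
            mp.grubbs_outlier_test([1.0, 1.0, 1.0], 1.0)


class TestGeneAppearanceFrequency:
    def test_single_split_counts_binary_and_degree_normalised(self, small_cohort):
        params = PipelineParams(n_splits=1, n_grid=(5,), mode="rank_only")
        ft = mp.gene_appearance_frequency(
            small_cohort.dataset, small_cohort.sets, small_cohort.ppi,
            n_splits=1, N=10, seed=0, params=params,
        )
        degrees = small_cohort.ppi.degrees()
        assert set(ft.table["raw_count"].unique()) <= {1}
        for gene, row in ft.table.iterrows():
            assert row["normalized_frequency"] == pytest.approx(
                row["raw_count"] / max(degrees.get(gene, 0), 1)
            )

    def test_counts_bounded_by_splits(self, small_cohort):
        params = PipelineParams(n_splits=1, n_grid=(5,), mode="rank_only")
        ft = mp.gene_appearance_frequency(
            small_cohort.dataset, small_cohort.sets, small_cohort.ppi,
            n_splits=3, N=10, seed=1, params=params,
        )
        assert (ft.table["raw_count"] <= 3).all()
        assert ft.n_splits == 3


class TestRankGeneSets:
    def test_planted_host_sets_rank_first(self, small_cohort):
        ds = small_cohort.dataset
        df = mp.rank_gene_sets(ds, small_cohort.sets,
                               ds.samples_with_label("recurrent"),
                               ds.samples_with_label("non_recurrent"))
        hosts = {p["set_id"] for p in small_cohort.planted}
        assert hosts <= set(df.head(4)["set_id"])
        assert (df["p_value"].diff().dropna() >= 0).all()
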