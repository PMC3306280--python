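"""End-to-end study-condition experiments on synthetic cohorts.

These functions bundle the package's own evaluation experiments — null
calibration of the module p-values, planted-module recovery, classifier
signal recovery, cross-cohort overlap reproducibility and mutation
enrichment — at the synthetic problem sizes the package uses throughout
(500 genes, 30 gene sets, 25-30 samples per class, 5 planted 8-gene
modules).  The classifier runs use n_splits=10 and an N grid of
(30, 40, 50, 60, 80): with ~150 modules per synthetic ranking this grid
spans the mid-depth of the list, where top-N membership is sensitive to the
test tumour's label (the very top is saturated by the planted modules and
carries no per-sample information).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .classifier import PipelineParams, evaluate_holdout
from .model import ModulePrognosis
from .ranking import welch_t
from .simulate import (
    SyntheticConfig,
    generate_cohort,
    generate_structure,
    planted_recovery_fraction,
)
from .validation import (
    cross_cohort_overlap_significance,
    label_permutation_control,
    mm_enrichment_ratio,
)
from .ranking import rank_modules

#: classifier settings for synthetic-scale cohorts (~150 modules)
SYNTH_PARAMS = PipelineParams(n_splits=10, n_grid=(30, 40, 50, 60, 80), mode="rank_only")


def null_calibration_rate(
    k: int, n_modules: int = 2000, n_per_class: int = 30, seed: int = 0
) -> float:
    """Fraction of size-k null modules with chi-square p < 0.05.

    Both classes are drawn from the same standard normal, so the fraction
    should sit near the nominal 0.05 if the chi-square calibration of the
    sum of squared t statistics is adequate.
    """
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n_modules * k, n_per_class))
    b = rng.normal(size=(n_modules * k, n_per_class))
    t = welch_t(a, b)
    sds = (t * t).reshape(n_modules, k).sum(axis=1)
    p = stats.chi2.sf(sds, df=k)
    return float(np.mean(p < 0.05))


def planted_recovery(seeds, top_n: int = 20, min_fraction: float = 0.5) -> float:
    """Mean fraction of planted modules surfacing in the top-n ranking.

    One default-configuration cohort per seed (500 genes, 30 sets, 5 planted
    8-gene modules, rho=0.6, shift 1.5 sd, 25 samples per class); a planted
    module counts as recovered when at least ``min_fraction`` of its genes
    lie in the top-n modules' gene union.
    """
    fractions = []
    for seed in seeds:
        cohort = generate_cohort(SyntheticConfig(seed=int(seed)))
        res = ModulePrognosis.from_cohort(cohort).fit()
        fractions.append(
            planted_recovery_fraction(res.ranked, cohort.planted, top_n, min_fraction)
        )
    return float(np.mean(fractions))


def classifier_auc(
    effect_shift: float,
    seeds,
    n_train_per_class: int = 20,
    n_test_per_class: int = 10,
    params: PipelineParams = SYNTH_PARAMS,
) -> float:
    """Mean hold-out AUC of the <OP> classifier over the given seeds.

    Each seed draws a cohort with ``n_train_per_class + n_test_per_class``
    samples per class; the test block is scored against the training block
    in fast rank-only mode.
    """
    aucs = []
    for seed in seeds:
        cfg = SyntheticConfig(
            seed=int(seed),
            effect_shift=effect_shift,
            n_samples_per_class=n_train_per_class + n_test_per_class,
        )
        cohort = generate_cohort(cfg)
        ds = cohort.dataset
        rec = ds.samples_with_label("recurrent")
        non = ds.samples_with_label("non_recurrent")
        train = rec[:n_train_per_class] + non[:n_train_per_class]
        test = rec[n_train_per_class:] + non[n_train_per_class:]
        rep = evaluate_holdout(
            ds, cohort.sets, cohort.ppi, train, test, params,
            base_seed=int(seed) * 7 + 1,
        )
        aucs.append(rep.auc)
    return float(np.mean(aucs))


def overlap_reproducibility(seed: int = 0, N: int = 20, n_perm: int = 50) -> dict:
    """Top-module overlap of two cohorts sharing planted structure vs null.

    Two cohorts share gene sets, edges and planted modules but draw
    independent expression noise; the observed top-N gene-union overlap is
    compared with label-permutation null overlaps.  Returns observed, null
    values, empirical p and the Grubbs outlier p.
    """
    cfg_a = SyntheticConfig(seed=int(seed))
    cfg_b = SyntheticConfig(seed=int(seed) + 1)
    structure = generate_structure(cfg_a)
    cohort_a = generate_cohort(cfg_a, structure=structure)
    cohort_b = generate_cohort(cfg_b, structure=structure)
    res_a = ModulePrognosis.from_cohort(cohort_a).fit()
    res_b = ModulePrognosis.from_cohort(cohort_b).fit()
    return cross_cohort_overlap_significance(
        res_a.ranked, res_b.ranked,
        cohort_a.dataset, cohort_b.dataset,
        res_a.partition, res_b.partition,
        N=N, n_perm=n_perm, seed=int(seed) + 2,
    )


def mutation_enrichment(seed: int = 0, N: int = 20, n_perm: int = 20) -> dict:
    """Mutated-module enrichment of the top-N ranking with permutation control.

    Returns the observed enrichment ratio, its Fisher p, and the mean and sd
    of the ratio under class-size-preserving label permutations.
    """
    cohort = generate_cohort(SyntheticConfig(seed=int(seed)))
    model = ModulePrognosis.from_cohort(cohort)
    res = model.fit()
    universe = {g for net in res.networks for g in net.graph.nodes}
    enr = mm_enrichment_ratio(res.ranked, cohort.mutated, universe, N=N)

    def ratio_stat(labels):
        ga = [s for s in res.samples if labels[s] == "recurrent"]
        gb = [s for s in res.samples if labels[s] == "non_recurrent"]
        ranked = rank_modules(res.partition, model.dataset, ga, gb)
        r = mm_enrichment_ratio(ranked, cohort.mutated, universe, N=N)
        return r.ratio_corrected

    perm = label_permutation_control(
        ratio_stat, model.dataset.labels, n_perm=n_perm, seed=int(seed) + 3
    )
    null = np.asarray(perm["null"], dtype=float)
    return {
        "ratio": enr.ratio,
        "ratio_corrected": enr.ratio_corrected,
        "fisher_p": enr.p_value,
        "perm_mean_ratio": float(np.mean(null)),
        "perm_sd_ratio": float(np.std(null)),
        "n_modules": len(res.ranked),
    }
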