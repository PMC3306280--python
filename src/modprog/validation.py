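"""Validation statistics for ranked modules.

Covers the four analyses used to establish that top-ranked modules carry
real recurrence signal: enrichment of known recurrence genes versus t-test
gene and whole-gene-set controls, Fisher-exact enrichment of somatically
mutated genes ("mutated modules") with a label-permutation control,
significance of cross-dataset top-module overlap with a Grubbs outlier
test, and the repeated-split gene appearance frequency normalised by
interaction-network connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import PipelineParams, overlap_percentage, random_split
from .community import Module, ModulePartition
from .io import NON_RECURRENT, RECURRENT, ExpressionDataset, GeneCatalog, GeneSetCollection, InteractionNetwork
from .networks import build_networks
from .ranking import RankedModules, all_gene_t, rank_modules, sds_p_value, top_n_gene_union
from .community import discover_all


@dataclass
class EnrichmentResult:
    """Observed fraction in the top-N list vs controls, with an enrichment ratio."""

    N: int
    observed_fraction: float
    control_fractions: dict[str, float]
    ratio: float
    p_value: float
    #: Haldane-style continuity-corrected ratio; finite even when the rest of
    #: the ranking holds no enriched modules
    ratio_corrected: float = float("nan")


@dataclass
class FrequencyTable:
    """Per-gene appearance counts over repeated splits, connectivity-normalised."""

    table: pd.DataFrame  # index gene_id; columns raw_count, normalized_frequency
    n_splits: int


def known_gene_fraction(top_genes: set, catalog: GeneCatalog) -> float:
    """Fraction of the top genes found in the catalog."""
    top = set(top_genes)
    if not top:
        raise ValueError("top_genes must be non-empty")
    return len(top & catalog.genes) / len(top)


def ttest_gene_control(
    ds: ExpressionDataset,
    group_a,
    group_b,
    m: int,
    equal_var: bool = False,
) -> set:
    """The m individually most differentially expressed genes (largest |t|)."""
    if m < 0:
        raise ValueError("m must be >= 0")
    if m == 0:
        return set()
    t = all_gene_t(ds, list(group_a), list(group_b), equal_var=equal_var)
    order = (
        pd.DataFrame({"abs_t": t.abs(), "gene": t.index})
        .sort_values(["abs_t", "gene"], ascending=[False, True])
    )
    return set(order["gene"].head(min(m, len(order))))


def rank_gene_sets(
    ds: ExpressionDataset,
    sets: GeneSetCollection,
    group_a,
    group_b,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Whole gene sets ranked by the same SDS / chi-square machinery.

    The control for the module lists: every measured member of a set enters
    the sum of squared t, with degrees of freedom equal to the member count.
    """
    t = all_gene_t(ds, list(group_a), list(group_b), equal_var=equal_var)
    measured = set(t.index)
    rows = []
    for sid, members in sets:
        present = [g for g in members if g in measured]
        if not present:
            continue
        sds = float((t.loc[present] ** 2).sum())
        rows.append((sid, len(present), sds, sds_p_value(sds, len(present)), present))
    df = pd.DataFrame(rows, columns=["set_id", "k", "sds", "p_value", "genes"])
    df = df.sort_values(["p_value", "sds", "set_id"], ascending=[True, False, True])
    return df.reset_index(drop=True)


def mutated_module_test(module, mutated: GeneCatalog, universe) -> float:
    """One-sided Fisher exact (hypergeometric upper tail) for mutation excess.

    2x2 table: module vs rest of the universe, mutated vs not.  Returns the
    probability of drawing at least the observed number of mutated genes
    into the module under random sampling from the universe.
    """
    genes = set(module.genes) if isinstance(module, Module) else set(module)
    uni = set(universe)
    if not genes <= uni:
        raise ValueError("module genes must be contained in the universe")
    k_mut = len(uni & mutated.genes)
    m = len(genes)
    x = len(genes & mutated.genes)
    # P(X >= x), X ~ Hypergeom(|U|, k_mut, m)
    return float(stats.hypergeom.sf(x - 1, len(uni), k_mut, m))


def mm_enrichment_ratio(
    ranked: RankedModules,
    mutated: GeneCatalog,
    universe,
    N: int,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Enrichment of Mutated Modules (MMs) among the top N ranked modules.

    A module is an MM when its mutation content is significant at ``alpha``
    by the one-sided Fisher test.  The ratio is the MM fraction in the top N
    over the MM fraction in the remaining modules; the p-value is a Fisher
    exact test on the [top/rest x MM/non-MM] table.
    """
    if len(ranked) <= N:
        raise ValueError(f"need more than N={N} ranked modules, have {len(ranked)}")
    flags = [
        mutated_module_test(e.module, mutated, universe) < alpha for e in ranked
    ]
    top, rest = flags[:N], flags[N:]
    mm_top, mm_rest = sum(top), sum(rest)
    frac_top = mm_top / len(top)
    frac_rest = mm_rest / len(rest)
    if frac_rest == 0.0:
        if mm_top:
            warnings.warn("no mutated modules outside the top list; ratio is infinite")
            ratio = float("inf")
        else:
            ratio = float("nan")
    else:
        ratio = frac_top / frac_rest
    table = [[mm_top, len(top) - mm_top], [mm_rest, len(rest) - mm_rest]]
    _, p = stats.fisher_exact(table, alternative="greater")
    corrected = ((mm_top + 0.5) / (len(top) + 1)) / ((mm_rest + 0.5) / (len(rest) + 1))
    return EnrichmentResult(
        N=N,
        observed_fraction=frac_top,
        control_fractions={"rest_modules": frac_rest},
        ratio=ratio,
        p_value=float(p),
        ratio_corrected=float(corrected),
    )


def permute_labels(labels: pd.Series, rng: np.random.Generator) -> pd.Series:
    """Shuffle recurrent/non_recurrent assignments among the labeled samples."""
    out = labels.copy()
    labeled = [s for s in labels.index if labels[s] in (RECURRENT, NON_RECURRENT)]
    vals = [labels[s] for s in labeled]
    perm = rng.permutation(len(vals))
    for s, i in zip(labeled, perm):
        out[s] = vals[i]
    return out


def label_permutation_control(
    statistic,
    labels: pd.Series,
    n_perm: int,
    seed: int,
) -> dict:
    """Null distribution of a label-dependent statistic under class-size-preserving
    label permutations.

    ``statistic`` is a callable taking a label Series and returning a float.
    Returns the observed value, the null values, and the add-one empirical
    p-value (r+1)/(n+1) for the observed being as large as the null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = float(statistic(labels))
    rng = np.random.default_rng(seed)
    null = np.array(
        [float(statistic(permute_labels(labels, rng))) for _ in range(n_perm)]
    )
    r = int((null >= observed).sum())
    return {
        "observed": observed,
        "null": null,
        "p_value": (r + 1) / (n_perm + 1),
    }


def grubbs_outlier_test(null_values, observed: float) -> float:
    """One-sided Grubbs test for the observed value being a single high outlier.

    The observed value is appended to the null sample; G = (observed - mean)
    / sd, and the p-value follows from the t-distribution form of the Grubbs
    critical value, p = min(1, n * P(T_{n-2} > t)) with
    t^2 = (n-2) a^2 / (1 - a^2), a = G sqrt(n) / (n-1).
    """
    null = np.asarray(list(null_values), dtype=float)
    if null.size < 3:
        raise ValueError("need at least 3 null values")
    sample = np.append(null, observed)
    n = sample.size
    sd = sample.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero standard deviation; Grubbs statistic undefined")
    g = (observed - sample.mean()) / sd
    if g <= 0.0:
        return 1.0
    a2 = (g * np.sqrt(n) / (n - 1)) ** 2
    if a2 >= 1.0:
        return 0.0
    t = np.sqrt((n - 2) * a2 / (1.0 - a2))
    p = n * stats.t.sf(t, df=n - 2)
    return float(min(1.0, p))


def gene_appearance_frequency(
    ds: ExpressionDataset,
    sets: GeneSetCollection,
    ppi: InteractionNetwork,
    n_splits: int = 1000,
    N: int = 100,
    seed: int = 0,
    params: PipelineParams | None = None,
) -> FrequencyTable:
    """How often each gene appears in the top-N modules of BOTH random halves.

    The labeled cohort is repeatedly bisected class-balanced; a gene is
    counted for a split when it lies in the top-N module gene union of each
    half.  Raw counts are divided by the gene's interaction-network degree
    (hub genes reach more modules by chance); genes absent from the network
    are normalised by degree 1 with a warning.
    """
    params = params or PipelineParams()
    labeled = [s for s in ds.sample_ids if ds.labels[s] in (RECURRENT, NON_RECURRENT)]
    counts: dict[str, int] = {}
    for i in range(n_splits):
        split = random_split(labeled, ds.labels, seed=seed + i)
        unions = []
        for half in (split.half_1, split.half_2):
            samples = list(half)
            nets = build_networks(ds, sets, ppi, samples)
            partition = discover_all(
                nets, max_size=params.max_module_size, weighted_paths=params.weighted_paths
            )
            group_a = [s for s in samples if ds.labels[s] == RECURRENT]
            group_b = [s for s in samples if ds.labels[s] == NON_RECURRENT]
            ranked = rank_modules(partition, ds, group_a, group_b, equal_var=params.equal_var)
            unions.append(top_n_gene_union(ranked, N))
        for g in unions[0] & unions[1]:
            counts[g] = counts.get(g, 0) + 1
    degrees = ppi.degrees()
    rows = {}
    missing = []
    for g, c in sorted(counts.items()):
        d = degrees.get(g, 0)
        if d == 0:
            missing.append(g)
            d = 1
        rows[g] = (c, c / d)
    if missing:
        warnings.warn(f"gene(s) absent from the interaction network, degree 1 used: {missing}")
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["raw_count", "normalized_frequency"]
    )
    table.index.name = "gene"
    return FrequencyTable(table=table, n_splits=n_splits)


def cross_cohort_overlap_significance(
    ranked_a: RankedModules,
    ranked_b: RankedModules,
    ds_a: ExpressionDataset,
    ds_b: ExpressionDataset,
    partition_a: ModulePartition,
    partition_b: ModulePartition,
    N: int,
    n_perm: int = 50,
    seed: int = 0,
    equal_var: bool = False,
) -> dict:
    """Observed top-N gene-union overlap of two cohorts vs a permutation null.

    Labels are permuted independently in each cohort, rankings recomputed on
    the frozen module partitions, and the overlap recorded; returns the
    observed overlap, the null overlaps, the add-one empirical p and the
    Grubbs outlier p of the observed against the null.
    """
    observed = overlap_percentage(
        top_n_gene_union(ranked_a, N), top_n_gene_union(ranked_b, N)
    )
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(n_perm):
        unions = []
        for ds, partition in ((ds_a, partition_a), (ds_b, partition_b)):
            labels = permute_labels(ds.labels, rng)
            ga = [s for s in ds.sample_ids if labels[s] == RECURRENT]
            gb = [s for s in ds.sample_ids if labels[s] == NON_RECURRENT]
            ranked = rank_modules(partition, ds, ga, gb, equal_var=equal_var)
            unions.append(top_n_gene_union(ranked, N))
        null.append(overlap_percentage(*unions))
    null = np.array(null)
    r = int((null >= observed).sum())
    return {
        "observed": float(observed),
        "null": null,
        "p_value": (r + 1) / (n_perm + 1),
        "grubbs_p": grubbs_outlier_test(null, observed),
    }
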