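"""Synthetic cohorts with planted differentially expressed modules.

The generator emulates the statistical structure the pipeline assumes: a
two-class tumour cohort (recurrent vs non-recurrent), overlapping gene
sets, sparse interaction edges inside sets, and a handful of planted
modules that are (a) densely wired so module discovery can isolate them,
(b) internally correlated through a Gaussian factor (pairwise correlation
~rho), and (c) mean-shifted between the classes by ``effect_shift`` noise
standard deviations.  Mutation flags are drawn at an elevated rate inside
planted modules so the mutation-enrichment statistics have signal to find.

Everything is reproducible from ``seed``; structure (sets, edges, planted
membership, mutations) and expression use separate streams derived from it,
so two cohorts can share one structure while drawing independent expression
noise (the cross-dataset reproducibility setting).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    NON_RECURRENT,
    RECURRENT,
    ExpressionDataset,
    GeneCatalog,
    GeneSetCollection,
    InteractionNetwork,
    write_expression,
    write_gene_catalog,
    write_gene_sets,
    write_interactions,
    write_labels,
)
from .ranking import RankedModules


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the planted-module recoverability setting: 500 genes, 30
    overlapping sets of 10-80 genes, 5 planted modules of 8 genes with
    within-module correlation 0.6 and a 1.5-sd class shift, 25 samples per
    class, unit noise on a log2-like baseline N(8, 2).
    """

    n_genes: int = 500
    n_sets: int = 30
    set_size_range: tuple[int, int] = (10, 80)
    intra_set_edge_prob: float = 0.05
    n_samples_per_class: int = 25
    n_planted_modules: int = 5
    planted_module_size: int = 8
    effect_shift: float = 1.5
    within_module_correlation: float = 0.6
    noise_sd: float = 1.0
    mutation_rate_background: float = 0.05
    mutation_rate_planted: float = 0.4
    planted_edge_prob: float = 0.8
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.planted_module_size <= 20):
            raise ValueError("planted_module_size must be in [2, 20]")
        for name in (
            "intra_set_edge_prob",
            "planted_edge_prob",
            "mutation_rate_background",
            "mutation_rate_planted",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if not 0.0 <= self.within_module_correlation < 1.0:
            raise ValueError("within_module_correlation must be in [0, 1)")
        if self.n_samples_per_class < 4:
            raise ValueError("need at least 4 samples per class")
        if self.planted_module_size > self.set_size_range[1]:
            raise ValueError("planted module larger than the largest host set")


@dataclass
class SyntheticStructure:
    """The label-independent part of a cohort: sets, edges, planting, mutations."""

    genes: list[str]
    sets: GeneSetCollection
    ppi: InteractionNetwork
    planted: list[dict]  # {"set_id": ..., "genes": [...]}
    mutated: GeneCatalog


@dataclass
class SyntheticCohort:
    dataset: ExpressionDataset
    sets: GeneSetCollection
    ppi: InteractionNetwork
    mutated: GeneCatalog
    planted: list[dict]


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    s_struct, s_expr = ss.spawn(2)
    return np.random.default_rng(s_struct), np.random.default_rng(s_expr)


def generate_structure(cfg: SyntheticConfig) -> SyntheticStructure:
    """Gene sets, interaction edges, planted modules and mutation flags."""
    rng, _ = _streams(cfg.seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    lo, hi = cfg.set_size_range
    hosts_needed = cfg.n_planted_modules
    sets: dict[str, list[str]] = {}
    members_by_set: list[list[str]] = []
    for j in range(cfg.n_sets):
        size = int(rng.integers(lo, hi + 1))
        if j < hosts_needed:
            size = max(size, min(hi, cfg.planted_module_size + 4))
        idx = rng.choice(cfg.n_genes, size=size, replace=False)
        members = sorted(genes[i] for i in idx)
        sets[f"SET{j:03d}"] = members
        members_by_set.append(members)

    planted: list[dict] = []
    used: set[str] = set()
    for j in range(hosts_needed):
        sid = f"SET{j:03d}"
        candidates = [g for g in members_by_set[j] if g not in used]
        if len(candidates) < cfg.planted_module_size:
            raise ValueError(
                f"host set {sid} too small for a disjoint planted module "
                f"({len(candidates)} free genes, need {cfg.planted_module_size})"
            )
        pick = rng.choice(len(candidates), size=cfg.planted_module_size, replace=False)
        module = sorted(candidates[i] for i in pick)
        used.update(module)
        planted.append({"set_id": sid, "genes": module})

    planted_by_set = {p["set_id"]: set(p["genes"]) for p in planted}
    edges: set[frozenset] = set()
    for j, members in enumerate(members_by_set):
        sid = f"SET{j:03d}"
        inside = planted_by_set.get(sid, set())
        n = len(members)
        draw = rng.random((n, n))
        for a in range(n):
            for b in range(a + 1, n):
                ga, gb = members[a], members[b]
                both_planted = ga in inside and gb in inside
                p = cfg.planted_edge_prob if both_planted else cfg.intra_set_edge_prob
                if draw[a, b] < p:
                    edges.add(frozenset((ga, gb)))
    # a random spanning path guarantees each planted module is connected
    for p in planted:
        order = list(rng.permutation(p["genes"]))
        for a, b in zip(order, order[1:]):
            edges.add(frozenset((a, b)))

    flags = rng.random(cfg.n_genes) < cfg.mutation_rate_background
    mutated = {g for g, f in zip(genes, flags) if f}
    planted_genes = sorted(used)
    extra = rng.random(len(planted_genes)) < cfg.mutation_rate_planted
    mutated -= set(planted_genes)
    mutated |= {g for g, f in zip(planted_genes, extra) if f}
    if not mutated:  # degenerate tiny configs: keep the catalog type valid
        mutated = {planted_genes[0] if planted_genes else genes[0]}

    return SyntheticStructure(
        genes=genes,
        sets=GeneSetCollection(sets=sets),
        ppi=InteractionNetwork(edges=edges),
        planted=planted,
        mutated=GeneCatalog(genes=mutated, annotation="mutated_gene"),
    )


def generate_cohort(
    cfg: SyntheticConfig, structure: SyntheticStructure | None = None
) -> SyntheticCohort:
    """Expression + labels for a cohort on the given (or freshly drawn) structure.

    Gene g in sample j: baseline_g + noise_sd * (sqrt(rho) f_mj +
    sqrt(1-rho) eps_gj) for planted-module genes (f_m a per-module shared
    factor) plus effect_shift * noise_sd in the recurrent class; baseline_g
    + noise_sd * eps_gj elsewhere.
    """
    if structure is None:
        structure = generate_structure(cfg)
    _, rng = _streams(cfg.seed)
    n = cfg.n_samples_per_class
    rec = [f"R{i:03d}" for i in range(n)]
    non = [f"N{i:03d}" for i in range(n)]
    samples = rec + non
    labels = pd.Series(
        [RECURRENT] * n + [NON_RECURRENT] * n, index=samples, dtype=object
    )
    g_index = {g: i for i, g in enumerate(structure.genes)}
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    eps = rng.normal(size=(cfg.n_genes, 2 * n))
    mat = baseline[:, None] + cfg.noise_sd * eps
    rho = cfg.within_module_correlation
    for p in structure.planted:
        rows = [g_index[g] for g in p["genes"]]
        factor = rng.normal(size=2 * n)
        mixed = np.sqrt(rho) * factor[None, :] + np.sqrt(1.0 - rho) * eps[rows, :]
        mat[rows, :] = baseline[rows, None] + cfg.noise_sd * mixed
        mat[rows, :n] += cfg.effect_shift * cfg.noise_sd
    if cfg.missing_rate > 0.0:
        mask = rng.random(mat.shape) < cfg.missing_rate
        # keep every row and column partially observed so imputation stays defined
        mask[:, 0] = False
        mask[0, :] = False
        mat = np.where(mask, np.nan, mat)
    values = pd.DataFrame(mat, index=structure.genes, columns=samples)
    ds = ExpressionDataset(values=values, labels=labels)
    return SyntheticCohort(
        dataset=ds,
        sets=structure.sets,
        ppi=structure.ppi,
        mutated=structure.mutated,
        planted=structure.planted,
    )


def write_fixture(directory, cohort: SyntheticCohort) -> dict[str, Path]:
    """Write the cohort in the exact text dialects the readers consume."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "labels": directory / "labels.tsv",
        "gene_sets": directory / "gene_sets.gmt",
        "interactions": directory / "interactions.tsv",
        "mutated_genes": directory / "mutated_genes.txt",
        "ground_truth": directory / "ground_truth.json",
    }
    write_expression(cohort.dataset, paths["expression"])
    write_labels(cohort.dataset.labels, paths["labels"])
    write_gene_sets(cohort.sets, paths["gene_sets"])
    write_interactions(cohort.ppi, paths["interactions"])
    write_gene_catalog(cohort.mutated, paths["mutated_genes"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump({"planted_modules": cohort.planted}, fh, indent=1, sort_keys=True)
    return paths


def planted_recovery_fraction(
    ranked: RankedModules,
    planted: list[dict],
    top_n: int = 20,
    min_fraction: float = 0.5,
) -> float:
    """Fraction of planted modules with >= min_fraction of their genes in the
    top-n ranked modules' gene union."""
    union: set[str] = set()
    for e in ranked.top(top_n):
        union.update(e.module.genes)
    hits = 0
    for p in planted:
        genes = set(p["genes"])
        if len(genes & union) >= min_fraction * len(genes):
            hits += 1
    return hits / len(planted) if planted else float("nan")
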