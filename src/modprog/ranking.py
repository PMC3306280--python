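"""Module-level differential expression: sum-of-squared-t with chi-square calibration.

Each gene in a module gets a two-sample t statistic between the recurrent
and non-recurrent samples (Welch by default).  The module's score of
differential significance is SDS = sum over its k genes of t_i^2.  Because
SDS grows with the module size k, it is calibrated against the chi-square
distribution with k degrees of freedom: p = P(chi2_k >= SDS), and modules
are ranked ascending by p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import Module, ModulePartition
from .io import ExpressionDataset

#: |t| assigned when both groups are constant at different means
DEGENERATE_T_CAP = 1e6


@dataclass(frozen=True)
class GeneScore:
    gene_id: str
    t: float


@dataclass(frozen=True)
class ModuleScore:
    module: Module
    k: int
    sds: float
    p_value: float


@dataclass
class RankedModules:
    """Module scores sorted ascending by p, ties by (larger SDS, set id, genes)."""

    entries: list[ModuleScore]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def top(self, n: int) -> list[ModuleScore]:
        return self.entries[: max(0, n)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.entries) + 1),
                "set_id": [e.module.set_id for e in self.entries],
                "k": [e.k for e in self.entries],
                "sds": [e.sds for e in self.entries],
                "p_value": [e.p_value for e in self.entries],
                "genes": [",".join(e.module.genes) for e in self.entries],
            }
        )


def welch_t(a: np.ndarray, b: np.ndarray, equal_var: bool = False) -> np.ndarray:
    """Row-wise two-sample t statistics for matrices of shape (genes, samples).

    Welch denominator sqrt(s_a^2/n_a + s_b^2/n_b) by default; pooled variance
    with ``equal_var``.  Degenerate rows (both groups constant): t = 0 when
    the means agree, +/-DEGENERATE_T_CAP with a warning when they differ.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 samples")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        denom = np.sqrt(va / na + vb / nb)
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    degenerate = denom == 0.0
    if degenerate.any():
        t = np.where(degenerate & (diff == 0.0), 0.0, t)
        hard = degenerate & (diff != 0.0)
        if hard.any():
            warnings.warn(
                f"{int(hard.sum())} gene(s) constant in both groups with different "
                f"means; |t| capped at {DEGENERATE_T_CAP:g}"
            )
            t = np.where(hard, np.sign(diff) * DEGENERATE_T_CAP, t)
    return t


def gene_t_score(
    ds: ExpressionDataset,
    gene_id: str,
    group_a: list[str],
    group_b: list[str],
    equal_var: bool = False,
) -> GeneScore:
    """t statistic for one gene, group_a minus group_b."""
    row = ds.values.loc[[gene_id]]
    if row.shape[0] != 1:
        raise ValueError(f"gene {gene_id!r} has {row.shape[0]} rows (collapse probes first)")
    t = welch_t(
        row[list(group_a)].to_numpy(), row[list(group_b)].to_numpy(), equal_var=equal_var
    )
    return GeneScore(gene_id=gene_id, t=float(t[0]))


def module_sds(scores: list[GeneScore]) -> tuple[float, int]:
    """SDS = sum of squared t over the module's genes; returns (sds, k)."""
    if not scores:
        raise ValueError("module has no gene scores")
    return float(sum(s.t * s.t for s in scores)), len(scores)


def sds_p_value(sds: float, k: int) -> float:
    """Upper-tail chi-square probability P(chi2_k >= sds)."""
    if sds < 0:
        raise ValueError("sds must be non-negative")
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(stats.chi2.sf(sds, df=k))


def all_gene_t(
    ds: ExpressionDataset,
    group_a: list[str],
    group_b: list[str],
    equal_var: bool = False,
) -> pd.Series:
    """Vectorised t statistics for every gene row, indexed by gene id."""
    t = welch_t(
        ds.values[list(group_a)].to_numpy(),
        ds.values[list(group_b)].to_numpy(),
        equal_var=equal_var,
    )
    return pd.Series(t, index=ds.values.index)


def rank_modules(
    partition: ModulePartition,
    ds: ExpressionDataset,
    group_a: list[str],
    group_b: list[str],
    equal_var: bool = False,
) -> RankedModules:
    """Score every module and sort ascending by chi-square p-value.

    Tie chain (p, -sds, set_id, gene tuple) makes the order independent of
    the input module order.  Identical gene sets arising from overlapping
    gene-set networks are deliberately not deduplicated.
    """
    tser = all_gene_t(ds, group_a, group_b, equal_var=equal_var)
    tmap = tser.to_dict()
    entries: list[ModuleScore] = []
    for mod in partition:
        missing = [g for g in mod.genes if g not in tmap]
        if missing:
            raise KeyError(f"module genes absent from expression data: {missing}")
        ts = np.array([tmap[g] for g in mod.genes])
        sds = float((ts * ts).sum())
        entries.append(
            ModuleScore(module=mod, k=mod.size, sds=sds, p_value=sds_p_value(sds, mod.size))
        )
    entries.sort(key=lambda e: (e.p_value, -e.sds, e.module.set_id, e.module.genes))
    return RankedModules(entries=entries)


def top_n_gene_union(ranked: RankedModules, n: int) -> set[str]:
    """Union of gene ids over the first min(n, total) ranked modules."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out: set[str] = set()
    for e in ranked.top(n):
        out.update(e.module.genes)
    return out
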