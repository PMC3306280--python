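"""Per-gene-set weighted co-expression networks.

For every gene set, the genes measured on the array become vertices, the
protein-interaction pairs falling inside the set become edges, and each edge
is weighted by the absolute Pearson correlation of the two genes' expression
vectors over the samples under analysis.  A gene belonging to several sets
appears in each of their networks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import ExpressionDataset, GeneSetCollection, InteractionNetwork

logger = logging.getLogger(__name__)


@dataclass
class WeightedGeneSetNetwork:
    """Co-expression graph for one gene set; edge weights are |Pearson r| in [0, 1]."""

    set_id: str
    graph: nx.Graph

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]


def pearson_weight(x: np.ndarray, y: np.ndarray) -> float:
    """Absolute Pearson correlation of two expression vectors.

    A zero-variance vector has no defined correlation; the weight is 0 with
    a warning so that constant (filtered or synthetic) genes do not abort a
    network build.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expression vectors must be 1-d and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a correlation weight")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        warnings.warn("zero-variance expression vector: weight set to 0")
        return 0.0
    # rounding can push |r| a few ulp above 1 for collinear vectors
    return min(float(abs((xc * yc).sum() / (sx * sy))), 1.0)


def build_networks(
    ds: ExpressionDataset,
    sets: GeneSetCollection,
    ppi: InteractionNetwork,
    sample_subset: list[str],
    cache: dict | None = None,
) -> list[WeightedGeneSetNetwork]:
    """Build one weighted network per gene set with >=2 nodes and >=1 edge.

    Weights are computed over ``sample_subset`` only; sets whose measured
    genes induce no interaction edge are skipped with a log entry.  ``cache``
    (optional dict) memoises networks by (set_id, sample tuple) because the
    prediction paradigm rebuilds the same half-cohorts repeatedly.
    """
    if not sample_subset:
        raise ValueError("sample_subset must be non-empty")
    sub = ds.values[list(sample_subset)]
    measured = set(sub.index)
    out: list[WeightedGeneSetNetwork] = []
    key_samples = tuple(sample_subset)
    for set_id, members in sets:
        if cache is not None and (set_id, key_samples) in cache:
            net = cache[(set_id, key_samples)]
            if net is not None:
                out.append(net)
            continue
        nodes = [g for g in members if g in measured]
        if len(nodes) < 2:
            logger.info("set %s: <2 measured genes, skipped", set_id)
            if cache is not None:
                cache[(set_id, key_samples)] = None
            continue
        edges = ppi.edges_within(nodes)
        if not edges:
            logger.info("set %s: no interaction edges among measured genes, skipped", set_id)
            if cache is not None:
                cache[(set_id, key_samples)] = None
            continue
        mat = sub.loc[nodes].to_numpy(dtype=float)
        idx = {g: i for i, g in enumerate(nodes)}
        # row-standardise once; zero-variance rows flagged for weight 0
        centred = mat - mat.mean(axis=1, keepdims=True)
        norms = np.sqrt((centred * centred).sum(axis=1))
        flat = norms == 0.0
        if flat.any():
            warnings.warn(
                f"set {set_id}: zero-variance gene(s) "
                f"{[nodes[i] for i in np.flatnonzero(flat)]}; their edges get weight 0"
            )
        safe = np.where(flat, 1.0, norms)
        unit = centred / safe[:, None]
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            ia, ib = idx[a], idx[b]
            if flat[ia] or flat[ib]:
                w = 0.0
            else:
                w = float(abs(np.dot(unit[ia], unit[ib])))
                w = min(w, 1.0)
            g.add_edge(a, b, weight=w)
        net = WeightedGeneSetNetwork(set_id=set_id, graph=g)
        if cache is not None:
            cache[(set_id, key_samples)] = net
        out.append(net)
    return out
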