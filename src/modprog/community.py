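"""Size-capped module discovery by weighted Girvan-Newman edge removal.

The edge score is the classic (unnormalised, unweighted-topology) edge
betweenness — the number of shortest paths over all unordered node pairs
crossing the edge, with equal fractional credit among co-shortest paths —
divided by the edge's co-expression weight.  Weak edges (low |r|) therefore
score high and are cut first.  Instead of cutting the dendrogram at maximal
modularity Q, removal stops as soon as every connected component holds at
most ``max_size`` genes; surviving components of two or more genes are the
modules, singletons are discarded.

Betweenness counts are computed with igraph's C implementation; the
division by the co-expression weight, the size-cap stopping rule and the
tie-breaking are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np

from .networks import WeightedGeneSetNetwork

#: divisor floor for zero-weight edges (zero-variance genes)
WEIGHT_FLOOR = 1e-6

DEFAULT_MAX_SIZE = 20


@dataclass(frozen=True)
class Module:
    """A connected group of 2..max_size genes from one gene-set network."""

    set_id: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(sorted(self.genes)))
        if len(self.genes) < 2:
            raise ValueError("a module needs at least 2 genes")

    @property
    def size(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class ModulePartition:
    """All modules across the analysed networks plus the singleton count."""

    modules: list[Module]
    discarded_singletons: int = 0

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)


def _to_igraph(net: WeightedGeneSetNetwork) -> tuple[ig.Graph, list[str]]:
    g_nx = net.graph
    nodes = sorted(g_nx.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges, weights = [], []
    for u, v, data in g_nx.edges(data=True):
        edges.append((index[u], index[v]))
        weights.append(float(data.get("weight", 1.0)))
    g = ig.Graph(n=len(nodes), edges=edges)
    g.es["w"] = weights
    return g, nodes


def _raw_betweenness(g: ig.Graph, eps: float, weighted_paths: bool) -> np.ndarray:
    """Unnormalised edge betweenness over unordered node pairs."""
    if weighted_paths:
        lengths = [1.0 / max(w, eps) for w in g.es["w"]]
        return np.asarray(g.edge_betweenness(directed=False, weights=lengths))
    return np.asarray(g.edge_betweenness(directed=False))


def edge_betweenness_scores(
    net: WeightedGeneSetNetwork,
    eps: float = WEIGHT_FLOOR,
    weighted_paths: bool = False,
) -> dict[tuple[str, str], float]:
    """Weight-divided edge betweenness for every edge of the network.

    Shortest paths are counted on the unweighted topology by default; with
    ``weighted_paths`` they minimise summed edge lengths 1/weight instead (a
    non-default variant).  Either way the raw betweenness is divided by the
    edge's weight, floored at ``eps`` so zero-weight edges do not produce
    infinite scores.
    """
    if net.graph.number_of_edges() == 0:
        raise ValueError("network has no edges")
    g, nodes = _to_igraph(net)
    raw = _raw_betweenness(g, eps, weighted_paths)
    out: dict[tuple[str, str], float] = {}
    for e, b in zip(g.es, raw):
        u, v = nodes[e.source], nodes[e.target]
        key = (u, v) if u <= v else (v, u)
        out[key] = b / max(e["w"], eps)
    return out


def girvan_newman_partition(
    net: WeightedGeneSetNetwork,
    max_size: int = DEFAULT_MAX_SIZE,
    weighted_paths: bool = False,
    batch_removal: bool = False,
    eps: float = WEIGHT_FLOOR,
) -> tuple[list[Module], int]:
    """Split one network into modules of at most ``max_size`` genes.

    Recomputes betweenness after every removal and removes the single
    highest-scoring edge among the components still over the cap (all
    co-maximal edges when ``batch_removal``), until no connected component
    exceeds the cap.  Exact score ties are broken by the lexicographically
    smallest (node, node) pair.  Returns (modules, discarded singleton
    count); modules are reported in deterministic order (by smallest gene
    id).
    """
    if max_size < 2:
        raise ValueError("max_size must be >= 2")
    g, nodes = _to_igraph(net)
    while True:
        comps = g.connected_components()
        sizes = np.asarray(comps.sizes())
        if not (sizes > max_size).any():
            break
        membership = np.asarray(comps.membership)
        oversized = set(np.flatnonzero(sizes > max_size))
        raw = _raw_betweenness(g, eps, weighted_paths)
        weights = np.maximum(np.asarray(g.es["w"], dtype=float), eps)
        scores = raw / weights
        best_key = None
        best_edges: list[int] = []
        for ei in range(g.ecount()):
            e = g.es[ei]
            if membership[e.source] not in oversized:
                continue
            u, v = nodes[e.source], nodes[e.target]
            pair = (u, v) if u <= v else (v, u)
            key = (-scores[ei], pair)
            if best_key is None or key < best_key:
                best_key = key
                best_edges = [ei]
            elif batch_removal and scores[ei] == -best_key[0]:
                best_edges.append(ei)
        if batch_removal:
            top = -best_key[0]
            best_edges = [
                ei
                for ei in range(g.ecount())
                if membership[g.es[ei].source] in oversized and scores[ei] == top
            ]
        g.delete_edges(best_edges)
    modules: list[Module] = []
    singletons = 0
    for comp in g.connected_components():
        if len(comp) == 1:
            singletons += 1
        else:
            modules.append(Module(set_id=net.set_id, genes=tuple(nodes[i] for i in comp)))
    modules.sort(key=lambda m: m.genes)
    return modules, singletons


def discover_all(
    nets: list[WeightedGeneSetNetwork],
    max_size: int = DEFAULT_MAX_SIZE,
    weighted_paths: bool = False,
) -> ModulePartition:
    """Run module discovery over every network; deterministic global ordering."""
    modules: list[Module] = []
    singletons = 0
    for net in nets:
        mods, s = girvan_newman_partition(
            net, max_size=max_size, weighted_paths=weighted_paths
        )
        modules.extend(mods)
        singletons += s
    modules.sort(key=lambda m: (m.set_id, m.genes))
    return ModulePartition(modules=modules, discarded_singletons=singletons)
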