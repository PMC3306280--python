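"""Shared fixtures: tiny hand-built datasets and a small synthetic cohort."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import modprog as mp


@pytest.fixture
def tiny_ds() -> mp.ExpressionDataset:
    """4 genes x 6 samples, 3 recurrent / 3 non-recurrent, no missing data."""
    rng = np.random.default_rng(123)
    samples = ["r1", "r2", "r3", "n1", "n2", "n3"]
    values = pd.DataFrame(
        rng.normal(size=(4, 6)), index=["GA", "GB", "GC", "GD"], columns=samples
    )
    labels = pd.Series(
        ["recurrent"] * 3 + ["non_recurrent"] * 3, index=samples, dtype=object
    )
    return mp.ExpressionDataset(values=values, labels=labels)


@pytest.fixture(scope="session")
def small_cohort() -> mp.SyntheticCohort:
    """Small planted cohort for classifier/validation unit tests."""
    cfg = mp.SyntheticConfig(
        n_genes=120,
        n_sets=8,
        set_size_range=(8, 25),
        n_samples_per_class=12,
        n_planted_modules=2,
        planted_module_size=5,
        effect_shift=2.0,
        seed=7,
    )
    return mp.generate_cohort(cfg)


def brute_force_edge_betweenness(g: nx.Graph) -> dict[tuple[str, str], float]:
    """Independent oracle: enumerate all shortest paths for every unordered pair
    and award each edge equal fractional credit per pair."""
    scores = {tuple(sorted(e)): 0.0 for e in g.edges}
    for s, t in itertools.combinations(sorted(g.nodes), 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        credit = 1.0 / len(paths)
        for path in paths:
            for u, v in zip(path, path[1:]):
                scores[tuple(sorted((u, v)))] += credit
    return scores


def make_network(edges_with_weights, set_id="S") -> mp.WeightedGeneSetNetwork:
    g = nx.Graph()
    for u, v, w in edges_with_weights:
        g.add_edge(u, v, weight=w)
    return mp.WeightedGeneSetNetwork(set_id=set_id, graph=g)


@pytest.fixture
def path_net() -> mp.WeightedGeneSetNetwork:
    return make_network([("a", "b", 1.0), ("b", "c", 1.0)])
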