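"""Filtered Spearman co-occurrence networks and their topology.

Construction follows the two-step taxon filter (mean relative abundance >=
0.01% and prevalence >= 1/6 of samples), all-pairs Spearman correlation with
Benjamini-Hochberg correction, and an edge threshold of |rho| > 0.7 with
q < 0.05.  Topology summaries report nodes, links, average degree, diameter
(largest component), average clustering coefficient, and relative modularity
RM = (M_obs - <M_rand>) / <M_rand> against an Erdos-Renyi G(N, L) ensemble —
a normalization that, unlike raw modularity (<= 1), can well exceed 1 for
strongly compartmentalized networks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from rhizodyn.data_model import DegenerateSampleError, OtuTable, ParameterError, total_sum_scaling

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeRecord",
    "TopologySummary",
    "filter_taxa",
    "correlation_edges",
    "build_graph",
    "topology_summary",
    "average_degree",
]


@dataclass
class EdgeRecord:
    taxon_a: str
    taxon_b: str
    rho: float
    p_raw: float
    q_bh: float

    def __post_init__(self) -> None:
        if self.taxon_a >= self.taxon_b:
            raise ParameterError("edges must be stored with taxon_a < taxon_b")

    @property
    def sign(self) -> str:
        return "positive" if self.rho > 0 else "negative"


@dataclass
class TopologySummary:
    nodes: int
    links: int
    average_degree: float
    diameter: int
    average_clustering_coefficient: float
    modularity_raw: float
    random_modularity_mean: float
    relative_modularity: float


def average_degree(nodes: int, links: int) -> float:
    """Mean degree 2L/N of an undirected graph."""
    if nodes <= 0:
        raise ParameterError("nodes must be positive")
    return 2.0 * links / nodes


# ---------------------------------------------------------------------------
# Taxon filtering


def filter_taxa(
    table: OtuTable,
    min_mean_rel_abundance: float = 1e-4,
    min_prevalence_fraction: float = 1.0 / 6.0,
) -> OtuTable:
    """Two-step filter on a relative-abundance table.

    Keeps taxa with mean relative abundance >= 0.01% and presence in at least
    ``ceil(n_samples / 6)`` samples.  Counts tables are total-sum scaled
    first.
    """
    if not table.is_relative:
        table = total_sum_scaling(table)
    rel = table.counts.to_numpy()
    n_samples = rel.shape[1]
    min_prev = math.ceil(n_samples * min_prevalence_fraction)
    keep = (rel.mean(axis=1) >= min_mean_rel_abundance) & (
        (rel > 0).sum(axis=1) >= min_prev
    )
    kept = [t for t, k in zip(table.taxon_ids, keep) if k]
    if not kept:
        logger.warning("taxon filter removed every taxon")
    return table.subset_taxa(kept)


# ---------------------------------------------------------------------------
# Correlation network


def correlation_edges(
    table: OtuTable,
    rho_min: float = 0.7,
    alpha: float = 0.05,
) -> list[EdgeRecord]:
    """All-pairs Spearman edges surviving |rho| > rho_min and BH q < alpha.

    Ties receive average ranks; constant taxa are skipped with a log entry;
    BH correction runs across every tested pair.
    """
    if len(table.sample_ids) < 5:
        raise ParameterError("need >= 5 samples for a correlation network")
    values = table.counts.to_numpy(dtype=float)
    taxa = np.array(table.taxon_ids)
    variable = np.ptp(values, axis=1) > 0
    n_const = int((~variable).sum())
    if n_const:
        logger.warning("%d constant taxa skipped in correlation network", n_const)
    idx = np.flatnonzero(variable)
    if idx.size < 2:
        return []
    sub = values[idx]
    rho, p = stats.spearmanr(sub, axis=1)
    if idx.size == 2:  # scipy returns scalars for a single pair
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    iu = np.triu_indices(idx.size, 1)
    p_flat = p[iu]
    q_flat = multipletests(p_flat, method="fdr_bh")[1]
    edges = []
    for (i, j), rho_ij, p_ij, q_ij in zip(zip(*iu), rho[iu], p_flat, q_flat):
        if abs(rho_ij) > rho_min and q_ij < alpha:
            a, b = sorted((taxa[idx[i]], taxa[idx[j]]))
            edges.append(
                EdgeRecord(a, b, float(rho_ij), float(p_ij), float(q_ij))
            )
    return edges


def build_graph(edges: Sequence[EdgeRecord]) -> nx.Graph:
    """Undirected graph of the retained edges (weights = rho)."""
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.taxon_a, e.taxon_b, rho=e.rho, sign=e.sign)
    return g


# ---------------------------------------------------------------------------
# Topology


def greedy_modules(
    graph: nx.Graph, method: str = "greedy", seed: int = 0
) -> list[set[str]]:
    """Modularity communities: deterministic greedy (default) or Louvain."""
    if method not in {"greedy", "louvain"}:
        raise ParameterError(f"unknown community method {method!r}")
    if graph.number_of_edges() == 0:
        return [{n} for n in sorted(graph.nodes)]
    if method == "louvain":
        communities = nx.community.louvain_communities(graph, seed=seed)
    else:
        communities = nx.community.greedy_modularity_communities(graph)
    return [set(c) for c in communities]


def topology_summary(
    edges: Sequence[EdgeRecord],
    n_random: int = 100,
    seed: int | None = None,
    null_model: str = "erdos_renyi",
) -> TopologySummary:
    """Topology of the co-occurrence network plus relative modularity.

    Nodes are taxa participating in >= 1 retained edge.  The diameter is the
    longest shortest path on the largest connected component.  RM compares
    greedy modularity against the mean modularity of ``n_random`` random
    graphs with identical N and L: Erdos-Renyi G(N, L) by default, or
    degree-preserving rewirings (``null_model="degree_preserving"``).
    """
    if null_model not in {"erdos_renyi", "degree_preserving"}:
        raise ParameterError(f"unknown null model {null_model!r}")
    if not edges:
        raise DegenerateSampleError("empty edge list")
    graph = build_graph(edges)
    n = graph.number_of_nodes()
    l = graph.number_of_edges()
    largest = max(nx.connected_components(graph), key=len)
    diameter = nx.diameter(graph.subgraph(largest))
    clustering = nx.average_clustering(graph)  # degree<2 nodes contribute 0
    modules = greedy_modules(graph)
    m_obs = nx.community.modularity(graph, modules)
    rng = np.random.default_rng(seed)
    m_rand = []
    for _ in range(n_random):
        if null_model == "degree_preserving":
            gr = graph.copy()
            nx.double_edge_swap(
                gr, nswap=4 * l, max_tries=40 * l + 100,
                seed=int(rng.integers(2**31)),
            )
        else:
            gr = nx.gnm_random_graph(n, l, seed=int(rng.integers(2**31)))
        m_rand.append(nx.community.modularity(gr, greedy_modules(gr)))
    mean_rand = float(np.mean(m_rand))
    rm = (m_obs - mean_rand) / mean_rand if mean_rand != 0 else math.nan
    return TopologySummary(
        nodes=n,
        links=l,
        average_degree=average_degree(n, l),
        diameter=int(diameter),
        average_clustering_coefficient=float(clustering),
        modularity_raw=float(m_obs),
        random_modularity_mean=mean_rand,
        relative_modularity=float(rm),
    )


def edges_to_frame(edges: Sequence[EdgeRecord]) -> pd.DataFrame:
    """Edge list as a TSV-ready DataFrame."""
    return pd.DataFrame(
        [
            (e.taxon_a, e.taxon_b, e.rho, e.p_raw, e.q_bh, e.sign)
            for e in edges
        ],
        columns=["taxon_a", "taxon_b", "rho", "p_raw", "q_bh", "sign"],
    )
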