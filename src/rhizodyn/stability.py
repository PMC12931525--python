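"""Network robustness and Zi-Pi keystone classification.

Robustness under random removal is the fraction of original nodes that keep
at least one link; targeted attacks remove nodes one at a time (keystones
first, then by degree) and track natural connectivity, the log-mean of the
exponentiated adjacency eigenvalues — a spectral redundancy measure that is
monotone non-increasing under edge deletion.

Keystones follow the within-module degree z-score (Zi) and among-module
participation coefficient (Pi) with the classic cutoffs: peripheral
(Zi <= 2.5, Pi <= 0.62), module hub (Zi > 2.5, Pi <= 0.62), connector
(Zi <= 2.5, Pi > 0.62), network hub (Zi > 2.5, Pi > 0.62).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from scipy.special import logsumexp

from rhizodyn.data_model import DegenerateSampleError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "ZI_THRESHOLD",
    "PI_THRESHOLD",
    "RobustnessCurve",
    "KeystoneRecord",
    "natural_connectivity",
    "robustness_random_removal",
    "targeted_attack",
    "zi_pi_classify",
]

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


@dataclass
class RobustnessCurve:
    removal_fractions: np.ndarray  # or removal steps for targeted attacks
    robustness_values: np.ndarray
    slope: float
    r_squared: float
    n_replicates: int


@dataclass
class KeystoneRecord:
    taxon_id: str
    zi: float
    pi: float
    category: str

    @property
    def is_keystone(self) -> bool:
        return self.category != "peripheral"


# ---------------------------------------------------------------------------
# Natural connectivity


def natural_connectivity(graph: nx.Graph) -> float:
    """ln(mean(exp(lambda_i))) over adjacency eigenvalues."""
    n = graph.number_of_nodes()
    if n == 0:
        raise DegenerateSampleError("empty graph")
    if graph.number_of_edges() == 0:
        return 0.0
    adjacency = nx.to_numpy_array(graph)
    eigvals = np.linalg.eigvalsh(adjacency)
    return float(logsumexp(eigvals) - np.log(n))


# ---------------------------------------------------------------------------
# Random removal robustness


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)


def robustness_random_removal(
    graph: nx.Graph,
    fractions: Sequence[float] | None = None,
    n_replicates: int = 100,
    seed: int | None = None,
) -> RobustnessCurve:
    """Mean fraction of original nodes keeping >= 1 link after removal.

    At each fraction f, round(f*N) uniformly random nodes are deleted;
    robustness is averaged over replicates; the slope and R^2 come from an
    OLS fit of robustness on f (fraction 0 contributes robustness 1).
    """
    if graph.number_of_nodes() == 0:
        raise DegenerateSampleError("empty graph")
    if fractions is None:
        fractions = np.arange(0.0, 0.951, 0.05)
    fractions = np.asarray(list(fractions), dtype=float)
    rng = np.random.default_rng(seed)
    nodes = list(graph.nodes)
    n = len(nodes)
    means = np.empty(fractions.size)
    for k, f in enumerate(fractions):
        n_remove = int(round(f * n))
        if n_remove == 0:
            means[k] = 1.0
            continue
        vals = np.empty(n_replicates)
        for r in range(n_replicates):
            drop = rng.choice(n, size=n_remove, replace=False)
            keep = [nodes[i] for i in np.setdiff1d(np.arange(n), drop)]
            sub = graph.subgraph(keep)
            vals[r] = sum(1 for _, d in sub.degree() if d >= 1) / n
        means[k] = vals.mean()
    slope, r2 = _ols(fractions, means)
    return RobustnessCurve(fractions, means, slope, r2, n_replicates)


# ---------------------------------------------------------------------------
# Targeted attack


def targeted_attack(
    graph: nx.Graph,
    order: str = "degree_desc",
    keystones: Sequence[KeystoneRecord] | None = None,
    max_removals: int | None = None,
) -> RobustnessCurve:
    """Sequential node removal tracking natural connectivity.

    ``degree_desc`` removes by initial degree (ties by node id);
    ``keystone_first`` removes identified keystones first (by degree), then
    the rest by degree; with no keystones it falls back to ``degree_desc``
    with a logged notice.  Values are the natural connectivity after each
    removal; slope and R^2 are from OLS on the number removed.
    """
    if order not in {"degree_desc", "keystone_first"}:
        raise ParameterError(f"unknown attack order {order!r}")
    n = graph.number_of_nodes()
    if n == 0:
        raise DegenerateSampleError("empty graph")
    if max_removals is None:
        max_removals = n - 1
    if max_removals > n:
        logger.warning("max_removals %d > N=%d; truncated", max_removals, n)
        max_removals = n - 1
    by_degree = sorted(graph.degree(), key=lambda kv: (-kv[1], kv[0]))
    ranking = [node for node, _ in by_degree]
    if order == "keystone_first":
        key_ids = [k.taxon_id for k in (keystones or []) if k.is_keystone]
        if not key_ids:
            logger.warning("no keystones identified; falling back to degree_desc")
        else:
            key_set = set(key_ids)
            ranking = [v for v in ranking if v in key_set] + [
                v for v in ranking if v not in key_set
            ]
    working = graph.copy()
    steps = [0.0]
    values = [natural_connectivity(working)]
    for i, victim in enumerate(ranking[:max_removals], start=1):
        working.remove_node(victim)
        steps.append(float(i))
        values.append(
            natural_connectivity(working) if working.number_of_nodes() else 0.0
        )
    steps_arr = np.asarray(steps)
    values_arr = np.asarray(values)
    slope, r2 = _ols(steps_arr, values_arr)
    return RobustnessCurve(steps_arr, values_arr, slope, r2, 1)


# ---------------------------------------------------------------------------
# Zi-Pi classification


def classify_zi_pi(zi: float, pi: float) -> str:
    if zi > ZI_THRESHOLD:
        return "network_hub" if pi > PI_THRESHOLD else "module_hub"
    return "connector" if pi > PI_THRESHOLD else "peripheral"


def zi_pi_classify(
    graph: nx.Graph,
    module_partition: Mapping[str, int] | Sequence[set[str]],
) -> list[KeystoneRecord]:
    """Within-module degree z-score and participation coefficient per node.

    ``Zi = (k_i,own - mean k_.,own) / sd k_.,own`` over the node's module
    (Zi = 0 when the module's sd is 0); ``Pi = 1 - sum_s (k_is / k_i)^2``
    (Pi = 0 for isolated nodes).
    """
    if not isinstance(module_partition, Mapping):
        module_partition = {
            node: idx
            for idx, members in enumerate(module_partition)
            for node in members
        }
    missing = [v for v in graph.nodes if v not in module_partition]
    if missing:
        raise ParameterError(f"partition lacks node {missing[0]!r}")
    modules: dict[int, list[str]] = {}
    for node in graph.nodes:
        modules.setdefault(module_partition[node], []).append(node)
    k_own = {
        node: sum(
            1
            for nb in graph.neighbors(node)
            if module_partition[nb] == module_partition[node]
        )
        for node in graph.nodes
    }
    out = []
    for mod, members in sorted(modules.items()):
        own = np.array([k_own[v] for v in members], dtype=float)
        mu, sd = own.mean(), own.std()
        for node in sorted(members):
            zi = (k_own[node] - mu) / sd if sd > 0 else 0.0
            k_total = graph.degree(node)
            if k_total == 0:
                pi = 0.0
            else:
                per_mod: dict[int, int] = {}
                for nb in graph.neighbors(node):
                    m = module_partition[nb]
                    per_mod[m] = per_mod.get(m, 0) + 1
                pi = 1.0 - sum((k / k_total) ** 2 for k in per_mod.values())
            out.append(
                KeystoneRecord(
                    taxon_id=node,
                    zi=float(zi),
                    pi=float(pi),
                    category=classify_zi_pi(float(zi), float(pi)),
                )
            )
    return out
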