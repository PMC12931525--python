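"""Metabolome-microbiome coupling: Mantel tests and cross-correlation networks.

The Mantel test correlates the off-diagonal upper triangles of two distance
matrices (community Bray-Curtis vs metabolite Euclidean on autoscaled
abundances) with a joint row/column permutation null.  The cross network
tests every metabolite x taxon pair with Spearman correlation and keeps
pairs at |rho| > 0.7 with raw p < 0.05 — deliberately without FDR, in
contrast to the FDR-corrected microbial network: the two analyses follow
different conventions and the asymmetry is intentional.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix

from rhizodyn.data_model import (
    AlignmentError,
    MetaboliteTable,
    OtuTable,
    ParameterError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MantelResult",
    "CrossEdge",
    "CrossNetworkSummary",
    "mantel_test",
    "metabolite_distance",
    "metabolite_otu_network",
]


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int


@dataclass
class CrossEdge:
    metabolite_id: str
    taxon_id: str
    rho: float
    p_raw: float

    @property
    def sign(self) -> str:
        return "positive" if self.rho > 0 else "negative"


@dataclass
class CrossNetworkSummary:
    n_pairs: int
    n_positive: int
    n_negative: int
    n_taxa: int
    n_metabolites: int


def metabolite_distance(table: MetaboliteTable) -> DistanceMatrix:
    """Euclidean distances between samples on per-metabolite z-scores."""
    x = table.abundance.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    mu = x.mean(axis=1)
    z = np.zeros_like(x)
    ok = sd > 0
    z[ok] = (x[ok] - mu[ok, None]) / sd[ok, None]
    diff = z[:, :, None] - z[:, None, :]
    d = np.sqrt((diff**2).sum(axis=0))
    return DistanceMatrix(d, ids=table.sample_ids)


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> MantelResult:
    """One-sided (greater) Mantel test of two distance matrices.

    r is the Pearson correlation of the upper triangles; the null jointly
    permutes rows and columns of ``d2``; p = (1 + #{r_perm >= r_obs}) /
    (1 + n_perm).
    """
    if list(d1.ids) != list(d2.ids):
        raise AlignmentError("distance matrices must share ids and order")
    a = np.asarray(d1.data, dtype=float)
    b = np.asarray(d2.data, dtype=float)
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    x = a[iu]
    r_obs = float(np.corrcoef(x, b[iu])[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        count += np.corrcoef(x, b[np.ix_(perm, perm)][iu])[0, 1] >= r_obs
    return MantelResult(
        r=r_obs, p=(1 + count) / (1 + n_perm), n_permutations=n_perm
    )


def metabolite_otu_network(
    dams: MetaboliteTable,
    otus: OtuTable,
    rho_min: float = 0.7,
    alpha: float = 0.05,
) -> tuple[list[CrossEdge], CrossNetworkSummary]:
    """Spearman cross-correlation network between metabolites and taxa.

    Every metabolite x taxon pair is tested (average ranks for ties); edges
    satisfy |rho| > rho_min and raw p < alpha.  The summary partitions the
    retained pairs into positive and negative and counts the distinct
    participants.
    """
    shared = [s for s in dams.sample_ids if s in otus.counts.columns]
    if len(shared) < 5:
        raise ParameterError("need >= 5 shared samples for the cross network")
    m = dams.abundance.loc[:, shared].to_numpy(dtype=float)
    o = otus.counts.loc[:, shared].to_numpy(dtype=float)
    edges: list[CrossEdge] = []
    n_skipped = 0
    for i, mid in enumerate(dams.metabolite_ids):
        if np.ptp(m[i]) == 0:
            n_skipped += 1
            continue
        for j, tid in enumerate(otus.taxon_ids):
            if np.ptp(o[j]) == 0:
                n_skipped += 1
                continue
            rho, p = stats.spearmanr(m[i], o[j])
            if abs(rho) > rho_min and p < alpha:
                edges.append(CrossEdge(mid, tid, float(rho), float(p)))
    if n_skipped:
        logger.warning("%d constant vectors skipped in cross network", n_skipped)
    n_pos = sum(e.rho > 0 for e in edges)
    summary = CrossNetworkSummary(
        n_pairs=len(edges),
        n_positive=n_pos,
        n_negative=len(edges) - n_pos,
        n_taxa=len({e.taxon_id for e in edges}),
        n_metabolites=len({e.metabolite_id for e in edges}),
    )
    return edges, summary
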