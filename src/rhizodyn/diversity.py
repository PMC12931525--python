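"""Alpha diversity, beta-diversity distances, PCoA and PERMANOVA.

Conventions: "Chao1" is the bias-corrected estimator (defined even without
doubletons); "Simpson" is the Gini-Simpson complement 1 - sum(p^2); weighted
UniFrac is the normalized variant so both beta metrics live in [0, 1].
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from sympy.utilities.iterables import multiset_permutations

from rhizodyn.data_model import (
    DegenerateSampleError,
    OtuTable,
    ParameterError,
    PhyloTree,
    ValidationError,
)

__all__ = [
    "AlphaResult",
    "OrdinationResult",
    "PermanovaResult",
    "chao1",
    "gini_simpson",
    "alpha_diversity",
    "beta_distance",
    "pcoa",
    "permanova",
]


@dataclass
class AlphaResult:
    sample_id: str
    chao1: float
    gini_simpson: float


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    variance_explained: np.ndarray  # share of positive-eigenvalue sum


@dataclass
class PermanovaResult:
    pseudo_f: float
    p: float
    n_permutations: int


# ---------------------------------------------------------------------------
# Alpha diversity


def chao1(counts: Sequence[float]) -> float:
    """Bias-corrected Chao1: S_obs + f1(f1-1) / (2(f2+1))."""
    arr = np.asarray(counts, dtype=float)
    if arr.size and not np.allclose(arr, np.rint(arr)):
        raise ValidationError("Chao1 requires integer counts")
    arr = np.rint(arr).astype(int)
    s_obs = int((arr > 0).sum())
    f1 = int((arr == 1).sum())
    f2 = int((arr == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def gini_simpson(abundances: Sequence[float]) -> float:
    """Gini-Simpson diversity 1 - sum(p_i^2)."""
    arr = np.asarray(abundances, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise DegenerateSampleError("all-zero abundance vector")
    p = arr / total
    return float(1.0 - (p**2).sum())


def alpha_diversity(table: OtuTable) -> list[AlphaResult]:
    """Chao1 and Gini-Simpson for every sample of a count table."""
    out = []
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy()
        out.append(
            AlphaResult(
                sample_id=sample,
                chao1=chao1(col),
                gini_simpson=gini_simpson(col),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Beta diversity


def _bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    denom = (x + y).sum()
    if denom == 0:
        raise DegenerateSampleError("Bray-Curtis of two empty samples")
    return float(np.abs(x - y).sum() / denom)


def _branch_table(tree: PhyloTree, taxa: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and per-branch tip-membership indicator (branches x taxa)."""
    index = {t: i for i, t in enumerate(taxa)}
    lengths = []
    members = []
    for node in tree.tree.postorder(include_self=False):
        if node.length is None:
            continue
        row = np.zeros(len(taxa))
        for tip in node.tips(include_self=True):
            if tip.name in index:
                row[index[tip.name]] = 1.0
        lengths.append(node.length)
        members.append(row)
    return np.asarray(lengths), np.asarray(members)


def beta_distance(
    table: OtuTable,
    metric: str = "bray_curtis",
    tree: PhyloTree | None = None,
) -> DistanceMatrix:
    """Pairwise Bray-Curtis or normalized weighted UniFrac distances.

    Both metrics are computed on per-sample relative abundances and lie in
    [0, 1].  Weighted UniFrac needs a tree covering every taxon:
    ``sum_b l_b |p_Ab - p_Bb| / sum_b l_b (p_Ab + p_Bb)`` where ``p_.b`` is
    the summed relative abundance of the tips below branch ``b``.
    """
    if metric not in {"bray_curtis", "weighted_unifrac"}:
        raise ParameterError(f"unknown metric {metric!r}")
    values = table.counts.to_numpy(dtype=float)
    sums = values.sum(axis=0)
    if (sums == 0).any():
        raise DegenerateSampleError("empty sample in beta_distance")
    rel = values / sums
    samples = table.sample_ids
    n = len(samples)
    out = np.zeros((n, n))
    if metric == "bray_curtis":
        for i, j in itertools.combinations(range(n), 2):
            out[i, j] = out[j, i] = _bray_curtis(rel[:, i], rel[:, j])
    else:
        if tree is None:
            raise ParameterError("weighted_unifrac requires a tree")
        tree.require_tips(table.taxon_ids)
        sheared = tree.shear(table.taxon_ids)
        lengths, members = _branch_table(sheared, table.taxon_ids)
        branch_abund = members @ rel  # branches x samples
        for i, j in itertools.combinations(range(n), 2):
            num = (lengths * np.abs(branch_abund[:, i] - branch_abund[:, j])).sum()
            den = (lengths * (branch_abund[:, i] + branch_abund[:, j])).sum()
            out[i, j] = out[j, i] = num / den if den > 0 else 0.0
    return DistanceMatrix(out, ids=samples)


# ---------------------------------------------------------------------------
# PCoA


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Classical (Gower) principal coordinates analysis.

    Negative eigenvalues are dropped from the variance shares; axes are
    ordered by decreasing eigenvalue.
    """
    dm = np.asarray(d.data, dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T):
        raise ValidationError("distance matrix must be symmetric")
    n = dm.shape[0]
    a = -0.5 * dm**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ a @ centerer
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    positive = eigval > max(eigval.max(), 0) * 1e-10
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    shares = eigval[positive] / eigval[positive].sum()
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(d.ids), columns=axes),
        eigenvalues=eigval,
        variance_explained=shares,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _permanova_f(d2: np.ndarray, labels: np.ndarray) -> float:
    n = d2.shape[0]
    groups, counts = np.unique(labels, return_counts=True)
    g = groups.size
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for grp, cnt in zip(groups, counts):
        idx = np.flatnonzero(labels == grp)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(cnt, 1)].sum() / cnt
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        if ss_among <= 0:
            raise DegenerateSampleError("zero variance distance matrix")
        return math.inf
    return (ss_among / (g - 1)) / (ss_within / (n - g))


def permanova(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int | str = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``n_perm`` may be an integer (seeded random label permutations;
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)) or ``"exhaustive"``
    (all distinct label arrangements; p = #{F_perm >= F_obs} / #arrangements,
    the observed arrangement included).
    """
    labels = np.asarray(list(groups))
    if labels.size != len(d.ids):
        raise ParameterError("one group label per sample required")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ParameterError("PERMANOVA needs >= 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ParameterError(f"group {small!r} has < 2 samples")
    d2 = np.asarray(d.data, dtype=float) ** 2
    f_obs = _permanova_f(d2, labels)
    if n_perm == "exhaustive":
        count_ge = 0
        total = 0
        for perm in multiset_permutations(list(labels)):
            f_perm = _permanova_f(d2, np.asarray(perm))
            count_ge += f_perm >= f_obs
            total += 1
        return PermanovaResult(
            pseudo_f=f_obs, p=count_ge / total, n_permutations=total
        )
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(int(n_perm)):
        f_perm = _permanova_f(d2, rng.permutation(labels))
        count_ge += f_perm >= f_obs
    p = (1 + count_ge) / (1 + int(n_perm))
    return PermanovaResult(pseudo_f=f_obs, p=p, n_permutations=int(n_perm))
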