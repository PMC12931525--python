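"""Null-model partitioning of community assembly into five ecological processes.

The framework compares, for every sample pair, the observed phylogenetic
turnover (beta mean nearest taxon distance, betaMNTD) and taxonomic turnover
(Bray-Curtis) against nulls:

- betaNTI: z-score of observed betaMNTD against a null obtained by shuffling
  taxon labels across the patristic distance matrix.  betaNTI > +2 indicates
  heterogeneous selection, betaNTI < -2 homogeneous selection.
- RCbray: rescaled rank of observed Bray-Curtis within a stochastic-assembly
  null that preserves each sample's richness and total abundance while
  drawing species by metacommunity occurrence frequency and individuals by
  metacommunity relative abundance.  |RCbray| > 0.95 with |betaNTI| < 2
  indicates dispersal limitation (+) or homogenizing dispersal (-); the
  remainder is undominated (drift).

Pairs with |betaNTI| < 2 and |RCbray| <= 0.95 are classified as undominated.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rhizodyn.data_model import (
    CoverageError,
    DegenerateSampleError,
    MetaboliteTable,
    OtuTable,
    ParameterError,
    PhyloTree,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PROCESSES",
    "AssemblyResult",
    "ProcessFractions",
    "MetaboliteBntiFit",
    "UndefinedNullError",
    "filter_for_assembly",
    "beta_mntd",
    "bnti",
    "rc_bray",
    "classify_processes",
    "metabolite_bnti_regression",
]

PROCESSES: tuple[str, ...] = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

BNTI_THRESHOLD = 2.0
RC_THRESHOLD = 0.95


class UndefinedNullError(ValueError):
    """The null distribution has zero spread; the z-score is undefined."""


@dataclass
class AssemblyResult:
    sample_a: str
    sample_b: str
    beta_mntd_obs: float
    bnti: float
    rc_bray: float
    process: str


@dataclass
class ProcessFractions:
    fractions: dict[str, float]
    n_pairs: int

    def __post_init__(self) -> None:
        if self.n_pairs and abs(sum(self.fractions.values()) - 1.0) > 1e-9:
            raise ValueError("process fractions must sum to 1")


@dataclass
class MetaboliteBntiFit:
    metabolite_id: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    significant: bool


# ---------------------------------------------------------------------------
# Filtering


def filter_for_assembly(
    table: OtuTable, groups: Mapping[str, Sequence[str]]
) -> OtuTable:
    """Keep taxa with abundance >= 1 in at least two samples of some group."""
    keep = np.zeros(len(table.taxon_ids), dtype=bool)
    for name, samples in groups.items():
        sub = table.counts.loc[:, list(samples)].to_numpy()
        keep |= (sub >= 1).sum(axis=1) >= 2
    kept = [t for t, k in zip(table.taxon_ids, keep) if k]
    return table.subset_taxa(kept)


# ---------------------------------------------------------------------------
# betaMNTD / betaNTI


def _relative_matrix(table: OtuTable, weighted: bool = True) -> np.ndarray:
    values = table.counts.to_numpy(dtype=float)
    if not weighted:  # presence/absence variant: equal weight per present taxon
        values = (values > 0).astype(float)
    sums = values.sum(axis=0)
    if (sums == 0).any():
        sample = table.sample_ids[int(np.argmin(sums))]
        raise DegenerateSampleError(f"sample {sample!r} is empty")
    return values / sums


def _nearest_taxon_distances(dist: np.ndarray, present: np.ndarray) -> np.ndarray:
    """ND[i, s] = min over taxa j present in sample s of dist[i, j]."""
    n_taxa, n_samples = present.shape
    nd = np.empty((n_taxa, n_samples))
    for s in range(n_samples):
        cols = np.flatnonzero(present[:, s])
        nd[:, s] = dist[:, cols].min(axis=1)
    return nd


def _beta_mntd_matrix(dist: np.ndarray, rel: np.ndarray) -> np.ndarray:
    """betaMNTD for all sample pairs given patristic distances and rel. abund."""
    nd = _nearest_taxon_distances(dist, rel > 0)
    cross = rel.T @ nd  # cross[a, b] = sum_i f_iA * min_{j in B} d_ij
    return 0.5 * (cross + cross.T)


def beta_mntd(
    table: OtuTable,
    patristic,
    pair: tuple[str, str],
    weighted: bool = True,
) -> float:
    """Abundance-weighted beta mean nearest taxon distance for one pair.

    ``patristic`` is a skbio ``DistanceMatrix`` (or anything with ``ids`` and
    index access) covering the taxa of both samples.
    """
    a, b = pair
    rel = _relative_matrix(table, weighted=weighted)
    ids = list(patristic.ids)
    missing = [t for t in table.taxon_ids if t not in set(ids)]
    if missing:
        raise CoverageError(f"patristic matrix lacks taxon {missing[0]!r}")
    order = [ids.index(t) for t in table.taxon_ids]
    dist = np.asarray(patristic.data)[np.ix_(order, order)]
    ia = table.sample_ids.index(a)
    ib = table.sample_ids.index(b)
    if not (rel[:, ia] > 0).any() or not (rel[:, ib] > 0).any():
        raise DegenerateSampleError("empty community in betaMNTD pair")
    full = _beta_mntd_matrix(dist, rel[:, [ia, ib]])
    return float(full[0, 1])


def bnti(
    table: OtuTable,
    tree: PhyloTree,
    pairs: Sequence[tuple[str, str]] | None = None,
    n_null: int = 1000,
    seed: int | None = None,
    weighted: bool = True,
) -> pd.DataFrame:
    """betaNTI for the requested sample pairs.

    The null shuffles taxon labels jointly across rows and columns of the
    patristic matrix ``n_null`` times; betaNTI = (obs - mean_null)/sd_null.
    Returns a DataFrame with columns sample_a, sample_b, beta_mntd_obs, bnti.
    """
    if n_null < 2:
        raise ParameterError("n_null must be >= 2")
    samples = table.sample_ids
    if pairs is None:
        pairs = list(itertools.combinations(samples, 2))
    if len(table.taxon_ids) < 100:
        logger.warning(
            "betaNTI on %d taxa; >=100 recommended for stable nulls",
            len(table.taxon_ids),
        )
    rng = np.random.default_rng(seed)
    dist = np.asarray(tree.patristic(table.taxon_ids).data)
    rel = _relative_matrix(table, weighted=weighted)
    n_taxa = rel.shape[0]
    idx = {s: i for i, s in enumerate(samples)}
    pair_idx = [(idx[a], idx[b]) for a, b in pairs]

    obs = _beta_mntd_matrix(dist, rel)
    null = np.empty((n_null, len(pairs)))
    rows = np.array([a for a, _ in pair_idx])
    cols = np.array([b for _, b in pair_idx])
    for k in range(n_null):
        perm = rng.permutation(n_taxa)
        bm = _beta_mntd_matrix(dist[np.ix_(perm, perm)], rel)
        null[k] = bm[rows, cols]
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = pairs[int(np.argmin(sd))]
        raise UndefinedNullError(f"null betaMNTD sd is 0 for pair {bad}")
    values = (obs[rows, cols] - mean) / sd
    return pd.DataFrame(
        {
            "sample_a": [a for a, _ in pairs],
            "sample_b": [b for _, b in pairs],
            "beta_mntd_obs": obs[rows, cols],
            "bnti": values,
        }
    )


# ---------------------------------------------------------------------------
# Raup-Crick on Bray-Curtis


def _bray(x: np.ndarray, y: np.ndarray) -> float:
    denom = (x + y).sum()
    if denom == 0:
        raise DegenerateSampleError("Bray-Curtis of two empty communities")
    return float(np.abs(x - y).sum() / denom)


def _null_community(
    rng: np.random.Generator,
    richness: int,
    total: int,
    occ_p: np.ndarray,
    abund_w: np.ndarray,
) -> np.ndarray:
    n_taxa = occ_p.size
    species = rng.choice(n_taxa, size=richness, replace=False, p=occ_p)
    out = np.zeros(n_taxa)
    out[species] = 1.0
    remaining = total - richness
    if remaining > 0:
        w = abund_w[species]
        out[species] += rng.multinomial(remaining, w / w.sum())
    return out


def rc_bray(
    table: OtuTable,
    pairs: Sequence[tuple[str, str]] | None = None,
    n_null: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Raup-Crick index on Bray-Curtis dissimilarity for the requested pairs.

    Null communities preserve each sample's observed richness and total count;
    species are drawn without replacement with probability proportional to
    metacommunity occurrence frequency, receive one founding individual each,
    and remaining individuals are allocated multinomially by metacommunity
    relative abundance.  RCbray in [-1, 1].
    """
    if n_null < 1:
        raise ParameterError("n_null must be >= 1")
    counts = table.counts.to_numpy(dtype=float)
    samples = table.sample_ids
    if pairs is None:
        pairs = list(itertools.combinations(samples, 2))
    occ = (counts > 0).sum(axis=1).astype(float)
    if (occ == 0).all():
        raise DegenerateSampleError("empty metacommunity")
    occ_p = occ / occ.sum()
    abund_w = counts.sum(axis=1)
    idx = {s: i for i, s in enumerate(samples)}
    richness = (counts > 0).sum(axis=0)
    totals = np.rint(counts.sum(axis=0)).astype(int)
    n_taxa = counts.shape[0]
    if (richness > (occ > 0).sum()).any():
        raise ParameterError("sample richness exceeds metacommunity richness")

    rng = np.random.default_rng(seed)
    records = []
    for a, b in pairs:
        ia, ib = idx[a], idx[b]
        obs = _bray(counts[:, ia], counts[:, ib])
        null = np.empty(n_null)
        for k in range(n_null):
            xa = _null_community(rng, int(richness[ia]), int(totals[ia]), occ_p, abund_w)
            xb = _null_community(rng, int(richness[ib]), int(totals[ib]), occ_p, abund_w)
            null[k] = _bray(xa, xb)
        less = float((null < obs - 1e-12).sum())
        equal = float((np.abs(null - obs) <= 1e-12).sum())
        rc = 2.0 * (less + 0.5 * equal) / n_null - 1.0
        records.append((a, b, obs, rc))
    return pd.DataFrame(
        records, columns=["sample_a", "sample_b", "bray_obs", "rc_bray"]
    )


# ---------------------------------------------------------------------------
# Classification


def classify_pair(bnti_value: float, rc_value: float) -> str:
    if bnti_value > BNTI_THRESHOLD:
        return "heterogeneous_selection"
    if bnti_value < -BNTI_THRESHOLD:
        return "homogeneous_selection"
    if rc_value > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc_value < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "undominated"


def classify_processes(
    bnti_frame: pd.DataFrame, rc_frame: pd.DataFrame
) -> tuple[list[AssemblyResult], ProcessFractions]:
    """Label each pair with its assembly process and summarize shares."""
    merged = bnti_frame.merge(rc_frame, on=["sample_a", "sample_b"], how="inner")
    if len(merged) < len(bnti_frame):
        logger.warning(
            "%d pair(s) missing RCbray values were excluded",
            len(bnti_frame) - len(merged),
        )
    results: list[AssemblyResult] = []
    for row in merged.itertuples(index=False):
        if np.isnan(row.bnti) or np.isnan(row.rc_bray):
            logger.warning(
                "pair (%s, %s) excluded: missing value", row.sample_a, row.sample_b
            )
            continue
        results.append(
            AssemblyResult(
                sample_a=row.sample_a,
                sample_b=row.sample_b,
                beta_mntd_obs=float(row.beta_mntd_obs),
                bnti=float(row.bnti),
                rc_bray=float(row.rc_bray),
                process=classify_pair(float(row.bnti), float(row.rc_bray)),
            )
        )
    n = len(results)
    fractions = {
        p: (sum(r.process == p for r in results) / n if n else 0.0)
        for p in PROCESSES
    }
    return results, ProcessFractions(fractions=fractions, n_pairs=n)


# ---------------------------------------------------------------------------
# Metabolite-betaNTI regression


def metabolite_bnti_regression(
    metabolites: MetaboliteTable,
    bnti_frame: pd.DataFrame,
    mode: str = "pair_difference",
    alpha: float = 0.05,
) -> list[MetaboliteBntiFit]:
    """OLS of betaNTI on a per-pair metabolite predictor.

    The predictor is |a_i - a_j| (``pair_difference``, default) or
    (a_i + a_j)/2 (``pair_mean``) of the metabolite's abundance in the two
    samples of each pair.
    """
    if mode not in {"pair_difference", "pair_mean"}:
        raise ParameterError(f"unknown mode {mode!r}")
    missing = [
        s
        for s in pd.unique(
            pd.concat([bnti_frame["sample_a"], bnti_frame["sample_b"]])
        )
        if s not in metabolites.abundance.columns
    ]
    if missing:
        raise ParameterError(f"betaNTI pair uses unknown sample {missing[0]!r}")
    y = bnti_frame["bnti"].to_numpy(dtype=float)
    fits: list[MetaboliteBntiFit] = []
    abundance = metabolites.abundance
    a_vals = abundance.loc[:, bnti_frame["sample_a"]].to_numpy()
    b_vals = abundance.loc[:, bnti_frame["sample_b"]].to_numpy()
    if mode == "pair_difference":
        x_all = np.abs(a_vals - b_vals)
    else:
        x_all = (a_vals + b_vals) / 2.0
    for mi, mid in enumerate(metabolites.metabolite_ids):
        x = x_all[mi]
        if np.ptp(x) == 0:
            logger.warning("metabolite %s: constant predictor, fit skipped", mid)
            continue
        res = stats.linregress(x, y)
        fits.append(
            MetaboliteBntiFit(
                metabolite_id=mid,
                slope=float(res.slope),
                intercept=float(res.intercept),
                r_squared=float(res.rvalue**2),
                p_value=float(res.pvalue),
                significant=bool(res.pvalue < alpha),
            )
        )
    return fits
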