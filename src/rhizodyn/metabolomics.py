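"""Differential-metabolite screening and set/pathway summaries.

A metabolite is differentially accumulated (DAM) between two stage groups
when its PLS-DA variable importance in projection exceeds 1 and its
|log2 fold change| is at least 1.  Fold change is the ratio of group means of
raw peak areas (B over A); zero means are replaced by half the smallest
positive value of the table.  The discriminant fit is a two-component PLS-DA
on autoscaled variables; this stands in for the orthogonal variant (OPLS-DA):
the VIP>1 screen is robust to the orthogonal filtering and no orthogonal
hyperparameters are published for this kind of study.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

from rhizodyn.data_model import (
    MetaboliteTable,
    ParameterError,
    PHASE_STAGES,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_COMPARISONS",
    "DamRecord",
    "VennSummary",
    "log2_fold_change",
    "plsda_vip",
    "screen_dams",
    "venn_partition",
    "ora_enrichment",
]

#: Consecutive stage pairs within each phase plus the within-phase skips,
#: mirroring six pairwise comparisons across the flowering/senescing design.
DEFAULT_COMPARISONS: dict[tuple[str, str], str] = {
    ("TB", "TIB"): "FS",
    ("TIB", "TFB"): "FS",
    ("TB", "TFB"): "FS",
    ("TFB", "TS"): "SS",
    ("TS", "TF"): "SS",
    ("TFB", "TF"): "SS",
}


@dataclass
class DamRecord:
    metabolite_id: str
    comparison: tuple[str, str]
    log2fc: float
    vip: float
    is_dam: bool


@dataclass
class VennSummary:
    sets: dict[str, set[str]]
    unique_counts: dict[str, int]
    intersection_counts: dict[tuple[str, ...], int]
    phase_unique_counts: dict[str, int]
    phase_unique_shares: dict[str, float]


# ---------------------------------------------------------------------------
# Fold change


def log2_fold_change(
    table: MetaboliteTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> pd.Series:
    """log2(mean_B / mean_A) per metabolite, with pseudo-value substitution.

    A zero group mean is replaced by half the smallest positive value in the
    whole table, so the result is always finite.
    """
    if not len(group_a) or not len(group_b):
        raise ParameterError("both groups must be nonempty")
    mean_a = table.abundance.loc[:, list(group_a)].mean(axis=1)
    mean_b = table.abundance.loc[:, list(group_b)].mean(axis=1)
    pseudo = table.min_positive() / 2.0
    n_zero = int((mean_a == 0).sum() + (mean_b == 0).sum())
    if n_zero:
        logger.warning(
            "%d zero group mean(s) replaced by pseudo-value %.3g", n_zero, pseudo
        )
    mean_a = mean_a.where(mean_a > 0, pseudo)
    mean_b = mean_b.where(mean_b > 0, pseudo)
    return np.log2(mean_b / mean_a)


# ---------------------------------------------------------------------------
# PLS-DA VIP


def _autoscale(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    out = np.zeros_like(x)
    nonzero = sd > 0
    out[:, nonzero] = (x[:, nonzero] - mu[nonzero]) / sd[nonzero]
    return out


def plsda_vip(
    table: MetaboliteTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    n_components: int = 2,
) -> pd.Series:
    """Variable importance in projection from a PLS-DA of two groups.

    Variables are autoscaled; y is a centered group indicator.  With weights
    ``w_a``, x-scores ``t_a`` and y-loadings ``q_a`` per component,
    ``VIP_j = sqrt(p * sum_a[s_a (w_ja/||w_a||)^2] / sum_a s_a)`` where
    ``s_a = q_a^2 t_a' t_a`` is the y-variance explained by component ``a``.
    The VIPs satisfy mean(VIP^2) = 1.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ParameterError("PLS-DA needs >= 2 samples per group")
    samples = list(group_a) + list(group_b)
    x = table.abundance.loc[:, samples].to_numpy().T  # samples x variables
    y = np.array([0.0] * len(group_a) + [1.0] * len(group_b))
    x = _autoscale(x)
    y = y - y.mean()
    max_rank = min(len(samples) - 1, x.shape[1])
    k = min(n_components, max_rank)
    if k < n_components:
        logger.warning(
            "requested %d PLS components, only %d extractable", n_components, k
        )
    pls = PLSRegression(n_components=k, scale=False)
    pls.fit(x, y)
    w = pls.x_weights_  # variables x components
    t = pls.x_scores_  # samples x components
    q = pls.y_loadings_[0]  # components
    ssy = (q**2) * (t**2).sum(axis=0)
    w_norm = w / np.linalg.norm(w, axis=0, keepdims=True)
    p = x.shape[1]
    vip = np.sqrt(p * (w_norm**2 @ ssy) / ssy.sum())
    return pd.Series(vip, index=table.metabolite_ids)


# ---------------------------------------------------------------------------
# Screening


def screen_dams(
    log2fc: pd.Series,
    vip: pd.Series,
    comparison: tuple[str, str] = ("A", "B"),
    vip_min: float = 1.0,
    log2fc_min: float = 1.0,
) -> list[DamRecord]:
    """Flag DAMs: VIP strictly greater than ``vip_min`` and |log2FC| >= ``log2fc_min``."""
    if not log2fc.index.equals(vip.index):
        raise ParameterError("log2fc and vip must be aligned on metabolite_id")
    records = []
    for mid in log2fc.index:
        fc = float(log2fc[mid])
        v = float(vip[mid])
        records.append(
            DamRecord(
                metabolite_id=mid,
                comparison=comparison,
                log2fc=fc,
                vip=v,
                is_dam=bool(v > vip_min and abs(fc) >= log2fc_min),
            )
        )
    return records


def screen_all_comparisons(
    table: MetaboliteTable,
    metadata,
    comparisons: Mapping[tuple[str, str], str] | None = None,
    vip_min: float = 1.0,
    log2fc_min: float = 1.0,
) -> tuple[list[DamRecord], dict[tuple[str, str], set[str]]]:
    """Run the DAM screen for every stage-pair comparison of the design."""
    comparisons = dict(comparisons or DEFAULT_COMPARISONS)
    records: list[DamRecord] = []
    dam_sets: dict[tuple[str, str], set[str]] = {}
    for (stage_a, stage_b) in comparisons:
        ga = metadata.samples_in_stage(stage_a)
        gb = metadata.samples_in_stage(stage_b)
        fc = log2_fold_change(table, ga, gb)
        vip = plsda_vip(table, ga, gb)
        recs = screen_dams(
            fc, vip, (stage_a, stage_b), vip_min=vip_min, log2fc_min=log2fc_min
        )
        records.extend(recs)
        dam_sets[(stage_a, stage_b)] = {r.metabolite_id for r in recs if r.is_dam}
    return records, dam_sets


# ---------------------------------------------------------------------------
# Venn partition


def venn_partition(
    dam_sets: Mapping[object, set[str]],
    phase_map: Mapping[object, str],
) -> VennSummary:
    """Set structure of per-comparison DAM sets with phase-specific shares.

    Phase-unique DAMs are those in the union of one phase's comparisons but
    not the other's; their shares sum to 1 over {FS, SS}.
    """
    bad = set(phase_map.values()) - set(PHASE_STAGES)
    if bad:
        raise ParameterError(f"unknown phase label(s) {sorted(bad)}")
    missing = set(dam_sets) - set(phase_map)
    if missing:
        raise ParameterError(f"comparison(s) without phase label: {missing}")
    keys = list(dam_sets)
    unique_counts = {}
    for key in keys:
        others = set().union(*(dam_sets[k] for k in keys if k != key)) if len(keys) > 1 else set()
        unique_counts[key] = len(dam_sets[key] - others)
    intersection_counts = {}
    for r in range(2, len(keys) + 1):
        for combo in itertools.combinations(keys, r):
            inter = set.intersection(*(dam_sets[k] for k in combo))
            intersection_counts[tuple(str(k) for k in combo)] = len(inter)
    phase_unions = {
        phase: set().union(
            *(dam_sets[k] for k in keys if phase_map[k] == phase), set()
        )
        for phase in PHASE_STAGES
    }
    fs_only = phase_unions["FS"] - phase_unions["SS"]
    ss_only = phase_unions["SS"] - phase_unions["FS"]
    total = len(fs_only) + len(ss_only)
    shares = {
        "FS": len(fs_only) / total if total else 0.0,
        "SS": len(ss_only) / total if total else 0.0,
    }
    return VennSummary(
        sets={str(k): set(v) for k, v in dam_sets.items()},
        unique_counts={str(k): v for k, v in unique_counts.items()},
        intersection_counts=intersection_counts,
        phase_unique_counts={"FS": len(fs_only), "SS": len(ss_only)},
        phase_unique_shares=shares,
    )


# ---------------------------------------------------------------------------
# Over-representation analysis


def ora_enrichment(
    dam_ids: set[str],
    annotation: Mapping[str, set[str]],
    background: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of DAMs per pathway.

    p = P(X >= k) with X ~ Hypergeometric(N=|background|, K=|pathway ∩
    background|, n=|dam_ids|); Benjamini-Hochberg q-values across pathways.
    """
    outside = dam_ids - background
    if outside:
        raise ValidationError(
            f"DAM id(s) outside background: {sorted(outside)[:3]}"
        )
    n_bg = len(background)
    n_dam = len(dam_ids)
    rows = []
    for pathway, members in annotation.items():
        in_bg = members & background
        k = len(in_bg & dam_ids)
        big_k = len(in_bg)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_dam)) if big_k else 1.0
        rows.append((pathway, big_k, k, p))
    frame = pd.DataFrame(rows, columns=["pathway", "pathway_size", "overlap", "p_raw"])
    if len(frame):
        frame["q_bh"] = multipletests(frame["p_raw"], method="fdr_bh")[1]
    else:
        frame["q_bh"] = []
    return frame.set_index("pathway")
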