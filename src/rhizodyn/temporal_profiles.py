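"""Short time-series profile clustering with permutation significance.

The procedure follows the classic short time-series expression mining recipe:

1. enumerate all candidate model profiles — unit-change sequences over T
   ordered time points with per-step changes in ``[-c, +c]``;
2. select ``m`` mutually dissimilar model profiles greedily, maximizing the
   minimum pairwise distance ``1 - Pearson(profile values)``;
3. transform each observed series to log2 ratios against its first time
   point and assign it to the most correlated model profile;
4. test each profile's assigned count against the count expected under
   within-series time-order permutations, with a binomial tail p-value and
   Bonferroni correction across the m profiles.

Stages are treated as equally spaced ordinal time points; real inter-stage
durations are deliberately not used (standard usage for this method).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from rhizodyn.data_model import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "ProfileModel",
    "ProfileAssignment",
    "ProfileSignificance",
    "generate_candidate_profiles",
    "select_model_profiles",
    "assign_series",
    "profile_significance",
    "log_ratio_transform",
]


@dataclass
class ProfileModel:
    profile_id: int
    unit_changes: tuple[int, ...]
    values: tuple[float, ...]  # cumulative, starts at 0

    @property
    def is_flat(self) -> bool:
        return all(c == 0 for c in self.unit_changes)


@dataclass
class ProfileAssignment:
    series_id: str
    profile_id: int
    correlation: float


@dataclass
class ProfileSignificance:
    profile_id: int
    observed_count: int
    expected_count: float
    p_raw: float
    p_adjusted: float
    significant: bool


# ---------------------------------------------------------------------------
# Candidate profiles


def generate_candidate_profiles(t: int, c: int) -> list[ProfileModel]:
    """All (2c+1)^(T-1) unit-change profiles over T time points."""
    if t < 3:
        raise ParameterError("need at least T=3 time points")
    if c < 1:
        raise ParameterError("c must be >= 1")
    profiles = []
    for pid, changes in enumerate(
        itertools.product(range(-c, c + 1), repeat=t - 1)
    ):
        values = (0.0, *np.cumsum(changes).astype(float))
        profiles.append(ProfileModel(pid, tuple(changes), values))
    return profiles


def _safe_corr(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation with constant-vector correlation defined as 0."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        return 0.0
    return float(np.corrcoef(xa, ya)[0, 1])


def select_model_profiles(
    candidates: Sequence[ProfileModel], m: int, seed: int | None = None
) -> list[ProfileModel]:
    """Greedy max-min-distance selection of ``m`` model profiles.

    Distance is ``1 - Pearson(values)``.  Selection starts from the profile
    with the largest summed |unit change| and always breaks ties by lowest
    profile id, so the result is deterministic regardless of ``seed``.
    """
    if m > len(candidates):
        raise ParameterError(f"m={m} exceeds candidate pool {len(candidates)}")
    if m == len(candidates):
        return list(candidates)
    n_nonflat = sum(not p.is_flat for p in candidates)
    if m > n_nonflat:
        raise ParameterError(f"m={m} exceeds non-flat candidate pool {n_nonflat}")
    start = max(
        candidates, key=lambda p: (sum(abs(u) for u in p.unit_changes), -p.profile_id)
    )
    selected = [start]
    values = {p.profile_id: np.asarray(p.values) for p in candidates}
    min_dist = {
        p.profile_id: 1.0 - _safe_corr(values[p.profile_id], values[start.profile_id])
        for p in candidates
    }
    chosen = {start.profile_id}
    while len(selected) < m:
        best = max(
            (p for p in candidates if p.profile_id not in chosen),
            key=lambda p: (min_dist[p.profile_id], -p.profile_id),
        )
        selected.append(best)
        chosen.add(best.profile_id)
        for p in candidates:
            if p.profile_id in chosen:
                continue
            dist = 1.0 - _safe_corr(values[p.profile_id], values[best.profile_id])
            if dist < min_dist[p.profile_id]:
                min_dist[p.profile_id] = dist
    return selected


# ---------------------------------------------------------------------------
# Assignment


def log_ratio_transform(
    series: pd.DataFrame, pseudo: float | None = None
) -> pd.DataFrame:
    """log2 ratio of each series against its first time point.

    Nonpositive raw values are replaced by ``pseudo`` (default: half the
    smallest positive value of the matrix) before taking ratios.
    """
    values = series.to_numpy(dtype=float)
    if pseudo is None:
        positive = values[values > 0]
        if positive.size == 0:
            raise ParameterError("series matrix has no positive entries")
        pseudo = float(positive.min()) / 2.0
    clipped = np.where(values > 0, values, pseudo)
    out = np.log2(clipped / clipped[:, [0]])
    return pd.DataFrame(out, index=series.index, columns=series.columns)


def assign_series(
    series: pd.DataFrame,
    profiles: Sequence[ProfileModel],
    transform: bool = True,
) -> list[ProfileAssignment]:
    """Assign each series to the most correlated model profile.

    ``series`` holds one row per id over T ordered time points.  Rows are
    log2-ratio transformed first (set ``transform=False`` when they already
    start at 0).  Constant series correlate 0 with everything and fall to the
    flat profile when present, else to the lowest profile id.
    """
    t = len(profiles[0].values)
    if series.shape[1] != t:
        raise ParameterError(
            f"series have {series.shape[1]} time points, profiles have {t}"
        )
    data = log_ratio_transform(series) if transform else series
    flat_ids = [p.profile_id for p in profiles if p.is_flat]
    ordered = sorted(profiles, key=lambda p: p.profile_id)

    x = data.to_numpy(dtype=float)
    pv = np.array([p.values for p in ordered], dtype=float)
    ids = np.array([p.profile_id for p in ordered])

    def _rowwise_z(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sd = mat.std(axis=1)
        ok = sd > 0
        z = np.zeros_like(mat)
        z[ok] = (mat[ok] - mat[ok].mean(axis=1, keepdims=True)) / sd[ok, None]
        return z, ok

    zx, x_ok = _rowwise_z(x)
    zp, p_ok = _rowwise_z(pv)
    corr = (zx @ zp.T) / x.shape[1]  # constant rows yield 0 everywhere
    # argmax over profiles sorted by id -> ties break to the lowest id
    best = np.argmax(corr, axis=1)
    out = []
    for i, sid in enumerate(data.index):
        if not x_ok[i]:
            pid = flat_ids[0] if flat_ids else ordered[0].profile_id
            out.append(ProfileAssignment(str(sid), int(pid), 0.0))
        else:
            out.append(
                ProfileAssignment(
                    str(sid), int(ids[best[i]]), float(corr[i, best[i]])
                )
            )
    return out


# ---------------------------------------------------------------------------
# Significance


def profile_significance(
    assignments: Sequence[ProfileAssignment],
    series: pd.DataFrame,
    profiles: Sequence[ProfileModel],
    n_perm: int = 50,
    seed: int | None = None,
    alpha: float = 0.05,
    transform: bool = True,
) -> list[ProfileSignificance]:
    """Permutation test of profile over-representation.

    The expected count per profile is the mean assigned count over ``n_perm``
    independent within-series time-order permutations of the raw series;
    p_raw = P(X >= observed) with X ~ Binomial(n_series, expected/n_series),
    Bonferroni-adjusted over the m profiles.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    if not len(series):
        return []
    rng = np.random.default_rng(seed)
    n_series = len(series)
    observed = pd.Series(0, index=[p.profile_id for p in profiles])
    for a in assignments:
        observed[a.profile_id] += 1
    null_counts = pd.Series(0.0, index=observed.index)
    raw = series.to_numpy(dtype=float)
    for _ in range(n_perm):
        order = np.argsort(rng.random(raw.shape), axis=1)
        perm = np.take_along_axis(raw, order, axis=1)
        perm_frame = pd.DataFrame(perm, index=series.index, columns=series.columns)
        for a in assign_series(perm_frame, profiles, transform=transform):
            null_counts[a.profile_id] += 1
    expected = null_counts / n_perm
    m = len(profiles)
    out = []
    for p in profiles:
        obs = int(observed[p.profile_id])
        exp = float(expected[p.profile_id])
        prob = min(max(exp / n_series, 0.0), 1.0)
        p_raw = float(stats.binom.sf(obs - 1, n_series, prob))
        p_adj = min(1.0, p_raw * m)
        out.append(
            ProfileSignificance(
                profile_id=p.profile_id,
                observed_count=obs,
                expected_count=exp,
                p_raw=p_raw,
                p_adjusted=p_adj,
                significant=bool(p_adj < alpha),
            )
        )
    return out
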