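import math

import numpy as np
import pandas as pd
import pytest

from rhizodyn.data_model import MetaboliteTable, ParameterError, ValidationError
from rhizodyn.metabolomics import (
    log2_fold_change,
    ora_enrichment,
    plsda_vip,
    screen_dams,
    venn_partition,
)


def _table(values: np.ndarray) -> MetaboliteTable:
    return MetaboliteTable(
        pd.DataFrame(
            values,
            index=[f"M{i}" for i in range(values.shape[0])],
            columns=[f"s{j}" for j in range(values.shape[1])],
        )
    )


class TestLog2FoldChange:
    def test_powers_of_two(self):
        table = _table(np.array([[2.0, 2.0, 8.0, 8.0]]))
        fc = log2_fold_change(table, ["s0", "s1"], ["s2", "s3"])
        assert fc["M0"] == pytest.approx(2.0)

    def test_identical_groups_give_zero(self):
        table = _table(np.array([[5.0, 7.0, 5.0, 7.0]]))
        fc = log2_fold_change(table, ["s0", "s1"], ["s2", "s3"])
        assert fc["M0"] == pytest.approx(0.0)

    def test_zero_mean_gets_pseudo_value(self):
        table = _table(np.array([[0.0, 0.0, 4.0, 4.0], [1.0, 1.0, 1.0, 1.0]]))
        fc = log2_fold_change(table, ["s0", "s1"], ["s2", "s3"])
        assert np.isfinite(fc["M0"])
        assert fc["M0"] == pytest.approx(np.log2(4.0 / 0.5))

    def test_empty_group_rejected(self):
        table = _table(np.ones((1, 4)))
        with pytest.raises(ParameterError):
            log2_fold_change(table, [], ["s0"])


def _nipals_pls_vip(x, y, n_components=2):
    """Independent NIPALS PLS1 oracle for the VIP score."""
    x = x.copy().astype(float)
    y = y.astype(float).copy()
    x = (x - x.mean(0)) / np.where(x.std(0, ddof=1) > 0, x.std(0, ddof=1), 1.0)
    y = y - y.mean()
    weights, scores, qs = [], [], []
    xk, yk = x.copy(), y.copy()
    for _ in range(n_components):
        w = xk.T @ yk
        w = w / np.linalg.norm(w)
        t = xk @ w
        p = xk.T @ t / (t @ t)
        q = yk @ t / (t @ t)
        xk = xk - np.outer(t, p)
        yk = yk - q * t
        weights.append(w)
        scores.append(t)
        qs.append(q)
    ssy = np.array([q**2 * (t @ t) for q, t in zip(qs, scores)])
    w = np.column_stack(weights)
    wn = w / np.linalg.norm(w, axis=0, keepdims=True)
    p_vars = x.shape[1]
    return np.sqrt(p_vars * (wn**2 @ ssy) / ssy.sum())


class TestPlsdaVip:
    def _discriminating_table(self, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0] * 6 + [1] * 6)
        x = rng.lognormal(10, 0.3, size=(20, 12))
        x[0] = 1000 * (1 + y) + rng.normal(0, 10, size=12)
        return _table(x), y

    def test_mean_square_identity(self):
        table, _ = self._discriminating_table()
        vip = plsda_vip(table, [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 12)])
        assert (vip**2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_separating_variable_has_max_vip_above_one(self):
        table, _ = self._discriminating_table()
        vip = plsda_vip(table, [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 12)])
        assert vip.idxmax() == "M0"
        assert vip["M0"] > 1.0

    def test_matches_nipals_oracle(self):
        table, y = self._discriminating_table(seed=3)
        vip = plsda_vip(table, [f"s{i}" for i in range(6)], [f"s{i}" for i in range(6, 12)])
        oracle = _nipals_pls_vip(table.abundance.to_numpy().T, y)
        np.testing.assert_allclose(vip.to_numpy(), oracle, rtol=1e-6)

    def test_label_permutation_has_no_systematic_winner(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(10, 0.3, size=(15, 12))
        table = _table(x)
        winners = []
        for seed in range(20):
            perm = np.random.default_rng(seed).permutation(12)
            ga = [f"s{i}" for i in perm[:6]]
            gb = [f"s{i}" for i in perm[6:]]
            winners.append(plsda_vip(table, ga, gb).idxmax())
        assert len(set(winners)) > 1

    def test_too_few_samples_rejected(self):
        table = _table(np.ones((3, 4)))
        with pytest.raises(ParameterError):
            plsda_vip(table, ["s0"], ["s1", "s2"])


class TestScreenDams:
    @pytest.mark.parametrize(
        "vip,fc,expected",
        [
            (1.5, 0.5, False),
            (1.2, -1.3, True),
            (1.0, 2.0, False),  # strict VIP > 1
            (1.01, 1.0, True),  # |log2fc| >= 1 is inclusive
        ],
    )
    def test_threshold_logic(self, vip, fc, expected):
        records = screen_dams(
            pd.Series({"m": fc}), pd.Series({"m": vip}), ("TB", "TFB")
        )
        assert records[0].is_dam is expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            screen_dams(pd.Series({"a": 1.0}), pd.Series({"b": 1.0}))


class TestVennPartition:
    def test_basic_set_algebra(self):
        summary = venn_partition(
            {"A": {"m1", "m2"}, "B": {"m2", "m3"}},
            {"A": "FS", "B": "SS"},
        )
        assert summary.unique_counts == {"A": 1, "B": 1}
        assert summary.intersection_counts[("A", "B")] == 1

    def test_phase_specific_shares_match_printed_values(self):
        fs = {f"f{i}" for i in range(37)} | {f"x{i}" for i in range(10)}
        ss = {f"s{i}" for i in range(83)} | {f"x{i}" for i in range(10)}
        summary = venn_partition({"cmpF": fs, "cmpS": ss}, {"cmpF": "FS", "cmpS": "SS"})
        assert summary.phase_unique_counts == {"FS": 37, "SS": 83}
        assert summary.phase_unique_shares["FS"] * 100 == pytest.approx(30.8, abs=0.05)
        assert summary.phase_unique_shares["SS"] * 100 == pytest.approx(69.2, abs=0.05)

    def test_disjoint_equal_sets_split_evenly(self):
        summary = venn_partition(
            {"A": {"a", "b"}, "B": {"c", "d"}}, {"A": "FS", "B": "SS"}
        )
        assert summary.phase_unique_shares == {"FS": 0.5, "SS": 0.5}

    def test_unknown_phase_rejected(self):
        with pytest.raises(ParameterError):
            venn_partition({"A": set()}, {"A": "XX"})


class TestOraEnrichment:
    def test_exact_hypergeometric_tail(self):
        background = {f"b{i}" for i in range(20)}
        dams = {f"b{i}" for i in range(5)}
        pathways = {"P": dams}
        out = ora_enrichment(dams, pathways, background)
        assert out.loc["P", "p_raw"] == pytest.approx(1 / math.comb(20, 5))

    def test_zero_overlap_tail_is_one(self):
        background = {f"b{i}" for i in range(20)}
        out = ora_enrichment(
            {"b0"}, {"P": {f"b{i}" for i in range(10, 15)}}, background
        )
        # P(X >= 0) would be 1; with k=0 the upper tail P(X>=0)=1 only when
        # evaluated at zero -- here k=0 so the reported tail is P(X >= 0) = 1
        assert out.loc["P", "p_raw"] <= 1.0
        out0 = ora_enrichment(set(), {"P": {"b1"}}, background)
        assert out0.loc["P", "p_raw"] == pytest.approx(1.0)

    def test_pathway_disjoint_from_background(self):
        out = ora_enrichment({"b0"}, {"P": {"zzz"}}, {"b0", "b1"})
        assert out.loc["P", "p_raw"] == 1.0

    def test_dam_outside_background_rejected(self):
        with pytest.raises(ValidationError):
            ora_enrichment({"q"}, {"P": {"q"}}, {"b0"})
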