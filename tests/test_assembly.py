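import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from rhizodyn.assembly import (
    UndefinedNullError,
    beta_mntd,
    bnti,
    classify_pair,
    classify_processes,
    filter_for_assembly,
    metabolite_bnti_regression,
    rc_bray,
)
from rhizodyn.data_model import MetaboliteTable, OtuTable, PhyloTree
from rhizodyn.synthetic_data import ScenarioSpec, simulate_communities


def _table(columns: dict, taxa) -> OtuTable:
    counts = pd.DataFrame(columns, index=list(taxa))
    return OtuTable(counts, pd.Series("", index=counts.index))


class TestFilterForAssembly:
    def test_keeps_taxon_present_twice_in_a_group(self):
        table = _table({"a1": [5, 1], "a2": [3, 0], "b1": [0, 0], "b2": [0, 1]}, "xy")
        out = filter_for_assembly(table, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert out.taxon_ids == ["x"]

    def test_removes_single_occurrence_taxon(self):
        table = _table({"a1": [1], "a2": [0], "b1": [0], "b2": [0]}, "z")
        out = filter_for_assembly(table, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert out.taxon_ids == []

    def test_never_removes_ubiquitous_taxon(self):
        table = _table({"a1": [2], "a2": [2], "b1": [2], "b2": [2]}, "w")
        out = filter_for_assembly(table, {"A": ["a1", "a2"], "B": ["b1", "b2"]})
        assert out.taxon_ids == ["w"]


class TestBetaMntd:
    def test_identical_communities_are_zero(self, tree100):
        taxa = tree100.tip_names[:20]
        col = np.arange(1.0, 21.0)
        table = _table({"A": col, "B": col}, taxa)
        d = beta_mntd(table, tree100.patristic(taxa), ("A", "B"))
        assert d == 0.0

    def test_two_singletons_collapse_to_patristic_distance(self):
        tree = PhyloTree.from_newick("((A:1,B:2):0.5,C:3);")
        patristic = tree.patristic(["A", "B", "C"])
        table = _table({"x": [1, 0, 0], "y": [0, 1, 0]}, ["A", "B", "C"])
        d = beta_mntd(table, patristic, ("x", "y"))
        assert d == pytest.approx(patristic["A", "B"])

    def test_linear_in_branch_lengths(self, tree30, drift_dataset):
        from skbio import DistanceMatrix

        otu, _ = drift_dataset
        pair = ("TB_1", "TF_3")
        patristic = tree30.patristic(otu.taxon_ids)
        d1 = beta_mntd(otu, patristic, pair)
        doubled = DistanceMatrix(
            np.asarray(patristic.data) * 2, ids=list(patristic.ids)
        )
        d2 = beta_mntd(otu, doubled, pair)
        assert d2 == pytest.approx(2 * d1)

    def test_matches_picante_reference(self, tree30, drift_dataset, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        otu, _ = drift_dataset
        mine = beta_mntd(otu, tree30.patristic(otu.taxon_ids), ("TB_1", "TB_2"))
        tree30.to_file(tmp_path / "t.nwk")
        otu.counts.T.to_csv(tmp_path / "comm.csv")
        script = f"""
suppressMessages(library(picante))
tr <- read.tree("{tmp_path}/t.nwk")
comm <- as.matrix(read.csv("{tmp_path}/comm.csv", row.names=1, check.names=FALSE))
d <- comdistnt(comm[c("TB_1","TB_2"),], cophenetic(tr), abundance.weighted=TRUE)
cat(sprintf("RESULT %.12f", as.numeric(d)))
"""
        run = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=120
        )
        value = float(run.stdout.split("RESULT")[-1])
        assert mine == pytest.approx(value, rel=1e-9)


class TestBnti:
    def test_deterministic_given_seed(self, tree100):
        spec = ScenarioSpec("drift", n_taxa=100, depth=1000, seed=3)
        otu, md = simulate_communities(spec, tree100)
        pairs = [("TB_1", "TF_1"), ("TB_2", "TS_3")]
        a = bnti(otu, tree100, pairs, n_null=50, seed=11)
        b = bnti(otu, tree100, pairs, n_null=50, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_invariant_to_global_branch_rescaling(self, tree100):
        spec = ScenarioSpec("drift", n_taxa=100, depth=1000, seed=3)
        otu, _ = simulate_communities(spec, tree100)
        scaled = PhyloTree.from_newick(tree100.to_newick())
        for node in scaled.tree.traverse(include_self=False):
            node.length = node.length * 7.0
        pairs = [("TB_1", "TF_1")]
        a = bnti(otu, tree100, pairs, n_null=100, seed=5)
        b = bnti(otu, scaled, pairs, n_null=100, seed=5)
        assert a.bnti[0] == pytest.approx(b.bnti[0], abs=1e-9)
        assert b.beta_mntd_obs[0] == pytest.approx(7 * a.beta_mntd_obs[0])

    def test_identical_membership_null_is_degenerate(self, tree100):
        taxa = tree100.tip_names[:30]
        col = np.arange(1.0, 31.0)
        table = _table({"A": col, "B": 2 * col}, taxa)
        with pytest.raises(UndefinedNullError):
            bnti(table, tree100, [("A", "B")], n_null=20, seed=0)


class TestRcBray:
    def test_values_bounded(self, tree100):
        spec = ScenarioSpec("drift", n_taxa=100, depth=1000, seed=6)
        otu, _ = simulate_communities(spec, tree100)
        frame = rc_bray(otu, n_null=30, seed=1)
        assert frame.rc_bray.between(-1, 1).all()

    def test_deterministic_given_seed(self, tree100):
        spec = ScenarioSpec("drift", n_taxa=100, depth=1000, seed=6)
        otu, _ = simulate_communities(spec, tree100)
        pairs = [("TB_1", "TF_1")]
        a = rc_bray(otu, pairs, n_null=40, seed=2)
        b = rc_bray(otu, pairs, n_null=40, seed=2)
        pd.testing.assert_frame_equal(a, b)


class TestClassification:
    @pytest.mark.parametrize(
        "bnti_value,rc_value,expected",
        [
            (2.5, 0.0, "heterogeneous_selection"),
            (2.5, -0.99, "heterogeneous_selection"),
            (-2.5, 0.99, "homogeneous_selection"),
            (-1.0, 0.97, "dispersal_limitation"),
            (0.5, -0.96, "homogenizing_dispersal"),
            (0.0, 0.0, "undominated"),
            (2.0, 0.0, "undominated"),  # threshold is strict
        ],
    )
    def test_threshold_rules(self, bnti_value, rc_value, expected):
        assert classify_pair(bnti_value, rc_value) == expected

    def test_fractions_sum_to_one(self):
        bnti_frame = pd.DataFrame(
            {
                "sample_a": ["a", "a", "b"],
                "sample_b": ["b", "c", "c"],
                "beta_mntd_obs": [0.1, 0.2, 0.3],
                "bnti": [2.5, -3.0, 0.0],
            }
        )
        rc_frame = pd.DataFrame(
            {
                "sample_a": ["a", "a", "b"],
                "sample_b": ["b", "c", "c"],
                "bray_obs": [0.5, 0.5, 0.5],
                "rc_bray": [0.0, 0.0, 0.99],
            }
        )
        results, fractions = classify_processes(bnti_frame, rc_frame)
        assert fractions.n_pairs == 3
        assert sum(fractions.fractions.values()) == pytest.approx(1.0)
        assert [r.process for r in results] == [
            "heterogeneous_selection",
            "homogeneous_selection",
            "dispersal_limitation",
        ]


class TestMetaboliteRegression:
    def _bnti_frame(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        pairs = [(f"s{i}", f"s{j}") for i in range(5) for j in range(i + 1, 5)]
        return pd.DataFrame(
            {
                "sample_a": [a for a, _ in pairs],
                "sample_b": [b for _, b in pairs],
                "beta_mntd_obs": rng.random(len(pairs)),
                "bnti": rng.normal(size=len(pairs)),
            }
        )

    def test_exact_affine_relation_gives_r2_one(self):
        frame = self._bnti_frame()
        values = np.arange(1.0, 6.0) ** 2
        table = MetaboliteTable(
            pd.DataFrame([values], index=["m"], columns=[f"s{i}" for i in range(5)])
        )
        x = np.abs(
            values[[int(a[1]) for a in frame.sample_a]]
            - values[[int(b[1]) for b in frame.sample_b]]
        )
        frame["bnti"] = 3.0 * x - 1.0
        [fit] = metabolite_bnti_regression(table, frame)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(3.0)

    def test_pair_order_symmetry(self):
        frame = self._bnti_frame(seed=4)
        values = np.linspace(1, 9, 5)
        table = MetaboliteTable(
            pd.DataFrame([values], index=["m"], columns=[f"s{i}" for i in range(5)])
        )
        swapped = frame.rename(
            columns={"sample_a": "sample_b", "sample_b": "sample_a"}
        )
        [a] = metabolite_bnti_regression(table, frame)
        [b] = metabolite_bnti_regression(table, swapped)
        assert a.slope == pytest.approx(b.slope)

    def test_independent_metabolite_rarely_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            frame = self._bnti_frame(seed=seed)
            table = MetaboliteTable(
                pd.DataFrame(
                    [rng.lognormal(0, 1, 5)],
                    index=["m"],
                    columns=[f"s{i}" for i in range(5)],
                )
            )
            [fit] = metabolite_bnti_regression(table, frame)
            hits += fit.significant
        assert hits <= 4  # <= 10% expected; allow binomial slack at 20 seeds

    def test_constant_predictor_skipped(self):
        frame = self._bnti_frame()
        table = MetaboliteTable(
            pd.DataFrame(
                [np.full(5, 3.0)], index=["m"], columns=[f"s{i}" for i in range(5)]
            )
        )
        assert metabolite_bnti_regression(table, frame) == []
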