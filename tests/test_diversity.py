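import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity

from rhizodyn.data_model import (
    DegenerateSampleError,
    OtuTable,
    ParameterError,
    ValidationError,
)
from rhizodyn.diversity import (
    beta_distance,
    chao1,
    gini_simpson,
    pcoa,
    permanova,
)


class TestAlpha:
    def test_chao1_direct_formula(self):
        assert chao1([4, 3, 2, 1, 1]) == pytest.approx(5.5)

    def test_chao1_without_singletons_is_richness(self):
        assert chao1([4, 3, 2, 2]) == 4.0

    def test_chao1_empty_community(self):
        assert chao1([0, 0, 0]) == 0.0

    def test_chao1_rejects_fractional_counts(self):
        with pytest.raises(ValidationError):
            chao1([1.5, 2.0])

    def test_chao1_never_below_observed_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            counts = rng.integers(0, 10, size=20)
            assert chao1(counts) >= (counts > 0).sum()

    @pytest.mark.parametrize(
        "abundances,expected",
        [([1, 1, 1, 1], 0.75), ([5], 0.0), ([1, 3], 0.375)],
    )
    def test_gini_simpson_values(self, abundances, expected):
        assert gini_simpson(abundances) == pytest.approx(expected)

    def test_gini_simpson_rejects_empty(self):
        with pytest.raises(DegenerateSampleError):
            gini_simpson([0, 0])


class TestBetaDistance:
    def test_bray_curtis_direct_formula(self):
        counts = pd.DataFrame({"x": [1.0, 2.0], "y": [2.0, 1.0]}, index=["a", "b"])
        table = OtuTable(counts, pd.Series("", index=counts.index))
        d = beta_distance(table, "bray_curtis")
        assert d["x", "y"] == pytest.approx(1 / 3)

    def test_identical_samples_distance_zero(self, tiny_otu, tiny_tree):
        counts = tiny_otu.counts.copy()
        counts["s2"] = counts["s1"]
        table = OtuTable(counts, tiny_otu.taxonomy)
        for metric, tree in [("bray_curtis", None), ("weighted_unifrac", tiny_tree)]:
            d = beta_distance(table, metric, tree)
            assert d["s1", "s2"] == pytest.approx(0.0)

    def test_disjoint_taxa_bray_is_one(self):
        counts = pd.DataFrame({"x": [3.0, 0.0], "y": [0.0, 7.0]}, index=["a", "b"])
        table = OtuTable(counts, pd.Series("", index=counts.index))
        assert beta_distance(table, "bray_curtis")["x", "y"] == pytest.approx(1.0)

    def test_weighted_unifrac_matches_skbio(self, drift_dataset, tree30):
        otu, _ = drift_dataset
        mine = beta_distance(otu, "weighted_unifrac", tree30)
        oracle = beta_diversity(
            "weighted_unifrac",
            otu.counts.to_numpy().T.astype(int),
            ids=otu.sample_ids,
            taxa=otu.taxon_ids,
            tree=tree30.tree,
            normalized=True,
        )
        np.testing.assert_allclose(
            np.asarray(mine.data), np.asarray(oracle.data), atol=1e-12
        )

    def test_distances_bounded_and_symmetric(self, drift_dataset, tree30):
        otu, _ = drift_dataset
        for metric in ("bray_curtis", "weighted_unifrac"):
            d = np.asarray(beta_distance(otu, metric, tree30).data)
            assert np.allclose(d, d.T)
            assert (d >= 0).all() and (d <= 1).all()
            assert np.allclose(np.diag(d), 0)

    def test_unifrac_without_tree_rejected(self, tiny_otu):
        with pytest.raises(ParameterError):
            beta_distance(tiny_otu, "weighted_unifrac")


class TestPcoa:
    def test_round_trip_recovers_euclidean_configuration(self):
        rng = np.random.default_rng(0)
        points = rng.normal(size=(7, 3))
        d = np.linalg.norm(points[:, None] - points[None, :], axis=2)
        res = pcoa(DistanceMatrix(d, ids=[f"s{i}" for i in range(7)]))
        coords = res.coordinates.to_numpy()
        d2 = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(d2, d, atol=1e-8)

    def test_collinear_points_load_on_one_axis(self):
        d = DistanceMatrix(
            np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float),
            ids=list("abc"),
        )
        res = pcoa(d)
        assert res.variance_explained[0] == pytest.approx(1.0)

    def test_duplicate_sample_gets_identical_coordinates(self):
        base = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        res = pcoa(DistanceMatrix(base, ids=list("abc")))
        np.testing.assert_allclose(
            res.coordinates.loc["b"].to_numpy(), res.coordinates.loc["c"].to_numpy()
        )

    def test_asymmetric_input_rejected(self):
        with pytest.raises((ValidationError, Exception)):
            bad = np.array([[0, 1], [2, 0]], dtype=float)
            pcoa(DistanceMatrix(bad, ids=list("ab")))


def _clustered_distance(gap: float, scale: float = 0.01, seed: int = 0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([np.zeros((3, 2)), np.full((3, 2), gap)])
    pts = pts + rng.normal(scale=scale, size=pts.shape)
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    return DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])


class TestPermanova:
    def test_exhaustive_two_tight_clusters(self):
        d = _clustered_distance(gap=10.0)
        res = permanova(d, ["x"] * 3 + ["y"] * 3, n_perm="exhaustive")
        assert res.p == pytest.approx(0.1)

    def test_seeded_p_reproducible(self):
        d = _clustered_distance(gap=2.0)
        labels = ["x"] * 3 + ["y"] * 3
        a = permanova(d, labels, n_perm=199, seed=7)
        b = permanova(d, labels, n_perm=199, seed=7)
        assert a.p == b.p
        assert a.p >= 1 / 200

    def test_reordering_invariance(self):
        d = _clustered_distance(gap=3.0, seed=2)
        labels = ["x", "x", "x", "y", "y", "y"]
        res = permanova(d, labels, n_perm="exhaustive")
        order = [3, 4, 5, 0, 1, 2]
        d2 = DistanceMatrix(
            np.asarray(d.data)[np.ix_(order, order)],
            ids=[d.ids[i] for i in order],
        )
        res2 = permanova(d2, [labels[i] for i in order], n_perm="exhaustive")
        assert res.p == pytest.approx(res2.p)
        assert res.pseudo_f == pytest.approx(res2.pseudo_f)

    def test_small_group_rejected(self):
        d = _clustered_distance(gap=1.0)
        with pytest.raises(ParameterError):
            permanova(d, ["x"] * 5 + ["y"], n_perm=9)

    def test_zero_variance_distances_rejected(self):
        d = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        with pytest.raises(DegenerateSampleError):
            permanova(d, ["x", "x", "y", "y"], n_perm=9)
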