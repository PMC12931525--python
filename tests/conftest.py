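import numpy as np
import pandas as pd
import pytest

from rhizodyn.data_model import MetaboliteTable, OtuTable, PhyloTree
from rhizodyn.synthetic_data import (
    ScenarioSpec,
    generate_fixture_bundle,
    simulate_communities,
    simulate_tree,
)


@pytest.fixture(scope="session")
def tree100():
    return simulate_tree(100, 1)


@pytest.fixture(scope="session")
def tree30():
    return simulate_tree(30, 2)


@pytest.fixture(scope="session")
def drift_dataset(tree30):
    spec = ScenarioSpec(scenario="drift", n_taxa=30, depth=500, seed=4)
    return simulate_communities(spec, tree30)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return generate_fixture_bundle(out, seed=1)


@pytest.fixture
def tiny_otu():
    counts = pd.DataFrame(
        {"s1": [4.0, 0.0, 1.0], "s2": [0.0, 2.0, 3.0]},
        index=["A", "B", "C"],
    )
    taxonomy = pd.Series(
        {
            "A": "d__Bacteria;p__Proteobacteria",
            "B": "d__Bacteria;p__Proteobacteria",
            "C": "d__Bacteria;p__Acidobacteriota",
        }
    )
    return OtuTable(counts, taxonomy)


@pytest.fixture
def tiny_tree():
    return PhyloTree.from_newick("((A:1,B:2):1,C:3);")


@pytest.fixture
def radiation_clade(tree100):
    """The tips of the grafted recent radiation: the tree's tightest
    patristic neighborhood."""
    tips = tree100.tip_names
    dist = np.asarray(tree100.patristic(tips).data)
    nearest = np.sort(dist, axis=1)[:, 1:12]
    focal = int(np.argmin(nearest.mean(axis=1)))
    order = np.argsort(dist[focal])
    return [tips[i] for i in order[:12]]
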