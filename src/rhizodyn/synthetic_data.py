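"""Synthetic fixture generators for every downstream pipeline stage.

The generators emulate the statistical structure the analyses assume, not the
chemistry or sequencing that produced the real data:

- :func:`simulate_tree` draws a pure-birth phylogeny for null-model tests.
- :func:`simulate_communities` draws OTU count tables under four assembly
  regimes.  Habitat filtering acts on a Brownian-motion trait evolved on the
  tree: the expected abundance of taxon *i* in sample *s* is proportional to
  ``exp(-(trait_i - E_s)^2 / (2 sigma^2))`` where ``E_s`` is the stage
  environment and ``sigma`` the filter width.  Heterogeneous selection
  separates stage-group environments by many filter widths; homogeneous
  selection shares one environment; dispersal limitation gives every sample
  an independent random species pool (no trait filter); drift samples a
  shared metacommunity multinomially at low depth.
- :func:`simulate_metabolome` draws peak areas whose per-stage log2 means
  follow short temporal archetypes, with optional planted differential
  metabolites between two stages.
- :func:`generate_fixture_bundle` writes one coherent four-file dataset
  combining selection-structured communities, planted modular co-occurrence
  blocks (Gaussian-copula log-abundance correlations) and monotone
  metabolite-OTU couplings.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from rhizodyn.data_model import (
    Dataset,
    MetaboliteTable,
    OtuTable,
    ParameterError,
    PhyloTree,
    SampleMetadata,
    STAGES,
)

__all__ = [
    "SCENARIOS",
    "ARCHETYPES",
    "ScenarioSpec",
    "MetabolomeSpec",
    "PlantedDam",
    "simulate_tree",
    "simulate_communities",
    "simulate_metabolome",
    "generate_fixture_bundle",
]

SCENARIOS: tuple[str, ...] = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "drift",
)

#: Five temporal archetypes on a log2 scale over the five ordered stages,
#: mirroring the qualitative shapes recovered in short time-series profile
#: clustering of root metabolites: a full-bloom peak that rebounds after
#: senescence, a dip that recovers, an early rise that plateaus then falls,
#: a continuous linear increase, and a W shape.
ARCHETYPES: dict[str, tuple[float, ...]] = {
    "peak_rebound": (0, 1, 2, 0, 2),
    "dip_recover": (0, -1, -1, 0, 0),
    "rise_plateau_fall": (0, 1, 1, 0, -1),
    "linear_increase": (0, 1, 2, 3, 4),
    "w_shape": (0, 1, 0, 0, 1),
    "flat": (0, 0, 0, 0, 0),
}


@dataclass
class ScenarioSpec:
    """Design of one simulated community dataset.

    filter_width is the trait-filter sigma; the default 0.3 (in units of the
    tip-trait standard deviation) combined with stage environments at +/-1
    gives a between-group separation of about 6.7 sigma in the heterogeneous
    regime, comfortably above the 3-sigma floor needed for |betaNTI| > 2 at
    100 taxa.
    """

    scenario: str
    n_taxa: int = 100
    n_stages: int = 5
    n_replicates: int = 3
    depth: int = 20000
    filter_width: float = 0.3
    env_spread: float = 1.0  # stage environments at +/- env_spread
    pool_fraction: float = 0.4  # dispersal limitation: taxa seen per sample
    niche_clade_size: int = 14  # homogeneous selection: focal-clade pool size
    jitter_sd: float | None = None  # lognormal overdispersion (per-scenario)
    weight_floor: float = 1e-5  # relative floor for sporadic rare members
    exclusion_fraction: float | None = None  # per-sample pool dropout
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ParameterError(f"unknown scenario {self.scenario!r}")
        if self.n_taxa < 20:
            raise ParameterError("n_taxa must be >= 20 for meaningful nulls")
        if self.depth <= 0:
            raise ParameterError("depth must be positive")
        if self.filter_width <= 0:
            raise ParameterError("filter width sigma must be positive")
        # homogeneous selection needs high turnover among close relatives for
        # the betaMNTD null to have leverage; the other regimes keep mild noise
        if self.jitter_sd is None:
            self.jitter_sd = 0.3 if self.scenario == "homogeneous_selection" else 0.5
        if self.exclusion_fraction is None:
            self.exclusion_fraction = (
                0.5 if self.scenario == "homogeneous_selection" else 0.05
            )


@dataclass
class PlantedDam:
    """A differential metabolite planted between two stages."""

    metabolite_id: str
    stage_a: str
    stage_b: str
    log2_effect: float


@dataclass
class MetabolomeSpec:
    n_metabolites: int = 60
    profile_shapes: Sequence[Sequence[float]] = field(
        default_factory=lambda: [
            ARCHETYPES["peak_rebound"],
            ARCHETYPES["dip_recover"],
            ARCHETYPES["rise_plateau_fall"],
            ARCHETYPES["linear_increase"],
            ARCHETYPES["w_shape"],
        ]
    )
    noise_cv: float = 0.2
    amplitude: float = 1.0  # log2 units per archetype step
    planted_dams: Sequence[PlantedDam] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv <= 0:
            raise ParameterError("noise_cv must be positive")


# ---------------------------------------------------------------------------
# Tree simulation


def simulate_tree(
    n_taxa: int,
    seed: int,
    radiation_size: int = 12,
    radiation_height: float = 0.08,
) -> PhyloTree:
    """Two-rate pure-birth tree with ``n_taxa`` tips, height scaled to 1.

    One clade of ``radiation_size`` tips is a recent radiation: a fast
    pure-birth subtree of relative height ``radiation_height`` replacing a
    random tip of the base Yule tree.  Real 16S phylogenies always carry such
    dense genus-level radiations, and the tight neighborhood they provide is
    what phylogenetically conserved habitat filtering acts on.  Trees with
    fewer than ~30 tips are plain Yule.
    """
    if n_taxa < 2:
        raise ParameterError("n_taxa must be >= 2")
    rng = random.Random(seed)
    graft = n_taxa >= 30 and radiation_size >= 2
    n_base = n_taxa - radiation_size + 1 if graft else n_taxa
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_base,
        rng=rng,
    )
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    height = max(depths)
    if height == 0:  # n=2: the process stops at the very first split
        for leaf in tree.leaf_node_iter():
            leaf.edge.length = 1.0
        height = 1.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / height
    if graft:
        sub = dendropy.model.birthdeath.birth_death_tree(
            birth_rate=1.0,
            death_rate=0.0,
            num_extant_tips=radiation_size,
            rng=rng,
        )
        sub_height = max(
            sub.calc_node_root_distances(return_leaf_distances_only=True)
        )
        for edge in sub.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length / sub_height * radiation_height
        host = rng.choice(tree.leaf_nodes())
        stem = max(host.edge.length - radiation_height, host.edge.length * 0.1)
        sub_root = sub.seed_node
        sub_root.edge.length = stem
        parent = host.parent_node
        parent.remove_child(host)
        parent.add_child(sub_root)
        tree.update_taxon_namespace()
    width = len(str(n_taxa))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        if leaf.taxon is None:
            leaf.taxon = tree.taxon_namespace.new_taxon(label="tmp")
        leaf.taxon.label = f"OTU{i + 1:0{width}d}"  # no underscores: newick-safe
    tree.seed_node.edge.length = None  # no root edge on a rooted tree
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    height = max(depths)
    # the birth process stops at the n-th speciation, leaving the youngest
    # sister pair with zero-length tips; let it run a little longer so every
    # branch length is strictly positive (ultrametricity is preserved)
    tail = 0.01 * height
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += tail
    height += tail
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / height
    newick = tree.as_string(schema="newick", suppress_rooting=True)
    return PhyloTree.from_newick(newick)


def _brownian_traits(tree: PhyloTree, rng: np.random.Generator) -> pd.Series:
    """Brownian-motion tip traits (variance 1 per unit branch length),
    z-scored across tips so stage environments have a fixed scale."""
    values: dict[int, float] = {id(tree.tree): 0.0}
    for node in tree.tree.preorder(include_self=False):
        parent_value = values[id(node.parent)]
        step = rng.normal(0.0, math.sqrt(max(node.length, 1e-12)))
        values[id(node)] = parent_value + step
    tips = list(tree.tree.tips())
    traits = np.array([values[id(t)] for t in tips])
    traits = (traits - traits.mean()) / traits.std()
    return pd.Series(traits, index=[t.name for t in tips])


def _clade_taxonomy(tree: PhyloTree) -> pd.Series:
    """Toy Silva-style lineages: phylum = index of the root child clade."""
    labels = {}
    for i, child in enumerate(tree.tree.children):
        for tip in child.tips(include_self=True):
            labels[tip.name] = f"d__Bacteria;p__Clade{i + 1}"
    return pd.Series(labels)


# ---------------------------------------------------------------------------
# Community simulation


def _design_metadata(n_stages: int, n_replicates: int) -> SampleMetadata:
    stages = list(STAGES[:n_stages])
    if n_stages > len(STAGES):
        stages += [f"S{i}" for i in range(len(STAGES), n_stages)]
    rows = []
    for stage in stages:
        for rep in range(1, n_replicates + 1):
            rows.append((f"{stage}_{rep}", stage, rep))
    frame = pd.DataFrame(rows, columns=["sample_id", "stage", "replicate"])
    frame = frame.set_index("sample_id")
    return SampleMetadata(frame)


def _overdisperse(
    w: np.ndarray, spec: ScenarioSpec, rng: np.random.Generator
) -> np.ndarray:
    """Abundance floor, lognormal noise and random per-sample pool dropout.

    The floor lets taxa far outside the trait filter appear sporadically; the
    jitter decorrelates replicate abundances; the dropout removes a small
    random taxon subset from each sample's pool, so no two samples ever share
    an identical membership (identical membership makes the taxon-shuffling
    betaMNTD null degenerate).  All three leave the filter-driven dominant
    structure intact.
    """
    w = w + spec.weight_floor * w.max()
    if spec.jitter_sd > 0:
        w = w * rng.lognormal(0.0, spec.jitter_sd, size=w.shape)
    n_taxa, n_samples = w.shape
    n_drop = int(round(spec.exclusion_fraction * n_taxa))
    for s in range(n_samples):
        w[rng.choice(n_taxa, size=n_drop, replace=False), s] = 0.0
    return w


def _expected_weights(
    spec: ScenarioSpec,
    traits: np.ndarray,
    stages: Sequence[str],
    stage_of: Sequence[str],
    rng: np.random.Generator,
    dist: np.ndarray | None = None,
) -> np.ndarray:
    """Per-sample expected abundance weights (taxa x samples), unnormalized."""
    n_taxa = traits.size
    n_samples = len(stage_of)
    sigma = spec.filter_width
    if spec.scenario == "heterogeneous_selection":
        split = math.ceil(len(stages) / 2)
        group_b = set(stages[split:])
        env = {
            s: (spec.env_spread if s in group_b else -spec.env_spread)
            for s in stages
        }
        e = np.array([env[s] for s in stage_of])
        w = np.exp(-((traits[:, None] - e[None, :]) ** 2) / (2 * sigma**2))
        w = _overdisperse(w, spec, rng)
    elif spec.scenario == "homogeneous_selection":
        # The shared niche trait is perfectly phylogenetically conserved:
        # patristic proximity to a focal lineage.  The focal lineage anchors
        # the tightest k-neighborhood of the tree, so every sample draws a
        # (heavily subsampled) community of close relatives, which is what
        # gives the taxon-shuffling betaMNTD null its leverage.
        if dist is None:
            raise ParameterError("homogeneous selection needs patristic distances")
        k = min(spec.niche_clade_size, n_taxa - 1)
        nearest = np.sort(dist, axis=1)[:, 1:k]
        focal = int(np.argmin(nearest.mean(axis=1)))
        radius = np.sort(dist[focal])[k - 1]
        sigma_d = max(radius / 2.0, 1e-3)
        w = np.exp(-(dist[focal][:, None] ** 2) / (2 * sigma_d**2))
        w = np.repeat(w, n_samples, axis=1)
        w = _overdisperse(w, spec, rng)
    elif spec.scenario == "dispersal_limitation":
        w = np.zeros((n_taxa, n_samples))
        pool_size = max(2, int(round(spec.pool_fraction * n_taxa)))
        for s in range(n_samples):
            pool = rng.choice(n_taxa, size=pool_size, replace=False)
            w[pool, s] = rng.lognormal(0.0, 1.0, size=pool_size)
    else:  # drift
        meta = rng.lognormal(0.0, 1.0, size=n_taxa)
        w = np.repeat(meta[:, None], n_samples, axis=1)
    return w + 1e-12


def simulate_communities(
    spec: ScenarioSpec, tree: PhyloTree
) -> tuple[OtuTable, SampleMetadata]:
    """Multinomial OTU counts under the spec's assembly regime."""
    tips = tree.tip_names
    if len(tips) < spec.n_taxa:
        raise ParameterError(
            f"tree has {len(tips)} tips but spec needs {spec.n_taxa}"
        )
    taxa = tips[: spec.n_taxa]
    rng = np.random.default_rng(spec.seed)
    traits = _brownian_traits(tree, rng).loc[taxa].to_numpy()
    metadata = _design_metadata(spec.n_stages, spec.n_replicates)
    stages = list(dict.fromkeys(metadata.frame["stage"]))
    stage_of = [metadata.stage_of(s) for s in metadata.sample_ids]
    dist = None
    if spec.scenario == "homogeneous_selection":
        dist = np.asarray(tree.patristic(taxa).data)
    weights = _expected_weights(spec, traits, stages, stage_of, rng, dist=dist)
    counts = np.empty_like(weights)
    for s in range(weights.shape[1]):
        p = weights[:, s] / weights[:, s].sum()
        counts[:, s] = rng.multinomial(spec.depth, p)
    taxonomy = _clade_taxonomy(tree).reindex(taxa)
    frame = pd.DataFrame(counts, index=taxa, columns=metadata.sample_ids)
    return OtuTable(frame, taxonomy), metadata


# ---------------------------------------------------------------------------
# Metabolome simulation


_CLASSES = ("terpenoid", "flavonoid", "phenolic_acid", "ester", "alkaloid")


def simulate_metabolome(
    spec: MetabolomeSpec, metadata: SampleMetadata
) -> MetaboliteTable:
    """Peak areas with archetype-shaped stage means and lognormal noise.

    Stage means follow ``base * 2^(amplitude * archetype[stage])``; noise is
    multiplicative lognormal with coefficient of variation ``noise_cv``;
    planted differential metabolites additionally multiply their stage_b
    samples by ``2^log2_effect``.
    """
    stages = list(dict.fromkeys(metadata.frame["stage"]))
    for shape in spec.profile_shapes:
        if len(shape) != len(stages):
            raise ParameterError(
                f"archetype length {len(shape)} != {len(stages)} stages"
            )
    rng = np.random.default_rng(spec.seed)
    sample_ids = metadata.sample_ids
    stage_of = [metadata.stage_of(s) for s in sample_ids]
    stage_idx = {s: i for i, s in enumerate(stages)}
    ids = [f"MET_{i + 1:04d}" for i in range(spec.n_metabolites)]
    planted_ids = {d.metabolite_id for d in spec.planted_dams}
    bad = planted_ids - set(ids)
    if bad:
        raise ParameterError(f"planted DAM id(s) not in table: {sorted(bad)}")

    sigma_ln = math.sqrt(math.log(1.0 + spec.noise_cv**2))
    values = np.empty((spec.n_metabolites, len(sample_ids)))
    shapes = [tuple(s) for s in spec.profile_shapes]
    for mi, mid in enumerate(ids):
        base = rng.lognormal(math.log(1e6), 0.5)
        if mid in planted_ids:
            shape = ARCHETYPES["flat"][: len(stages)]
        else:
            shape = shapes[mi % len(shapes)]
        log2_mean = np.array(
            [spec.amplitude * shape[stage_idx[s]] for s in stage_of]
        )
        mean = base * np.power(2.0, log2_mean)
        noise = rng.lognormal(-(sigma_ln**2) / 2.0, sigma_ln, size=len(sample_ids))
        values[mi] = mean * noise
    for dam in spec.planted_dams:
        mi = ids.index(dam.metabolite_id)
        mask = np.array([s == dam.stage_b for s in stage_of])
        values[mi, mask] *= 2.0**dam.log2_effect

    frame = pd.DataFrame(values, index=ids, columns=sample_ids)
    class_label = pd.Series(
        [_CLASSES[i % len(_CLASSES)] for i in range(len(ids))], index=ids
    )
    platform = pd.Series(
        ["LC" if i % 2 == 0 else "GC" for i in range(len(ids))], index=ids
    )
    return MetaboliteTable(frame, class_label, platform)


# ---------------------------------------------------------------------------
# Fixture bundle


@dataclass
class FixtureTruth:
    """Planted ground truth of a fixture bundle, for recovery checks."""

    modules: dict[str, list[str]]  # module name -> OTU ids
    coupled_pairs: list[tuple[str, str]]  # (metabolite_id, taxon_id)
    planted_dams: list[PlantedDam]


def generate_fixture_bundle(
    out_dir: str | Path,
    seed: int,
    n_selection_taxa: int = 70,
    n_modules: int = 3,
    module_size: int = 8,
    n_coupled: int = 6,
    module_rho: float = 0.8,
    module_log_sd: float = 1.0,
    depth: int = 50000,
    n_metabolites: int = 60,
    noise_cv: float = 0.2,
) -> tuple[Dataset, FixtureTruth, dict[str, Path]]:
    """Write one coherent four-file dataset with planted structure.

    The OTU table combines three taxon blocks: selection-structured taxa
    (heterogeneous-selection trait filter), modular taxa whose log expected
    abundances follow a Gaussian copula with within-module correlation
    ``module_rho`` and zero between-module correlation, and coupled taxa
    whose expected abundance is proportional to a designated metabolite's
    per-sample abundance (a monotone link).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    n_module_taxa = n_modules * module_size
    n_taxa = n_selection_taxa + n_module_taxa + n_coupled
    tree = simulate_tree(n_taxa, seed)
    taxa = tree.tip_names
    sel_taxa = taxa[:n_selection_taxa]
    mod_taxa = taxa[n_selection_taxa : n_selection_taxa + n_module_taxa]
    cpl_taxa = taxa[n_selection_taxa + n_module_taxa :]

    metadata = _design_metadata(n_stages=5, n_replicates=3)
    sample_ids = metadata.sample_ids
    n_samples = len(sample_ids)
    stage_of = [metadata.stage_of(s) for s in sample_ids]
    stages = list(dict.fromkeys(metadata.frame["stage"]))

    # metabolome first: coupled OTUs mirror metabolite values
    planted = [
        PlantedDam(f"MET_{i + 1:04d}", "TB", "TFB", 2.0 if i % 2 == 0 else -2.0)
        for i in range(4)
    ]
    met_spec = MetabolomeSpec(
        n_metabolites=n_metabolites,
        noise_cv=noise_cv,
        planted_dams=planted,
        seed=seed,
    )
    metabolites = simulate_metabolome(met_spec, metadata)
    coupled_mets = [
        m
        for m in metabolites.metabolite_ids
        if m not in {d.metabolite_id for d in planted}
    ][:n_coupled]

    # selection block: heterogeneous trait filter
    traits = _brownian_traits(tree, rng).loc[sel_taxa].to_numpy()
    spec = ScenarioSpec(scenario="heterogeneous_selection", n_taxa=n_taxa, seed=seed)
    sel_w = _expected_weights(
        ScenarioSpec(
            scenario="heterogeneous_selection", n_taxa=max(20, n_selection_taxa),
            seed=seed,
        ),
        traits,
        stages,
        stage_of,
        rng,
    )
    sel_w = sel_w / sel_w.sum(axis=0, keepdims=True)

    # modular block: Gaussian copula of log expected abundance
    modules: dict[str, list[str]] = {}
    mod_w = np.empty((n_module_taxa, n_samples))
    for m in range(n_modules):
        members = mod_taxa[m * module_size : (m + 1) * module_size]
        modules[f"module_{m + 1}"] = list(members)
        # exact-variance factor and orthogonalized per-taxon noise, so the
        # realized latent correlation concentrates at the planted module_rho
        # instead of fluctuating with the factor's sample variance
        factor = rng.normal(size=n_samples)
        factor = (factor - factor.mean()) / factor.std()
        latent = np.empty((module_size, n_samples))
        for i in range(module_size):
            eps = rng.normal(size=n_samples)
            eps = eps - eps.mean()
            eps = eps - (eps @ factor) / (factor @ factor) * factor
            eps = eps / eps.std()
            latent[i] = math.sqrt(module_rho) * factor + math.sqrt(
                1 - module_rho
            ) * eps
        mod_w[m * module_size : (m + 1) * module_size] = np.exp(
            module_log_sd * latent
        )
    # coupled block: expected abundance proportional to metabolite abundance
    cpl_w = metabolites.abundance.loc[coupled_mets, sample_ids].to_numpy().copy()

    # Combine blocks.  Only the selection block is normalized per sample;
    # the modular and coupled blocks get global scales (average per-sample
    # mass 0.15 and 0.10).  A per-sample normalization of those blocks would
    # put the planted common factor into the compositional denominator and
    # cancel the very correlations the fixture plants; with the stable
    # selection block dominating the denominator, closure distortion of the
    # planted Spearman structure stays negligible.
    sel_block = 0.75 * sel_w  # already column-normalized above
    mod_block = mod_w * (0.15 * n_samples / mod_w.sum())
    cpl_block = (cpl_w / cpl_w.mean(axis=1, keepdims=True)) * (0.10 / n_coupled)
    weights = np.vstack([sel_block, mod_block, cpl_block])
    counts = np.empty_like(weights)
    for s in range(n_samples):
        p = weights[:, s] / weights[:, s].sum()
        counts[:, s] = rng.multinomial(depth, p)
    order = sel_taxa + mod_taxa + cpl_taxa
    taxonomy = _clade_taxonomy(tree).reindex(order)
    otu = OtuTable(pd.DataFrame(counts, index=order, columns=sample_ids), taxonomy)

    paths = {
        "otu": out_dir / "otu_table.tsv",
        "tree": out_dir / "tree.nwk",
        "metabolites": out_dir / "metabolites.tsv",
        "metadata": out_dir / "metadata.tsv",
        "truth": out_dir / "fixture_truth.json",
    }
    otu.to_tsv(paths["otu"])
    tree.to_file(paths["tree"])
    metabolites.to_tsv(paths["metabolites"])
    metadata.to_tsv(paths["metadata"])
    truth = FixtureTruth(
        modules=modules,
        coupled_pairs=list(zip(coupled_mets, cpl_taxa)),
        planted_dams=planted,
    )
    paths["truth"].write_text(
        json.dumps(
            {
                "modules": truth.modules,
                "coupled_pairs": truth.coupled_pairs,
                "planted_dams": [vars(d) for d in truth.planted_dams],
            },
            indent=2,
        )
    )
    dataset = Dataset(otu=otu, tree=tree, metabolites=metabolites, metadata=metadata)
    return dataset, truth, paths
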