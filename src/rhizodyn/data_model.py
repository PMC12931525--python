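"""Typed containers, readers/writers and validation for all pipeline tables.

File orientation is taxa/metabolites-as-rows, samples-as-columns; the same
orientation is kept in memory (``pandas.DataFrame`` with feature ids as the
index and sample ids as the columns).  All loaders validate against the
invariants of the corresponding container and raise subclasses of
:class:`ValidationError` with the offending id in the message.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import skbio
from skbio import DistanceMatrix

__all__ = [
    "STAGES",
    "PHASES",
    "PHASE_STAGES",
    "RANKS",
    "ValidationError",
    "AlignmentError",
    "CoverageError",
    "DegenerateSampleError",
    "ParameterError",
    "SampleMetadata",
    "OtuTable",
    "MetaboliteTable",
    "PhyloTree",
    "DistanceMatrix",
    "Dataset",
    "load_dataset",
    "total_sum_scaling",
    "aggregate_by_rank",
]

#: Ordered floral stages: bud, initial bloom, full bloom, senescence, fading.
STAGES: tuple[str, ...] = ("TB", "TIB", "TFB", "TS", "TF")

#: Phase groups; the full-bloom stage TFB belongs to both phases.
PHASE_STAGES: dict[str, tuple[str, ...]] = {
    "FS": ("TB", "TIB", "TFB"),
    "SS": ("TFB", "TS", "TF"),
}
PHASES: tuple[str, ...] = tuple(PHASE_STAGES)

#: Silva-style lineage ranks, in file order.
RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")


class ValidationError(ValueError):
    """A container invariant is violated."""


class AlignmentError(ValidationError):
    """Sample ids are inconsistent between tables."""


class CoverageError(ValidationError):
    """The phylogeny does not cover every analyzed taxon."""


class DegenerateSampleError(ValidationError):
    """A sample carries no signal (e.g. an all-zero column)."""


class ParameterError(ValueError):
    """An operation received an invalid parameter."""


# ---------------------------------------------------------------------------
# Sample metadata


@dataclass
class SampleMetadata:
    """Per-sample design information: stage, derived phase(s) and replicate."""

    frame: pd.DataFrame  # index: sample_id; columns: stage, replicate

    def __post_init__(self) -> None:
        required = {"stage", "replicate"}
        if not required.issubset(self.frame.columns):
            raise ValidationError(
                f"metadata must have columns {sorted(required)}"
            )
        if self.frame.index.duplicated().any():
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        bad = set(self.frame["stage"]) - set(STAGES)
        if bad:
            raise ValidationError(f"unknown stage(s) {sorted(bad)}")
        reps = self.frame["replicate"]
        if (reps <= 0).any() or not np.issubdtype(reps.dtype, np.integer):
            raise ValidationError("replicate must be a positive integer")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def stage_of(self, sample_id: str) -> str:
        return str(self.frame.loc[sample_id, "stage"])

    def samples_in_stage(self, stage: str) -> list[str]:
        if stage not in STAGES:
            raise ParameterError(f"unknown stage {stage!r}")
        return list(self.frame.index[self.frame["stage"] == stage])

    def samples_in_phase(self, phase: str) -> list[str]:
        """Samples of a phase; TFB samples are members of both FS and SS."""
        if phase not in PHASE_STAGES:
            raise ParameterError(f"unknown phase {phase!r}")
        keep = self.frame["stage"].isin(PHASE_STAGES[phase])
        return list(self.frame.index[keep])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleMetadata":
        frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        if "sample_id" not in frame.columns:
            raise ValidationError("metadata TSV must have a 'sample_id' column")
        frame = frame.set_index("sample_id")
        frame["replicate"] = frame["replicate"].astype(int)
        return cls(frame)

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.reset_index().rename(columns={"index": "sample_id"})
        if "sample_id" not in out.columns:
            out = out.rename(columns={out.columns[0]: "sample_id"})
        out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# OTU table


@dataclass
class OtuTable:
    """Taxa x samples abundance matrix with per-taxon lineage strings."""

    counts: pd.DataFrame  # index: taxon_id; columns: sample_id
    taxonomy: pd.Series  # index: taxon_id; semicolon-delimited lineage
    is_relative: bool = False

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate taxon_id {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative abundance in OTU table")
        self.counts.index.name = "taxon_id"
        self.counts.columns.name = None
        self.taxonomy = self.taxonomy.reindex(self.counts.index).fillna("")
        if self.is_relative:
            sums = self.counts.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValidationError(
                    "is_relative set but sample sums differ from 1"
                )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OtuTable":
        missing = [s for s in sample_ids if s not in self.counts.columns]
        if missing:
            raise AlignmentError(f"sample {missing[0]!r} absent from OTU table")
        return OtuTable(
            self.counts.loc[:, list(sample_ids)].copy(),
            self.taxonomy.copy(),
            self.is_relative,
        )

    def subset_taxa(self, taxon_ids: Sequence[str]) -> "OtuTable":
        # a taxon subset no longer sums to 1 per sample, so the flag drops
        return OtuTable(
            self.counts.loc[list(taxon_ids)].copy(),
            self.taxonomy.loc[list(taxon_ids)].copy(),
            is_relative=False,
        )

    @classmethod
    def from_tsv(cls, path: str | Path, is_relative: bool = False) -> "OtuTable":
        frame = pd.read_csv(path, sep="\t", dtype={"taxon_id": str})
        if frame.columns[0] != "taxon_id" or frame.columns[-1] != "taxonomy":
            raise ValidationError(
                "OTU TSV must start with 'taxon_id' and end with 'taxonomy'"
            )
        frame = frame.set_index("taxon_id")
        taxonomy = frame.pop("taxonomy").astype(str)
        return cls(frame.astype(float), taxonomy, is_relative)

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out["taxonomy"] = self.taxonomy
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Metabolite table


@dataclass
class MetaboliteTable:
    """Metabolites x samples peak-area matrix with class and platform labels."""

    abundance: pd.DataFrame  # index: metabolite_id; columns: sample_id
    class_label: pd.Series = None  # type: ignore[assignment]
    platform: pd.Series = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.abundance.index.duplicated().any():
            dup = self.abundance.index[self.abundance.index.duplicated()][0]
            raise ValidationError(f"duplicate metabolite_id {dup!r}")
        if (self.abundance.to_numpy() < 0).any():
            raise ValidationError("negative abundance in metabolite table")
        self.abundance.index.name = "metabolite_id"
        self.abundance.columns.name = None
        if self.class_label is None:
            self.class_label = pd.Series("unknown", index=self.abundance.index)
        if self.platform is None:
            self.platform = pd.Series("LC", index=self.abundance.index)
        self.class_label = self.class_label.reindex(self.abundance.index)
        self.platform = self.platform.reindex(self.abundance.index)
        bad = set(self.platform.dropna()) - {"LC", "GC"}
        if bad:
            raise ValidationError(f"unknown platform(s) {sorted(bad)}")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "MetaboliteTable":
        missing = [s for s in sample_ids if s not in self.abundance.columns]
        if missing:
            raise AlignmentError(
                f"sample {missing[0]!r} absent from metabolite table"
            )
        return MetaboliteTable(
            self.abundance.loc[:, list(sample_ids)].copy(),
            self.class_label.copy(),
            self.platform.copy(),
        )

    def subset_metabolites(self, ids: Sequence[str]) -> "MetaboliteTable":
        return MetaboliteTable(
            self.abundance.loc[list(ids)].copy(),
            self.class_label.loc[list(ids)].copy(),
            self.platform.loc[list(ids)].copy(),
        )

    def min_positive(self) -> float:
        values = self.abundance.to_numpy()
        positive = values[values > 0]
        if positive.size == 0:
            raise DegenerateSampleError("metabolite table has no positive entry")
        return float(positive.min())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MetaboliteTable":
        frame = pd.read_csv(path, sep="\t", dtype={"metabolite_id": str})
        for col in ("metabolite_id", "class", "platform"):
            if col not in frame.columns:
                raise ValidationError(f"metabolite TSV must have column {col!r}")
        frame = frame.set_index("metabolite_id")
        class_label = frame.pop("class").astype(str)
        platform = frame.pop("platform").astype(str)
        return cls(frame.astype(float), class_label, platform)

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame(
            {"class": self.class_label, "platform": self.platform}
        )
        out = pd.concat([out, self.abundance], axis=1)
        out.index.name = "metabolite_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Phylogenetic tree


@dataclass
class PhyloTree:
    """Rooted phylogeny with nonnegative branch lengths, wrapping skbio."""

    tree: skbio.TreeNode

    def __post_init__(self) -> None:
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
            if node.length < 0:
                raise ValidationError(
                    f"negative branch length at node {node.name!r}"
                )

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def require_tips(self, taxon_ids: Iterable[str]) -> None:
        tips = set(self.tip_names)
        for taxon in taxon_ids:
            if taxon not in tips:
                raise CoverageError(f"tree lacks tip {taxon!r}")

    def patristic(self, taxon_ids: Sequence[str] | None = None) -> DistanceMatrix:
        """Tip-to-tip (patristic) distance matrix, optionally reordered."""
        dm = self.tree.tip_tip_distances()
        if taxon_ids is not None:
            self.require_tips(taxon_ids)
            dm = dm.filter(list(taxon_ids))
        return dm

    def shear(self, taxon_ids: Sequence[str]) -> "PhyloTree":
        self.require_tips(taxon_ids)
        return PhyloTree(self.tree.shear(list(taxon_ids)))

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        return cls(skbio.TreeNode.read(io.StringIO(newick)))

    @classmethod
    def from_file(cls, path: str | Path) -> "PhyloTree":
        return cls(skbio.TreeNode.read(str(path)))

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree.write(buf)
        return buf.getvalue()

    def to_file(self, path: str | Path) -> None:
        self.tree.write(str(path))


# ---------------------------------------------------------------------------
# Dataset


@dataclass
class Dataset:
    """Aligned bundle of all four inputs."""

    otu: OtuTable
    tree: PhyloTree
    metabolites: MetaboliteTable
    metadata: SampleMetadata


def load_dataset(
    otu_path: str | Path,
    tree_path: str | Path,
    metabolite_path: str | Path,
    metadata_path: str | Path,
) -> Dataset:
    """Load and align the four standard input files.

    Sample ids are aligned to the metadata order across all tables; the tree
    must cover every OTU.  Raises :class:`AlignmentError` naming the first
    missing sample and :class:`CoverageError` naming the first missing tip.
    """
    metadata = SampleMetadata.from_tsv(metadata_path)
    otu = OtuTable.from_tsv(otu_path)
    metabolites = MetaboliteTable.from_tsv(metabolite_path)
    tree = PhyloTree.from_file(tree_path)

    order = metadata.sample_ids
    otu = otu.subset_samples(order)
    metabolites = metabolites.subset_samples(order)
    tree.require_tips(otu.taxon_ids)
    return Dataset(otu=otu, tree=tree, metabolites=metabolites, metadata=metadata)


# ---------------------------------------------------------------------------
# Table operations


def total_sum_scaling(table: OtuTable) -> OtuTable:
    """Convert counts to per-sample relative abundances (columns sum to 1)."""
    sums = table.counts.sum(axis=0)
    zero = sums.index[sums == 0]
    if len(zero):
        raise DegenerateSampleError(f"sample {zero[0]!r} has all-zero counts")
    rel = table.counts.div(sums, axis=1)
    return OtuTable(rel, table.taxonomy.copy(), is_relative=True)


def _rank_label(lineage: str, rank: str) -> str:
    idx = RANKS.index(rank)
    fields = [f.strip() for f in str(lineage).split(";")]
    fields = [_RANK_PREFIX.sub("", f) for f in fields]
    if idx >= len(fields) or not fields[idx]:
        return "Unclassified"
    return fields[idx]


def aggregate_by_rank(table: OtuTable, rank: str) -> OtuTable:
    """Sum abundances over taxa sharing the same lineage label at ``rank``.

    Unparseable or missing lineages collapse into an ``"Unclassified"`` row.
    Per-sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ParameterError(f"unknown rank {rank!r}; choose from {RANKS}")
    labels = table.taxonomy.map(lambda lin: _rank_label(lin, rank))
    grouped = table.counts.groupby(labels.to_numpy()).sum()
    grouped = grouped.sort_index()
    taxonomy = pd.Series(grouped.index, index=grouped.index)
    return OtuTable(grouped, taxonomy, table.is_relative)
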