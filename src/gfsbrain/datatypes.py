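"""In-memory domain containers shared across the pipeline.

All tabular state is held in pandas objects; trees are dendropy trees
wrapped in :class:`Phylogeny`. Readers in :mod:`gfsbrain.io` construct
these; every analysis module consumes them and never touches files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SpeciesTraitTable",
    "GeneFamilyMatrix",
    "Phylogeny",
    "ExpressionMatrix",
    "SyntheticTruth",
]


@dataclass
class SpeciesTraitTable:
    """Per-species traits: brain mass (g), body mass (g), MLSP (yr).

    ``ei`` is filled by :func:`gfsbrain.encephalization.compute_ei` or by
    :func:`gfsbrain.encephalization.attach_external_ei`; ``ei_source``
    records which path produced it.
    """

    data: pd.DataFrame  # index: species_id; columns brain_mass_g, body_mass_g, mlsp_yr
    ei: Optional[pd.Series] = None
    ei_source: Optional[str] = None  # "internal" | "external"

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_species(self) -> int:
        return len(self.data)

    def mlsp(self) -> pd.Series:
        """MLSP in years; NaN where missing."""
        return self.data["mlsp_yr"]

    def require_mlsp(self) -> pd.Series:
        miss = self.data.index[self.data["mlsp_yr"].isna()].tolist()
        if miss:
            raise ValueError(f"MLSP missing for species: {miss}")
        return self.data["mlsp_yr"]

    def require_ei(self) -> pd.Series:
        if self.ei is None:
            raise ValueError("Ei has not been computed or attached")
        return self.ei


@dataclass
class GeneFamilyMatrix:
    """Family x species copy-number counts (gene family size, GFS)."""

    family_ids: list[str]
    species_ids: list[str]
    counts: np.ndarray  # (n_families, n_species) non-negative ints
    gene_membership: Optional[dict[str, str]] = None  # gene_id -> family_id

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.family_ids), len(self.species_ids)):
            raise ValueError("counts shape does not match id lists")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.array_equal(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.family_ids)) != len(self.family_ids):
            raise ValueError("duplicate family_id")

    @property
    def n_families(self) -> int:
        return len(self.family_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.family_ids, columns=self.species_ids)

    def restrict_species(self, species: list[str]) -> "GeneFamilyMatrix":
        missing = [s for s in species if s not in self.species_ids]
        if missing:
            raise ValueError(f"species absent from count matrix: {missing}")
        idx = [self.species_ids.index(s) for s in species]
        return GeneFamilyMatrix(
            family_ids=list(self.family_ids),
            species_ids=list(species),
            counts=self.counts[:, idx],
            gene_membership=self.gene_membership,
        )


class Phylogeny:
    """Rooted species phylogeny with branch lengths (dendropy-backed)."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels in tree")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValueError("tree has an edge with no branch length")
            if edge.length < 0:
                raise ValueError("negative branch length")
        self.tip_labels = sorted(labels)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def n_edges(self) -> int:
        return sum(
            1 for e in self.tree.preorder_edge_iter() if e.head_node is not self.tree.seed_node
        )

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path lengths."""
        depths: dict[str, float] = {}
        node_depth = {self.tree.seed_node: 0.0}
        for node in self.tree.preorder_node_iter():
            if node is not self.tree.seed_node:
                node_depth[node] = node_depth[node.parent_node] + node.edge.length
            if node.is_leaf():
                depths[node.taxon.label] = node_depth[node]
        return depths

    def shared_path_matrix(self, species: list[str]) -> np.ndarray:
        """C[i, j] = root-to-MRCA path length for tips i, j; diagonal = tip depth.

        This is the Brownian-motion trait covariance up to a rate constant.
        """
        missing = set(species) - set(self.tip_labels)
        if missing:
            raise ValueError(f"species not in tree: {sorted(missing)}")
        n = len(species)
        pos = {s: i for i, s in enumerate(species)}
        node_depth: dict = {self.tree.seed_node: 0.0}
        C = np.zeros((n, n))
        # postorder: each internal node's depth is the shared path for every
        # tip pair split across two of its children
        below: dict = {}
        for node in self.tree.preorder_node_iter():
            if node is not self.tree.seed_node:
                node_depth[node] = node_depth[node.parent_node] + node.edge.length
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                lab = node.taxon.label
                below[node] = [pos[lab]] if lab in pos else []
                if lab in pos:
                    C[pos[lab], pos[lab]] = node_depth[node]
            else:
                kids = [below[c] for c in node.child_nodes()]
                d = node_depth[node]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in kids[a]:
                            for j in kids[b]:
                                C[i, j] = C[j, i] = d
                below[node] = [i for k in kids for i in k]
        return C


@dataclass
class ExpressionMatrix:
    """Gene x sample expression with per-sample metadata.

    Metadata columns: tissue, region (CX|SC|CB|other), age_value, age_unit,
    period (prenatal|postnatal).
    """

    values: pd.DataFrame  # genes x samples, non-negative
    metadata: pd.DataFrame  # index sample_id

    def __post_init__(self) -> None:
        orphans = [c for c in self.values.columns if c not in self.metadata.index]
        if orphans:
            raise ValueError(f"samples without metadata: {orphans}")
        if (self.values.values < 0).any():
            raise ValueError("negative expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def panel(self, name: str) -> "ExpressionMatrix":
        """Subset to one sample block: tissue | regional | developmental.

        Uses the optional `panel` metadata column when present; otherwise
        falls back to region labels (tissue panel = region "other",
        regional and developmental = CX/SC/CB brain samples).
        """
        if name not in ("tissue", "regional", "developmental"):
            raise ValueError(f"unknown panel {name!r}")
        if "panel" in self.metadata.columns:
            return self.subset_samples(self.metadata["panel"] == name)
        if name == "tissue":
            return self.subset_samples(self.metadata["region"] == "other")
        return self.subset_samples(self.metadata["region"].isin(["CX", "SC", "CB"]))

    def subset_samples(self, mask) -> "ExpressionMatrix":
        if not isinstance(mask, pd.Series):
            mask = pd.Series(np.asarray(mask), index=self.metadata.index)
        keep = self.metadata.index[mask.reindex(self.metadata.index, fill_value=False)]
        keep = [s for s in self.values.columns if s in set(keep)]
        return ExpressionMatrix(self.values[keep], self.metadata.loc[keep])


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded by the synthetic-data generator."""

    ei_linked_families: set[str] = field(default_factory=set)
    mlsp_linked_families: set[str] = field(default_factory=set)
    phylo_only_families: set[str] = field(default_factory=set)
    enriched_terms: set[str] = field(default_factory=set)
    module_labels: dict[str, int] = field(default_factory=dict)
    prominent_genes: set[str] = field(default_factory=set)
    developmental_genes: set[str] = field(default_factory=set)
    hub_genes: dict[int, str] = field(default_factory=dict)
    generator_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sets = [self.ei_linked_families, self.mlsp_linked_families, self.phylo_only_families]
        for a in range(3):
            for b in range(a + 1, 3):
                if sets[a] & sets[b]:
                    raise ValueError("planted family classes must be pairwise disjoint")

    def to_json_dict(self) -> dict:
        return {
            "ei_linked_families": sorted(self.ei_linked_families),
            "mlsp_linked_families": sorted(self.mlsp_linked_families),
            "phylo_only_families": sorted(self.phylo_only_families),
            "enriched_terms": sorted(self.enriched_terms),
            "module_labels": self.module_labels,
            "prominent_genes": sorted(self.prominent_genes),
            "developmental_genes": sorted(self.developmental_genes),
            "hub_genes": {str(k): v for k, v in self.hub_genes.items()},
            "generator_params": self.generator_params,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            ei_linked_families=set(d.get("ei_linked_families", [])),
            mlsp_linked_families=set(d.get("mlsp_linked_families", [])),
            phylo_only_families=set(d.get("phylo_only_families", [])),
            enriched_terms=set(d.get("enriched_terms", [])),
            module_labels={k: int(v) for k, v in d.get("module_labels", {}).items()},
            prominent_genes=set(d.get("prominent_genes", [])),
            developmental_genes=set(d.get("developmental_genes", [])),
            hub_genes={int(k): v for k, v in d.get("hub_genes", {}).items()},
            generator_params=d.get("generator_params", {}),
        )
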