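"""Readers and writers for every external file the pipeline touches.

Canonical tabular dialect: TSV, UTF-8, header row, no quoting (tabs are
not permitted inside fields). Trees are Newick; result objects serialize
to JSON elsewhere. Readers validate strictly and never silently drop
rows; every reader is the inverse of its writer on valid data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneFamilyMatrix, Phylogeny, SpeciesTraitTable

__all__ = [
    "read_species_traits",
    "write_species_traits",
    "read_family_counts",
    "write_family_counts",
    "read_newick",
    "write_newick",
    "read_go_map",
    "write_go_map",
    "read_expression",
    "write_expression",
]


class SchemaError(ValueError):
    """A required column or structural element is missing."""


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_species_traits(path) -> SpeciesTraitTable:
    """Read a species trait TSV (species, brain_mass_g, body_mass_g[, mlsp_yr]).

    Missing MLSP cells (empty string or "NA") are recorded as absent, never
    as zero. Masses must be strictly positive.
    """
    raw = _read_tsv(path)
    for col in ("species", "brain_mass_g", "body_mass_g"):
        if col not in raw.columns:
            raise SchemaError(f"trait table missing required column: {col}")
    if raw["species"].duplicated().any():
        dups = raw["species"][raw["species"].duplicated()].tolist()
        raise ValueError(f"duplicate species: {dups}")
    data = pd.DataFrame(index=pd.Index(raw["species"], name="species"))
    for col in ("brain_mass_g", "body_mass_g"):
        vals = pd.to_numeric(raw[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0]) + 2  # header is line 1
            raise ValueError(f"non-numeric {col} at line {row}")
        bad = vals <= 0
        if bad.any():
            row = int(vals.index[bad][0]) + 2
            raise ValueError(f"non-positive {col} at line {row}")
        data[col] = vals.values
    if "mlsp_yr" in raw.columns:
        mlsp = raw["mlsp_yr"].replace({"": np.nan, "NA": np.nan})
        mlsp = pd.to_numeric(mlsp, errors="raise")
        if (mlsp.dropna() <= 0).any():
            row = int(mlsp.index[mlsp <= 0][0]) + 2
            raise ValueError(f"non-positive mlsp_yr at line {row}")
        data["mlsp_yr"] = mlsp.values
    else:
        data["mlsp_yr"] = np.nan
    return SpeciesTraitTable(data=data)


def write_species_traits(table: SpeciesTraitTable, path) -> None:
    out = table.data.reset_index()
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_family_counts(path, species: list[str]) -> GeneFamilyMatrix:
    """Read a family x species count TSV restricted/reordered to `species`."""
    raw = _read_tsv(path)
    if raw.columns[0] != "family_id":
        raise SchemaError("first column must be family_id")
    if raw["family_id"].duplicated().any():
        dups = raw["family_id"][raw["family_id"].duplicated()].tolist()
        raise ValueError(f"duplicate family_id: {dups}")
    missing = [s for s in species if s not in raw.columns]
    if missing:
        raise SchemaError(f"count table missing species columns: {missing}")
    counts = np.empty((len(raw), len(species)), dtype=np.int64)
    for j, sp in enumerate(species):
        vals = pd.to_numeric(raw[sp], errors="coerce")
        if vals.isna().any():
            cell = raw[sp][vals.isna()].iloc[0]
            raise ValueError(f"non-numeric count {cell!r} in column {sp}")
        if not np.array_equal(vals.values, np.round(vals.values)):
            bad = raw[sp][vals != np.round(vals)].iloc[0]
            raise ValueError(f"non-integer count {bad!r} in column {sp}")
        if (vals < 0).any():
            raise ValueError(f"negative count in column {sp}")
        counts[:, j] = vals.astype(np.int64).values
    return GeneFamilyMatrix(
        family_ids=raw["family_id"].tolist(), species_ids=list(species), counts=counts
    )


def write_family_counts(matrix: GeneFamilyMatrix, path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "family_id"
    frame.reset_index().to_csv(path, sep="\t", index=False)


def read_newick(path) -> Phylogeny:
    """Read a single rooted Newick tree; all edges must carry branch lengths."""
    with open(path) as fh:
        text = fh.read()
    return Phylogeny.from_newick(text)


def write_newick(phylo: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(phylo.to_newick() + "\n")


def read_go_map(path) -> dict[str, set[str]]:
    """Read (term_id, gene_id) pairs into a term -> gene multimap.

    Duplicate pairs collapse; an empty file is an error.
    """
    raw = _read_tsv(path)
    for col in ("term_id", "gene_id"):
        if col not in raw.columns:
            raise SchemaError(f"GO map missing required column: {col}")
    if len(raw) == 0:
        raise ValueError("GO annotation file contains no pairs")
    out: dict[str, set[str]] = {}
    for term, gene in zip(raw["term_id"], raw["gene_id"]):
        out.setdefault(term, set()).add(gene)
    return out


def write_go_map(term_to_genes: dict[str, set[str]], path) -> None:
    rows = [
        {"term_id": t, "gene_id": g}
        for t in sorted(term_to_genes)
        for g in sorted(term_to_genes[t])
    ]
    pd.DataFrame(rows, columns=["term_id", "gene_id"]).to_csv(path, sep="\t", index=False)


_REQUIRED_META = ("sample_id", "tissue", "region", "age_value", "age_unit", "period")


def read_expression(path, metadata_path) -> ExpressionMatrix:
    """Read genes x samples expression plus per-sample metadata.

    Every expression column must have a metadata row; an orphan sample is
    an error naming the sample.
    """
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = _read_tsv(metadata_path)
    for col in _REQUIRED_META:
        if col not in meta.columns:
            raise SchemaError(f"metadata missing required column: {col}")
    meta = meta.set_index("sample_id")
    meta["age_value"] = pd.to_numeric(meta["age_value"], errors="coerce")
    orphans = [c for c in values.columns if c not in meta.index]
    if orphans:
        raise ValueError(f"expression samples without metadata: {orphans}")
    if (values.values < 0).any():
        raise ValueError("negative expression values")
    return ExpressionMatrix(values=values, metadata=meta.loc[list(values.columns)])


def write_expression(expr: ExpressionMatrix, path, metadata_path) -> None:
    out = expr.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    meta = expr.metadata.reset_index()
    if meta.columns[0] != "sample_id":
        meta = meta.rename(columns={meta.columns[0]: "sample_id"})
    meta.to_csv(metadata_path, sep="\t", index=False)
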