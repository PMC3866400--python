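"""Brain-expression characterization of selected gene families.

Prominence: a gene is prominently expressed in the brain when its brain
value ranks highest or second highest among the tissue panel (top
2/16 = 12.5th percentile at 16 tissues). Family-level enrichment
resamples FAMILY sets (genes inherited), matching the family-structured
null the selection cascade operates on. Developmental-variance genes are
those with the largest ratio of cortical expression variance during
development (age <= dev_max_age) to adulthood. Regional categorization
labels each gene by the brain region (CX, SC, CB) with its highest mean
expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix

__all__ = [
    "ProminenceCall",
    "EnrichmentReport",
    "prominence_calls",
    "tissue_panel",
    "family_set_enrichment",
    "developmental_variance_genes",
    "regional_max_category",
]


@dataclass
class ProminenceCall:
    gene_id: str
    brain_rank: int  # 1 = highest among tissues
    prominent: bool


@dataclass
class EnrichmentReport:
    observed_count: int
    expected_mean: float
    expected_sd: float
    empirical_p: float
    direction: str  # over | under
    n_samples: int

    def to_json_dict(self) -> dict:
        return self.__dict__.copy()


def tissue_panel(expr: ExpressionMatrix) -> pd.DataFrame:
    """Collapse to one value per gene per tissue (mean over samples)."""
    by_tissue = {}
    for tissue, meta in expr.metadata.groupby("tissue"):
        cols = [c for c in expr.values.columns if c in set(meta.index)]
        by_tissue[tissue] = expr.values[cols].mean(axis=1)
    return pd.DataFrame(by_tissue)


def prominence_calls(
    panel: pd.DataFrame, brain_tissue: str = "brain", top_ranks: int = 2
) -> list[ProminenceCall]:
    """Rank the brain among tissues per gene; prominent iff rank <= top_ranks.

    `panel` is genes x tissues with exactly one column per tissue. Ties:
    tissues equal to the brain value share its rank (a gene is prominent
    unless more than `top_ranks` - 1 tissues STRICTLY exceed brain).
    """
    if brain_tissue not in panel.columns:
        raise ValueError(f"no tissue labelled {brain_tissue!r}")
    vals = panel.to_numpy(dtype=float)
    b = panel.columns.get_loc(brain_tissue)
    brain = vals[:, b]
    n_strictly_above = (vals > brain[:, None]).sum(axis=1)
    ranks = n_strictly_above + 1
    return [
        ProminenceCall(gene_id=g, brain_rank=int(ranks[i]), prominent=bool(ranks[i] <= top_ranks))
        for i, g in enumerate(panel.index)
    ]


def family_set_enrichment(
    target_families: set[str],
    membership: dict[str, str],
    gene_flags: dict[str, bool],
    pool: set[str],
    n_samples: int = 10000,
    seed: int = 0,
    direction: str = "over",
) -> EnrichmentReport:
    """Count flagged genes in target families vs equally sized family samples.

    Resampling is at the family level: each null replicate draws
    |target_families| families from `pool` and counts the flagged genes
    they contain. Genes without a flag are dropped (not counted).
    """
    if direction not in ("over", "under"):
        raise ValueError("direction must be 'over' or 'under'")
    if not target_families <= pool:
        raise ValueError("target families must come from the pool")
    pool_ids = sorted(pool)
    k = len(target_families)
    if k > len(pool_ids):
        raise ValueError("target larger than pool")
    flagged_per_family = {f: 0 for f in pool_ids}
    for gene, fam in membership.items():
        if fam in flagged_per_family and gene_flags.get(gene, False):
            flagged_per_family[fam] += 1
    weights = np.array([flagged_per_family[f] for f in pool_ids], dtype=float)
    observed = int(sum(flagged_per_family[f] for f in target_families))

    rng = np.random.default_rng(seed)
    n_pool = len(pool_ids)
    null = np.empty(n_samples)
    chunk = max(1, min(n_samples, int(2e7 / max(n_pool, 1))))
    done = 0
    while done < n_samples:
        b = min(chunk, n_samples - done)
        picks = np.argsort(rng.random((b, n_pool)), axis=1)[:, :k]
        null[done : done + b] = weights[picks].sum(axis=1)
        done += b
    if direction == "over":
        p = (1.0 + (null >= observed).sum()) / (1.0 + n_samples)
    else:
        p = (1.0 + (null <= observed).sum()) / (1.0 + n_samples)
    return EnrichmentReport(
        observed_count=observed,
        expected_mean=float(null.mean()),
        expected_sd=float(null.std(ddof=1)) if n_samples > 1 else 0.0,
        empirical_p=float(p),
        direction=direction,
        n_samples=n_samples,
    )


def developmental_variance_genes(
    expr: ExpressionMatrix,
    dev_max_age: float = 18.0,
    top_percentile: float = 10.0,
) -> tuple[set[str], pd.DataFrame]:
    """Genes with the highest developmental-to-adult variance ratio.

    Uses cortical (CX) samples only; development = age <= dev_max_age.
    Genes with zero variance in both periods are excluded (flagged in the
    returned frame). Returns (selected genes, per-gene frame).
    """
    meta = expr.metadata
    cx = meta[meta["region"] == "CX"]
    dev_cols = cx.index[cx["age_value"] <= dev_max_age].tolist()
    adult_cols = cx.index[cx["age_value"] > dev_max_age].tolist()
    if len(dev_cols) < 3 or len(adult_cols) < 3:
        raise ValueError("need >= 3 cortical samples in both development and adulthood")
    dev_var = expr.values[dev_cols].var(axis=1, ddof=1)
    adult_var = expr.values[adult_cols].var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = dev_var / adult_var
    frame = pd.DataFrame(
        {"dev_var": dev_var, "adult_var": adult_var, "ratio": ratio}
    )
    frame["degenerate"] = (dev_var == 0) & (adult_var == 0)
    usable = frame[~frame["degenerate"]].copy()
    usable["ratio"] = usable["ratio"].replace(np.inf, np.finfo(float).max)
    cutoff = np.percentile(usable["ratio"], 100.0 - top_percentile)
    selected = set(usable.index[usable["ratio"] >= cutoff])
    return selected, frame


def regional_max_category(expr: ExpressionMatrix) -> pd.Series:
    """Label each gene by the region (CX, SC, CB) of maximal mean expression.

    Exact ties break by fixed priority CX > SC > CB.
    """
    means = {}
    for region in ("CX", "SC", "CB"):
        cols = expr.metadata.index[expr.metadata["region"] == region].tolist()
        cols = [c for c in expr.values.columns if c in set(cols)]
        if not cols:
            raise ValueError(f"no samples for region {region}")
        means[region] = expr.values[cols].mean(axis=1)
    frame = pd.DataFrame(means)[["CX", "SC", "CB"]]
    # idxmax returns the first column on ties, which is the CX>SC>CB priority
    return frame.idxmax(axis=1)
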