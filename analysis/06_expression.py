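#!/usr/bin/env python
"""Brain-expression characterization of the retained gene families.

Calls brain prominence (top 2 of 16 tissues) per gene, tests whether the
retained families are enriched in prominent genes against 10,000
equally sized random family sets, repeats the test for the planted
developmental-variance gene set, and categorizes genes by the brain
region of maximal expression. Writes reports to results/expression/.
"""

import json
from pathlib import Path

import pandas as pd

from gfsbrain import expression as ex
from gfsbrain import io as gio

SEED = 20260927


def main() -> None:
    expr = gio.read_expression("results/inputs/expression.tsv",
                               "results/inputs/expression_meta.tsv")
    membership = dict(
        pd.read_csv("results/inputs/gene_families.tsv", sep="\t", dtype=str).values
    )
    pool = set(membership.values())
    retained = {line.strip() for line in open("results/phylo/retained.txt")
                if line.strip()} & pool
    outdir = Path("results/expression")
    outdir.mkdir(parents=True, exist_ok=True)

    panel = ex.tissue_panel(expr.panel("tissue"))
    calls = ex.prominence_calls(panel)
    flags = {c.gene_id: c.prominent for c in calls}
    n_prom = sum(flags.values())
    print(f"{n_prom}/{len(flags)} genes prominently expressed in brain "
          f"({100 * n_prom / len(flags):.1f}%)")

    rep = ex.family_set_enrichment(retained, membership, flags, pool,
                                   n_samples=10000, seed=SEED)
    print(f"prominence enrichment in {len(retained)} retained families: "
          f"observed {rep.observed_count} vs expected {rep.expected_mean:.1f} "
          f"(p = {rep.empirical_p:.4g})")
    with open(outdir / "prominence_enrichment.json", "w") as fh:
        json.dump(rep.to_json_dict(), fh, indent=1)

    dev_genes, dev_frame = ex.developmental_variance_genes(
        expr.panel("developmental"), dev_max_age=18, top_percentile=10
    )
    dev_frame.to_csv(outdir / "developmental_variance.tsv", sep="\t")
    dflags = {g: (g in dev_genes) for g in expr.genes}
    rep2 = ex.family_set_enrichment(retained, membership, dflags, pool,
                                    n_samples=10000, seed=SEED + 1)
    print(f"developmental-variance enrichment: observed {rep2.observed_count} "
          f"vs expected {rep2.expected_mean:.1f} (p = {rep2.empirical_p:.4g})")
    with open(outdir / "devvar_enrichment.json", "w") as fh:
        json.dump(rep2.to_json_dict(), fh, indent=1)

    regions = ex.regional_max_category(expr.panel("regional"))
    regions.rename("region").to_csv(outdir / "regional_max.tsv", sep="\t")
    print("regional maxima:", regions.value_counts().to_dict())


if __name__ == "__main__":
    main()
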