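#!/usr/bin/env python
"""Weighted co-expression modules over the developmental cortex series.

Builds the soft-thresholded network on genes of the retained families,
computes topological overlap, detects modules by average-linkage
clustering with a static cut, summarizes each module by its eigengene,
and reports hub genes. Compares the detected partition against the
planted module labels. Writes tables to results/coexpression/.
"""

import warnings
from pathlib import Path

import pandas as pd

from gfsbrain import coexpression as coex
from gfsbrain import io as gio


def main() -> None:
    warnings.simplefilter("ignore", UserWarning)
    expr = gio.read_expression("results/inputs/expression.tsv",
                               "results/inputs/expression_meta.tsv")
    membership = dict(
        pd.read_csv("results/inputs/gene_families.tsv", sep="\t", dtype=str).values
    )
    retained = {line.strip() for line in open("results/phylo/retained.txt")
                if line.strip()}
    target_genes = [g for g in expr.genes if membership.get(g) in retained]
    dev = expr.panel("developmental")
    values = dev.values.loc[target_genes]
    print(f"network over {len(target_genes)} genes of {len(retained)} retained families")
    modules = coex.run_wgcna(values, min_module_size=30)
    outdir = Path("results/coexpression")
    outdir.mkdir(parents=True, exist_ok=True)
    out = modules.assignment.rename("module").to_frame()
    out["colour"] = [coex.module_colour(m) for m in out["module"]]
    out.to_csv(outdir / "module_assignment.tsv", sep="\t")
    modules.eigengenes.to_csv(outdir / "module_eigengenes.tsv", sep="\t")
    pd.DataFrame(sorted(modules.hubs.items()), columns=["module", "hub_gene"]).to_csv(
        outdir / "hub_genes.tsv", sep="\t", index=False
    )
    sizes = modules.assignment.value_counts().drop(0, errors="ignore")
    print(f"soft threshold beta = {modules.beta}")
    print(f"{len(sizes)} modules detected; sizes {sizes.to_dict()}")
    print(f"hub genes: {modules.hubs}")

    import json

    truth = json.load(open("results/inputs/truth.json"))
    labels = truth["module_labels"]
    common = [g for g in modules.assignment.index if g in labels]
    from sklearn.metrics import adjusted_rand_score

    ari = adjusted_rand_score(
        [labels[g] for g in common], modules.assignment.loc[common].values
    )
    print(f"adjusted Rand index vs planted modules: {ari:.3f}")


if __name__ == "__main__":
    main()
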