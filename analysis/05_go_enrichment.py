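#!/usr/bin/env python
"""GO functional-bias tests on the selected family sets.

Runs the mean-correlation test over all eligible GO terms (>50 families)
and the annotation-density-adjusted enrichment test for each cascade
stage (sig_ei, preferential, sig_partial, phylo-retained), with 10,000
resamples and Bonferroni correction. Writes per-term tables to
results/go/ and reports terms significant after correction.
"""

from pathlib import Path

import pandas as pd

from gfsbrain import association as assoc
from gfsbrain import encephalization as ence
from gfsbrain import go_enrichment as goe
from gfsbrain import io as gio
from gfsbrain.pipeline import _term_frame

SEED = 20260927


def main() -> None:
    traits = gio.read_species_traits("results/inputs/traits.tsv")
    ence.compute_ei(traits)
    matrix = gio.read_family_counts("results/inputs/family_counts.tsv", traits.species)
    matrix = assoc.filter_families(matrix, min_species=6)
    membership = dict(
        pd.read_csv("results/inputs/gene_families.tsv", sep="\t", dtype=str).values
    )
    raw = gio.read_go_map("results/inputs/go_annotations.tsv")
    gomap = goe.build_term_family_map(raw, membership, min_term_families=50)
    print(f"{len(gomap.eligible_terms)} eligible GO terms (>50 families)")

    records = assoc.family_correlations(matrix, traits.require_ei(), traits.mlsp())
    outdir = Path("results/go")
    outdir.mkdir(parents=True, exist_ok=True)

    meanr = goe.mean_correlation_test(gomap, records, n_samples=10000, seed=SEED)
    frame = _term_frame(meanr).sort_values("bonferroni_p")
    frame.to_csv(outdir / "mean_correlation.tsv", sep="\t", index=False)
    sig = frame[frame["bonferroni_p"] < 0.05]
    print(f"mean-correlation test: {len(sig)} terms significant after Bonferroni")

    background = {r.family_id for r in records if not r.zero_variance}
    for stage_file in ("sig_ei", "preferential", "sig_partial"):
        path = Path(f"results/association/{stage_file}.txt")
        fams = {line.strip() for line in open(path) if line.strip()} & background
        res = goe.adjusted_enrichment_test(gomap, fams, background,
                                           n_samples=10000, seed=SEED + 1)
        frame = _term_frame(res).sort_values("bonferroni_p")
        frame.to_csv(outdir / f"enrichment_{stage_file}.tsv", sep="\t", index=False)
        sig = frame[frame["bonferroni_p"] < 0.05]["term_id"].tolist()
        print(f"adjusted enrichment on {stage_file} (n={len(fams)}): "
              f"{len(sig)} significant terms {sig}")
    retained_path = Path("results/phylo/retained.txt")
    if retained_path.exists():
        fams = {line.strip() for line in open(retained_path) if line.strip()} & background
        res = goe.adjusted_enrichment_test(gomap, fams, background,
                                           n_samples=10000, seed=SEED + 2)
        frame = _term_frame(res).sort_values("bonferroni_p")
        frame.to_csv(outdir / "enrichment_phylo_retained.tsv", sep="\t", index=False)
        sig = frame[frame["bonferroni_p"] < 0.05]["term_id"].tolist()
        print(f"adjusted enrichment on phylo-retained (n={len(fams)}): "
              f"{len(sig)} significant terms {sig}")


if __name__ == "__main__":
    main()
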