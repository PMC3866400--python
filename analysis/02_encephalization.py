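#!/usr/bin/env python
"""Fit the allometric regression and compute the encephalization index.

Reads results/inputs/traits.tsv, fits log10(brain) ~ log10(body) by OLS,
and writes the per-species residuals (Ei) plus the fit summary to
results/encephalization/.
"""

import json
from pathlib import Path

from gfsbrain import encephalization as ence
from gfsbrain import io as gio


def main() -> None:
    traits = gio.read_species_traits("results/inputs/traits.tsv")
    res = ence.compute_ei(traits)
    outdir = Path("results/encephalization")
    outdir.mkdir(parents=True, exist_ok=True)
    res.residuals.rename("ei").to_csv(outdir / "ei.tsv", sep="\t")
    with open(outdir / "fit.json", "w") as fh:
        json.dump({"slope": res.slope, "intercept": res.intercept,
                   "r_squared": res.r_squared, "n": res.n}, fh, indent=1)
    print(f"allometric fit on {res.n} species: "
          f"slope {res.slope:.3f}, intercept {res.intercept:.3f}, "
          f"R^2 {res.r_squared:.3f}")
    print(f"Ei range: {res.residuals.min():.3f} .. {res.residuals.max():.3f} "
          f"(log10 g); wrote {outdir}/ei.tsv")


if __name__ == "__main__":
    main()
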