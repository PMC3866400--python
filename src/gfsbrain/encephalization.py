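"""Encephalization index: residuals of a log-log brain ~ body allometry.

Ei_s is the residual of species s from an ordinary least-squares fit of
log(brain mass) on log(body mass). Base-10 logs by default (allometric
convention); residual-based Pearson correlations downstream are invariant
to the base up to a positive constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SpeciesTraitTable

__all__ = ["EncephalizationResult", "compute_ei", "attach_external_ei"]


@dataclass
class EncephalizationResult:
    slope: float
    intercept: float
    residuals: pd.Series  # Ei per species, log-grams
    r_squared: float
    n: int
    log_base: float

    def to_json_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "n": self.n,
            "log_base": self.log_base,
            "ei": {k: float(v) for k, v in self.residuals.items()},
        }


def compute_ei(traits: SpeciesTraitTable, log_base: float = 10.0) -> EncephalizationResult:
    """OLS fit of log(brain) ~ log(body); Ei = observed - fitted.

    Stores the residuals on `traits` (ei_source="internal") and returns the
    full fit. Requires >= 3 species with strictly positive masses.
    """
    if traits.n_species < 3:
        raise ValueError("need at least 3 species for the allometric regression")
    brain = traits.data["brain_mass_g"].to_numpy(dtype=float)
    body = traits.data["body_mass_g"].to_numpy(dtype=float)
    if (brain <= 0).any() or (body <= 0).any():
        raise ValueError("non-positive mass")
    lb = math.log(log_base)
    y = np.log(brain) / lb
    x = np.log(body) / lb
    fit = stats.linregress(x, y)
    resid = y - (fit.intercept + fit.slope * x)
    residuals = pd.Series(resid, index=traits.data.index, name="ei")
    traits.ei = residuals
    traits.ei_source = "internal"
    return EncephalizationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residuals=residuals,
        r_squared=float(fit.rvalue) ** 2,
        n=traits.n_species,
        log_base=log_base,
    )


def attach_external_ei(traits: SpeciesTraitTable, ei_table: pd.Series) -> SpeciesTraitTable:
    """Attach externally supplied brain residuals, overriding internal ones.

    Mirrors the use of residuals from a larger reference regression than
    the analysis clade itself: every analysis species must be present.
    """
    missing = [s for s in traits.species if s not in ei_table.index]
    if missing:
        raise ValueError(f"external Ei table missing species: {missing}")
    traits.ei = ei_table.reindex(traits.data.index).astype(float)
    traits.ei_source = "external"
    return traits
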