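"""Per-family association of gene family size (GFS) with encephalization.

The screen computes a Pearson correlation between each family's
copy-number profile and the encephalization index (Ei) across species,
tests the excess of positive correlations with a 2-cell chi-square and a
Monte-Carlo permutation null, controls for maximum lifespan (MLSP) via
first-order partial correlations, and applies the selection cascade:

    significant Ei correlation (r > 0, p < alpha)
      -> preferential Ei association (r_Ei > r_MLSP)
      -> significant positive partial correlation given MLSP

Zero-variance families carry an undefined r and are excluded from tail
counts and from selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GeneFamilyMatrix

__all__ = [
    "FamilyAssociationRecord",
    "ShiftTestResult",
    "filter_families",
    "family_correlations",
    "chi_square_shift",
    "permutation_shift_test",
    "overall_gene_number_correlation",
    "partial_correlations",
    "select_families",
    "records_to_frame",
]


@dataclass
class FamilyAssociationRecord:
    family_id: str
    r_ei: float  # NaN if GFS variance is zero
    p_ei: float
    r_mlsp: float = float("nan")
    p_mlsp: float = float("nan")
    partial_r: float = float("nan")
    partial_p: float = float("nan")
    n_species: int = 0
    zero_variance: bool = False
    flags: dict = field(default_factory=dict)


@dataclass
class ShiftTestResult:
    n_total: int
    n_positive: int
    n_negative: int
    n_zero: int
    expected_positive: float
    shift: float
    chi2: float
    chi2_p: float
    perm_p: float
    n_permutations: int
    null_positive_counts: dict  # mean, sd, quantiles
    histogram: dict  # bin_edges, observed, null_mean
    mode: str

    def to_json_dict(self) -> dict:
        d = self.__dict__.copy()
        d["histogram"] = {k: list(np.asarray(v, dtype=float)) for k, v in self.histogram.items()}
        return d


def filter_families(matrix: GeneFamilyMatrix, min_species: int = 6) -> GeneFamilyMatrix:
    """Retain families with count > 0 in at least `min_species` species."""
    if min_species < 1:
        raise ValueError("min_species must be >= 1")
    present = (matrix.counts > 0).sum(axis=1)
    keep = present >= min_species
    if not keep.any():
        raise ValueError("presence filter removed every family")
    return GeneFamilyMatrix(
        family_ids=[f for f, k in zip(matrix.family_ids, keep) if k],
        species_ids=list(matrix.species_ids),
        counts=matrix.counts[keep],
        gene_membership=matrix.gene_membership,
    )


def _rowwise_pearson(counts: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r and two-sided t-distribution p of each row against v.

    Rows with zero variance get r = NaN, p = NaN.
    """
    n = counts.shape[1]
    c = counts - counts.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    c_norm = np.sqrt((c**2).sum(axis=1))
    v_norm = np.sqrt((vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (c @ vc) / (c_norm * v_norm)
    r = np.clip(r, -1.0, 1.0)
    r[c_norm == 0] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.minimum(np.maximum(p, np.finfo(float).tiny), 1.0)
    p[np.isnan(r)] = np.nan
    return r, p


def family_correlations(
    matrix: GeneFamilyMatrix,
    ei: pd.Series,
    mlsp: Optional[pd.Series] = None,
) -> list[FamilyAssociationRecord]:
    """Pearson r and two-sided p per family for Ei (and MLSP if given)."""
    if matrix.counts.shape[1] < 3:
        raise ValueError("need at least 3 species")
    ei_v = ei.reindex(matrix.species_ids).to_numpy(dtype=float)
    if np.isnan(ei_v).any():
        raise ValueError("Ei missing for some species in the count matrix")
    r_ei, p_ei = _rowwise_pearson(matrix.counts.astype(float), ei_v)
    if mlsp is not None:
        mlsp_v = mlsp.reindex(matrix.species_ids).to_numpy(dtype=float)
        if np.isnan(mlsp_v).any():
            raise ValueError("MLSP missing for some species in the count matrix")
        r_ml, p_ml = _rowwise_pearson(matrix.counts.astype(float), mlsp_v)
    else:
        r_ml = np.full(matrix.n_families, np.nan)
        p_ml = np.full(matrix.n_families, np.nan)
    n = matrix.counts.shape[1]
    return [
        FamilyAssociationRecord(
            family_id=fid,
            r_ei=float(r_ei[i]),
            p_ei=float(p_ei[i]),
            r_mlsp=float(r_ml[i]),
            p_mlsp=float(p_ml[i]),
            n_species=n,
            zero_variance=bool(np.isnan(r_ei[i])),
        )
        for i, fid in enumerate(matrix.family_ids)
    ]


def chi_square_shift(n_positive: int, n_total: int) -> tuple[float, float]:
    """2-cell goodness-of-fit chi-square against an equal positive/negative split.

    chi2 = 2 (n_positive - n_total/2)^2 / (n_total/2), 1 df.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_positive <= n_total:
        raise ValueError("n_positive out of range")
    expected = n_total / 2.0
    chi2 = 2.0 * (n_positive - expected) ** 2 / expected
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def permutation_shift_test(
    matrix: GeneFamilyMatrix,
    ei: pd.Series,
    n_permutations: int = 1000,
    seed: int = 0,
    mode: str = "per_family",
    n_bins: int = 40,
) -> ShiftTestResult:
    """Monte-Carlo null for the positive-correlation excess.

    Each replicate permutes GFS values across species and recounts
    positive correlations. `per_family` permutes each family's counts
    independently; `shared_relabel` applies a single species permutation
    per replicate, preserving cross-family covariance. The empirical
    p-value uses the +1 correction and never returns 0.
    """
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    if mode not in ("per_family", "shared_relabel"):
        raise ValueError(f"unknown permutation mode: {mode}")
    rng = np.random.default_rng(seed)
    counts = matrix.counts.astype(float)
    ei_v = ei.reindex(matrix.species_ids).to_numpy(dtype=float)
    n_fam, n_sp = counts.shape

    r_obs, _ = _rowwise_pearson(counts, ei_v)
    valid = ~np.isnan(r_obs)
    obs_pos = int((r_obs[valid] > 0).sum())
    obs_neg = int((r_obs[valid] < 0).sum())
    n_zero = int((r_obs[valid] == 0).sum()) + int((~valid).sum())

    # precompute row-centered count matrix; a permutation of ei preserves
    # its mean and norm, so only the dot products change per replicate
    c = counts - counts.mean(axis=1, keepdims=True)
    c_norm = np.sqrt((c**2).sum(axis=1))
    ei_c = ei_v - ei_v.mean()
    ei_norm = np.sqrt((ei_c**2).sum())
    denom = c_norm * ei_norm

    bin_edges = np.linspace(-1.0, 1.0, n_bins + 1)
    obs_hist, _ = np.histogram(r_obs[valid], bins=bin_edges)
    null_hist = np.zeros(n_bins)
    null_pos = np.empty(n_permutations, dtype=np.int64)
    for b in range(n_permutations):
        if mode == "per_family":
            perm = np.argsort(rng.random((n_fam, n_sp)), axis=1)
            e = ei_c[perm]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.einsum("ij,ij->i", c, e) / denom
        else:
            e = ei_c[rng.permutation(n_sp)]
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (c @ e) / denom
        r = r[np.isfinite(r)]
        null_pos[b] = (r > 0).sum()
        h, _ = np.histogram(r, bins=bin_edges)
        null_hist += h
    null_hist /= n_permutations

    perm_p = (1.0 + (null_pos >= obs_pos).sum()) / (1.0 + n_permutations)
    chi2, chi2_p = chi_square_shift(obs_pos, obs_pos + obs_neg)
    q = np.quantile(null_pos, [0.025, 0.25, 0.5, 0.75, 0.975])
    return ShiftTestResult(
        n_total=n_fam,
        n_positive=obs_pos,
        n_negative=obs_neg,
        n_zero=n_zero,
        expected_positive=(obs_pos + obs_neg) / 2.0,
        shift=obs_pos - (obs_pos + obs_neg) / 2.0,
        chi2=chi2,
        chi2_p=chi2_p,
        perm_p=float(perm_p),
        n_permutations=n_permutations,
        null_positive_counts={
            "mean": float(null_pos.mean()),
            "sd": float(null_pos.std(ddof=1)),
            "q025": float(q[0]),
            "q25": float(q[1]),
            "median": float(q[2]),
            "q75": float(q[3]),
            "q975": float(q[4]),
        },
        histogram={
            "bin_edges": bin_edges,
            "observed": obs_hist,
            "null_mean": null_hist,
        },
        mode=mode,
    )


def overall_gene_number_correlation(
    matrix: GeneFamilyMatrix, ei: pd.Series
) -> tuple[float, float]:
    """Pearson correlation of per-species total gene count with Ei."""
    if matrix.counts.shape[1] < 3:
        raise ValueError("need at least 3 species")
    totals = matrix.counts.sum(axis=0).astype(float)
    if np.ptp(totals) == 0:
        raise ValueError("per-species totals have zero variance")
    ei_v = ei.reindex(matrix.species_ids).to_numpy(dtype=float)
    res = stats.pearsonr(totals, ei_v)
    return float(res.statistic), float(res.pvalue)


def partial_correlations(
    records: list[FamilyAssociationRecord],
    ei: pd.Series,
    mlsp: pd.Series,
) -> list[FamilyAssociationRecord]:
    """First-order partial correlation of GFS with Ei controlling MLSP.

    r_{xy.z} = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)) with a
    two-sided t test on n - 3 df; equivalent to the t test on the Ei
    coefficient in the multiple regression GFS ~ Ei + MLSP.
    """
    common = [s for s in ei.index if s in set(mlsp.index)]
    r_yz = float(np.corrcoef(ei.loc[common], mlsp.loc[common])[0, 1])
    if abs(r_yz) >= 1.0 - 1e-12:
        raise ValueError("Ei and MLSP are collinear; partial correlation undefined")
    for rec in records:
        if rec.zero_variance or np.isnan(rec.r_mlsp):
            rec.partial_r = float("nan")
            rec.partial_p = float("nan")
            continue
        num = rec.r_ei - rec.r_mlsp * r_yz
        den = np.sqrt((1.0 - rec.r_mlsp**2) * (1.0 - r_yz**2))
        pr = num / den if den > 0 else float("nan")
        pr = float(np.clip(pr, -1.0, 1.0))
        df = rec.n_species - 3
        if df <= 0 or np.isnan(pr):
            rec.partial_r, rec.partial_p = pr, float("nan")
            continue
        t = pr * np.sqrt(df / max(1.0 - pr**2, 1e-300))
        rec.partial_r = pr
        rec.partial_p = float(min(max(2.0 * stats.t.sf(abs(t), df=df), np.finfo(float).tiny), 1.0))
    return records


_STAGES = ("sig_ei", "preferential", "sig_partial")


def select_families(
    records: list[FamilyAssociationRecord],
    stage: str,
    alpha: float = 0.05,
) -> set[str]:
    """Apply one stage of the selection cascade and return the family set.

    sig_ei:      r_ei > 0 and p_ei < alpha
    preferential: sig_ei and r_ei > r_mlsp
    sig_partial: partial_r > 0 and partial_p < alpha
    """
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    out: set[str] = set()
    for rec in records:
        if rec.zero_variance:
            continue
        sig_ei = rec.r_ei > 0 and rec.p_ei < alpha
        if stage == "sig_ei" and sig_ei:
            out.add(rec.family_id)
        elif stage == "preferential" and sig_ei and rec.r_ei > rec.r_mlsp:
            out.add(rec.family_id)
        elif stage == "sig_partial":
            if not np.isnan(rec.partial_r) and rec.partial_r > 0 and rec.partial_p < alpha:
                out.add(rec.family_id)
        rec.flags["significant_ei"] = sig_ei
        rec.flags["preferential_ei"] = sig_ei and rec.r_ei > rec.r_mlsp
        if not np.isnan(rec.partial_r):
            rec.flags["significant_partial"] = rec.partial_r > 0 and rec.partial_p < alpha
    return out


def records_to_frame(records: list[FamilyAssociationRecord]) -> pd.DataFrame:
    """One row per family, suitable for TSV output."""
    return pd.DataFrame(
        {
            "family_id": [r.family_id for r in records],
            "r_ei": [r.r_ei for r in records],
            "p_ei": [r.p_ei for r in records],
            "r_mlsp": [r.r_mlsp for r in records],
            "p_mlsp": [r.p_mlsp for r in records],
            "partial_r": [r.partial_r for r in records],
            "partial_p": [r.partial_p for r in records],
            "n_species": [r.n_species for r in records],
            "zero_variance": [r.zero_variance for r in records],
        }
    )
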