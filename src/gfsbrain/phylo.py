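"""Pagel's lambda under a PGLS model of gene family size on Ei.

For each family, the model is y ~ N(X beta, sigma^2 C(lambda)) where
C(lambda) applies the Pagel transform to the tree's shared-path matrix:
off-diagonal elements scaled by lambda in [0, 1], diagonal (root-to-tip
depths) untouched, so non-ultrametric trees are handled. lambda is
estimated by bounded maximum likelihood (20-point grid pre-scan followed
by Brent refinement); likelihood-ratio tests against lambda = 0 and
lambda = 1 use a chi-square(1) reference without a boundary mixture
correction, which makes the lambda = 0 test conservative.

The elimination rule marks a family as phylogenetically confounded when
lambda is significantly above 0 AND indistinguishable from 1
(p_vs_0 < 0.05 and p_vs_1 > 0.05); such families are removed from the
selection cascade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .datatypes import GeneFamilyMatrix, Phylogeny

__all__ = [
    "LambdaFit",
    "phylo_covariance",
    "pgls_loglik",
    "fit_lambda",
    "fit_lambda_matrix",
    "phylo_filter",
]

_SIGMA2_FLOOR = 1e-12
_GRID = np.linspace(0.0, 1.0, 20)


@dataclass
class LambdaFit:
    family_id: str
    lambda_hat: float
    loglik_hat: float
    loglik_lambda0: float
    loglik_lambda1: float
    p_vs_0: float
    p_vs_1: float
    beta_ei: float
    degenerate: bool = False

    def eliminated(self, alpha0: float = 0.05, alpha1: float = 0.05) -> bool:
        return (self.p_vs_0 < alpha0) and (self.p_vs_1 > alpha1)


def phylo_covariance(tree: Phylogeny, species: list[str], lam: float) -> np.ndarray:
    """Pagel-transformed shared-path covariance for the given species order."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    C = tree.shared_path_matrix(species)
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def _apply_lambda(C: np.ndarray, lam: float) -> np.ndarray:
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def pgls_loglik(
    y: np.ndarray, X: np.ndarray, C: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """ML Gaussian log-likelihood of the GLS model y ~ N(X beta, sigma^2 C).

    beta = (X' C^-1 X)^-1 X' C^-1 y; sigma2 = r' C^-1 r / n (ML, not REML).
    Returns (loglik, beta, sigma2). Near-singular C gets one jitter of
    1e-10 * mean(diag); a singular design matrix is an error.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        C = C + 1e-10 * np.mean(np.diag(C)) * np.eye(n)
        L = np.linalg.cholesky(C)
    # whiten: solve L a = v  =>  a' a = v' C^-1 v
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    XtX = Xw.T @ Xw
    if np.linalg.cond(XtX) > 1e12:
        raise np.linalg.LinAlgError("singular X' C^-1 X")
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    sigma2 = max(float(resid @ resid) / n, _SIGMA2_FLOOR)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + logdet + n)
    return loglik, beta, sigma2


def _profile(C0: np.ndarray, y: np.ndarray, X: np.ndarray):
    def nll(lam: float) -> float:
        try:
            ll, _, _ = pgls_loglik(y, X, _apply_lambda(C0, lam))
        except np.linalg.LinAlgError:
            return np.inf
        return -ll

    return nll


def fit_lambda(
    tree: Phylogeny,
    y: pd.Series,
    x: pd.Series | None = None,
    family_id: str = "",
    C0: np.ndarray | None = None,
    species: list[str] | None = None,
) -> LambdaFit:
    """Profile-ML estimate of lambda for one family, with LRTs vs 0 and 1.

    `x` is the Ei predictor; pass None for an intercept-only model. A
    precomputed shared-path matrix `C0` (with matching `species` order)
    skips tree traversal when fitting many families.
    """
    if species is None:
        species = list(y.index)
    yv = y.reindex(species).to_numpy(dtype=float)
    if len(yv) < 4:
        raise ValueError("need at least 4 species")
    if np.ptp(yv) == 0:
        raise ValueError("zero-variance response")
    if x is not None:
        X = np.column_stack([np.ones(len(yv)), x.reindex(species).to_numpy(dtype=float)])
    else:
        X = np.ones((len(yv), 1))
    if C0 is None:
        C0 = tree.shared_path_matrix(species)

    off = C0[~np.eye(len(C0), dtype=bool)]
    if np.max(np.abs(off)) < 1e-12 * np.mean(np.diag(C0)):
        # star phylogeny: likelihood flat in lambda
        ll, beta, _ = pgls_loglik(yv, X, _apply_lambda(C0, 0.0))
        return LambdaFit(
            family_id=family_id,
            lambda_hat=0.0,
            loglik_hat=ll,
            loglik_lambda0=ll,
            loglik_lambda1=ll,
            p_vs_0=1.0,
            p_vs_1=1.0,
            beta_ei=float(beta[-1]) if x is not None else float("nan"),
            degenerate=True,
        )

    nll = _profile(C0, yv, X)
    grid_vals = np.array([nll(g) for g in _GRID])
    i = int(np.argmin(grid_vals))
    lo = _GRID[max(i - 1, 0)]
    hi = _GRID[min(i + 1, len(_GRID) - 1)]
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-6})
    lam_hat = float(np.clip(res.x, 0.0, 1.0))
    ll_hat = -float(res.fun)
    # never report a worse optimum than the grid or the boundaries
    ll0 = -nll(0.0)
    ll1 = -nll(1.0)
    for cand_lam, cand_ll in ((0.0, ll0), (1.0, ll1), (float(_GRID[i]), -grid_vals[i])):
        if cand_ll > ll_hat:
            lam_hat, ll_hat = cand_lam, cand_ll
    _, beta, _ = pgls_loglik(yv, X, _apply_lambda(C0, lam_hat))
    lr0 = max(0.0, 2.0 * (ll_hat - ll0))
    lr1 = max(0.0, 2.0 * (ll_hat - ll1))
    return LambdaFit(
        family_id=family_id,
        lambda_hat=lam_hat,
        loglik_hat=ll_hat,
        loglik_lambda0=ll0,
        loglik_lambda1=ll1,
        p_vs_0=float(stats.chi2.sf(lr0, df=1)) if lr0 > 0 else 1.0,
        p_vs_1=float(stats.chi2.sf(lr1, df=1)) if lr1 > 0 else 1.0,
        beta_ei=float(beta[-1]) if x is not None else float("nan"),
    )


def fit_lambda_matrix(
    tree: Phylogeny,
    matrix: GeneFamilyMatrix,
    ei: pd.Series,
    families: list[str] | None = None,
    log_counts: bool = True,
) -> dict[str, LambdaFit]:
    """Fit lambda for each requested family of a count matrix (shared C0).

    By default the response is log(1 + GFS): copy numbers are heavy-tailed
    and a Gaussian PGLS on raw counts lets a single copy-rich species
    dominate the likelihood; the log scale is the conventional one for
    size traits. Set log_counts=False to fit raw counts.
    """
    species = list(matrix.species_ids)
    C0 = tree.shared_path_matrix(species)
    x = ei.reindex(species)
    fits: dict[str, LambdaFit] = {}
    want = set(families) if families is not None else None
    for i, fid in enumerate(matrix.family_ids):
        if want is not None and fid not in want:
            continue
        yv = matrix.counts[i].astype(float)
        if log_counts:
            yv = np.log1p(yv)
        yv = pd.Series(yv, index=species)
        if np.ptp(yv.to_numpy()) == 0:
            continue  # zero-variance family: skipped, cannot be fit
        fits[fid] = fit_lambda(tree, yv, x, family_id=fid, C0=C0, species=species)
    return fits


def phylo_filter(
    fits: dict[str, LambdaFit], alpha0: float = 0.05, alpha1: float = 0.05
) -> set[str]:
    """Retain families WITHOUT significant phylogenetic interdependence.

    Eliminated iff p_vs_0 < alpha0 and p_vs_1 > alpha1.
    """
    return {fid for fid, fit in fits.items() if not fit.eliminated(alpha0, alpha1)}
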