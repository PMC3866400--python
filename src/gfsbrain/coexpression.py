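"""Weighted co-expression network analysis over developmental samples.

Adjacency a_ij = |cor(x_i, x_j)|^beta (unsigned network); beta is chosen
as the smallest power whose connectivity distribution approximates a
scale-free law (R^2 of the log-log degree histogram >= target).
Topological overlap (TOM) similarity augments direct adjacency with
shared-neighbourhood strength; modules are detected by average-linkage
hierarchical clustering of 1 - TOM with a static cut, small clusters
falling back to module 0 (unassigned). Each module is summarized by its
eigengene (first principal component of the member genes' z-scored
profiles) and its hub gene (highest intramodular connectivity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "CoexpressionModuleSet",
    "adjacency_matrix",
    "select_soft_threshold",
    "scale_free_fit",
    "topological_overlap",
    "detect_modules",
    "module_eigengene",
    "hub_genes",
    "run_wgcna",
]


@dataclass
class CoexpressionModuleSet:
    beta: int
    assignment: pd.Series  # gene -> module id (0 = unassigned)
    eigengenes: pd.DataFrame  # samples x modules, unit-norm columns
    hubs: dict[int, str]
    parameters: dict = field(default_factory=dict)


def adjacency_matrix(values: pd.DataFrame, beta: int, signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded adjacency from gene x sample expression."""
    corr = np.corrcoef(values.to_numpy(dtype=float))
    corr = np.nan_to_num(corr, nan=0.0)
    if signed:
        a = ((1.0 + corr) / 2.0) ** beta
    else:
        a = np.abs(corr) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=values.index, columns=values.index)


def scale_free_fit(adjacency: pd.DataFrame, n_bins: int = 10) -> float:
    """Signed scale-free fit index over connectivity bins.

    R^2 of log10(freq) vs log10(mean k), multiplied by -sign(slope): a
    scale-free degree distribution has decreasing frequency in k, so a
    positive-slope fit (many high-connectivity genes) scores negatively
    and is never selected.
    """
    k = np.asarray(adjacency).sum(axis=1)
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() > 0:
            xs.append(np.log10(k[mask].mean()))
            ys.append(np.log10(mask.sum()))
    if len(xs) < 3:
        return 0.0
    if max(xs) - min(xs) < 0.3:
        # connectivity spans < 2x: a power-law fit over such a degenerate
        # range is meaningless, so report no fit rather than a spurious R^2
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    if not np.isfinite(r):
        return 0.0
    return float(-np.sign(r) * r**2)


def select_soft_threshold(
    values: pd.DataFrame,
    candidate_betas: list[int] | None = None,
    rsq_target: float = 0.8,
) -> int:
    """Smallest beta achieving the scale-free fit target, else argmax R^2."""
    if values.shape[1] < 8:
        raise ValueError("need at least 8 samples")
    if values.shape[0] < 30:
        raise ValueError("need at least 30 genes for a stable scale-free fit")
    if candidate_betas is None:
        candidate_betas = list(range(1, 21))
    corr = np.abs(np.nan_to_num(np.corrcoef(values.to_numpy(dtype=float)), nan=0.0))
    np.fill_diagonal(corr, 0.0)
    best_beta, best_rsq = candidate_betas[0], -1.0
    for beta in candidate_betas:
        a = corr**beta
        rsq = scale_free_fit(pd.DataFrame(a, index=values.index, columns=values.index))
        if rsq >= rsq_target:
            return int(beta)
        if rsq > best_rsq:
            best_beta, best_rsq = beta, rsq
    warnings.warn(
        f"no candidate beta reached R^2 >= {rsq_target}; using beta={best_beta} "
        f"(max R^2 = {best_rsq:.3f})",
        stacklevel=2,
    )
    return int(best_beta)


def topological_overlap(adjacency: pd.DataFrame | np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij); TOM_ii = 1."""
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be square and symmetric")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / den
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    tom_dissim: np.ndarray,
    gene_ids: list[str],
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters smaller than `min_module_size` become module 0 (unassigned);
    surviving modules are labelled 1, 2, ... by decreasing size.
    """
    d = np.asarray(tom_dissim, dtype=float)
    n = d.shape[0]
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size: all unassigned", stacklevel=2)
        return pd.Series(0, index=gene_ids)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    max_h = link[:, 2].max()
    raw = hierarchy.fcluster(link, t=cut_height * max_h, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    keep = sizes[sizes >= min_module_size].index
    # deterministic labels: by decreasing size, ties by smallest member index
    order = sorted(
        keep,
        key=lambda c: (-sizes[c], int(np.flatnonzero(raw == c)[0])),
    )
    relabel = {c: i + 1 for i, c in enumerate(order)}
    out = np.array([relabel.get(c, 0) for c in raw])
    return pd.Series(out, index=gene_ids)


_MODULE_COLOURS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]


def module_colour(module_id: int) -> str:
    """Deterministic colour alias for a module id (0 = grey/unassigned)."""
    if module_id == 0:
        return "grey"
    return _MODULE_COLOURS[(module_id - 1) % len(_MODULE_COLOURS)]


def module_eigengene(values: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """First-PC eigengene per module over the given samples.

    Member genes are z-scored across samples before the SVD; the
    eigengene (sample-score vector) is unit-normalized and sign-oriented
    so its mean correlation with member genes is non-negative. Modules
    whose genes are all constant raise a flagging error for that module
    (column filled with NaN).
    """
    eigengenes = {}
    for mod in sorted(set(assignment) - {0}):
        genes = assignment.index[assignment == mod]
        if len(genes) < 2:
            continue
        sub = values.loc[genes].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=0)
        keep = sd > 0
        if keep.sum() == 0:
            eigengenes[mod] = np.full(values.shape[1], np.nan)
            continue
        z = (sub[keep] - sub[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        eg = vt[0]
        eg = eg / np.linalg.norm(eg)
        cors = np.array([np.corrcoef(eg, row)[0, 1] for row in z])
        if np.nanmean(cors) < 0:
            eg = -eg
        eigengenes[mod] = eg
    return pd.DataFrame(eigengenes, index=values.columns)


def hub_genes(adjacency: pd.DataFrame, assignment: pd.Series) -> dict[int, str]:
    """Per module, the gene with maximal intramodular connectivity.

    Ties break lexicographically by gene id.
    """
    a = adjacency.to_numpy()
    ids = list(adjacency.index)
    pos = {g: i for i, g in enumerate(ids)}
    hubs: dict[int, str] = {}
    for mod in sorted(set(assignment) - {0}):
        members = [g for g in assignment.index[assignment == mod] if g in pos]
        if not members:
            continue
        midx = np.array([pos[g] for g in members])
        kin = a[np.ix_(midx, midx)].sum(axis=1)
        best = kin.max()
        winners = sorted(members[i] for i in np.flatnonzero(kin >= best - 1e-15))
        hubs[mod] = winners[0]
    return hubs


def run_wgcna(
    values: pd.DataFrame,
    beta: int | None = None,
    min_module_size: int = 30,
    cut_height: float = 0.99,
    rsq_target: float = 0.8,
    signed: bool = False,
) -> CoexpressionModuleSet:
    """Full network pipeline: beta selection -> TOM -> modules -> eigengenes."""
    if beta is None:
        beta = select_soft_threshold(values, rsq_target=rsq_target)
    adj = adjacency_matrix(values, beta=beta, signed=signed)
    tom = topological_overlap(adj)
    assignment = detect_modules(
        1.0 - tom, list(values.index), min_module_size=min_module_size, cut_height=cut_height
    )
    eig = module_eigengene(values, assignment)
    hubs = hub_genes(adj, assignment)
    return CoexpressionModuleSet(
        beta=int(beta),
        assignment=assignment,
        eigengenes=eig,
        hubs=hubs,
        parameters={
            "min_module_size": min_module_size,
            "cut_height": cut_height,
            "rsq_target": rsq_target,
            "signed": signed,
        },
    )
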