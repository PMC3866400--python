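"""Synthetic-data generators with planted, recorded ground truth.

Each generator emulates one input of the analysis: a birth-death species
phylogeny, allometric brain/body masses with a lifespan confounder,
Poisson gene-family-count matrices in which configurable fractions of
families track the encephalization index (Ei), maximum lifespan (MLSP),
or phylogeny alone, GO annotations with a controllable per-family
density bias, and multi-tissue / developmental expression with planted
co-expression modules. Every planted id is recorded in a
:class:`~gfsbrain.datatypes.SyntheticTruth`.

Counts are Poisson around a log-linear predictor rather than explicit
birth-death gain/loss along the tree; phylogenetic confounding enters
through a Brownian deviate added to the predictor. This gives direct
control of effect sizes and truth labels.
"""

from __future__ import annotations

import random

import dendropy
import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GeneFamilyMatrix,
    Phylogeny,
    SpeciesTraitTable,
    SyntheticTruth,
)

__all__ = [
    "simulate_tree",
    "simulate_traits",
    "simulate_gfs",
    "simulate_go",
    "simulate_expression",
]


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) tree with `n_tips` extant tips, labelled s001...

    Tips are relabelled deterministically in leaf-iteration order so that
    the same seed always yields the same Newick string.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = random.Random(seed)
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    width = max(3, len(str(n_tips)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"s{i:0{width}d}"
    # the simulator stops at the n-th speciation, which leaves the last
    # daughter branches with zero length; evolve the tree onward by the
    # waiting time to the (n+1)-th event so terminal branches are positive
    extra = rng.expovariate(n_tips * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and (edge.length is None or edge.length <= 0):
            edge.length = max(edge.length or 0.0, 1e-8)
    return Phylogeny(tree)


def _brownian_cov(phylo: Phylogeny, species: list[str]) -> np.ndarray:
    """Shared-path covariance scaled to unit mean tip variance."""
    C = phylo.shared_path_matrix(species)
    scale = np.mean(np.diag(C))
    if scale <= 0:
        raise ValueError("tree has zero depth")
    return C / scale


def _mvn_on_tree(C: np.ndarray, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    L = np.linalg.cholesky(C + 1e-10 * np.eye(len(C)))
    z = rng.standard_normal((size, len(C)))
    return z @ L.T


def simulate_traits(
    tree: Phylogeny,
    allometric_slope: float = 0.75,
    allometric_intercept: float = -1.3,
    ei_sd: float = 0.25,
    mlsp_ei_corr: float = 0.79,
    seed: int = 0,
    body_mean_log10: float = 3.5,
    body_sd_log10: float = 1.5,
    mlsp_mean_yr: float = 30.0,
    mlsp_sd_yr: float = 10.0,
) -> tuple[SpeciesTraitTable, pd.Series]:
    """Allometric traits on a tree, with MLSP correlated with true Ei.

    log10 body mass evolves by Brownian motion on the tree; log10 brain =
    intercept + slope * log10 body + e with e ~ N(0, ei_sd^2) iid across
    tips (e is the true Ei). MLSP is an affine monotone transform of
    rho * z(e) + sqrt(1 - rho^2) * noise, floored at 1 yr, so the realized
    Pearson correlation with true Ei approaches `mlsp_ei_corr` as n grows.
    Returns the trait table (true Ei pre-attached) and the true-Ei series.
    """
    if ei_sd <= 0:
        raise ValueError("ei_sd must be positive")
    if abs(mlsp_ei_corr) > 1:
        raise ValueError("mlsp_ei_corr must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    species = tree.tip_labels
    C = _brownian_cov(tree, species)
    bm = _mvn_on_tree(C, rng)[0]
    log_body = body_mean_log10 + body_sd_log10 * bm
    e = rng.normal(0.0, ei_sd, size=len(species))
    log_brain = allometric_intercept + allometric_slope * log_body + e
    z = (e - e.mean()) / e.std() if e.std() > 0 else np.zeros_like(e)
    eta = rng.standard_normal(len(species))
    w = mlsp_ei_corr * z + np.sqrt(max(0.0, 1.0 - mlsp_ei_corr**2)) * eta
    mlsp = np.maximum(mlsp_mean_yr + mlsp_sd_yr * w, 1.0)
    data = pd.DataFrame(
        {
            "brain_mass_g": 10.0**log_brain,
            "body_mass_g": 10.0**log_body,
            "mlsp_yr": mlsp,
        },
        index=pd.Index(species, name="species"),
    )
    true_ei = pd.Series(e, index=data.index, name="true_ei")
    table = SpeciesTraitTable(data=data)
    table.ei = true_ei.copy()
    table.ei_source = "true"
    return table, true_ei


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std()
    return (v - v.mean()) / s if s > 0 else np.zeros_like(v)


def simulate_gfs(
    tree: Phylogeny,
    traits: SpeciesTraitTable,
    n_families: int,
    frac_ei: float = 0.0,
    frac_mlsp: float = 0.0,
    frac_phylo: float = 0.0,
    effect_size: float = 1.0,
    base_log_mean: float = 1.0,
    seed: int = 0,
    min_present_species: int = 6,
    true_ei: pd.Series | None = None,
    genes_per_family_mean: float = 3.0,
) -> tuple[GeneFamilyMatrix, SyntheticTruth]:
    """Family x species Poisson counts with planted Ei/MLSP/phylogeny links.

    counts ~ Poisson(exp(base_log_mean + beta * x_s + phi_s)) where x_s is
    standardized true Ei (ei-linked), standardized MLSP (mlsp-linked) or 0;
    beta = effect_size for linked families; phi_s is a unit-variance
    Brownian deviate on the tree for phylo-only families. Families failing
    the presence rule (count > 0 in >= `min_present_species` species) are
    redrawn; persistent violators are dropped and recorded.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if frac_ei + frac_mlsp + frac_phylo > 1 + 1e-12:
        raise ValueError("planted fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    species = tree.tip_labels
    if list(traits.data.index) != species:
        traits_data = traits.data.reindex(species)
    else:
        traits_data = traits.data
    ei_vec = (true_ei if true_ei is not None else traits.require_ei()).reindex(species).to_numpy()
    z_ei = _standardize(ei_vec)
    mlsp_raw = traits_data["mlsp_yr"].to_numpy(dtype=float)
    z_mlsp = _standardize(mlsp_raw) if not np.isnan(mlsp_raw).any() else np.zeros(len(species))
    C = _brownian_cov(tree, species)
    L = np.linalg.cholesky(C + 1e-10 * np.eye(len(C)))

    n_ei = int(np.floor(frac_ei * n_families))
    n_mlsp = int(np.floor(frac_mlsp * n_families))
    n_phylo = int(np.floor(frac_phylo * n_families))
    width = max(4, len(str(n_families)))
    fam_ids = [f"fam{i + 1:0{width}d}" for i in range(n_families)]
    classes = np.array(
        ["ei"] * n_ei + ["mlsp"] * n_mlsp + ["phylo"] * n_phylo
        + ["null"] * (n_families - n_ei - n_mlsp - n_phylo)
    )

    def draw_row(cls: str) -> np.ndarray:
        if cls == "ei":
            x = effect_size * z_ei
        elif cls == "mlsp":
            x = effect_size * z_mlsp
        else:
            x = np.zeros(len(species))
        phi = (rng.standard_normal(len(species)) @ L.T) if cls == "phylo" else 0.0
        lam = np.exp(base_log_mean + x + phi)
        return rng.poisson(lam)

    counts = np.zeros((n_families, len(species)), dtype=np.int64)
    dropped: list[str] = []
    for i, cls in enumerate(classes):
        row = draw_row(cls)
        attempts = 0
        while (row > 0).sum() < min_present_species and attempts < 20:
            row = draw_row(cls)
            attempts += 1
        if (row > 0).sum() < min_present_species:
            dropped.append(fam_ids[i])
        counts[i] = row
    keep = np.array([f not in set(dropped) for f in fam_ids])
    fam_ids = [f for f, k in zip(fam_ids, keep) if k]
    counts = counts[keep]
    classes = classes[keep]

    # genes per family: reference-species copy number, at least one gene
    membership: dict[str, str] = {}
    for i, fid in enumerate(fam_ids):
        n_genes = max(1, int(counts[i, 0]))
        for g in range(n_genes):
            membership[f"{fid}_g{g + 1:03d}"] = fid

    matrix = GeneFamilyMatrix(
        family_ids=fam_ids, species_ids=list(species), counts=counts, gene_membership=membership
    )
    truth = SyntheticTruth(
        ei_linked_families={f for f, c in zip(fam_ids, classes) if c == "ei"},
        mlsp_linked_families={f for f, c in zip(fam_ids, classes) if c == "mlsp"},
        phylo_only_families={f for f, c in zip(fam_ids, classes) if c == "phylo"},
        generator_params={
            "n_families": n_families,
            "frac_ei": frac_ei,
            "frac_mlsp": frac_mlsp,
            "frac_phylo": frac_phylo,
            "effect_size": effect_size,
            "base_log_mean": base_log_mean,
            "seed": seed,
            "min_present_species": min_present_species,
            "dropped_families": dropped,
        },
    )
    return matrix, truth


def simulate_go(
    families: list[str],
    n_terms: int = 100,
    mean_families_per_term: int = 60,
    planted_terms: int = 0,
    plant_fold: float = 1.0,
    target_set: set[str] | None = None,
    density_bias: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, set[str]], SyntheticTruth]:
    """Term -> family annotation map with optional planted enrichment.

    Each term draws member families without replacement; planted terms
    sample `target_set` families at `plant_fold` x the background rate.
    With density_bias > 0, target-set families receive proportionally
    more annotations across ALL terms (weight `density_bias` vs 1),
    inflating raw per-term counts without any term-specific structure —
    the situation the annotation-density adjustment corrects.
    """
    if plant_fold < 1:
        raise ValueError("plant_fold must be >= 1")
    if planted_terms > n_terms:
        raise ValueError("planted_terms exceeds n_terms")
    target = set(target_set or set())
    rng = np.random.default_rng(seed)
    fam = np.array(families)
    in_target = np.array([f in target for f in fam], dtype=float)
    base_w = np.where((in_target > 0) & (density_bias > 0), density_bias, 1.0)
    term_ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    planted = (
        {str(t) for t in rng.choice(term_ids, size=planted_terms, replace=False)}
        if planted_terms
        else set()
    )
    go_map: dict[str, set[str]] = {}
    for t in term_ids:
        size = min(len(fam), max(2, int(rng.poisson(mean_families_per_term))))
        w = base_w * np.where((in_target > 0) & (t in planted), plant_fold, 1.0)
        p = w / w.sum()
        members = rng.choice(fam, size=size, replace=False, p=p)
        go_map[t] = {str(f) for f in members}
    truth = SyntheticTruth(
        enriched_terms=planted,
        generator_params={
            "n_terms": n_terms,
            "mean_families_per_term": mean_families_per_term,
            "planted_terms": planted_terms,
            "plant_fold": plant_fold,
            "density_bias": density_bias,
            "seed": seed,
        },
    )
    return go_map, truth


def go_map_to_gene_pairs(
    go_map: dict[str, set[str]], membership: dict[str, str]
) -> dict[str, set[str]]:
    """Expand a term -> family map to term -> gene via one member gene each."""
    fam_to_gene: dict[str, str] = {}
    for gene, fid in sorted(membership.items()):
        fam_to_gene.setdefault(fid, gene)
    return {
        t: {fam_to_gene[f] for f in fams if f in fam_to_gene} for t, fams in go_map.items()
    }


def simulate_expression(
    genes: list[str],
    n_tissues: int = 16,
    brain_fraction_prominent: float = 0.0,
    regions: tuple[int, int, int] = (4, 4, 4),
    dev_timepoints: list[float] | None = None,
    n_modules: int = 0,
    module_corr: float = 0.8,
    noise_sd: float = 1.0,
    seed: int = 0,
    dev_fraction: float = 0.0,
    hub_loading_ratio: float = 1.0 / 0.6,
    baseline: float = 10.0,
    module_fraction: float = 1.0,
    prominent_target_genes: set[str] | None = None,
    dev_target_genes: set[str] | None = None,
    target_fold: float = 3.0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Multi-tissue + regional + developmental expression with planted structure.

    Columns:
      * one sample per tissue (`tissue_brain`, `tissue_02`...), region "other";
      * adult brain samples per region (CX, SC, CB) per `regions` counts;
      * one cortical (CX) sample per developmental age in `dev_timepoints`
        (years relative to birth; negative = prenatal).

    Planted structure: a `brain_fraction_prominent` fraction of genes have
    their brain-tissue value drawn above every other tissue; a
    `module_fraction` subset of genes is split into `n_modules` modules,
    each sharing a latent developmental curve with loadings giving
    pairwise correlation ~= module_corr (one hub per module carries a
    `hub_loading_ratio`-times-larger loading); a `dev_fraction` of
    non-module genes get a high-amplitude early (age <= 18) excursion.
    When `prominent_target_genes` / `dev_target_genes` are given, those
    genes are `target_fold` times as likely to be planted, coupling the
    expression signatures to a chosen gene set. Metadata carries a
    `panel` column (tissue | regional | developmental) naming each
    sample block.
    """
    if n_modules and not (0 < module_corr < 1):
        raise ValueError("module_corr must lie in (0, 1)")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if dev_timepoints is None:
        dev_timepoints = [-0.5, -0.25, 0.5, 1, 2, 4, 8, 13, 18, 25, 30, 40]
    rng = np.random.default_rng(seed)
    genes = list(genes)
    n_genes = len(genes)

    def _weighted_pick(n_pick: int, targets: set[str] | None) -> np.ndarray:
        if n_pick == 0:
            return np.array([], dtype=int)
        w = np.ones(n_genes)
        if targets:
            w[[i for i, g in enumerate(genes) if g in targets]] = target_fold
        return rng.choice(n_genes, size=n_pick, replace=False, p=w / w.sum())

    # --- tissue panel ---
    tissue_names = ["brain"] + [f"tissue{i:02d}" for i in range(2, n_tissues + 1)]
    tissue_vals = baseline + rng.gamma(2.0, 2.0, size=(n_genes, n_tissues))
    n_prom = int(round(brain_fraction_prominent * n_genes))
    prom_idx = _weighted_pick(n_prom, prominent_target_genes)
    if n_prom:
        others_max = tissue_vals[prom_idx, 1:].max(axis=1)
        tissue_vals[prom_idx, 0] = others_max * (1.2 + 0.3 * rng.random(n_prom))

    # --- adult regional brain samples ---
    region_labels = ["CX"] * regions[0] + ["SC"] * regions[1] + ["CB"] * regions[2]
    regional_vals = baseline + rng.gamma(2.0, 2.0, size=(n_genes, len(region_labels)))

    # --- developmental cortical series ---
    ages = np.asarray(dev_timepoints, dtype=float)
    n_dev = len(ages)
    module_labels = np.zeros(n_genes, dtype=int)
    hub: dict[int, str] = {}
    dev_vals = baseline + noise_sd * rng.standard_normal((n_genes, n_dev))
    if n_modules:
        if n_dev < n_modules + 1:
            raise ValueError("need more developmental timepoints than modules")
        n_module_genes = int(round(module_fraction * n_genes))
        per_mod = n_module_genes // n_modules
        loading = noise_sd * np.sqrt(module_corr / (1.0 - module_corr))
        order = rng.permutation(n_genes)
        t01 = (ages - ages.min()) / (ages.max() - ages.min() + 1e-12)
        # smooth random curves, orthogonalized across modules so planted
        # modules are mutually uncorrelated by construction
        raw = np.column_stack(
            [
                rng.standard_normal() * np.sin(np.pi * t01 * (1 + m % 4))
                + rng.standard_normal() * t01
                + rng.standard_normal() * t01**2
                + 0.3 * rng.standard_normal(n_dev)
                for m in range(n_modules)
            ]
        )
        raw = raw - raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)
        curves = q / q.std(axis=0)
        for m in range(1, n_modules + 1):
            idx = order[(m - 1) * per_mod : m * per_mod]
            if len(idx) < 2:
                continue
            curve = curves[:, m - 1]
            module_labels[idx] = m
            hub_gene_idx = idx[0]
            for gi in idx:
                a = loading * (hub_loading_ratio if gi == hub_gene_idx else 1.0)
                dev_vals[gi] = baseline + a * curve + noise_sd * rng.standard_normal(n_dev)
            hub[m] = genes[hub_gene_idx]

    n_devplant = int(round(dev_fraction * n_genes))
    dev_gene_idx = np.array([], dtype=int)
    if n_devplant:
        eligible = np.where(module_labels == 0)[0]
        n_devplant = min(n_devplant, len(eligible))
        w = np.ones(len(eligible))
        if dev_target_genes:
            w[[k for k, i in enumerate(eligible) if genes[i] in dev_target_genes]] = target_fold
        dev_gene_idx = rng.choice(eligible, size=n_devplant, replace=False, p=w / w.sum())
        early = ages <= 18
        amp = 5.0 * noise_sd
        for gi in dev_gene_idx:
            dev_vals[gi, early] += amp * rng.standard_normal(early.sum())

    dev_vals = np.maximum(dev_vals, 0.0)
    tissue_vals = np.maximum(tissue_vals, 0.0)
    regional_vals = np.maximum(regional_vals, 0.0)

    cols, meta_rows = [], []
    blocks = []
    for i, t in enumerate(tissue_names):
        cols.append(f"tis_{t}")
        meta_rows.append((f"tis_{t}", t, "other", 35.0, "years", "postnatal", "tissue"))
    blocks.append(tissue_vals)
    for j, reg in enumerate(region_labels):
        sid = f"adult_{reg}_{j + 1:02d}"
        cols.append(sid)
        meta_rows.append((sid, "brain", reg, 35.0, "years", "postnatal", "regional"))
    blocks.append(regional_vals)
    for j, age in enumerate(ages):
        sid = f"dev_CX_{j + 1:02d}"
        cols.append(sid)
        meta_rows.append(
            (sid, "brain", "CX", float(age), "years",
             "prenatal" if age < 0 else "postnatal", "developmental")
        )
    blocks.append(dev_vals)

    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=cols)
    metadata = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "tissue", "region", "age_value", "age_unit", "period", "panel"],
    ).set_index("sample_id")
    expr = ExpressionMatrix(values=values, metadata=metadata)
    truth = SyntheticTruth(
        module_labels={genes[i]: int(module_labels[i]) for i in range(n_genes)},
        prominent_genes={genes[i] for i in prom_idx},
        developmental_genes={genes[i] for i in dev_gene_idx},
        hub_genes=hub,
        generator_params={
            "n_tissues": n_tissues,
            "brain_fraction_prominent": brain_fraction_prominent,
            "regions": list(regions),
            "dev_timepoints": list(map(float, ages)),
            "n_modules": n_modules,
            "module_corr": module_corr,
            "noise_sd": noise_sd,
            "dev_fraction": dev_fraction,
            "seed": seed,
        },
    )
    return expr, truth
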