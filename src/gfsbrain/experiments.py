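"""Planted-truth validation experiments for the analysis cascade.

Each experiment generates data with the synthetic module under stated
conditions, runs the corresponding pipeline step, and returns summary
rates. The acceptance test suite asserts the expected behavior on these
experiments; ``scripts/acceptance.py`` reports their values. All
randomness flows from the caller's seed.

Problem sizes are chosen so each experiment completes in seconds to a
few minutes on one core; the methods note records the conditions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import association as assoc
from . import coexpression as coex
from . import encephalization as ence
from . import expression as exprmod
from . import go_enrichment as goe
from . import phylo as phy
from . import synthetic as syn

__all__ = [
    "null_shift_calibration",
    "planted_recovery",
    "confounder_removal",
    "lambda_recovery",
    "phylo_filter_discrimination",
    "go_density_adjustment",
    "prominence_null_fraction",
    "module_recovery",
    "oracle_equivalences",
]


def _clade(n_species: int, seed: int, mlsp_ei_corr: float = 0.79):
    tree = syn.simulate_tree(n_species, seed=seed)
    traits, true_ei = syn.simulate_traits(tree, mlsp_ei_corr=mlsp_ei_corr, seed=seed + 1)
    return tree, traits, true_ei


def null_shift_calibration(
    n_runs: int = 30,
    n_families: int = 2000,
    n_species: int = 40,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Shift-test rejection rate and per-tail selection fraction under the null.

    No planted effects: the permutation test should reject at ~alpha and
    the positive-tail significant fraction should sit near alpha/2.
    """
    rejections = 0
    fracs = []
    for run in range(n_runs):
        s = seed + 97 * run
        tree, traits, true_ei = _clade(n_species, s)
        matrix, _ = syn.simulate_gfs(tree, traits, n_families, seed=s + 2, true_ei=true_ei)
        ence.compute_ei(traits)
        records = assoc.family_correlations(matrix, traits.require_ei(), traits.mlsp())
        sig = assoc.select_families(records, "sig_ei", alpha=alpha)
        fracs.append(len(sig) / len(records))
        shift = assoc.permutation_shift_test(
            matrix, traits.require_ei(), n_permutations=n_permutations, seed=s + 3
        )
        rejections += shift.perm_p <= alpha
    return {
        "n_runs": n_runs,
        "rejections": int(rejections),
        "mean_sig_ei_fraction": float(np.mean(fracs)),
        "sig_ei_fractions": fracs,
        "n_families": n_families,
    }


def planted_recovery(
    n_seeds: int = 10,
    n_families: int = 1000,
    n_species: int = 40,
    frac_ei: float = 0.2,
    effect_size: float = 1.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Recall and FDR of the sig_ei selection against the planted truth."""
    recalls, fdrs = [], []
    for run in range(n_seeds):
        s = seed + 131 * run
        tree, traits, true_ei = _clade(n_species, s)
        matrix, truth = syn.simulate_gfs(
            tree, traits, n_families, frac_ei=frac_ei, effect_size=effect_size,
            seed=s + 2, true_ei=true_ei,
        )
        ence.compute_ei(traits)
        records = assoc.family_correlations(matrix, traits.require_ei(), traits.mlsp())
        sig = assoc.select_families(records, "sig_ei", alpha=alpha)
        truth_set = truth.ei_linked_families
        recalls.append(len(sig & truth_set) / len(truth_set))
        fdrs.append(len(sig - truth_set) / len(sig) if sig else 0.0)
    return {
        "recall": float(np.mean(recalls)),
        "fdr": float(np.mean(fdrs)),
        "n_seeds": n_seeds,
        "n_families": n_families,
    }


def confounder_removal(
    n_seeds: int = 10,
    n_families: int = 1000,
    n_species: int = 40,
    frac_ei: float = 0.2,
    frac_mlsp: float = 0.2,
    effect_size: float = 1.0,
    mlsp_ei_corr: float = 0.79,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Exclusion of MLSP-linked families by the partial-correlation stage.

    Returns the fraction of planted mlsp-linked families absent from the
    sig_partial selection, and the change in ei-linked recall between the
    sig_ei and sig_partial stages.
    """
    exclusions, drops = [], []
    for run in range(n_seeds):
        s = seed + 173 * run
        tree, traits, true_ei = _clade(n_species, s, mlsp_ei_corr=mlsp_ei_corr)
        matrix, truth = syn.simulate_gfs(
            tree, traits, n_families, frac_ei=frac_ei, frac_mlsp=frac_mlsp,
            effect_size=effect_size, seed=s + 2, true_ei=true_ei,
        )
        ence.compute_ei(traits)
        records = assoc.family_correlations(matrix, traits.require_ei(), traits.mlsp())
        assoc.partial_correlations(records, traits.require_ei(), traits.require_mlsp())
        sig_ei = assoc.select_families(records, "sig_ei", alpha=alpha)
        sig_partial = assoc.select_families(records, "sig_partial", alpha=alpha)
        ml, ei = truth.mlsp_linked_families, truth.ei_linked_families
        exclusions.append(1.0 - len(ml & sig_partial) / len(ml))
        drops.append(len(ei & sig_ei) / len(ei) - len(ei & sig_partial) / len(ei))
    return {
        "mlsp_exclusion_rate": float(np.mean(exclusions)),
        "ei_recall_drop": float(np.mean(drops)),
        "n_seeds": n_seeds,
    }


def lambda_recovery(
    n_tips: int = 64,
    n_replicates: int = 100,
    seed: int = 0,
) -> dict:
    """ML lambda recovery on Brownian vs iid Gaussian tip traits."""
    tree = syn.simulate_tree(n_tips, seed=seed)
    C = tree.shared_path_matrix(tree.tip_labels)
    C = C / np.mean(np.diag(C))
    L = np.linalg.cholesky(C + 1e-10 * np.eye(n_tips))
    rng = np.random.default_rng(seed + 1)
    bm_lams, bm_p1_ok, iid_lams, iid_p0_ok = [], 0, [], 0
    for _ in range(n_replicates):
        y_bm = pd.Series(rng.standard_normal(n_tips) @ L.T, index=tree.tip_labels)
        fit = phy.fit_lambda(tree, y_bm)
        bm_lams.append(fit.lambda_hat)
        bm_p1_ok += fit.p_vs_1 > 0.05
        y_iid = pd.Series(rng.standard_normal(n_tips), index=tree.tip_labels)
        fit0 = phy.fit_lambda(tree, y_iid)
        iid_lams.append(fit0.lambda_hat)
        iid_p0_ok += fit0.p_vs_0 > 0.05
    return {
        "mean_lambda_brownian": float(np.mean(bm_lams)),
        "frac_p_vs_1_above_05_brownian": bm_p1_ok / n_replicates,
        "mean_lambda_iid": float(np.mean(iid_lams)),
        "frac_p_vs_0_above_05_iid": iid_p0_ok / n_replicates,
        "n_replicates": n_replicates,
    }


def phylo_filter_discrimination(
    n_seeds: int = 10,
    n_families: int = 160,
    n_species: int = 40,
    base_log_mean: float = 5.0,
    seed: int = 0,
) -> dict:
    """Elimination rates for planted phylogeny-only vs Ei-linked families.

    Copy-rich families (exp(base_log_mean) ~ 150 copies per species) keep
    Poisson sampling noise small relative to the heritable Brownian
    signal; the generator's true Ei is the PGLS predictor so the
    experiment isolates the filter's discrimination from upstream
    Ei-estimation error.
    """
    ph, ei = [], []
    for run in range(n_seeds):
        s = seed + 211 * run
        tree, traits, true_ei = _clade(n_species, s)
        matrix, truth = syn.simulate_gfs(
            tree, traits, n_families, frac_ei=0.3, frac_phylo=0.3,
            effect_size=1.0, base_log_mean=base_log_mean, seed=s + 2, true_ei=true_ei,
        )
        fits = phy.fit_lambda_matrix(tree, matrix, true_ei)
        ph += [fits[f].eliminated() for f in truth.phylo_only_families if f in fits]
        ei += [fits[f].eliminated() for f in truth.ei_linked_families if f in fits]
    return {
        "phylo_only_elimination_rate": float(np.mean(ph)),
        "ei_linked_elimination_rate": float(np.mean(ei)),
        "n_seeds": n_seeds,
    }


def go_density_adjustment(
    n_seeds: int = 5,
    n_families: int = 1500,
    n_terms: int = 100,
    n_samples: int = 10000,
    density_bias: float = 2.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """False-positive rates of the adjusted vs raw-count GO test under a
    pure annotation-density bias (no term-specific planting)."""
    adj_flags, raw_flags = [], []
    for run in range(n_seeds):
        s = seed + 257 * run
        rng = np.random.default_rng(s)
        fams = [f"fam{i:04d}" for i in range(n_families)]
        target = set(rng.choice(fams, size=n_families // 5, replace=False))
        go_map, _ = syn.simulate_go(
            fams, n_terms=n_terms, mean_families_per_term=70,
            target_set=target, density_bias=density_bias, seed=s + 1,
        )
        mem = {f + "_g1": f for f in fams}
        pairs = {t: {f + "_g1" for f in v} for t, v in go_map.items()}
        gomap = goe.build_term_family_map(pairs, mem, min_term_families=50)
        adj = goe.adjusted_enrichment_test(gomap, target, set(fams),
                                           n_samples=n_samples, seed=s + 2)
        raw = goe.adjusted_enrichment_test(gomap, target, set(fams),
                                           n_samples=n_samples, seed=s + 2, adjust=False)
        adj_flags += [t.empirical_p <= alpha for t in adj]
        raw_flags += [t.empirical_p <= alpha for t in raw]
    return {
        "fpr_adjusted": float(np.mean(adj_flags)),
        "fpr_raw": float(np.mean(raw_flags)),
        "n_terms_tested": len(adj_flags),
    }


def prominence_null_fraction(n_genes: int = 20000, n_tissues: int = 16, seed: int = 0) -> dict:
    """Fraction of genes called brain-prominent under tissue exchangeability."""
    genes = [f"g{i:05d}" for i in range(n_genes)]
    expr, _ = syn.simulate_expression(
        genes, n_tissues=n_tissues, brain_fraction_prominent=0.0, seed=seed
    )
    panel = exprmod.tissue_panel(expr.subset_samples(expr.metadata["region"] == "other"))
    calls = exprmod.prominence_calls(panel)
    frac = float(np.mean([c.prominent for c in calls]))
    return {"prominent_fraction": frac, "expected": 2.0 / n_tissues, "n_genes": n_genes}


def module_recovery(
    n_seeds: int = 20,
    n_modules: int = 5,
    genes_per_module: int = 50,
    module_corr: float = 0.8,
    n_timepoints: int = 60,
    seed: int = 0,
) -> dict:
    """ARI of detected vs planted modules, and planted-hub recovery rate."""
    from sklearn.metrics import adjusted_rand_score

    genes = [f"g{i:04d}" for i in range(n_modules * genes_per_module)]
    timepoints = [float(t) for t in np.linspace(-0.7, 40.0, n_timepoints)]
    aris, hub_hits, hub_total = [], 0, 0
    for run in range(n_seeds):
        expr, truth = syn.simulate_expression(
            genes, n_modules=n_modules, module_corr=module_corr,
            dev_timepoints=timepoints, seed=seed + 307 * run,
        )
        dev = expr.subset_samples(expr.metadata.index.str.startswith("dev_"))
        modules = coex.run_wgcna(dev.values, min_module_size=30)
        labels = [truth.module_labels[g] for g in dev.values.index]
        aris.append(adjusted_rand_score(labels, modules.assignment.values))
        planted = set(truth.hub_genes.values())
        hub_hits += sum(1 for h in modules.hubs.values() if h in planted)
        hub_total += len(truth.hub_genes)
    return {
        "mean_ari": float(np.mean(aris)),
        "min_ari": float(np.min(aris)),
        "hub_recovery_rate": hub_hits / hub_total,
        "n_seeds": n_seeds,
    }


def oracle_equivalences(seed: int = 0) -> dict:
    """Maximum deviations of the fast implementations from brute-force oracles."""
    from scipy import stats

    rng = np.random.default_rng(seed)
    # Pearson r vs scipy per family
    counts = rng.poisson(5.0, size=(50, 20))
    counts[0] += np.arange(20)  # ensure variance
    species = [f"s{i:03d}" for i in range(20)]
    from .datatypes import GeneFamilyMatrix

    matrix = GeneFamilyMatrix(
        family_ids=[f"f{i}" for i in range(50)], species_ids=species, counts=counts
    )
    ei = pd.Series(rng.normal(size=20), index=species)
    mlsp = pd.Series(0.5 * ei.values + rng.normal(size=20), index=species)
    recs = assoc.family_correlations(matrix, ei, mlsp)
    err_r = max(
        abs(r.r_ei - stats.pearsonr(counts[i], ei.values).statistic)
        for i, r in enumerate(recs)
        if not r.zero_variance
    )
    # partial r vs residual-on-residual
    assoc.partial_correlations(recs, ei, mlsp)
    err_partial = 0.0
    for i, rec in enumerate(recs):
        if rec.zero_variance:
            continue
        rx = counts[i] - np.poly1d(np.polyfit(mlsp, counts[i], 1))(mlsp)
        ry = ei.values - np.poly1d(np.polyfit(mlsp, ei.values, 1))(mlsp)
        err_partial = max(err_partial, abs(rec.partial_r - np.corrcoef(rx, ry)[0, 1]))
    # PGLS loglik vs dense MVN; GLS with identity vs OLS
    tree = syn.simulate_tree(8, seed=seed + 5)
    C = phy.phylo_covariance(tree, tree.tip_labels, 0.6)
    X = np.column_stack([np.ones(8), rng.normal(size=8)])
    y = rng.normal(size=8)
    ll, beta, s2 = phy.pgls_loglik(y, X, C)
    err_loglik = abs(ll - stats.multivariate_normal(mean=X @ beta, cov=s2 * C).logpdf(y))
    _, beta_i, _ = phy.pgls_loglik(y, X, np.eye(8))
    err_gls = float(np.max(np.abs(beta_i - np.linalg.lstsq(X, y, rcond=None)[0])))
    # TOM vs triple loop
    a = rng.uniform(0, 1, size=(6, 6))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    tom = coex.topological_overlap(a)
    k = a.sum(axis=1)
    err_tom = 0.0
    for i in range(6):
        for j in range(6):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(6))
            ref = (shared + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
            err_tom = max(err_tom, abs(tom[i, j] - ref))
    return {
        "pearson_max_error": float(err_r),
        "partial_max_error": float(err_partial),
        "pgls_loglik_error": float(err_loglik),
        "gls_identity_vs_ols_error": float(err_gls),
        "tom_max_error": float(err_tom),
    }
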