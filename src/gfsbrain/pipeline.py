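"""End-to-end orchestration of the selection cascade from one config.

Stages, in fixed order: simulate (or load) -> encephalization ->
association screen (+ permutation shift test) -> GO tests -> phylogenetic
filter -> expression characterization -> co-expression modules. A single
root seed spawns one sub-seed per stage through a fixed counter scheme
(numpy SeedSequence over (root, stage_index)), recorded in the manifest,
so each stage is individually reproducible.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import coexpression as coex
from . import encephalization as ence
from . import expression as exprmod
from . import go_enrichment as goe
from . import io as gio
from . import phylo as phy
from . import synthetic as syn
from .datatypes import SyntheticTruth

__all__ = ["run_pipeline", "summarize_run", "stage_seed", "write_simulation_bundle"]

logger = logging.getLogger("gfsbrain")

_STAGE_INDEX = {
    "simulate": 0,
    "encephalization": 1,
    "associate": 2,
    "go": 3,
    "phylo": 4,
    "expression": 5,
    "coexpress": 6,
}


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    ss = np.random.SeedSequence(entropy=(int(root_seed), _STAGE_INDEX[stage]))
    return int(ss.generate_state(1)[0] % (2**31))


_DEFAULT_PARAMS = {
    "min_species": 6,
    "alpha": 0.05,
    "permutations": 1000,
    "perm_mode": "per_family",
    "min_term_families": 50,
    "go_samples": 10000,
    "expr_samples": 10000,
    "dev_max_age": 18.0,
    "top_percentile": 10.0,
    "min_module_size": 30,
    "cut_height": 0.99,
    "log_base": 10.0,
}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping or a path to a YAML file")
    if "seed" not in config:
        raise ValueError("config must set a root seed")
    if "simulate" not in config and "inputs" not in config:
        raise ValueError("config must contain a 'simulate' or an 'inputs' block")
    return config


def write_simulation_bundle(config: dict, outdir: Path) -> dict:
    """Generate and write the full synthetic input bundle; returns file paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = dict(config.get("simulate", {}))
    seed = stage_seed(int(config["seed"]), "simulate")
    tree = syn.simulate_tree(
        n_tips=int(sim.get("n_species", 40)),
        birth_rate=float(sim.get("birth_rate", 1.0)),
        seed=seed,
    )
    traits, true_ei = syn.simulate_traits(
        tree,
        ei_sd=float(sim.get("ei_sd", 0.25)),
        mlsp_ei_corr=float(sim.get("mlsp_ei_corr", 0.79)),
        seed=seed + 1,
    )
    matrix, truth = syn.simulate_gfs(
        tree,
        traits,
        n_families=int(sim.get("n_families", 2000)),
        frac_ei=float(sim.get("frac_ei", 0.0)),
        frac_mlsp=float(sim.get("frac_mlsp", 0.0)),
        frac_phylo=float(sim.get("frac_phylo", 0.0)),
        effect_size=float(sim.get("effect_size", 1.0)),
        base_log_mean=float(sim.get("base_log_mean", 1.0)),
        seed=seed + 2,
        true_ei=true_ei,
    )
    go_cfg = dict(sim.get("go", {}))
    go_map, go_truth = syn.simulate_go(
        matrix.family_ids,
        n_terms=int(go_cfg.get("n_terms", 100)),
        mean_families_per_term=int(go_cfg.get("mean_families_per_term", 60)),
        planted_terms=int(go_cfg.get("planted_terms", 0)),
        plant_fold=float(go_cfg.get("plant_fold", 1.0)),
        target_set=truth.ei_linked_families,
        density_bias=float(go_cfg.get("density_bias", 0.0)),
        seed=seed + 3,
    )
    truth.enriched_terms = go_truth.enriched_terms
    ex_cfg = dict(sim.get("expression", {}))
    genes = sorted(matrix.gene_membership)
    ei_genes = {
        g for g, f in matrix.gene_membership.items() if f in truth.ei_linked_families
    }
    expr, ex_truth = syn.simulate_expression(
        genes,
        n_tissues=int(ex_cfg.get("n_tissues", 16)),
        brain_fraction_prominent=float(ex_cfg.get("brain_fraction_prominent", 0.0)),
        n_modules=int(ex_cfg.get("n_modules", 0)),
        module_corr=float(ex_cfg.get("module_corr", 0.8)),
        noise_sd=float(ex_cfg.get("noise_sd", 1.0)),
        dev_fraction=float(ex_cfg.get("dev_fraction", 0.0)),
        dev_timepoints=ex_cfg.get("dev_timepoints"),
        module_fraction=float(ex_cfg.get("module_fraction", 0.5)),
        prominent_target_genes=ei_genes,
        dev_target_genes=ei_genes,
        target_fold=float(ex_cfg.get("target_fold", 3.0)),
        seed=seed + 4,
    )
    truth.module_labels = ex_truth.module_labels
    truth.prominent_genes = ex_truth.prominent_genes
    truth.developmental_genes = ex_truth.developmental_genes
    truth.hub_genes = ex_truth.hub_genes
    truth.generator_params["go"] = go_truth.generator_params
    truth.generator_params["expression"] = ex_truth.generator_params
    truth.generator_params["realized_mlsp_ei_corr"] = float(
        np.corrcoef(traits.data["mlsp_yr"], true_ei)[0, 1]
    )

    paths = {
        "traits": str(outdir / "traits.tsv"),
        "counts": str(outdir / "family_counts.tsv"),
        "tree": str(outdir / "tree.nwk"),
        "go": str(outdir / "go_annotations.tsv"),
        "membership": str(outdir / "gene_families.tsv"),
        "expression": str(outdir / "expression.tsv"),
        "expression_meta": str(outdir / "expression_meta.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    gio.write_species_traits(traits, paths["traits"])
    gio.write_family_counts(matrix, paths["counts"])
    gio.write_newick(tree, paths["tree"])
    gene_pairs = syn.go_map_to_gene_pairs(go_map, matrix.gene_membership)
    gio.write_go_map(gene_pairs, paths["go"])
    pd.DataFrame(
        sorted(matrix.gene_membership.items()), columns=["gene_id", "family_id"]
    ).to_csv(paths["membership"], sep="\t", index=False)
    gio.write_expression(expr, paths["expression"], paths["expression_meta"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
    return paths


def _read_membership(path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(frame["gene_id"], frame["family_id"]))


def run_pipeline(config) -> dict:
    """Execute the cascade; returns the run manifest (JSON-serializable)."""
    config = _load_config(config)
    root_seed = int(config["seed"])
    outdir = Path(config.get("outdir", "gfsbrain_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    params = {**_DEFAULT_PARAMS, **config.get("params", {})}
    stages_on = {
        s: bool(config.get("stages", {}).get(s, True))
        for s in ("associate", "go", "phylo", "expression", "coexpress")
    }
    manifest: dict = {
        "config": config,
        "seeds": {s: stage_seed(root_seed, s) for s in _STAGE_INDEX},
        "cascade": {},
        "outputs": {},
        "stages_run": [],
        "software_version": _version(),
    }

    try:
        if "simulate" in config:
            paths = write_simulation_bundle(config, outdir / "inputs")
        else:
            paths = dict(config["inputs"])
        manifest["outputs"]["inputs"] = paths
        manifest["stages_run"].append("simulate" if "simulate" in config else "load")

        traits = gio.read_species_traits(paths["traits"])
        tree = gio.read_newick(paths["tree"])
        matrix = gio.read_family_counts(paths["counts"], traits.species)
        if "membership" in paths and paths["membership"]:
            matrix.gene_membership = _read_membership(paths["membership"])

        ei_res = ence.compute_ei(traits, log_base=params["log_base"])
        manifest["cascade"]["n_species"] = traits.n_species
        manifest["stages_run"].append("encephalization")
        _dump(outdir / "encephalization.json", ei_res.to_json_dict())

        matrix = assoc.filter_families(matrix, min_species=params["min_species"])
        manifest["cascade"]["families_after_presence_filter"] = matrix.n_families

        retained: set[str] = set()
        records = []
        if stages_on["associate"]:
            records = assoc.family_correlations(matrix, traits.require_ei(), traits.mlsp())
            shift = assoc.permutation_shift_test(
                matrix,
                traits.require_ei(),
                n_permutations=int(params["permutations"]),
                seed=manifest["seeds"]["associate"],
                mode=params["perm_mode"],
            )
            assoc.partial_correlations(records, traits.require_ei(), traits.require_mlsp())
            sig_ei = assoc.select_families(records, "sig_ei", alpha=params["alpha"])
            pref = assoc.select_families(records, "preferential", alpha=params["alpha"])
            sig_partial = assoc.select_families(records, "sig_partial", alpha=params["alpha"])
            manifest["cascade"].update(
                {
                    "n_positive": shift.n_positive,
                    "chi2": shift.chi2,
                    "perm_p": shift.perm_p,
                    "sig_ei": len(sig_ei),
                    "preferential": len(pref),
                    "sig_partial": len(sig_partial),
                }
            )
            frame = assoc.records_to_frame(records)
            frame.to_csv(outdir / "family_associations.tsv", sep="\t", index=False)
            _dump(outdir / "shift_test.json", shift.to_json_dict())
            manifest["outputs"]["associations"] = str(outdir / "family_associations.tsv")
            manifest["stages_run"].append("associate")
            retained = sig_partial
        else:
            manifest["cascade"]["associate"] = "skipped"

        if stages_on["phylo"] and stages_on["associate"]:
            fits = phy.fit_lambda_matrix(tree, matrix, traits.require_ei(), sorted(retained))
            kept = phy.phylo_filter(fits)
            manifest["cascade"]["after_phylo_filter"] = len(kept)
            lam_frame = pd.DataFrame(
                {
                    "family_id": [f.family_id for f in fits.values()],
                    "lambda_hat": [f.lambda_hat for f in fits.values()],
                    "p_vs_0": [f.p_vs_0 for f in fits.values()],
                    "p_vs_1": [f.p_vs_1 for f in fits.values()],
                    "eliminated": [f.eliminated() for f in fits.values()],
                }
            )
            lam_frame.to_csv(outdir / "lambda_fits.tsv", sep="\t", index=False)
            manifest["outputs"]["lambda_fits"] = str(outdir / "lambda_fits.tsv")
            manifest["stages_run"].append("phylo")
            retained = kept
        elif not stages_on["phylo"]:
            manifest["cascade"]["phylo"] = "skipped"

        if stages_on["go"] and stages_on["associate"] and matrix.gene_membership:
            raw = gio.read_go_map(paths["go"])
            gomap = goe.build_term_family_map(
                raw, matrix.gene_membership, min_term_families=params["min_term_families"]
            )
            meanr = goe.mean_correlation_test(
                gomap, records, n_samples=int(params["go_samples"]),
                seed=manifest["seeds"]["go"],
            )
            background = {r.family_id for r in records if not r.zero_variance}
            test_set = retained & background
            results = {"mean_correlation": _term_frame(meanr)}
            if test_set:
                enr = goe.adjusted_enrichment_test(
                    gomap, test_set, background,
                    n_samples=int(params["go_samples"]),
                    seed=manifest["seeds"]["go"] + 1,
                )
                results["adjusted_enrichment"] = _term_frame(enr)
                manifest["cascade"]["go_significant_terms"] = int(
                    (results["adjusted_enrichment"]["bonferroni_p"] < params["alpha"]).sum()
                )
            else:
                manifest["cascade"]["go_significant_terms"] = 0
            for name, frame in results.items():
                path = outdir / f"go_{name}.tsv"
                frame.sort_values("bonferroni_p").to_csv(path, sep="\t", index=False)
                manifest["outputs"][f"go_{name}"] = str(path)
            manifest["stages_run"].append("go")
        elif not stages_on["go"]:
            manifest["cascade"]["go"] = "skipped"

        if stages_on["expression"] and matrix.gene_membership:
            expr = gio.read_expression(paths["expression"], paths["expression_meta"])
            panel = exprmod.tissue_panel(expr.panel("tissue"))
            calls = exprmod.prominence_calls(panel)
            flags = {c.gene_id: c.prominent for c in calls}
            pool = set(matrix.family_ids)
            target = retained & pool if retained else set()
            if target:
                report = exprmod.family_set_enrichment(
                    target, matrix.gene_membership, flags, pool,
                    n_samples=int(params["expr_samples"]),
                    seed=manifest["seeds"]["expression"],
                )
                manifest["cascade"]["prominent_enrichment_p"] = report.empirical_p
                _dump(outdir / "prominence_enrichment.json", report.to_json_dict())
            dev_genes, dev_frame = exprmod.developmental_variance_genes(
                expr.panel("developmental"), dev_max_age=params["dev_max_age"],
                top_percentile=params["top_percentile"],
            )
            dev_frame.to_csv(outdir / "developmental_variance.tsv", sep="\t")
            regions = exprmod.regional_max_category(expr.panel("regional"))
            regions.rename("region").to_csv(outdir / "regional_max.tsv", sep="\t")
            manifest["cascade"]["n_prominent_genes"] = int(sum(flags.values()))
            manifest["cascade"]["n_developmental_genes"] = len(dev_genes)
            manifest["stages_run"].append("expression")
        elif not stages_on["expression"]:
            manifest["cascade"]["expression"] = "skipped"

        if stages_on["coexpress"] and matrix.gene_membership:
            expr = gio.read_expression(paths["expression"], paths["expression_meta"])
            dev = expr.panel("developmental")
            if dev.values.shape[1] >= 8 and dev.values.shape[0] >= 30:
                target_genes = (
                    [g for g, f in matrix.gene_membership.items() if f in retained]
                    if retained
                    else list(dev.values.index)
                )
                sub = dev.values.loc[[g for g in dev.values.index if g in set(target_genes)]]
                if sub.shape[0] >= 30:
                    modules = coex.run_wgcna(
                        sub,
                        min_module_size=int(params["min_module_size"]),
                        cut_height=float(params["cut_height"]),
                    )
                    modules.assignment.rename("module").to_csv(
                        outdir / "module_assignment.tsv", sep="\t"
                    )
                    modules.eigengenes.to_csv(outdir / "module_eigengenes.tsv", sep="\t")
                    manifest["cascade"]["n_modules"] = int(
                        len(set(modules.assignment) - {0})
                    )
                    manifest["cascade"]["beta"] = modules.beta
                    manifest["stages_run"].append("coexpress")
                else:
                    manifest["cascade"]["coexpress"] = "too few selected genes"
            else:
                manifest["cascade"]["coexpress"] = "too few developmental samples"
        elif not stages_on["coexpress"]:
            manifest["cascade"]["coexpress"] = "skipped"

    except Exception as exc:  # partial manifest with failure record
        manifest["failure"] = {"stage": manifest["stages_run"][-1] if manifest["stages_run"] else "setup", "error": str(exc)}
        _dump(outdir / "manifest.json", manifest)
        raise

    _dump(outdir / "manifest.json", manifest)
    return manifest


def _term_frame(results) -> pd.DataFrame:
    frame = pd.DataFrame(
        {
            "term_id": [r.term_id for r in results],
            "statistic": [r.statistic for r in results],
            "expected": [r.expected for r in results],
            "empirical_p": [r.empirical_p for r in results],
            "bonferroni_p": [r.bonferroni_p for r in results],
            "n_families": [r.n_families_in_term for r in results],
        }
    )
    frame["neg_log10_p"] = -np.log10(frame["empirical_p"])
    return frame


def _dump(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")


def _version() -> str:
    try:
        from importlib.metadata import version

        return version("gfsbrain")
    except Exception:
        return "unknown"


def summarize_run(manifest: dict, stream=None) -> str:
    """Human-readable cascade report from a manifest."""
    lines = ["gfsbrain run summary", "=" * 22]
    casc = manifest.get("cascade", {})
    order = [
        ("n_species", "species"),
        ("families_after_presence_filter", "families after presence filter"),
        ("n_positive", "families with r > 0"),
        ("chi2", "shift chi-square"),
        ("perm_p", "permutation p (positive excess)"),
        ("sig_ei", "significant Ei correlation (r > 0, p < alpha)"),
        ("preferential", "preferential Ei association (r_Ei > r_MLSP)"),
        ("sig_partial", "significant partial correlation | MLSP"),
        ("after_phylo_filter", "retained after phylogenetic filter"),
        ("go_significant_terms", "GO terms significant after Bonferroni"),
        ("n_prominent_genes", "brain-prominent genes"),
        ("n_modules", "co-expression modules"),
    ]
    for key, label in order:
        if key in casc:
            val = casc[key]
            lines.append(f"  {label}: {val:.4g}" if isinstance(val, float) else f"  {label}: {val}")
    for key, val in casc.items():
        if isinstance(val, str):
            lines.append(f"  [{key}: {val}]")
    if "failure" in manifest:
        lines.append(f"  FAILED at stage {manifest['failure']['stage']}: {manifest['failure']['error']}")
    lines.append(f"  stages run: {', '.join(manifest.get('stages_run', []))}")
    text = "\n".join(lines)
    if stream is not None:
        print(text, file=stream)
    return text
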