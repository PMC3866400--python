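import numpy as np
import pytest

from gfsbrain import encephalization as ence
from gfsbrain import synthetic as syn


class TestSimulateTree:
    def test_small_tree_shape(self):
        t = syn.simulate_tree(3, birth_rate=1.0, seed=7)
        assert t.n_tips == 3
        assert t.n_edges() == 4

    def test_larger_tree_edge_count(self):
        t = syn.simulate_tree(64, birth_rate=1.0, seed=1)
        assert t.n_tips == 64
        assert t.n_edges() == 126

    def test_deterministic_newick(self):
        a = syn.simulate_tree(10, seed=5).to_newick()
        b = syn.simulate_tree(10, seed=5).to_newick()
        assert a == b

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_tree(2, seed=1)


class TestSimulateTraits:
    def test_degenerate_noise_gives_zero_residuals(self):
        tree = syn.simulate_tree(20, seed=3)
        traits, _ = syn.simulate_traits(tree, ei_sd=1e-9, seed=4)
        res = ence.compute_ei(traits)
        assert np.allclose(res.residuals, 0.0, atol=1e-6)

    def test_allometric_plugin(self):
        tree = syn.simulate_tree(50, seed=2)
        traits, true_ei = syn.simulate_traits(
            tree, allometric_slope=0.75, allometric_intercept=1.0, ei_sd=1e-9, seed=5
        )
        log_body = np.log10(traits.data["body_mass_g"])
        log_brain = np.log10(traits.data["brain_mass_g"])
        assert np.allclose(log_brain, 1.0 + 0.75 * log_body, atol=1e-6)

    def test_mlsp_tracks_target_correlation(self):
        # realized corr(MLSP, true Ei) should approach the 0.79 target
        rs = []
        for seed in range(20):
            tree = syn.simulate_tree(200, seed=seed + 50)
            traits, true_ei = syn.simulate_traits(tree, mlsp_ei_corr=0.79, seed=seed)
            rs.append(np.corrcoef(traits.data["mlsp_yr"], true_ei)[0, 1])
        assert abs(np.mean(rs) - 0.79) < 0.1

    def test_invalid_correlation_rejected(self):
        tree = syn.simulate_tree(5, seed=1)
        with pytest.raises(ValueError):
            syn.simulate_traits(tree, mlsp_ei_corr=1.5, seed=0)


class TestSimulateGfs:
    def test_planted_bookkeeping_exact(self, clade40):
        tree, traits, true_ei = clade40
        m, truth = syn.simulate_gfs(
            tree, traits, 500, frac_ei=0.2, effect_size=1.0, seed=8, true_ei=true_ei
        )
        dropped = set(truth.generator_params["dropped_families"])
        assert len(truth.ei_linked_families) == 100 - len(
            dropped & {f"fam{i + 1:04d}" for i in range(100)}
        )
        assert truth.ei_linked_families.isdisjoint(truth.mlsp_linked_families)
        assert truth.ei_linked_families <= set(m.family_ids)

    def test_null_mean_correlation_near_zero(self, clade40):
        tree, traits, true_ei = clade40
        m, _ = syn.simulate_gfs(tree, traits, 2000, seed=12, true_ei=true_ei)
        from gfsbrain import association as assoc

        recs = assoc.family_correlations(m, traits.require_ei())
        assert abs(np.nanmean([r.r_ei for r in recs])) < 0.02

    def test_planted_effect_drives_correlation(self, clade40):
        # Monte-Carlo derived bound: median ei-linked Pearson r >= 0.5 at
        # effect size 1.0 on 40 species
        tree, traits, true_ei = clade40
        medians = []
        for seed in range(5):
            m, truth = syn.simulate_gfs(
                tree, traits, 300, frac_ei=0.3, effect_size=1.0,
                seed=20 + seed, true_ei=true_ei,
            )
            from gfsbrain import association as assoc

            recs = assoc.family_correlations(m, traits.require_ei())
            rs = [r.r_ei for r in recs if r.family_id in truth.ei_linked_families]
            medians.append(np.median(rs))
        assert min(medians) >= 0.5

    def test_deterministic_bit_for_bit(self, clade40):
        tree, traits, true_ei = clade40
        a, _ = syn.simulate_gfs(tree, traits, 50, frac_ei=0.1, seed=3, true_ei=true_ei)
        b, _ = syn.simulate_gfs(tree, traits, 50, frac_ei=0.1, seed=3, true_ei=true_ei)
        assert np.array_equal(a.counts, b.counts)
        assert a.family_ids == b.family_ids

    def test_presence_rule_enforced(self, clade40):
        tree, traits, true_ei = clade40
        m, _ = syn.simulate_gfs(tree, traits, 400, base_log_mean=0.0, seed=6,
                                true_ei=true_ei)
        assert ((m.counts > 0).sum(axis=1) >= 6).all()

    def test_fraction_overflow_rejected(self, clade40):
        tree, traits, true_ei = clade40
        with pytest.raises(ValueError):
            syn.simulate_gfs(tree, traits, 10, frac_ei=0.6, frac_mlsp=0.6,
                             seed=1, true_ei=true_ei)


class TestSimulateGo:
    def test_planted_term_count_exact(self):
        fams = [f"f{i}" for i in range(300)]
        _, truth = syn.simulate_go(
            fams, n_terms=50, planted_terms=3, plant_fold=3.0,
            target_set=set(fams[:50]), seed=2,
        )
        assert len(truth.enriched_terms) == 3

    def test_density_bias_doubles_target_annotations(self):
        fams = [f"f{i}" for i in range(1000)]
        target = set(fams[:200])
        gm, _ = syn.simulate_go(
            fams, n_terms=150, mean_families_per_term=60,
            target_set=target, density_bias=2.0, seed=4,
        )
        ann = {f: 0 for f in fams}
        for members in gm.values():
            for f in members:
                ann[f] += 1
        t = np.mean([ann[f] for f in target])
        b = np.mean([ann[f] for f in fams if f not in target])
        assert t / b == pytest.approx(2.0, abs=0.3)

    def test_no_bias_is_uniform(self):
        fams = [f"f{i}" for i in range(500)]
        target = set(fams[:100])
        gm, _ = syn.simulate_go(fams, n_terms=100, target_set=target,
                                plant_fold=1.0, density_bias=0.0, seed=9)
        props = [len(m & target) / len(m) for m in gm.values()]
        # binomial sampling error around 0.2 at term size ~60
        assert abs(np.mean(props) - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 60) / np.sqrt(100)

    def test_plant_fold_below_one_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_go(["f1"], n_terms=2, plant_fold=0.5, seed=1)


class TestSimulateExpression:
    def test_single_tight_module_limit(self):
        genes = [f"g{i}" for i in range(40)]
        tp = list(np.linspace(-0.5, 30, 25))
        expr, truth = syn.simulate_expression(
            genes, n_modules=1, module_corr=0.999, noise_sd=1e-3,
            dev_timepoints=tp, seed=3,
        )
        dev = expr.subset_samples(expr.metadata.index.str.startswith("dev_"))
        members = [g for g, m in truth.module_labels.items() if m == 1]
        sub = dev.values.loc[members].to_numpy()
        corr = np.corrcoef(sub)
        assert corr[np.triu_indices_from(corr, 1)].min() >= 0.99

    def test_prominent_fraction_under_exchangeability(self):
        genes = [f"g{i}" for i in range(5000)]
        expr, truth = syn.simulate_expression(
            genes, n_tissues=16, brain_fraction_prominent=0.0, seed=6
        )
        from gfsbrain import expression as ex

        panel = ex.tissue_panel(expr.subset_samples(expr.metadata["region"] == "other"))
        frac = np.mean([c.prominent for c in ex.prominence_calls(panel)])
        sd = np.sqrt(0.125 * 0.875 / 5000)
        assert abs(frac - 0.125) < 3 * sd
        assert truth.prominent_genes == set()

    def test_within_exceeds_between_module_correlation(self):
        genes = [f"g{i}" for i in range(200)]
        tp = list(np.linspace(-0.5, 30, 40))
        expr, truth = syn.simulate_expression(
            genes, n_modules=5, module_corr=0.8, dev_timepoints=tp, seed=1
        )
        dev = expr.subset_samples(expr.metadata.index.str.startswith("dev_"))
        labels = np.array([truth.module_labels[g] for g in dev.values.index])
        corr = np.corrcoef(dev.values.to_numpy())
        iu = np.triu_indices_from(corr, 1)
        same = labels[iu[0]] == labels[iu[1]]
        nonzero = (labels[iu[0]] != 0) & (labels[iu[1]] != 0)
        within = corr[iu][same & nonzero]
        between = corr[iu][~same & nonzero]
        assert within.mean() > between.mean() + 0.3

    def test_invalid_module_corr_rejected(self):
        with pytest.raises(ValueError):
            syn.simulate_expression(["g1"], n_modules=2, module_corr=1.5, seed=1)

    def test_deterministic(self):
        genes = [f"g{i}" for i in range(30)]
        a, _ = syn.simulate_expression(genes, seed=5)
        b, _ = syn.simulate_expression(genes, seed=5)
        assert a.values.equals(b.values)
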