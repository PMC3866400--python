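import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gfsbrain import association as assoc
from gfsbrain import encephalization as ence
from gfsbrain import synthetic as syn
from tests.conftest import make_matrix


class TestChiSquareShift:
    def test_matches_generic_goodness_of_fit(self):
        for n_pos, n_tot in [(8789, 12373), (60, 100), (7, 19)]:
            chi2, p = assoc.chi_square_shift(n_pos, n_tot)
            ref = stats.chisquare([n_pos, n_tot - n_pos])
            assert chi2 == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_exact_balance_is_zero(self):
        assert assoc.chi_square_shift(50, 100)[0] == 0.0

    def test_closed_form_small_case(self):
        assert assoc.chi_square_shift(60, 100)[0] == pytest.approx(4.0, abs=1e-12)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            assoc.chi_square_shift(0, 0)


class TestFamilyCorrelations:
    def test_matches_brute_force_pearson(self, rng):
        counts = rng.poisson(5, size=(40, 12))
        counts[3] = 7  # zero-variance row
        m = make_matrix(counts)
        ei = pd.Series(rng.normal(size=12), index=m.species_ids)
        recs = assoc.family_correlations(m, ei)
        for i, rec in enumerate(recs):
            if rec.zero_variance:
                assert i == 3
                continue
            r_ref, p_ref = stats.pearsonr(counts[i], ei.values)
            assert rec.r_ei == pytest.approx(r_ref, abs=1e-12)
            assert rec.p_ei == pytest.approx(p_ref, rel=1e-9)

    def test_perfect_linear_relation(self):
        ei = pd.Series([0.1, 0.2, 0.3, 0.4, 0.5], index=[f"s{i:03d}" for i in range(5)])
        counts = np.round(20 * ei.values + 5).astype(int)[None, :]
        recs = assoc.family_correlations(make_matrix(counts), ei)
        assert recs[0].r_ei == pytest.approx(1.0, abs=1e-12)

    def test_null_families_center_on_zero(self, rng):
        counts = rng.poisson(3, size=(10000, 20))
        ei = pd.Series(rng.normal(size=20), index=[f"s{i:03d}" for i in range(20)])
        recs = assoc.family_correlations(make_matrix(counts), ei)
        mean_r = np.nanmean([r.r_ei for r in recs])
        assert abs(mean_r) < 0.02


class TestPresenceFilter:
    def test_boundary_at_exactly_min_species(self):
        counts = np.zeros((3, 39), dtype=int)
        counts[0, :5] = 1  # present in 5 -> dropped
        counts[1, :6] = 1  # present in exactly 6 -> retained ("no less than six")
        counts[2, :] = 2
        out = assoc.filter_families(make_matrix(counts), min_species=6)
        assert out.family_ids == ["fam001", "fam002"]

    def test_min_one_is_identity_without_allzero_rows(self):
        counts = np.array([[1, 0], [0, 3]])
        out = assoc.filter_families(make_matrix(counts), min_species=1)
        assert out.n_families == 2

    def test_empty_result_rejected(self):
        counts = np.array([[1, 0], [0, 3]])
        with pytest.raises(ValueError, match="every family"):
            assoc.filter_families(make_matrix(counts), min_species=2)


class TestPartialCorrelations:
    def test_closed_form_value(self):
        # r_xy=0.6, r_xz=0.5, r_yz=0.7 -> (0.6-0.35)/sqrt(0.75*0.51) = 0.40425
        rec = assoc.FamilyAssociationRecord("f", r_ei=0.6, p_ei=0.01, r_mlsp=0.5, n_species=30)
        ei = pd.Series([0.0, 1.0, 2.0, 3.0], index=list("abcd"))
        mlsp = pd.Series([0.0, 0.9, 2.2, 2.7], index=list("abcd"))
        r_yz = np.corrcoef(ei, mlsp)[0, 1]
        assoc.partial_correlations([rec], ei, mlsp)
        expect = (0.6 - 0.5 * r_yz) / np.sqrt((1 - 0.25) * (1 - r_yz**2))
        assert rec.partial_r == pytest.approx(expect, abs=1e-12)

    def test_equals_residual_on_residual_oracle(self, rng):
        n = 25
        species = [f"s{i:03d}" for i in range(n)]
        ei = pd.Series(rng.normal(size=n), index=species)
        mlsp = pd.Series(0.6 * ei.values + rng.normal(size=n), index=species)
        counts = rng.poisson(np.exp(1 + 0.5 * ei.values), size=(30, n))
        m = make_matrix(counts, species=species)
        recs = assoc.family_correlations(m, ei, mlsp)
        assoc.partial_correlations(recs, ei, mlsp)
        for i, rec in enumerate(recs):
            if rec.zero_variance:
                continue
            rx = counts[i] - np.poly1d(np.polyfit(mlsp, counts[i], 1))(mlsp)
            ry = ei.values - np.poly1d(np.polyfit(mlsp, ei.values, 1))(mlsp)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert rec.partial_r == pytest.approx(oracle, abs=1e-10)

    def test_uncorrelated_covariate_reduces_to_simple_r(self):
        # mlsp exactly orthogonal to both GFS and Ei
        species = list("abcdef")
        ei = pd.Series([1.0, -1.0, 2.0, -2.0, 0.5, -0.5], index=species)
        mlsp = pd.Series([1.0, 1.0, -1.0, -1.0, -1.0, 1.0], index=species)
        counts = np.array([[3, 1, 4, 0, 2, 2]])
        counts = counts - 0  # integers fine
        m = make_matrix(counts, species=species)
        recs = assoc.family_correlations(m, ei, mlsp)
        if abs(recs[0].r_mlsp) < 1e-12 and abs(np.corrcoef(ei, mlsp)[0, 1]) < 1e-12:
            assoc.partial_correlations(recs, ei, mlsp)
            assert recs[0].partial_r == pytest.approx(recs[0].r_ei, abs=1e-10)

    def test_collinear_covariate_rejected(self):
        species = list("abcd")
        ei = pd.Series([1.0, 2.0, 3.0, 4.0], index=species)
        recs = [assoc.FamilyAssociationRecord("f", 0.5, 0.1, 0.2, n_species=4)]
        with pytest.raises(ValueError, match="collinear"):
            assoc.partial_correlations(recs, ei, 2 * ei + 1)


class TestSelectionCascade:
    def test_stage_membership_example(self):
        rec = assoc.FamilyAssociationRecord(
            "f", r_ei=0.5, p_ei=0.04, r_mlsp=0.6, n_species=39
        )
        assert "f" in assoc.select_families([rec], "sig_ei")
        assert "f" not in assoc.select_families([rec], "preferential")

    def test_preferential_nested_in_sig_ei(self, rng):
        recs = [
            assoc.FamilyAssociationRecord(
                f"f{i}",
                r_ei=rng.uniform(-1, 1),
                p_ei=rng.uniform(0, 1),
                r_mlsp=rng.uniform(-1, 1),
                n_species=39,
            )
            for i in range(500)
        ]
        pref = assoc.select_families(recs, "preferential")
        sig = assoc.select_families(recs, "sig_ei")
        assert pref <= sig

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="unknown stage"):
            assoc.select_families([], "nope")


class TestPermutationShift:
    def test_deterministic_under_seed(self, clade40):
        tree, traits, true_ei = clade40
        m, _ = syn.simulate_gfs(tree, traits, 100, seed=9, true_ei=true_ei)
        a = assoc.permutation_shift_test(m, traits.require_ei(), 50, seed=5)
        b = assoc.permutation_shift_test(m, traits.require_ei(), 50, seed=5)
        assert a.perm_p == b.perm_p
        assert a.null_positive_counts == b.null_positive_counts

    def test_p_lower_bound(self, clade40):
        tree, traits, true_ei = clade40
        m, _ = syn.simulate_gfs(tree, traits, 200, frac_ei=0.5, effect_size=1.5,
                                seed=2, true_ei=true_ei)
        res = assoc.permutation_shift_test(m, traits.require_ei(), 100, seed=1)
        assert res.perm_p >= 1.0 / 101.0

    def test_shared_relabel_mode_runs(self, clade40):
        tree, traits, true_ei = clade40
        m, _ = syn.simulate_gfs(tree, traits, 100, seed=9, true_ei=true_ei)
        res = assoc.permutation_shift_test(
            m, traits.require_ei(), 50, seed=5, mode="shared_relabel"
        )
        assert res.mode == "shared_relabel"
        assert 0 < res.perm_p <= 1

    def test_too_few_permutations_rejected(self, clade40):
        tree, traits, true_ei = clade40
        m, _ = syn.simulate_gfs(tree, traits, 50, seed=9, true_ei=true_ei)
        with pytest.raises(ValueError):
            assoc.permutation_shift_test(m, traits.require_ei(), 5, seed=1)


class TestOverallGeneNumber:
    def test_linear_totals_give_r_one(self):
        species = [f"s{i:03d}" for i in range(6)]
        ei = pd.Series(np.linspace(-1, 1, 6), index=species)
        totals = np.round(1000 + 100 * ei.values).astype(int)
        counts = np.zeros((1, 6), dtype=int)
        counts[0] = totals
        r, p = assoc.overall_gene_number_correlation(make_matrix(counts, species=species), ei)
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_constant_totals_rejected(self):
        species = [f"s{i:03d}" for i in range(4)]
        ei = pd.Series([0.1, 0.2, 0.3, 0.4], index=species)
        counts = np.full((3, 4), 5)
        with pytest.raises(ValueError, match="zero variance"):
            assoc.overall_gene_number_correlation(make_matrix(counts, species=species), ei)

    def test_matches_brute_force_column_sums(self, clade40, rng):
        tree, traits, true_ei = clade40
        m, _ = syn.simulate_gfs(tree, traits, 300, seed=4, true_ei=true_ei)
        r, _ = assoc.overall_gene_number_correlation(m, traits.require_ei())
        ref = np.corrcoef(m.counts.sum(axis=0), traits.require_ei().values)[0, 1]
        assert r == pytest.approx(ref, abs=1e-12)
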