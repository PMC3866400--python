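import numpy as np
import pytest

from gfsbrain import go_enrichment as goe
from gfsbrain import synthetic as syn
from gfsbrain.association import FamilyAssociationRecord


def _records(r_by_family):
    return [
        FamilyAssociationRecord(f, r_ei=r, p_ei=0.5, n_species=40)
        for f, r in r_by_family.items()
    ]


class TestTermFamilyMap:
    def test_eligibility_is_strictly_more_than_threshold(self):
        mem = {f"g{i}": f"f{i}" for i in range(60)}
        pairs = {
            "GO:51": {f"g{i}" for i in range(51)},
            "GO:50": {f"g{i}" for i in range(50)},
        }
        gomap = goe.build_term_family_map(pairs, mem, min_term_families=50)
        assert gomap.eligible_terms == ["GO:51"]

    def test_any_member_rule_counts_family_once(self):
        mem = {"g1": "fA", "g2": "fA", "g3": "fB"}
        pairs = {"GO:1": {"g1", "g2", "g3"}}
        gomap = goe.build_term_family_map(pairs, mem, min_term_families=1)
        assert gomap.term_families["GO:1"] == {"fA", "fB"}

    def test_idempotent_under_extra_member_gene(self):
        mem = {"g1": "fA", "g2": "fA", "g3": "fB"}
        a = goe.build_term_family_map({"GO:1": {"g1", "g3"}}, mem, 1)
        b = goe.build_term_family_map({"GO:1": {"g1", "g2", "g3"}}, mem, 1)
        assert a.term_families == b.term_families

    def test_empty_eligible_set_rejected(self):
        mem = {"g1": "fA"}
        with pytest.raises(ValueError, match="no term"):
            goe.build_term_family_map({"GO:1": {"g1"}}, mem, min_term_families=50)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expect", [(0.0004, 100, 0.04), (0.5, 10, 1.0), (0.2, 1, 0.2)]
    )
    def test_examples(self, p, m, expect):
        assert goe.bonferroni_correct([p], m) == [pytest.approx(expect)]

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            goe.bonferroni_correct([0.1], 0)
        with pytest.raises(ValueError):
            goe.bonferroni_correct([0.1, 0.2], 1)


class TestMeanCorrelationTest:
    def _map_and_records(self, rng, n_fam=400, term_sizes=(60, 80)):
        fams = [f"f{i:03d}" for i in range(n_fam)]
        mem = {f + "_g": f for f in fams}
        pairs = {}
        for t, size in enumerate(term_sizes):
            chosen = rng.choice(fams, size=size, replace=False)
            pairs[f"GO:{t}"] = {f + "_g" for f in chosen}
        gomap = goe.build_term_family_map(pairs, mem, min_term_families=50)
        recs = _records({f: rng.normal() for f in fams})
        return gomap, recs

    def test_planted_high_r_term_detected(self, rng):
        fams = [f"f{i:03d}" for i in range(400)]
        mem = {f + "_g": f for f in fams}
        r = {f: rng.normal(0, 0.2) for f in fams}
        hot = fams[:60]
        for f in hot:
            r[f] = rng.normal(0.8, 0.1)
        pairs = {"GO:hot": {f + "_g" for f in hot},
                 "GO:rand": {f + "_g" for f in rng.choice(fams, 70, replace=False)}}
        gomap = goe.build_term_family_map(pairs, mem, min_term_families=50)
        res = {t.term_id: t for t in goe.mean_correlation_test(gomap, _records(r),
                                                               n_samples=2000, seed=1)}
        assert res["GO:hot"].bonferroni_p < 0.05
        assert res["GO:hot"].statistic > res["GO:hot"].expected

    def test_term_containing_whole_pool_has_p_one(self, rng):
        fams = [f"f{i:03d}" for i in range(80)]
        mem = {f + "_g": f for f in fams}
        pairs = {"GO:all": {f + "_g" for f in fams}}
        gomap = goe.build_term_family_map(pairs, mem, min_term_families=50)
        res = goe.mean_correlation_test(
            gomap, _records({f: rng.normal() for f in fams}), n_samples=500, seed=2
        )
        assert res[0].empirical_p == 1.0
        assert res[0].statistic == pytest.approx(res[0].expected, abs=1e-9)

    def test_deterministic_under_seed(self, rng):
        gomap, recs = self._map_and_records(rng)
        a = goe.mean_correlation_test(gomap, recs, n_samples=500, seed=7)
        b = goe.mean_correlation_test(gomap, recs, n_samples=500, seed=7)
        assert [t.empirical_p for t in a] == [t.empirical_p for t in b]


class TestAdjustedEnrichment:
    def test_zero_overlap_term_p_one(self, rng):
        fams = [f"f{i:03d}" for i in range(200)]
        mem = {f + "_g": f for f in fams}
        pairs = {
            "GO:low": {f + "_g" for f in fams[100:]},  # disjoint from test set
            "GO:wide": {f + "_g" for f in fams[25:90]},
        }
        gomap = goe.build_term_family_map(pairs, mem, min_term_families=50)
        res = {t.term_id: t for t in goe.adjusted_enrichment_test(
            gomap, set(fams[:50]), set(fams), n_samples=300, seed=3
        )}
        assert res["GO:low"].statistic == 0.0
        assert res["GO:low"].empirical_p == 1.0

    def test_unannotated_test_set_rejected(self):
        fams = [f"f{i:03d}" for i in range(200)]
        mem = {f + "_g": f for f in fams}
        pairs = {"GO:low": {f + "_g" for f in fams[100:]}}
        gomap = goe.build_term_family_map(pairs, mem, min_term_families=50)
        with pytest.raises(ValueError, match="no annotations"):
            goe.adjusted_enrichment_test(gomap, set(fams[:50]), set(fams), 100, 1)

    def test_invariant_to_global_doubling_of_annotations(self, rng):
        # duplicating every term doubles d(S) and leaves each term's count
        # unchanged, so every comparison — hence every p — is identical
        fams = [f"f{i:03d}" for i in range(300)]
        mem = {f + "_g": f for f in fams}
        pairs = {}
        for t in range(4):
            chosen = rng.choice(fams, size=70, replace=False)
            pairs[f"GO:{t}"] = {f + "_g" for f in chosen}
        doubled = dict(pairs)
        doubled.update({k + "_copy": set(v) for k, v in pairs.items()})
        g1 = goe.build_term_family_map(pairs, mem, min_term_families=50)
        g2 = goe.build_term_family_map(doubled, mem, min_term_families=50)
        test_set = set(fams[:60])
        r1 = {t.term_id: t.empirical_p for t in goe.adjusted_enrichment_test(
            g1, test_set, set(fams), n_samples=400, seed=9)}
        r2 = {t.term_id: t.empirical_p for t in goe.adjusted_enrichment_test(
            g2, test_set, set(fams), n_samples=400, seed=9)}
        for term in r1:
            assert r1[term] == pytest.approx(r2[term], abs=1e-12)

    def test_density_bias_fools_raw_but_not_adjusted(self):
        # the module's reason for being, on a single generated instance
        fams = [f"f{i:04d}" for i in range(1200)]
        target = set(fams[:250])
        gm, _ = syn.simulate_go(
            fams, n_terms=60, mean_families_per_term=70,
            target_set=target, density_bias=2.0, seed=21,
        )
        mem = {f + "_g": f for f in fams}
        pairs = {t: {f + "_g" for f in v} for t, v in gm.items()}
        gomap = goe.build_term_family_map(pairs, mem, min_term_families=50)
        adj = goe.adjusted_enrichment_test(gomap, target, set(fams),
                                           n_samples=2000, seed=5)
        raw = goe.adjusted_enrichment_test(gomap, target, set(fams),
                                           n_samples=2000, seed=5, adjust=False)
        fpr_adj = np.mean([t.empirical_p <= 0.05 for t in adj])
        fpr_raw = np.mean([t.empirical_p <= 0.05 for t in raw])
        assert fpr_raw > 0.15
        assert fpr_adj < 0.15

    def test_test_set_must_be_subset(self, rng):
        fams = [f"f{i}" for i in range(100)]
        mem = {f + "_g": f for f in fams}
        pairs = {"GO:1": {f + "_g" for f in fams[:60]}}
        gomap = goe.build_term_family_map(pairs, mem, min_term_families=50)
        with pytest.raises(ValueError, match="subset"):
            goe.adjusted_enrichment_test(gomap, {"zz"}, set(fams), 100, 1)

    def test_empirical_p_never_zero(self, rng):
        fams = [f"f{i:03d}" for i in range(200)]
        mem = {f + "_g": f for f in fams}
        pairs = {"GO:1": {f + "_g" for f in fams[:80]}}
        gomap = goe.build_term_family_map(pairs, mem, min_term_families=50)
        res = goe.adjusted_enrichment_test(gomap, set(fams[:80]), set(fams), 200, 1)
        assert res[0].empirical_p >= 1.0 / 201.0
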