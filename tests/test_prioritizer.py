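import pytest
from hypothesis import given, settings, strategies as st

from serrata.germline_prioritizer import (
    FilterConfig,
    GeneSets,
    PrioritizedVariant,
    cross_family_exclusion,
    filter_round1,
    gene_function_prioritize,
    predictor_score,
    prioritize_cohort,
    segregation_filter,
)
from serrata.types import GenotypeCall, Pedigree, PedigreeMember

from conftest import make_variant, verdicts


def ped2(fam="F1"):
    return Pedigree(fam, (
        PedigreeMember(f"{fam}.a", affected=True),
        PedigreeMember(f"{fam}.b", affected=True),
    ))


def het(s):
    return GenotypeCall(s, "het", 30, 30, 60)


def hom_ref(s):
    return GenotypeCall(s, "hom_ref", 60, 0, 60)


class TestPredictorScore:
    def test_all_six_deleterious(self):
        assert predictor_score(make_variant(predictor_verdicts=verdicts(6))) == 6

    def test_three_deleterious_three_tolerated(self):
        assert predictor_score(make_variant(predictor_verdicts=verdicts(3))) == 3

    def test_all_unavailable_scores_zero(self):
        v = make_variant(predictor_verdicts=verdicts(0, n_unavailable=6))
        assert predictor_score(v) == 0


class TestRound1:
    def test_rare_missense_with_enough_votes_retained(self):
        v = make_variant(pop_freqs={"gnomad": 5e-4},
                         predictor_verdicts=verdicts(4))
        assert filter_round1([v]) == [v]

    def test_common_missense_removed(self):
        v = make_variant(pop_freqs={"gnomad": 2e-3},
                         predictor_verdicts=verdicts(6))
        assert filter_round1([v]) == []

    def test_synonymous_removed(self):
        v = make_variant(consequence="synonymous", impact="synonymous",
                         predictor_verdicts=verdicts(6))
        assert filter_round1([v]) == []

    def test_frameshift_with_unavailable_predictors_retained(self):
        v = make_variant(ref="AT", alt="A", consequence="frameshift",
                         impact="truncating",
                         predictor_verdicts=verdicts(0, n_unavailable=6))
        assert filter_round1([v]) == [v]

    def test_maf_exactly_at_threshold_removed(self):
        v = make_variant(pop_freqs={"gnomad": 0.001},
                         predictor_verdicts=verdicts(6))
        assert filter_round1([v]) == []

    def test_score_exactly_at_min_votes_retained(self):
        v = make_variant(predictor_verdicts=verdicts(3))
        assert filter_round1([v]) == [v]

    def test_order_preserved(self):
        vs = [make_variant(pos=p, predictor_verdicts=verdicts(5))
              for p in (30, 10, 20)]
        assert [v.pos for v in filter_round1(vs)] == [30, 10, 20]


class TestSegregation:
    def test_het_in_both_of_two_affected_dominant(self):
        ped = ped2()
        v = make_variant(predictor_verdicts=verdicts(5))
        gts = {v.key: {"F1.a": het("F1.a"), "F1.b": het("F1.b")}}
        assert segregation_filter([v], gts, ped) == [(v, "dominant")]

    def test_het_in_one_of_two_removed(self):
        ped = ped2()
        v = make_variant()
        gts = {v.key: {"F1.a": het("F1.a"), "F1.b": hom_ref("F1.b")}}
        assert segregation_filter([v], gts, ped) == []

    def test_het_in_all_six_affected_retained(self):
        ped = Pedigree("F6", tuple(
            PedigreeMember(f"F6.{i}", affected=True) for i in range(6)
        ))
        v = make_variant()
        gts = {v.key: {f"F6.{i}": het(f"F6.{i}") for i in range(6)}}
        assert segregation_filter([v], gts, ped) == [(v, "dominant")]

    def test_hom_alt_still_counts_as_carrier_under_dominant(self):
        ped = ped2()
        v = make_variant()
        gts = {v.key: {
            "F1.a": het("F1.a"),
            "F1.b": GenotypeCall("F1.b", "hom_alt", 0, 60, 60),
        }}
        assert segregation_filter([v], gts, ped) == [(v, "dominant")]

    def test_missing_genotype_fails_shared_rule_by_default(self):
        ped = ped2()
        v = make_variant()
        gts = {v.key: {
            "F1.a": het("F1.a"),
            "F1.b": GenotypeCall("F1.b", "missing", 0, 0, 0,
                                 depths_available=False),
        }}
        assert segregation_filter([v], gts, ped) == []
        relaxed = FilterConfig(missing_genotype_fails=False)
        assert segregation_filter([v], gts, ped, relaxed) == [(v, "dominant")]

    def test_hom_alt_in_all_affected_is_recessive(self):
        ped = ped2()
        v = make_variant()
        hom = lambda s: GenotypeCall(s, "hom_alt", 0, 60, 60)
        gts = {v.key: {"F1.a": hom("F1.a"), "F1.b": hom("F1.b")}}
        out = segregation_filter(
            [v], gts, ped, FilterConfig(inheritance="recessive")
        )
        assert out == [(v, "recessive")]

    def test_compound_het_surrogate(self):
        ped = ped2()
        v1 = make_variant(pos=100)
        v2 = make_variant(pos=200)
        gts = {
            v.key: {"F1.a": het("F1.a"), "F1.b": het("F1.b")}
            for v in (v1, v2)
        }
        out = segregation_filter(
            [v1, v2], gts, ped, FilterConfig(inheritance="recessive")
        )
        assert [(v.pos, m) for v, m in out] == [(100, "recessive"),
                                               (200, "recessive")]


class TestCrossFamilyExclusion:
    def _cohort(self, seg_in_b: bool):
        ped_a, ped_b = ped2("A"), ped2("B")
        v = make_variant(predictor_verdicts=verdicts(5))
        gt_a = {v.key: {"A.a": het("A.a"), "A.b": het("A.b")}}
        if seg_in_b:
            gt_b = {v.key: {"B.a": het("B.a"), "B.b": het("B.b")}}
            retained_b = [(v, "dominant")]
        else:
            gt_b = {v.key: {"B.a": het("B.a"), "B.b": hom_ref("B.b")}}
            retained_b = []
        retained = {"A": [(v, "dominant")], "B": retained_b}
        gts = {"A": gt_a, "B": gt_b}
        peds = {"A": ped_a, "B": ped_b}
        return v, retained, gts, peds

    def test_consistent_segregation_kept_in_both(self):
        v, retained, gts, peds = self._cohort(seg_in_b=True)
        out = cross_family_exclusion(retained, gts, peds)
        assert out["A"] == [(v, "dominant")] and out["B"] == [(v, "dominant")]

    def test_inconsistent_segregation_removed_everywhere(self):
        # derived rule application: variant segregates in A, carried by
        # only one of two affecteds in B -> dropped from A (and absent in B)
        v, retained, gts, peds = self._cohort(seg_in_b=False)
        out = cross_family_exclusion(retained, gts, peds)
        assert out["A"] == [] and out["B"] == []

    def test_external_exclusion_list(self):
        v, retained, gts, peds = self._cohort(seg_in_b=True)
        out = cross_family_exclusion(retained, gts, peds,
                                     external_exclusion=[v.key])
        assert out["A"] == [] and out["B"] == []


class TestGeneFunctionPrioritize:
    sets = GeneSets(
        prioritized={"senescence": ("INO80X",), "cancer": ("CANC1",)},
        excluded={"non_cancer_disease": ("CFTRX",)},
    )

    def _pv(self, gene):
        return PrioritizedVariant(
            variant=make_variant(gene=gene), family_id="F1",
            round_reached=1, predictor_score=5,
        )

    def test_round3_attaches_criterion(self):
        out = gene_function_prioritize([self._pv("INO80X")], self.sets, round=3)
        assert out[0].selection_criterion == "Senescence candidate"
        assert out[0].round_reached == 3

    def test_round2_removes_excluded_gene(self):
        assert gene_function_prioritize([self._pv("CFTRX")], self.sets, round=2) == []

    def test_gene_in_no_set_removed_at_round3(self):
        assert gene_function_prioritize([self._pv("NOPE")], self.sets, round=3) == []

    def test_overlapping_prioritized_and_excluded_rejected(self):
        with pytest.raises(ValueError, match="both"):
            GeneSets(prioritized={"cancer": ("X",)},
                     excluded={"vague_function": ("X",)})


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_prioritize(per_family_variants, per_family_genotypes,
                           pedigrees, gene_sets, config):
    """Naive per-variant re-evaluation of every rule, written independently
    of the pipeline's filter implementations."""
    score = lambda v: sum(
        1 for x in v.predictor_verdicts.values() if x == "deleterious"
    )

    def passes_round1(v):
        maf = max(v.pop_freqs.values()) if v.pop_freqs else 0.0
        if maf >= config.maf_threshold:
            return False
        if v.impact == "truncating":
            return True
        if v.impact == "missense":
            return score(v) >= config.min_deleterious_votes
        return False

    def shared(fam, v):
        for m in pedigrees[fam].affected_sequenced:
            call = per_family_genotypes[fam].get(v.key, {}).get(m.sample_id)
            if call is None or call.gt not in ("het", "hom_alt"):
                return False
        return True

    r1 = {
        fam: [v for v in vs if passes_round1(v)]
        for fam, vs in per_family_variants.items()
    }
    seg = {fam: [v for v in vs if shared(fam, v)] for fam, vs in r1.items()}

    def consistent_elsewhere(fam, v):
        for other, gmap in per_family_genotypes.items():
            if other == fam:
                continue
            calls = gmap.get(v.key, {})
            if any(c.gt in ("het", "hom_alt") for c in calls.values()):
                if not shared(other, v):
                    return False
        return True

    r2 = {
        fam: [
            v for v in vs
            if consistent_elsewhere(fam, v)
            and v.gene not in gene_sets.all_excluded
        ]
        for fam, vs in seg.items()
    }
    r3 = {
        fam: [v for v in vs if gene_sets.criteria_for(v.gene)]
        for fam, vs in r2.items()
    }
    return r1, r2, r3


class TestOracleEquivalence:
    def test_cohort_matches_brute_force(self, cohort):
        """Three-round output identical to naive re-evaluation (dominant)."""
        config = FilterConfig(inheritance="dominant")
        variants = {f: [v for v, _ in r] for f, r in cohort.germline.items()}
        genotypes = {
            f: {v.key: c for v, c in r} for f, r in cohort.germline.items()
        }
        peds = {p.family_id: p for p in cohort.pedigrees}
        result = prioritize_cohort(
            variants, genotypes, peds, cohort.gene_sets, config
        )
        r1, r2, r3 = brute_force_prioritize(
            variants, genotypes, peds, cohort.gene_sets, config
        )
        total = sum(len(v) for v in variants.values())
        assert total <= 3000  # oracle stays cheap
        for fam in variants:
            assert [v.key for v in result[fam].round1] == [
                v.key for v in r1[fam]
            ]
            assert sorted(pv.variant.key for pv in result[fam].round2) == sorted(
                v.key for v in r2[fam]
            )
            assert sorted(pv.variant.key for pv in result[fam].round3) == sorted(
                v.key for v in r3[fam]
            )

    def test_monotonicity_per_family(self, cohort):
        variants = {f: [v for v, _ in r] for f, r in cohort.germline.items()}
        genotypes = {
            f: {v.key: c for v, c in r} for f, r in cohort.germline.items()
        }
        peds = {p.family_id: p for p in cohort.pedigrees}
        result = prioritize_cohort(
            variants, genotypes, peds, cohort.gene_sets
        )
        for fam, p in result.items():
            k1 = {v.key for v in p.round1}
            k2 = {pv.variant.key for pv in p.round2}
            k3 = {pv.variant.key for pv in p.round3}
            assert k3 <= k2 <= k1


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

variant_strategy = st.builds(
    lambda pos, maf, votes, impact: make_variant(
        pos=pos,
        consequence=impact,
        impact={"missense": "missense", "synonymous": "synonymous",
                "stop_gained": "truncating"}[impact],
        pop_freqs={} if maf == 0 else {"gnomad": maf},
        predictor_verdicts=verdicts(votes),
    ),
    pos=st.integers(1, 10_000),
    maf=st.one_of(st.just(0.0), st.floats(1e-7, 0.05)),
    votes=st.integers(0, 6),
    impact=st.sampled_from(["missense", "synonymous", "stop_gained"]),
)


@given(st.lists(variant_strategy, max_size=30))
@settings(max_examples=50, deadline=None)
def test_round1_is_subset_and_idempotent(vs):
    out = filter_round1(vs)
    assert all(v in vs for v in out)
    assert filter_round1(out) == out


@given(st.lists(variant_strategy, max_size=30),
       st.floats(0, 0.01), st.integers(0, 6))
@settings(max_examples=50, deadline=None)
def test_round1_threshold_semantics(vs, maf_thr, min_votes):
    cfg = FilterConfig(maf_threshold=maf_thr, min_deleterious_votes=min_votes)
    for v in filter_round1(vs, cfg):
        assert v.maf < maf_thr
        assert v.impact in ("missense", "truncating")
        if v.impact == "missense":
            assert predictor_score(v) >= min_votes
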