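import numpy as np
import pytest

from serrata.mutational_profile import (
    ID83_CATEGORIES,
    SBS96_CATEGORIES,
    CatalogVector,
    ReferenceMismatchError,
    build_catalog,
    classify_load,
    compute_burden,
    driver_report,
    flag_aetiology,
    id_classify,
    refit_signatures,
    sbs96_classify,
)
from serrata.resources import load_id83_bin_table
from serrata.types import GenotypeCall

from conftest import make_variant

_COMP = str.maketrans("ACGT", "TGCA")


def ref_of(seq: str) -> dict:
    return {"chr1": seq}


def snv(pos, ref, alt):
    return make_variant(pos=pos, ref=ref, alt=alt)


class TestSbs96:
    def test_category_count_and_order(self):
        assert len(SBS96_CATEGORIES) == 96
        assert SBS96_CATEGORIES[0] == "A[C>A]A"
        assert SBS96_CATEGORIES[-1] == "T[T>G]T"

    def test_pyrimidine_center_direct(self):
        # ACA with C>T at center
        assert sbs96_classify(snv(5, "C", "T"), ref_of("GGGACAGGG")) == "A[C>T]A"

    def test_purine_center_reverse_complemented(self):
        # TGT with G>A: revcomp -> ACA, C>T
        assert sbs96_classify(snv(5, "G", "A"), ref_of("GGGTGTGGG")) == "A[C>T]A"

    def test_derived_a_to_g_example(self):
        # CAT with A>G: revcomp(CAT)=ATG, alt G->C  =>  A[T>C]G
        assert sbs96_classify(snv(5, "A", "G"), ref_of("GGGCATGGG")) == "A[T>C]G"

    def test_reference_mismatch_raises(self):
        with pytest.raises(ReferenceMismatchError):
            sbs96_classify(snv(5, "T", "A"), ref_of("GGGACAGGG"))

    def test_edge_of_contig_unclassifiable(self):
        assert sbs96_classify(snv(1, "G", "A"), ref_of("GACGT")) is None

    def test_n_in_context_unclassifiable(self):
        assert sbs96_classify(snv(5, "C", "T"), ref_of("GGGNCAGGG")) is None

    def test_strand_involution_exhaustive(self):
        """A mutation and its reverse-complement representation always get
        the same label, for all 96 (context, alt) combinations."""
        for five in "ACGT":
            for center, alts in (("C", "AGT"), ("T", "ACG")):
                for three in "ACGT":
                    for alt in alts:
                        fwd_seq = f"G{five}{center}{three}G"
                        fwd = sbs96_classify(snv(3, center, alt), ref_of(fwd_seq))
                        rc_seq = fwd_seq.translate(_COMP)[::-1]
                        rc = sbs96_classify(
                            snv(3, center.translate(_COMP), alt.translate(_COMP)),
                            ref_of(rc_seq),
                        )
                        assert fwd == rc
                        assert fwd in SBS96_CATEGORIES


def brute_force_microhomology(seq: str, pos0: int, deleted: str) -> int:
    """Oracle: longest m such that the deleted sequence shares an m-prefix
    with the right flank or an m-suffix with the left flank."""
    best = 0
    for m in range(1, len(deleted)):
        right = seq[pos0 + len(deleted): pos0 + len(deleted) + m]
        left = seq[pos0 - m: pos0]
        if right == deleted[:m] or left == deleted[-m:]:
            best = max(best, m)
    return best


class TestId83:
    def test_category_count(self):
        assert len(ID83_CATEGORIES) == 83
        assert len(set(ID83_CATEGORIES)) == 83

    def test_bin_table_matches_categories(self):
        table = load_id83_bin_table()
        assert [row[0] for row in table] == list(ID83_CATEGORIES)

    def test_del_t_in_long_homopolymer(self):
        #       123456789
        seq = "GGTTTTTTGG"  # run of 6 T at 3..8
        v = make_variant(pos=2, ref="GT", alt="G")
        assert id_classify(v, ref_of(seq)) == "1:Del:T:5"

    def test_ins_c_next_to_single_c(self):
        # derived by run counting: one existing C -> run-length-1 bin
        seq = "GGACAGG"
        v = make_variant(pos=4, ref="C", alt="CC")
        assert id_classify(v, ref_of(seq)) == "1:Ins:C:1"

    def test_del_a_maps_to_t_by_complement(self):
        seq = "GGCAAAGG"
        v = make_variant(pos=3, ref="CA", alt="C")
        assert id_classify(v, ref_of(seq)) == "1:Del:T:2"

    def test_4bp_deletion_with_2bp_microhomology(self):
        # delete TACG; right flank begins TA -> MH length 2 (brute-forced)
        seq = "GGGGCTACGTAGGGGG"
        deleted = "TACG"
        pos0 = 5
        assert seq[pos0:pos0 + 4] == deleted
        assert brute_force_microhomology(seq, pos0, deleted) == 2
        v = make_variant(pos=5, ref="C" + deleted, alt="C")
        assert id_classify(v, ref_of(seq)) == "4:Del:M:2"

    def test_tandem_repeat_deletion(self):
        # ACG ACG ACG: deleting one unit leaves 2 copies -> R:2
        seq = "GGTACGACGACGTT"
        v = make_variant(pos=3, ref="TACG", alt="T")
        assert id_classify(v, ref_of(seq)) == "3:Del:R:2"

    def test_non_repeat_deletion_r0(self):
        seq = "GGGATCCGTAGGG"
        v = make_variant(pos=4, ref="ATC", alt="A")
        mh = brute_force_microhomology(seq, 4, "TC")
        assert mh == 0
        assert id_classify(v, ref_of(seq)) == "2:Del:R:0"

    def test_complex_indel_unclassifiable(self):
        v = make_variant(pos=4, ref="AT", alt="GCC")
        assert id_classify(v, ref_of("GGGATGGG")) is None

    def test_microhomology_agrees_with_oracle_randomized(self):
        from serrata.mutational_profile import _microhomology

        rng = np.random.default_rng(17)
        bases = np.array(list("ACGT"))
        for _ in range(200):
            seq = "".join(bases[rng.integers(0, 4, size=60)])
            size = int(rng.integers(2, 6))
            pos0 = int(rng.integers(10, 40))
            deleted = seq[pos0: pos0 + size]
            assert _microhomology(ref_of(seq), "chr1", pos0, deleted) == \
                brute_force_microhomology(seq, pos0, deleted)


class TestBuildCatalog:
    def test_counts_conserved(self):
        seq = "GGGACAGGGACAGGGACAGGG"
        muts = [snv(p, "C", "T") for p in (5, 11, 17)]
        vec = build_catalog(muts, ref_of(seq), "SBS96")
        assert vec.counts.sum() == 3
        assert vec.counts[SBS96_CATEGORIES.index("A[C>T]A")] == 3

    def test_empty_sample_zero_vector(self):
        vec = build_catalog([], ref_of("ACGT"), "SBS96")
        assert vec.total == 0 and vec.unclassifiable == 0

    def test_indels_ignored_under_sbs96_but_tallied(self):
        seq = "GGGACAGGG"
        muts = [snv(5, "C", "T"),
                make_variant(pos=3, ref="GA", alt="G",
                             consequence="frameshift", impact="truncating")]
        vec = build_catalog(muts, ref_of(seq), "SBS96")
        assert vec.total == 1 and vec.ignored == 1
        assert vec.total + vec.unclassifiable + vec.ignored == len(muts)

    def test_classified_plus_unclassifiable_equals_input(self, cohort):
        from serrata.pipeline import _read_fasta  # reuse loader shape

        reference = cohort.reference
        muts = [v for v, _ in cohort.somatic["SPS.07"]
                if "GLSITE" not in v.flags]
        for scheme in ("SBS96", "ID"):
            vec = build_catalog(muts, reference, scheme)
            assert vec.total + vec.unclassifiable + vec.ignored == len(muts)


class TestBurden:
    def _muts(self, n_snv, n_indel):
        muts = [snv(i + 1, "A", "G") for i in range(n_snv)]
        muts += [
            make_variant(pos=10_000 + i, ref="AT", alt="A",
                         consequence="frameshift", impact="truncating")
            for i in range(n_indel)
        ]
        return muts

    def test_hypermutated_at_27_6(self):
        rep = compute_burden(self._muts(1380, 0), 50.0)
        assert rep.tmb == pytest.approx(27.6)
        assert rep.load_class == "hypermutated"

    def test_hypermutated_at_89(self):
        rep = compute_burden(self._muts(4450, 0), 50.0)
        assert rep.tmb == pytest.approx(89.0)
        assert rep.load_class == "hypermutated"

    def test_ultra_hypermutated_indels(self):
        rep = compute_burden(self._muts(0, 5030), 50.0)
        assert rep.indel_burden == pytest.approx(100.6)
        assert rep.load_class == "ultra_hypermutated"

    def test_exactly_ten_is_non_hypermutated(self):
        rep = compute_burden(self._muts(500, 0), 50.0)
        assert rep.tmb == pytest.approx(10.0)
        assert rep.load_class == "non_hypermutated"

    def test_exactly_hundred_is_hypermutated(self):
        assert classify_load(100.0) == "hypermutated"

    def test_classes_partition(self):
        for tmb in (0, 5, 10, 10.001, 50, 100, 100.001, 500):
            assert classify_load(tmb) in (
                "non_hypermutated", "hypermutated", "ultra_hypermutated"
            )

    def test_zero_footprint_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            compute_burden([], 0.0)


def grid_search_two_signatures(v, s1, s2, step=0.01, w_max=1.5):
    """Oracle for 2-signature refits: exhaustive 2-D scan over both
    non-negative weights (same least-squares objective as the fitter),
    returning the normalized weight of the first signature."""
    grid = np.arange(0.0, w_max + step / 2, step)
    best = (0.0, 0.0)
    best_err = np.inf
    for w1 in grid:
        resid = v - w1 * s1
        errs = np.linalg.norm(
            resid[None, :] - grid[:, None] * s2[None, :], axis=1
        )
        j = int(np.argmin(errs))
        if errs[j] < best_err:
            best_err = float(errs[j])
            best = (float(w1), float(grid[j]))
    total = best[0] + best[1]
    return best[0] / total if total else 0.0


class TestRefit:
    def test_exact_two_signature_mixture(self, sbs_catalog):
        mix = 0.7 * sbs_catalog.signatures["SBS1"] + \
              0.3 * sbs_catalog.signatures["SBS5"]
        counts = np.round(mix * 100_000).astype(int)
        vec = CatalogVector("SBS96", counts)
        res = refit_signatures(vec, sbs_catalog.subset(["SBS1", "SBS5"]))
        assert res.weights["SBS1"] == pytest.approx(0.7, abs=0.01)
        assert res.weights["SBS5"] == pytest.approx(0.3, abs=0.01)
        assert res.cosine > 0.999

    def test_single_signature_recovered_from_full_catalog(self, sbs_catalog):
        profile = sbs_catalog.signatures["SBS1"]
        counts = np.round(profile * 100_000).astype(int)
        res = refit_signatures(CatalogVector("SBS96", counts), sbs_catalog)
        assert set(res.weights) == {"SBS1"}
        assert res.weights["SBS1"] == pytest.approx(1.0)

    def test_zero_vector_defined_result(self, sbs_catalog):
        res = refit_signatures(
            CatalogVector("SBS96", np.zeros(96, dtype=int)), sbs_catalog
        )
        assert res.weights == {} and res.n_mutations == 0

    def test_weights_nonnegative_and_sum_one(self, sbs_catalog):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 50, size=96)
        res = refit_signatures(CatalogVector("SBS96", counts), sbs_catalog)
        assert all(w >= 0 for w in res.weights.values())
        assert sum(res.weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_nnls_matches_grid_search_on_two_signature_problems(
        self, sbs_catalog
    ):
        rng = np.random.default_rng(11)
        s1 = sbs_catalog.signatures["SBS1"]
        s2 = sbs_catalog.signatures["SBS5"]
        for w_true in (0.2, 0.5, 0.85):
            n = 5_000
            counts = rng.multinomial(n, w_true * s1 + (1 - w_true) * s2)
            vec = CatalogVector("SBS96", counts)
            res = refit_signatures(
                vec, sbs_catalog.subset(["SBS1", "SBS5"]),
                prune_threshold=0.0, min_cosine_drop=0.0,
            )
            w_grid = grid_search_two_signatures(counts / n, s1, s2)
            assert res.weights.get("SBS1", 0.0) == pytest.approx(
                w_grid, abs=0.01
            )

    def test_sampled_three_signature_mixture_recovery(self, sbs_catalog):
        """Mixture {SBS1 .5, SBS5 .3, SBS15 .2} at n=2000: recovered
        within +/-0.05 (derived via fixed-seed simulation)."""
        rng = np.random.default_rng(11)
        truth = {"SBS1": 0.5, "SBS5": 0.3, "SBS15": 0.2}
        p = sum(w * sbs_catalog.signatures[s] for s, w in truth.items())
        counts = rng.multinomial(2_000, p)
        res = refit_signatures(CatalogVector("SBS96", counts), sbs_catalog)
        for sig, w in truth.items():
            assert res.weights.get(sig, 0.0) == pytest.approx(w, abs=0.05)


class TestAetiology:
    def _refit(self, weights):
        from serrata.mutational_profile import RefitResult

        return RefitResult(weights=weights, cosine=0.99,
                           n_mutations=1000, pruned=[])

    def test_clock_like_dominant(self):
        flags = flag_aetiology(self._refit({"SBS1": 0.6, "SBS5": 0.4}))
        assert flags == {"clock-like": pytest.approx(1.0)}

    def test_mmr_deficiency_flagged(self):
        flags = flag_aetiology(self._refit({"SBS1": 0.7, "SBS15": 0.3}))
        assert "MMR-deficiency" in flags

    def test_small_weight_suppressed_as_overfitting_guard(self):
        flags = flag_aetiology(self._refit({"SBS1": 0.98, "SBS15": 0.02}))
        assert "MMR-deficiency" not in flags

    def test_artifact_flag(self):
        flags = flag_aetiology(self._refit({"SBS54": 0.2, "SBS1": 0.8}))
        assert "possible-artifact" in flags


class TestDriverReport:
    def _mut(self, gene, hgvs, alt, depth=100):
        v = make_variant(gene=gene, protein_change=hgvs)
        return (v, GenotypeCall("t", "het", depth - alt, alt, depth))

    def test_braf_v600e_high_tier_hotspot(self):
        rep = driver_report([self._mut("BRAF", "V600E", 32)])
        [c] = rep.calls
        assert c.tier == "high" and c.hotspot

    def test_low_aaf_still_reported(self):
        rep = driver_report([self._mut("BRAF", "V600E", 12)])
        [c] = rep.calls
        assert c.tier == "low" and c.hotspot

    def test_aaf_exactly_20_percent_is_high(self):
        rep = driver_report([self._mut("MLH1", "R687Q", 20)])
        assert rep.calls[0].tier == "high"

    def test_kras_a146t_flagged_hotspot(self):
        rep = driver_report([self._mut("KRAS", "A146T", 25)])
        [c] = rep.calls
        assert c.hotspot and c.gene == "KRAS"

    def test_non_driver_gene_ignored(self):
        rep = driver_report([self._mut("TTN", "A1T", 40)])
        assert rep.calls == []
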