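"""Fusion validation tests: chimera reconstruction, prefilters, normal-panel
screening, assembly and gap-fill breakpoint confirmation (with boundary cases
for every matching rule), genomic artifact checks and feature scoring."""

import numpy as np
import pytest

from somapipe.fusion import (
    Breakpoint,
    CandidateFusion,
    annotate_and_score,
    assemble_contigs,
    contig_validate,
    gapfill_validate,
    genomic_artifact_check,
    normal_panel_filter,
    prefilter_candidates,
    reconstruct_chimera,
    splice_class_of,
)
from somapipe.intervals import GenomicInterval
from somapipe.seq import revcomp

from conftest import random_seq


def make_candidate(rng, length=400, junction=200):
    chimera = random_seq(rng, length)
    return CandidateFusion(
        "c1",
        Breakpoint("chr1", 0, "+", None),
        Breakpoint("chr2", 0, "+", None),
        chimera=chimera,
        junction_index=junction,
    )


def tiling_reads(template, read_length=100, step=3):
    return [template[i : i + read_length] for i in range(0, len(template) - read_length + 1, step)]


class TestReconstruction:
    def test_full_flanks_give_400_base_chimera(self, rng):
        genome = {"chrA": random_seq(rng, 1000), "chrB": random_seq(rng, 1000)}
        cand = reconstruct_chimera(genome, Breakpoint("chrA", 500, "+"), Breakpoint("chrB", 300, "+"))
        assert len(cand.chimera) == 400
        assert cand.junction_index == 200
        assert cand.chimera[:200] == genome["chrA"][300:500]
        assert cand.chimera[200:] == genome["chrB"][300:500]

    def test_truncation_near_contig_edge(self, rng):
        genome = {"chrA": random_seq(rng, 1000), "chrB": random_seq(rng, 1000)}
        cand = reconstruct_chimera(genome, Breakpoint("chrA", 30, "+"), Breakpoint("chrB", 300, "+"))
        assert cand.junction_index == 30
        assert len(cand.chimera) == 230

    def test_minus_strand_five_prime_flank_is_reverse_complement(self, rng):
        genome = {"chrA": random_seq(rng, 1000), "chrB": random_seq(rng, 1000)}
        cand = reconstruct_chimera(genome, Breakpoint("chrA", 500, "-"), Breakpoint("chrB", 300, "+"))
        assert cand.chimera[:200] == revcomp(genome["chrA"][500:700])

    def test_off_contig_breakpoint_rejected(self, rng):
        genome = {"chrA": random_seq(rng, 100)}
        with pytest.raises(ValueError, match="off contig"):
            reconstruct_chimera(genome, Breakpoint("chrA", 500, "+"), Breakpoint("chrA", 10, "+"))


class TestPrefilter:
    def test_biotype_readthrough_and_interchromosomal(self, reference):
        genes = reference["genes"]
        genome = reference["genome"]
        coding = [g for g in genes if g.biotype == "protein_coding" and g.chrom == "chr1"]
        mirna = next(g for g in genes if g.biotype == "miRNA")
        c_bio = reconstruct_chimera(
            genome, Breakpoint("chr1", coding[0].exons[0].end, "+", coding[0].name),
            Breakpoint("chr1", mirna.exons[0].start, mirna.strand, mirna.name), "bio")
        c_rt = reconstruct_chimera(
            genome, Breakpoint("chr1", coding[0].exons[0].end, "+", coding[0].name),
            Breakpoint("chr1", coding[1].exons[-1].start, "+", coding[1].name), "rt")
        c_far = reconstruct_chimera(
            genome, Breakpoint("chr1", coding[0].exons[0].end, "+", coding[0].name),
            Breakpoint("chrM", 300, "+", None), "mito")
        c_ok = reconstruct_chimera(
            genome, Breakpoint("chr1", coding[0].exons[0].end, "+", coding[0].name),
            Breakpoint("chr1", coding[4].exons[-1].start, coding[4].strand, coding[4].name), "ok")
        kept, removed = prefilter_candidates([c_bio, c_rt, c_far, c_ok], genes)
        assert removed == {"bio": "biotype:miRNA", "rt": "read_through", "mito": "mitochondrial"}
        assert [c.candidate_id for c in kept] == ["ok"]


class TestNormalPanel:
    @pytest.mark.parametrize(
        "n_reads,n_samples,removed",
        [(4, 4, True), (5, 5, True), (4, 3, False), (3, 4, False), (10, 2, False), (0, 0, False)],
    )
    def test_more_than_three_reads_and_samples(self, rng, n_reads, n_samples, removed):
        cand = make_candidate(rng)
        j = cand.junction_index
        read_sets = {f"S{i}": [] for i in range(max(n_samples, 1))}
        for k in range(n_reads):
            read = cand.chimera[j - 30 - k : j + 30 - k]
            read_sets[f"S{k % max(n_samples, 1)}"].append(read)
        out = normal_panel_filter(cand, read_sets)
        assert out["removed"] is removed

    def test_minimum_overlap_of_10_perfect_bases(self, rng):
        cand = make_candidate(rng)
        j = cand.junction_index
        ten = cand.chimera[j - 5 : j + 5]
        nine = cand.chimera[j - 5 : j + 4]
        assert normal_panel_filter(cand, {"S": [ten]})["supporting"] == (1, 1)
        assert normal_panel_filter(cand, {"S": [nine]})["supporting"] == (0, 0)

    def test_mismatched_or_flank_only_reads_do_not_support(self, rng):
        cand = make_candidate(rng)
        j = cand.junction_index
        mismatched = list(cand.chimera[j - 30 : j + 30])
        mismatched[30 - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mismatched[29]]
        flank_only = cand.chimera[10:90]
        out = normal_panel_filter(cand, {"S": ["".join(mismatched), flank_only]})
        assert out["supporting"] == (0, 0)


class TestAssembly:
    def test_error_free_tiling_reads_reassemble_chimera(self, rng):
        template = random_seq(rng, 400)
        contigs = assemble_contigs(tiling_reads(template))
        assert any(template in c or c in template for c in contigs)
        assert any(len(c) >= 350 for c in contigs)

    def test_disjoint_regions_give_separate_contigs(self, rng):
        a, b = random_seq(rng, 200), random_seq(rng, 200)
        reads = tiling_reads(a, 80, 2) + tiling_reads(b, 80, 2)
        contigs = assemble_contigs(reads)
        assert any(c in a or a in c for c in contigs)
        assert any(c in b or b in c for c in contigs)
        assert not any((a[-40:] + b[:40]) in c for c in contigs)

    def test_matches_greedy_overlap_oracle_on_small_instances(self, rng):
        """Greedy overlap-layout assembly of <=50 error-free reads must agree
        with the de Bruijn unitigs on the reconstructed sequence."""

        def greedy_overlap_assemble(reads):
            seqs = sorted(set(reads), key=reads.index)
            while len(seqs) > 1:
                best = (0, None, None)
                for i, x in enumerate(seqs):
                    for k, y in enumerate(seqs):
                        if i == k:
                            continue
                        for o in range(min(len(x), len(y)), 9, -1):
                            if x[-o:] == y[:o]:
                                if o > best[0]:
                                    best = (o, i, k)
                                break
                if best[0] == 0:
                    break
                o, i, k = best
                merged = seqs[i] + seqs[k][o:]
                seqs = [s for n, s in enumerate(seqs) if n not in (i, k)] + [merged]
            return max(seqs, key=len)

        template = random_seq(rng, 250)
        reads = tiling_reads(template, 60, 5)  # 39 reads
        oracle = greedy_overlap_assemble(reads)
        contigs = assemble_contigs(reads, k_ladder=(31,))
        assert oracle == template
        assert any(oracle in c or c in oracle for c in contigs)

    def test_empty_and_short_reads_rejected(self):
        with pytest.raises(ValueError):
            assemble_contigs([])
        with pytest.raises(ValueError):
            assemble_contigs(["ACGT"], k_ladder=(31,))


class TestContigValidation:
    def test_spanning_contig_validates(self, rng):
        cand = make_candidate(rng)
        j = cand.junction_index
        assert contig_validate(cand.chimera[j - 20 : j + 20], cand)

    def test_three_base_side_requirement(self, rng):
        cand = make_candidate(rng)
        j = cand.junction_index
        assert contig_validate(cand.chimera[j - 17 : j + 3], cand)
        assert not contig_validate(cand.chimera[j - 18 : j + 2], cand)

    def test_at_most_one_mismatch(self, rng):
        cand = make_candidate(rng)
        j = cand.junction_index
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        one = list(cand.chimera[j - 20 : j + 20])
        one[5] = flip[one[5]]
        assert contig_validate("".join(one), cand)
        two = list(cand.chimera[j - 20 : j + 20])
        two[5], two[14] = flip[two[5]], flip[two[14]]
        assert not contig_validate("".join(two), cand)


class TestGapFill:
    def test_error_free_junction_reads_validate_with_zero_delta(self, rng):
        cand = make_candidate(rng)
        out = gapfill_validate(cand, tiling_reads(cand.chimera))
        assert out["validated"]
        assert out["reconstructed_length_delta"] == 0
        assert out["left_overlap"] >= 3 and out["right_overlap"] >= 3

    def test_flank_only_reads_do_not_close_gap(self, rng):
        cand = make_candidate(rng)
        out = gapfill_validate(cand, tiling_reads(cand.chimera[:180]))
        assert not out["validated"]
        assert out["reason"] == "gap not closed"

    def test_no_reads_reports_no_coverage(self, rng):
        out = gapfill_validate(make_candidate(rng), [])
        assert not out["validated"] and out["reason"] == "no coverage"

    @pytest.mark.parametrize("deleted,valid", [(1, True), (2, False)])
    def test_length_delta_tolerance_one_base(self, rng, deleted, valid):
        # reads come from the true transcript; the candidate chimera is missing
        # `deleted` bases at the junction, so the rebuilt gap is 5 + deleted
        true_tx = random_seq(rng, 400)
        j = 200
        chimera = true_tx[: j - deleted] + true_tx[j:]
        cand = CandidateFusion("c", Breakpoint("chr1", 0, "+"), Breakpoint("chr2", 0, "+"),
                               chimera=chimera, junction_index=j - deleted)
        out = gapfill_validate(cand, tiling_reads(true_tx))
        assert out["validated"] is valid
        if not valid:
            assert out["reconstructed_length_delta"] == deleted

    def test_invariant_to_read_order_and_monotone_in_coverage(self, rng):
        cand = make_candidate(rng)
        reads = tiling_reads(cand.chimera)
        out1 = gapfill_validate(cand, reads)
        out2 = gapfill_validate(cand, reads[::-1])
        assert out1 == out2
        j = cand.junction_index
        more = reads + [cand.chimera[j - 50 : j + 50]] * 5
        assert gapfill_validate(cand, more)["validated"]


class TestGenomicArtifacts:
    def plant(self, rng, copy_len, span_extra=None, mismatch_at=None):
        """Chimera plus toy genome; optionally a duplicated chimera window of
        ``copy_len`` bases, or a locus reading through the junction by
        ``span_extra`` bases (with guard mismatches at the boundary)."""
        chimera = random_seq(rng, 400)
        j = 200
        genome = list(random_seq(rng, 3000))
        if copy_len:
            genome[1000 : 1000 + copy_len] = chimera[60 : 60 + copy_len]
            # guard mismatches so the exact run cannot extend by luck
            flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
            genome[999] = flip[chimera[59]]
            genome[998] = flip[chimera[58]]
            genome[1000 + copy_len] = flip[chimera[60 + copy_len]]
            genome[1001 + copy_len] = flip[chimera[61 + copy_len]]
        if span_extra is not None:
            seg = chimera[140 : j + span_extra]
            if mismatch_at is not None:
                seg = list(seg)
                flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
                seg[mismatch_at] = flip[seg[mismatch_at]]
                seg = "".join(seg)
            genome[2000 : 2000 + len(seg)] = seg
            flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
            genome[1999] = flip[chimera[139]]
            genome[1998] = flip[chimera[138]]
            genome[2000 + len(seg)] = flip[chimera[j + span_extra] if j + span_extra < 400 else "A"]
            genome[2001 + len(seg)] = flip[chimera[j + span_extra + 1] if j + span_extra + 1 < 400 else "A"]
        cand = CandidateFusion("c", Breakpoint("chrX", 0, "+"), Breakpoint("chrY", 0, "+"),
                               chimera=chimera, junction_index=j,
                               source_spans=[GenomicInterval("chrQ", 0, 1)])
        return cand, {"chrZ": "".join(genome)}

    @pytest.mark.parametrize("copy_len,flagged", [(51, True), (50, False)])
    def test_misalignment_needs_more_than_50_exact_bases(self, rng, copy_len, flagged):
        cand, genome = self.plant(rng, copy_len)
        assert genomic_artifact_check(cand, genome)["misalignment"] is flagged

    @pytest.mark.parametrize("span_extra,flagged", [(11, True), (10, False)])
    def test_breakpoint_overhang_needs_more_than_10_bases(self, rng, span_extra, flagged):
        cand, genome = self.plant(rng, 0, span_extra=span_extra)
        assert genomic_artifact_check(cand, genome)["breakpoint_artifact"] is flagged

    def test_identity_boundary_at_99_percent(self, rng):
        # 80-base spanning locus, 20-base overhang: exact copy (identity 1.0)
        # flags; one mismatch (identity 0.9875 <= 0.99) does not
        exact, genome = self.plant(rng, 0, span_extra=20)
        assert genomic_artifact_check(exact, genome)["breakpoint_artifact"]
        noisy, genome2 = self.plant(rng, 0, span_extra=20, mismatch_at=40)
        assert not genomic_artifact_check(noisy, genome2)["breakpoint_artifact"]

    def test_low_complexity_window_flagged(self, rng):
        # a homopolymer run scores 100 on the fraction-of-maximum DUST scale;
        # note a pure AT dinucleotide repeat only reaches ~49 and is NOT flagged
        cand, genome = self.plant(rng, 0)
        cand.chimera = cand.chimera[:100] + "A" * 80 + cand.chimera[180:]
        assert genomic_artifact_check(cand, genome)["low_complexity"]
        at_repeat, genome2 = self.plant(rng, 0)
        at_repeat.chimera = at_repeat.chimera[:100] + "AT" * 40 + at_repeat.chimera[180:]
        assert not genomic_artifact_check(at_repeat, genome2)["low_complexity"]

    def test_clean_unique_chimera_unflagged(self, rng):
        cand, genome = self.plant(rng, 0)
        flags = genomic_artifact_check(cand, genome)
        assert flags == {"misalignment": False, "low_complexity": False,
                         "breakpoint_artifact": False}


class TestAnnotationScoring:
    @pytest.mark.parametrize(
        "donor,acceptor,expect",
        [("GT", "AG", "major"), ("GC", "AG", "minor"), ("AT", "AC", "minor"),
         ("AA", "AA", "noncanonical")],
    )
    def test_splice_classes(self, donor, acceptor, expect):
        assert splice_class_of(donor, acceptor) == expect

    def test_exon_boundary_fusion_scores_maximum(self, reference):
        genes = reference["genes"]
        genome = dict(reference["genome"])
        coding = [g for g in genes if g.biotype == "protein_coding" and g.chrom == "chr1"
                  and g.strand == "+"]
        g5, g3 = coding[0], coding[2]
        bp5 = Breakpoint("chr1", g5.exons[0].end, "+", g5.name)
        bp3 = Breakpoint("chr1", g3.exons[1].start, "+", g3.name)
        cand = reconstruct_chimera(genome, bp5, bp3, "scored")
        # force matching phase: both breakpoints at exon edges of GT..AG introns
        cb5 = g5.coding_bases_before(bp5.pos) % 3
        cb3 = g3.coding_bases_before(bp3.pos) % 3
        annotate_and_score(cand, genes, genome)
        f = cand.features
        assert f["at_splice_junction5"] and f["at_splice_junction3"]
        assert f["splice_class"] == "major"
        assert f["in_frame"] is (cb5 == cb3)
        expected = 2 + 2 + 2 + (2 if cb5 == cb3 else 0)
        assert cand.score == expected

    def test_artifact_flags_subtract_three_each(self, rng):
        cand = make_candidate(rng)
        cand.validation.update({"misalignment": True, "breakpoint_artifact": True})
        annotate_and_score(cand, [], {"chr1": "A" * 10, "chr2": "A" * 10})
        assert cand.score <= -6 + 2  # two flags, at most splice-class credit
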