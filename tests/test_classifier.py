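"""Amplicon stripping, spliced alignment, true-positive and category calls."""

import pytest

from stace.classifier import (
    AmpliconAlignment,
    POLYA_ADAPTER,
    align_amplicon,
    assemble_full_length,
    check_splice_signals,
    classify_result,
    detect_and_strip_polya,
    detect_and_strip_sl1,
    evaluate_amplicon,
    is_true_positive,
)
from stace.genome import AnnotationIndex, GenomeSequence
from stace.mapper import TagMapping
from stace.primers import SL1_PRIMER, UNIVERSAL_PRIMER, revcomp


class TestStripSL1:
    def test_full_leader(self):
        body = "ACGTACGTACGT"
        assert detect_and_strip_sl1(SL1_PRIMER + body) == (body, True)

    def test_partial_leader_suffix(self):
        body = "ACGTACGTACGT"
        read = SL1_PRIMER[-14:] + body
        assert detect_and_strip_sl1(read) == (body, True)

    def test_no_leader(self):
        body = "ACGTACGTACGT"
        assert detect_and_strip_sl1(body) == (body, False)

    def test_below_minimum_not_stripped(self):
        body = "CCGTACGTACGT"
        read = SL1_PRIMER[-8:] + body
        stripped, found = detect_and_strip_sl1(read, min_sl1=12)
        assert not found and stripped == read


class TestStripPolyA:
    def test_long_tail_stripped(self):
        assert detect_and_strip_polya("ACGTC" + "A" * 16) == ("ACGTC", True)

    def test_short_tail_kept(self):
        assert detect_and_strip_polya("ACGTC" + "A" * 5) == ("ACGTC" + "A" * 5, False)

    def test_adapter_then_tail(self):
        read = "ACGTC" + "A" * 16 + revcomp(UNIVERSAL_PRIMER)
        assert detect_and_strip_polya(read) == ("ACGTC", True)

    def test_adapter_is_universal_primer_revcomp(self):
        assert POLYA_ADAPTER == revcomp(UNIVERSAL_PRIMER)


class TestAlignAmplicon:
    def test_simulator_amplicons_recover_planted_exons(self, sim_clean):
        """Upstream reads spliced from planted exons align to those exons."""
        for g in sim_clean.truth.novel_genes:
            for amp_id, read in sim_clean.amplicons:
                if f"tag={g.tag}" not in amp_id or not amp_id.endswith("up"):
                    continue
                body, found = detect_and_strip_sl1(read)
                assert found
                aln = align_amplicon(body, sim_clean.genome, amp_id)
                assert aln is not None
                assert aln.strand == g.strand
                # upstream read covers transcript start..tag end: on + that is
                # exons truncated at the tag; block boundaries must be a
                # subset of the planted exon structure
                for (s, e), (ps, pe) in zip(aln.blocks, g.exons):
                    assert s == ps or e == pe

    def test_single_exon_read_single_block(self, sim_clean):
        g = sim_clean.truth.novel_genes[0]
        chrom = sim_clean.genome.sequences[g.chrom]
        s, e = g.exons[0]
        aln = align_amplicon(chrom[s : e], sim_clean.genome)
        assert aln is not None and len(aln.blocks) == 1
        assert aln.introns == []

    def test_substitution_requires_mismatch_budget(self, sim_clean):
        g = sim_clean.truth.novel_genes[0]
        chrom = sim_clean.genome.sequences[g.chrom]
        s, e = g.exons[0]
        read = chrom[s:e]
        mid = len(read) // 2
        sub = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[mid]]
        mutated = read[:mid] + sub + read[mid + 1 :]
        assert align_amplicon(mutated, sim_clean.genome, max_mismatch=0) is None
        aln = align_amplicon(mutated, sim_clean.genome, max_mismatch=1)
        assert aln is not None and aln.blocks == [(s, e)]

    def test_unalignable_read_reported_none(self, sim_clean):
        assert align_amplicon("TTTT" * 20, sim_clean.genome) is None


class TestTruePositive:
    def _aln(self, chrom, b5, b3, strand="+"):
        lo, hi = min(b5, b3), max(b5, b3)
        return AmpliconAlignment("a", chrom, strand, [(lo - 1, hi)])

    def test_plus_orientation_containment(self):
        # a recovered cDNA spanning II:8786297-8787044 around a tag at II:8786920
        aln = self._aln("II", 8786297, 8787044)
        tag = TagMapping("N" * 21, "II", 8786920 - 1, "+")
        assert is_true_positive(aln, tag)

    def test_minus_orientation_boundaries_bracket_tag(self):
        # minus-strand result: printed 5' boundary (9376228) exceeds 3' (9375792)
        aln = self._aln("II", 9376228, 9375792, strand="-")
        tag = TagMapping("N" * 21, "II", 9375813 - 1, "+")
        assert is_true_positive(aln, tag)

    def test_disjoint_span_is_false(self):
        aln = self._aln("X", 100, 200)
        tag = TagMapping("N" * 21, "X", 999999 - 1, "+")
        assert not is_true_positive(aln, tag)

    def test_other_chromosome_is_false_not_error(self):
        aln = self._aln("X", 100, 200)
        tag = TagMapping("N" * 21, "II", 100, "+")
        assert not is_true_positive(aln, tag)


class TestSpliceSignals:
    def test_simulator_introns_canonical(self, sim_clean, clean_index):
        for g in sim_clean.truth.novel_genes:
            aln = AmpliconAlignment("a", g.chrom, g.strand, list(g.exons))
            signals = check_splice_signals(aln, sim_clean.genome)
            assert len(signals) == len(g.exons) - 1
            assert all(s.canonical for s in signals)

    def test_gc_ag_mutant_flagged_not_rejected(self, sim_clean):
        g = next(gene for gene in sim_clean.truth.novel_genes if len(gene.exons) >= 2)
        mutated = dict(sim_clean.genome.sequences)
        seq = mutated[g.chrom]
        a, b = g.exons[0][1], g.exons[1][0]  # first intron, genomic
        if g.strand == "+":
            seq = seq[: a + 1] + "C" + seq[a + 2 :]  # GT -> GC at the donor
        else:
            seq = seq[: b - 2] + "GC" + seq[b:]  # donor is at the genomic right end
        mutated[g.chrom] = seq
        genome2 = GenomeSequence(sim_clean.genome.chrom_names, mutated)
        aln = AmpliconAlignment("a", g.chrom, g.strand, list(g.exons))
        signals = check_splice_signals(aln, genome2)
        assert signals[0].canonical is False
        assert signals[0].dinucleotides.startswith("GC")

    def test_zero_intron_alignment_empty_status(self, sim_clean):
        g = sim_clean.truth.novel_genes[0]
        aln = AmpliconAlignment("a", g.chrom, g.strand, [g.exons[0]])
        assert check_splice_signals(aln, sim_clean.genome) == []


class TestClassifyResult:
    def test_planted_categories_zero_confusion(self, sim_clean, clean_index):
        """Novel, pseudogene-overlap and ncRNA-overlap cases all come back
        exactly as planted."""
        for g in sim_clean.truth.novel_genes:
            aln = AmpliconAlignment("a", g.chrom, g.strand, list(g.exons))
            category, genes = classify_result(aln, clean_index)
            assert category == "novel_gene" and genes == []
        for g in sim_clean.truth.annotated_genes:
            aln = AmpliconAlignment("a", g.chrom, g.strand, list(g.exons))
            category, genes = classify_result(aln, clean_index)
            if g.biotype in ("pseudogene", "ncRNA"):
                assert category == "non_coding_overlap"
            else:
                assert category == "annotation_extension"
            assert g.gene_id in genes

    def test_non_coding_precedence_over_coding(self, clean_index, sim_clean):
        """An amplicon overlapping both a coding gene and a pseudogene is
        reported as a non-coding overlap."""
        pseudo = next(g for g in sim_clean.truth.annotated_genes if g.biotype == "pseudogene")
        coding = next(g for g in sim_clean.truth.annotated_genes
                      if g.biotype == "protein_coding" and g.chrom == pseudo.chrom)
        lo = min(pseudo.exons[0][0], coding.exons[0][0])
        hi = max(pseudo.exons[-1][1], coding.exons[-1][1])
        aln = AmpliconAlignment("a", pseudo.chrom, "+", [(lo, hi)])
        category, _ = classify_result(aln, clean_index)
        assert category == "non_coding_overlap"


class TestAssembleFullLength:
    def _pair(self, sim, gene, index):
        mapping = TagMapping(gene.tag, gene.chrom, gene.tag_interval[0],
                             "+" if gene.strand == "+" else "-")
        pair = {}
        for amp_id, read in sim.amplicons:
            if f"tag={gene.tag}" in amp_id:
                d = "up" if amp_id.endswith("up") else "down"
                pair[d] = evaluate_amplicon(read, amp_id, sim.genome, index, mapping)
        up, down = pair["up"].alignment, pair["down"].alignment
        up.sl1_found = pair["up"].sl1_found
        down.polya_found = pair["down"].polya_found
        return up, down, mapping

    def test_pair_merges_to_planted_gene(self, sim_clean, clean_index):
        for g in sim_clean.truth.novel_genes:
            up, down, mapping = self._pair(sim_clean, g, clean_index)
            merge = assemble_full_length(up, down, mapping)
            assert not merge.rejected
            assert merge.blocks == list(g.exons)
            assert merge.strand == g.strand
            assert merge.full_length  # SL1 fraction is 1 in this world

    def test_upstream_only_is_partial(self, sim_clean, clean_index):
        g = sim_clean.truth.novel_genes[0]
        up, down, mapping = self._pair(sim_clean, g, clean_index)
        down.polya_found = False  # downstream evidence withdrawn
        merge = assemble_full_length(up, down, mapping)
        assert not merge.rejected and not merge.full_length

    def test_conflicting_overlap_rejected(self, sim_clean, clean_index):
        g = next(gene for gene in sim_clean.truth.novel_genes if len(gene.exons) >= 2)
        up, down, mapping = self._pair(sim_clean, g, clean_index)
        # a fake downstream spanning the same region as the upstream but with
        # one internal junction displaced: chains disagree over the overlap
        blocks = list(up.blocks)
        s2, e2 = blocks[1]
        blocks[1] = (s2 + 2, e2)
        conflicting = AmpliconAlignment("fake", up.chrom, up.strand, blocks)
        merge = assemble_full_length(up, conflicting, mapping)
        assert merge.rejected and "disagree" in merge.reason
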