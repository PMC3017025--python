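"""Primer derivation and the structure/Tm screens, vs exhaustive oracles."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stace.primers import (
    DEFAULT_CONSTRAINTS,
    SL1_PRIMER,
    UNIVERSAL_PRIMER,
    RT_PRIMER,
    PrimerConstraints,
    derive_primer,
    dimer_score,
    gc_percent,
    hairpin_score,
    revcomp,
    screen_primer,
    tm_estimate,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


class TestRevcomp:
    def test_nlaiii_site_is_self_complementary(self):
        assert revcomp("CATG") == "CATG"

    def test_real_screen_primer(self):
        # independent base-by-base complementation of a 21-nt screen primer
        primer = "GTTAGGATCGTAGAGGACATG"
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        expected = "".join(comp[b] for b in reversed(primer))
        assert expected == "CATGTCCTCTACGATCCTAAC"
        assert revcomp(primer) == expected

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(dna)
    def test_involution(self, seq):
        assert revcomp(revcomp(seq)) == seq

    def test_invalid_character_is_error(self):
        with pytest.raises(ValueError):
            revcomp("ACGU")


def oracle_hairpin(seq, min_loop=3):
    """Exhaustive substring-pair search: longest l with seq[i:i+l] reverse-
    complementary to seq[j:j+l] and a loop of >= min_loop between them."""
    n = len(seq)
    best = 0
    for l in range(1, n // 2 + 1):
        for i in range(n - l + 1):
            for j in range(i + l + min_loop, n - l + 1):
                if seq[i : i + l] == revcomp(seq[j : j + l]):
                    best = max(best, l)
    return best


class TestHairpin:
    @pytest.mark.parametrize(
        "seq,stem,flagged",
        [("GGGGAAAACCCC", 4, True), ("ACACACACACAC", 0, False)],
    )
    def test_examples_match_oracle(self, seq, stem, flagged):
        assert oracle_hairpin(seq) == stem
        got_stem, got_flag = hairpin_score(seq)
        assert (got_stem, got_flag) == (stem, flagged)

    def test_below_minimum_length_clean_by_definition(self):
        assert hairpin_score("GGGGACCCCA", min_stem=4, min_loop=3) == (0, False)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=11, max_size=24))
    def test_agrees_with_exhaustive_oracle(self, seq):
        stem, _ = hairpin_score(seq)
        assert stem == oracle_hairpin(seq)


def oracle_dimer_max_run(a, b):
    """Exhaustive offset scan: longest contiguous complementary run when a
    (5'->3') is laid against b (3'->5')."""
    rb = b[::-1]
    best = 0
    for off in range(-(len(rb) - 1), len(a)):
        run = 0
        for j in range(len(rb)):
            i = off + j
            if 0 <= i < len(a) and a[i] == revcomp(rb[j]):
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


class TestDimer:
    def test_full_complement_flagged(self):
        d = dimer_score("AAAAAAAA", "TTTTTTTT")
        assert d.max_run == 8 and d.flagged

    def test_self_complementary_motif(self):
        # ACGTACGT contains the self-complementary ACGT: run >= 4
        d = dimer_score("ACGTACGT", "ACGTACGT", min_run=5)
        assert d.max_run >= 4
        assert d.flagged == (d.max_run >= 5 or d.anchored_run >= 3)

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            dimer_score("ACGT", "")

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(a=st.text(alphabet="ACGT", min_size=2, max_size=15),
           b=st.text(alphabet="ACGT", min_size=2, max_size=15))
    def test_max_run_agrees_with_oracle(self, a, b):
        assert dimer_score(a, b).max_run == oracle_dimer_max_run(a, b)


REAL_PRIMERS = [
    "GTTAGGATCGTAGAGGACATG", "AGAGGATTAATTCCCCCCATG", "GGGGGAAAATCGAAAGACATG",
    "GAAACGAAGAAGAAAAGCATG", "TTCGACGGCAGATTGTTCATG", "TAGCTCAGTCAAAACAACATG",
    "AAAGTTGAGCTTCTGCTCATG", "TGGTTGTTAGTAGTGTACATG", "CCATCTAAAGGGCTCTACA",
    "CTCATTGAAGGTGAAGCAT", "TGAAATGTCACAGTACACAT", "GAGAGAATTGTTGTGACCAT",
]


class TestTm:
    def test_gc_raises_tm(self):
        assert tm_estimate("GCGCGCGCGC") > tm_estimate("ATATATATAT")

    def test_monotone_under_gc_extension(self):
        seq = "CATGACGTAC"
        assert tm_estimate(seq + "GC") >= tm_estimate(seq)

    def test_wallace_rule_cross_check_on_primer_length_oligos(self):
        """Wallace 2(A+T)+4(G+C) tracks the NN estimate within 8 degC at the
        19-21-nt lengths the rule was designed for."""
        for p in REAL_PRIMERS:
            at = p.count("A") + p.count("T")
            gc = p.count("G") + p.count("C")
            wallace = 2 * at + 4 * gc
            assert abs(tm_estimate(p) - wallace) <= 8.0

    def test_too_short_is_error(self):
        with pytest.raises(ValueError):
            tm_estimate("ACGT")

    def test_real_screen_primers_fall_in_annealing_window(self):
        # all primers used at the 60 degC annealing step melt within [55, 65]
        for p in REAL_PRIMERS:
            assert 55.0 <= tm_estimate(p) <= 65.0


class TestFixedPrimers:
    def test_rt_primer_contains_universal_primer(self):
        assert UNIVERSAL_PRIMER in RT_PRIMER
        assert RT_PRIMER.endswith("T" * 16 + "VN")

    def test_sl1_length(self):
        assert len(SL1_PRIMER) == 22


class TestDerivePrimer:
    def test_output_revalidates_against_individual_screens(self, sim_clean):
        """Whatever derive_primer returns passes every screen it claims."""
        for g in sim_clean.truth.novel_genes:
            cand = derive_primer(g.tag)
            assert cand is not None
            ok, diag = screen_primer(cand.sequence)
            assert ok
            trimmed = g.tag[cand.trim_left : len(g.tag) - cand.trim_right]
            assert cand.sequence == revcomp(trimmed)
            assert len(cand.sequence) >= DEFAULT_CONSTRAINTS.min_length

    def test_all_at_tag_has_no_primer(self):
        assert derive_primer("CATGATATATATATATATATA") is None

    def test_trim_search_is_exhaustive(self, sim_clean):
        """Equivalent to brute-force enumeration over all admissible trims."""
        c = DEFAULT_CONSTRAINTS
        for g in sim_clean.truth.genes:
            tag = g.tag
            admissible = []
            for left, right in itertools.product(range(c.max_trim + 1), repeat=2):
                if left + right > c.max_trim or len(tag) - left - right < c.min_length:
                    continue
                primer = revcomp(tag[left : len(tag) - right])
                if screen_primer(primer, c)[0]:
                    admissible.append((left + right, left, primer))
            got = derive_primer(tag, c)
            if not admissible:
                assert got is None
            else:
                admissible.sort()
                assert got.sequence == admissible[0][2]

    def test_untrimmed_21mer_is_admissible_shape(self):
        """A clean tag can come back untrimmed as a full 21-nt primer."""
        cand = derive_primer("CATGTAAAAGGTGGGTTGATC")
        if cand is not None and cand.trim_left == cand.trim_right == 0:
            assert len(cand.sequence) == 21

    def test_gc_window_respected(self):
        relaxed = PrimerConstraints(tm_min=0, tm_max=100, hairpin_min_stem=99,
                                    dimer_min_run=99)
        cand = derive_primer("CATGTAAAAGGTGGGTTGATC", relaxed)
        assert cand is not None
        assert 35.0 <= gc_percent(cand.sequence) <= 45.0
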