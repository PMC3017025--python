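"""Curated validation records from the original C. elegans STACE screens.

Two small datasets are inlined here so the classifier's decision rules can
be exercised against real experimental outcomes without any external data:

``RECOVERED_CDNAS``
    The 14 SL1-trans-spliced cDNA sequences recovered by STACE from Set 3
    and earlier experiments: the gene-specific primer, the genomic location
    of the seeding SAGE tag, and the outermost 5'/3' mapping boundaries of
    the sequenced amplicon (1-based WormBase-style coordinates; for
    minus-strand results the printed 5' coordinate exceeds the 3' one).
    Record ``2.2`` carries a corrupted 5' coordinate in the published
    source (an extra digit placing it tens of megabases away); it is stored
    as ``None`` here and the containment span falls back to the tag-side
    coordinate.

``SCREEN_OUTCOMES``
    Per-set result classifications: counts of novel genes, annotation
    extensions and non-protein-coding overlaps among the candidate cDNAs,
    and the number of SAGE tag primers tested.

``SCREEN_FUNNELS``
    Per-set survivor counts of the tag-filtering cascade, from the initial
    library size down to the primers actually tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class RecoveredCdna:
    """One experimentally recovered cDNA anchored at a SAGE tag."""

    label: str
    full_length: bool  # polyadenylated 3' end recovered in addition to SL1
    primer: str
    chrom: str
    tag_pos: int  # 1-based start of the tag's genomic interval
    boundary_5p: int | None  # 1-based; None where the printed value is corrupt
    boundary_3p: int
    note: str

    @property
    def tag_length(self) -> int:
        # the tag is the reverse complement of the gene-specific primer
        return len(self.primer)

    @property
    def tag_interval(self) -> tuple[int, int]:
        """1-based closed genomic interval of the tag."""
        return self.tag_pos, self.tag_pos + self.tag_length - 1

    @property
    def span(self) -> tuple[int, int]:
        """Closed genomic span between the outermost mapping boundaries.

        Orientation-agnostic (min/max of the two ends); a missing 5'
        coordinate falls back to the tag-side coordinate.
        """
        b5 = self.boundary_5p if self.boundary_5p is not None else self.tag_pos
        return min(b5, self.boundary_3p), max(b5, self.boundary_3p)

    @property
    def sl1_found(self) -> bool:
        return True  # every recovered cDNA was SL1 trans-spliced

    @property
    def polya_found(self) -> bool:
        return self.full_length


RECOVERED_CDNAS: tuple[RecoveredCdna, ...] = (
    RecoveredCdna("P.1", True, "GTTAGGATCGTAGAGGACATG", "II", 8786920, 8786297, 8787044,
                  "overlaps a pseudogene: extension to annotated exon"),
    RecoveredCdna("P.2", False, "AGAGGATTAATTCCCCCCATG", "II", 9375813, 9376228, 9375792,
                  "overlaps a protein-coding gene"),
    RecoveredCdna("P.3", True, "GGGGGAAAATCGAAAGACATG", "II", 10201160, 10202155, 10201084,
                  "overlaps an ncRNA gene: evidence for new intron"),
    RecoveredCdna("1.1", False, "GAAACGAAGAAGAAAAGCATG", "V", 19434698, 19434352, 19434718,
                  "evidence of a novel gene"),
    RecoveredCdna("1.2", True, "TTCGACGGCAGATTGTTCATG", "V", 19432707, 19433037, 19432406,
                  "evidence for new 5' UTR"),
    RecoveredCdna("1.3", True, "TAGCTCAGTCAAAACAACATG", "V", 5812559, 5813070, 5812296,
                  "evidence for extension to 3' UTR"),
    RecoveredCdna("1.4a", False, "AAAGTTGAGCTTCTGCTCATG", "X", 2346863, 2335678, 2346883,
                  "evidence for new coding sequence"),
    RecoveredCdna("1.4b", False, "AAAGTTGAGCTTCTGCTCATG", "X", 2346863, 2345479, 2346883,
                  "evidence for new transcriptional start site"),
    RecoveredCdna("2.1a", False, "TGGTTGTTAGTAGTGTACATG", "II", 15229391, 15207408, 15229412,
                  "evidence for new 3' UTR exon"),
    RecoveredCdna("2.1b", False, "TGGTTGTTAGTAGTGTACATG", "II", 15229391, 15216289, 15229412,
                  "evidence for new initial coding exon"),
    RecoveredCdna("2.2", True, "CCATCTAAAGGGCTCTACA", "IV", 4415359, None, 4415616,
                  "evidence for extension to 3' UTR; printed 5' coordinate corrupt"),
    RecoveredCdna("3.1", True, "CTCATTGAAGGTGAAGCAT", "X", 14690913, 14692920, 14690763,
                  "evidence for new 3' UTR"),
    RecoveredCdna("3.2", False, "TGAAATGTCACAGTACACAT", "III", 7604002, 7601399, 7604022,
                  "evidence of a novel gene"),
    RecoveredCdna("3.3", True, "GAGAGAATTGTTGTGACCAT", "X", 4681136, 4682689, 4680952,
                  "evidence of a novel gene"),
)


# Per-set classification of tested primers: (novel genes, annotation
# extensions, non-protein-coding overlaps, primers tested).
SCREEN_OUTCOMES: dict[str, tuple[int, int, int, int]] = {
    "preliminary": (1, 0, 2, 6),
    "set1": (3, 1, 0, 30),
    "set2": (0, 2, 0, 12),
    "set3": (2, 1, 0, 96),
}

# Cascade survivor counts per screening set: total, mappable,
# non-transcriptome, frequency, position, GC, primer-able, primers tested.
SCREEN_FUNNELS: dict[str, tuple[int, ...]] = {
    "set1": (16587, 13743, 3052, 616, 418, 128, 39, 30),
    "set2": (14701, 10534, 4755, 365, 41, 19, 12, 12),
    "set3": (359457, 32416, 13542, 8211, 469, 124, 106, 96),
}


def recovered_cdnas_frame() -> pd.DataFrame:
    """The recovered-cDNA records as a DataFrame (1-based coordinates)."""
    return pd.DataFrame(
        {
            "label": [r.label for r in RECOVERED_CDNAS],
            "full_length": [r.full_length for r in RECOVERED_CDNAS],
            "primer": [r.primer for r in RECOVERED_CDNAS],
            "chrom": [r.chrom for r in RECOVERED_CDNAS],
            "tag_pos": [r.tag_pos for r in RECOVERED_CDNAS],
            "boundary_5p": [r.boundary_5p for r in RECOVERED_CDNAS],
            "boundary_3p": [r.boundary_3p for r in RECOVERED_CDNAS],
            "note": [r.note for r in RECOVERED_CDNAS],
        }
    )


def round_half_away(x: float) -> int:
    """Round half away from zero (the convention of the printed percentages)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def success_rate_summary() -> pd.DataFrame:
    """Candidates, primers tested and success percentage per screening set.

    The percentage is ``100 * candidates / primers`` rounded half away from
    zero; a ``total`` row aggregates all sets.
    """
    rows = []
    tot = [0, 0, 0, 0]
    for name, (novel, ext, nc, primers) in SCREEN_OUTCOMES.items():
        candidates = novel + ext + nc
        rows.append(
            {
                "set": name,
                "novel_genes": novel,
                "annotation_extensions": ext,
                "non_coding_overlaps": nc,
                "candidates": candidates,
                "primers_tested": primers,
                "percent_success": round_half_away(100.0 * candidates / primers),
            }
        )
        tot[0] += novel
        tot[1] += ext
        tot[2] += nc
        tot[3] += primers
    candidates = tot[0] + tot[1] + tot[2]
    rows.append(
        {
            "set": "total",
            "novel_genes": tot[0],
            "annotation_extensions": tot[1],
            "non_coding_overlaps": tot[2],
            "candidates": candidates,
            "primers_tested": tot[3],
            "percent_success": round_half_away(100.0 * candidates / tot[3]),
        }
    )
    return pd.DataFrame(rows)
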