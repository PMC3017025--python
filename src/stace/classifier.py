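"""STACE amplicon interpretation.

Sequenced amplicons are read in mRNA sense. The 5' (upstream) product may
begin with the SL1 trans-spliced leader; the 3' (downstream) product ends in
a polyA tail, optionally followed by the reverse complement of the universal
primer region of the reverse-transcription adapter. After stripping these,
the body is spliced-aligned to the genome (or a precomputed BLAT-style
alignment in BED12/PSL form is ingested).

An amplicon is a *true positive* when its genomic span overlaps the tag that
seeded its primer. True positives are categorised against the annotation:
overlap with a pseudogene or ncRNA is a non-protein-coding overlap; overlap
with a protein-coding gene is an annotation extension (the tag itself was
non-transcriptome, so the amplicon necessarily adds sequence); no overlap at
all is a novel gene. An upstream/downstream amplicon pair that agree over
the tag merge into a cDNA model; the model is full-length when the upstream
read carried SL1 and the downstream read carried polyA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import AnnotationIndex, GenomeSequence
from .mapper import TagMapping
from .primers import SL1_PRIMER, UNIVERSAL_PRIMER, revcomp

CATEGORIES = ("novel_gene", "annotation_extension", "non_coding_overlap")

POLYA_ADAPTER = revcomp(UNIVERSAL_PRIMER)


@dataclass
class AmpliconAlignment:
    """A spliced genomic alignment: ordered exon blocks, 0-based half-open."""

    amplicon_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    sl1_found: bool = False
    polya_found: bool = False

    def __post_init__(self):
        self.blocks = sorted(self.blocks)
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping blocks in alignment {self.amplicon_id!r}")

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:])]

    @property
    def five_prime_boundary(self) -> int:
        """Outermost 5' genomic coordinate, 1-based."""
        s, e = self.span
        return s + 1 if self.strand == "+" else e

    @property
    def three_prime_boundary(self) -> int:
        """Outermost 3' genomic coordinate, 1-based."""
        s, e = self.span
        return e if self.strand == "+" else s + 1


def detect_and_strip_sl1(read: str, min_sl1: int = 12) -> tuple[str, bool]:
    """Remove a leading SL1 leader (suffix of the leader, >= min_sl1, exact)."""
    read = read.upper()
    for l in range(len(SL1_PRIMER), min_sl1 - 1, -1):
        if read.startswith(SL1_PRIMER[-l:]):
            return read[l:], True
    return read, False


def detect_and_strip_polya(
    read: str, min_a: int = 10, adapter: str = POLYA_ADAPTER
) -> tuple[str, bool]:
    """Remove a trailing 3' adapter (if present) then a polyA run >= min_a.

    A run shorter than ``min_a`` is left in place and reported absent.
    """
    read = read.upper()
    if adapter and read.endswith(adapter):
        read = read[: -len(adapter)]
    n = len(read)
    i = n
    while i > 0 and read[i - 1] == "A":
        i -= 1
    if n - i >= min_a:
        return read[:i], True
    return read, False


def _occurrences(haystack: str, needle: str, start: int = 0) -> list[int]:
    out = []
    i = haystack.find(needle, start)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _block_extents(chrom: str, read: str, r: int, g: int, budget: int):
    """Exact-match extents from (read r, genome g), longest first.

    Each extent may absorb up to ``budget`` internal substitutions; returns
    (length, mismatches_used) pairs.
    """
    n, m = len(read), len(chrom)
    extents = []
    l, used = 0, 0
    while True:
        while r + l < n and g + l < m and read[r + l] == chrom[g + l]:
            l += 1
        extents.append((l, used))
        if used < budget and r + l < n and g + l < m:
            l += 1  # consume one substitution and keep extending
            used += 1
        else:
            break
    extents.reverse()  # longest (most permissive) first
    return extents


def _chain(
    chrom: str,
    read: str,
    r: int,
    gmin: int,
    min_intron: int,
    seed_len: int,
    budget: int,
    max_shift: int = 12,
) -> list[tuple[int, int]] | None:
    """Find exon blocks covering read[r:] with genomic starts >= gmin."""
    n = len(read)
    if r == n:
        return []
    sl = min(seed_len, n - r)
    seed = read[r : r + sl]
    for g in _occurrences(chrom, seed, gmin):
        for l, used in _block_extents(chrom, read, r, g, budget):
            if l < sl:
                continue
            if r + l == n:
                return [(g, g + l)]
            # splice: the greedy extension may overshoot the true junction
            # when the intron begins with the next exon's bases; retry with
            # the junction shifted back by s.
            for s in range(0, min(max_shift, l - 1) + 1):
                end = g + l - s
                rest = _chain(
                    chrom, read, r + l - s, end + min_intron,
                    min_intron, seed_len, budget - used, max_shift,
                )
                if rest is not None:
                    return [(g, end)] + rest
    return None


def _prefer_gt_ag(chrom: str, blocks: list[tuple[int, int]], strand: str, window: int = 12):
    """Slide each junction within its ambiguity window onto GT..AG.

    Two junction placements are equivalent when the bases flanking the
    intron repeat across it; among equivalent placements the one yielding a
    canonical GT..AG intron (on the transcribed strand) is preferred.
    """

    def canonical(a: int, b: int) -> bool:
        intron = chrom[a:b]
        if strand == "-":
            intron = revcomp(intron)
        return intron.startswith("GT") and intron.endswith("AG")

    blocks = list(blocks)
    for idx in range(len(blocks) - 1):
        (s1, e1), (s2, e2) = blocks[idx], blocks[idx + 1]
        if canonical(e1, s2):
            continue
        chosen = None
        for t in range(1, window + 1):
            # shift right: exon 1 grows, exon 2 shrinks
            if (
                s2 + t < e2
                and all(chrom[e1 + i] == chrom[s2 + i] for i in range(t))
                and canonical(e1 + t, s2 + t)
            ):
                chosen = t
                break
            # shift left: exon 1 shrinks, exon 2 grows
            if (
                e1 - t > s1
                and all(chrom[e1 - 1 - i] == chrom[s2 - 1 - i] for i in range(t))
                and canonical(e1 - t, s2 - t)
            ):
                chosen = -t
                break
        if chosen is not None:
            blocks[idx] = (s1, e1 + chosen)
            blocks[idx + 1] = (s2 + chosen, e2)
    return blocks


def align_amplicon(
    read: str,
    genome: GenomeSequence,
    amplicon_id: str = "",
    min_intron: int = 30,
    max_mismatch: int = 0,
    seed_len: int = 16,
) -> AmpliconAlignment | None:
    """Spliced alignment of a stripped amplicon to a toy-scale genome.

    Greedy maximal exact seeding and chaining; gaps of >= ``min_intron`` bp
    between blocks are introns, re-placed onto GT..AG boundaries when an
    equivalent placement exists. Full read coverage is required; returns
    ``None`` when no covering chain exists on either strand of any
    chromosome. ``max_mismatch`` > 0 tolerates that many internal
    substitutions.
    """
    read = read.upper()
    if not read:
        return None
    for chrom in genome.chrom_names:
        seq = genome.sequences[chrom]
        for strand, oriented in (("+", read), ("-", revcomp(read))):
            blocks = _chain(seq, oriented, 0, 0, min_intron, seed_len, max_mismatch)
            if blocks is not None:
                blocks = _prefer_gt_ag(seq, blocks, strand)
                return AmpliconAlignment(
                    amplicon_id=amplicon_id, chrom=chrom, strand=strand, blocks=blocks
                )
    return None


def is_true_positive(alignment: AmpliconAlignment, tag_mapping: TagMapping) -> bool:
    """True iff the alignment's genomic span overlaps the seeding tag.

    The span is the closed interval between the two outermost mapping
    boundaries, which makes the test orientation-agnostic (minus-strand
    results report 5' > 3'). A different chromosome is simply false.
    """
    if alignment.chrom != tag_mapping.chrom:
        return False
    lo = min(alignment.five_prime_boundary, alignment.three_prime_boundary)
    hi = max(alignment.five_prime_boundary, alignment.three_prime_boundary)
    tag_lo, tag_hi = tag_mapping.start + 1, tag_mapping.end  # 1-based closed
    return lo <= tag_hi and tag_lo <= hi


@dataclass(frozen=True)
class IntronSignal:
    start: int  # 0-based half-open genomic intron
    end: int
    dinucleotides: str  # donor..acceptor on the transcribed strand, e.g. "GT..AG"
    canonical: bool


def check_splice_signals(
    alignment: AmpliconAlignment, genome: GenomeSequence
) -> list[IntronSignal]:
    """Label each inferred intron canonical iff it is GT..AG (strand-adjusted)."""
    out = []
    seq = genome.sequences[alignment.chrom]
    for s, e in alignment.introns:
        intron = seq[s:e]
        if alignment.strand == "-":
            intron = revcomp(intron)
        donor, acceptor = intron[:2], intron[-2:]
        out.append(
            IntronSignal(
                start=s,
                end=e,
                dinucleotides=f"{donor}..{acceptor}",
                canonical=donor == "GT" and acceptor == "AG",
            )
        )
    return out


def classify_result(
    alignment: AmpliconAlignment, index: AnnotationIndex
) -> tuple[str, list[str]]:
    """Category of a true-positive amplicon against the annotation.

    Precedence: any overlapped pseudogene/ncRNA -> non_coding_overlap;
    else any overlapped gene -> annotation_extension; else novel_gene.
    Overlap is >= 1 bp intersection between the amplicon span and a gene
    span.
    """
    s, e = alignment.span
    genes = index.genes_overlapping(alignment.chrom, s, e)
    gene_ids = [g.gene_id for g in genes]
    if any(g.biotype in ("pseudogene", "ncRNA") for g in genes):
        return "non_coding_overlap", gene_ids
    if genes:
        return "annotation_extension", gene_ids
    return "novel_gene", gene_ids


@dataclass
class StaceResult:
    """The full interpretation of one amplicon (or amplicon pair)."""

    amplicon_id: str
    true_positive: bool
    category: str | None = None
    full_length: bool = False
    sl1_found: bool = False
    polya_found: bool = False
    splice_signals: list[IntronSignal] = field(default_factory=list)
    overlapped_genes: list[str] = field(default_factory=list)
    alignment: AmpliconAlignment | None = None
    notes: str = ""


def evaluate_amplicon(
    read: str,
    amplicon_id: str,
    genome: GenomeSequence,
    index: AnnotationIndex,
    tag_mapping: TagMapping,
    min_intron: int = 30,
    max_mismatch: int = 0,
) -> StaceResult:
    """Strip, align and interpret a single amplicon read end-to-end."""
    body, sl1 = detect_and_strip_sl1(read)
    body, polya = detect_and_strip_polya(body)
    aln = align_amplicon(
        body, genome, amplicon_id=amplicon_id, min_intron=min_intron, max_mismatch=max_mismatch
    )
    if aln is None:
        return StaceResult(
            amplicon_id=amplicon_id,
            true_positive=False,
            sl1_found=sl1,
            polya_found=polya,
            notes="unaligned",
        )
    aln.sl1_found = sl1
    aln.polya_found = polya
    tp = is_true_positive(aln, tag_mapping)
    result = StaceResult(
        amplicon_id=amplicon_id,
        true_positive=tp,
        sl1_found=sl1,
        polya_found=polya,
        splice_signals=check_splice_signals(aln, genome),
        alignment=aln,
    )
    if tp:
        result.category, result.overlapped_genes = classify_result(aln, index)
    return result


@dataclass
class MergeResult:
    """Outcome of merging an upstream/downstream amplicon pair."""

    chrom: str | None = None
    strand: str | None = None
    blocks: list[tuple[int, int]] = field(default_factory=list)
    full_length: bool = False
    rejected: bool = False
    reason: str = ""


def _restrict(blocks: list[tuple[int, int]], lo: int, hi: int) -> list[tuple[int, int]]:
    out = []
    for s, e in blocks:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 < e2:
            out.append((s2, e2))
    return out


def assemble_full_length(
    upstream: AmpliconAlignment,
    downstream: AmpliconAlignment,
    tag_mapping: TagMapping,
) -> MergeResult:
    """Merge the two amplicons of one tag into a cDNA model.

    Both alignments must lie on the same chromosome and strand, their exon
    chains must agree exactly over the genomic overlap, and that overlap
    must contain the tag interval. Full length requires SL1 evidence on the
    upstream read and polyA evidence on the downstream read.
    """
    if upstream.chrom != downstream.chrom or upstream.strand != downstream.strand:
        return MergeResult(rejected=True, reason="different chromosome or strand")
    lo = max(upstream.span[0], downstream.span[0])
    hi = min(upstream.span[1], downstream.span[1])
    if lo >= hi:
        return MergeResult(rejected=True, reason="no genomic overlap")
    if not (lo <= tag_mapping.start and tag_mapping.end <= hi):
        return MergeResult(rejected=True, reason="overlap does not contain the tag")
    up_ov = _restrict(upstream.blocks, lo, hi)
    down_ov = _restrict(downstream.blocks, lo, hi)
    if up_ov != down_ov:
        return MergeResult(
            rejected=True,
            reason=f"exon chains disagree over the overlap: {up_ov} vs {down_ov}",
        )
    merged: list[tuple[int, int]] = []
    for s, e in sorted(upstream.blocks + downstream.blocks):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return MergeResult(
        chrom=upstream.chrom,
        strand=upstream.strand,
        blocks=merged,
        full_length=upstream.sl1_found and downstream.polya_found,
    )


def spliced_sequence(merge: MergeResult, genome: GenomeSequence) -> str:
    """mRNA-sense spliced sequence of a merged cDNA model."""
    seq = "".join(genome.fetch(merge.chrom, s, e) for s, e in merge.blocks)
    return revcomp(seq) if merge.strand == "-" else seq


def parse_bed12(path) -> list[AmpliconAlignment]:
    """Ingest spliced alignments from BED12 (e.g. converted BLAT output)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"BED12 requires 12 columns, got {len(f)}: {line!r}")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(starts) != int(f[9]):
                raise ValueError(f"inconsistent block count in BED12 line {name!r}")
            blocks = [
                (chrom_start + st, chrom_start + st + sz) for st, sz in zip(starts, sizes)
            ]
            out.append(
                AmpliconAlignment(amplicon_id=name, chrom=chrom, strand=strand, blocks=blocks)
            )
    return out


def parse_psl(path) -> list[AmpliconAlignment]:
    """Ingest spliced alignments from PSL (BLAT's native tab format)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("psLayout", "match", "-", " ")):
                continue
            f = line.split("\t")
            if len(f) < 21:
                continue
            strand, qname, tname = f[8], f[9], f[13]
            sizes = [int(x) for x in f[18].rstrip(",").split(",")]
            tstarts = [int(x) for x in f[20].rstrip(",").split(",")]
            blocks = [(ts, ts + sz) for ts, sz in zip(tstarts, sizes)]
            out.append(
                AmpliconAlignment(
                    amplicon_id=qname, chrom=tname, strand=strand[-1], blocks=blocks
                )
            )
    return out
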