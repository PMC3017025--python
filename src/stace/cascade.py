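"""The tag-screening cascade.

Novel-gene candidate tags are the survivors of a fixed sequence of filters:

1. mappable          — exactly one exact genomic locus;
2. non_transcriptome — no overlap with any annotated exon, and absent from
                       the virtual transcriptome (catches junction tags);
3. frequency         — at least 3 observations per 100,000 reads, so that
                       singleton sequencing errors are discarded;
4. position          — no intron overlap and at least 500 bp from any
                       annotated 5' or 3' gene boundary, biasing the screen
                       toward whole novel genes rather than missed exons;
5. gc                — GC content within [35, 45] %, the band from which
                       usable primers can be derived;
6. primerable        — a trimmed reverse-complement primer passes the
                       structure/Tm screens.

The per-stage survivor counts form the funnel report. A tag is counted at a
stage only if it passed every earlier stage; a failure leaves later stages
not evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import primers as primers_mod
from .genome import (
    AnnotationIndex,
    GenomeSequence,
    distance_to_nearest_gene_boundary,
)
from .mapper import GenomeIndex, TagMapping, classify_mappability
from .primers import PrimerConstraints, gc_percent, revcomp
from .sage import SageTag, TagLibrary, normalized_frequency

STAGES = ("mappable", "non_transcriptome", "frequency", "position", "gc", "primerable")

# Funnel column headings, matching the reporting convention of the original
# C. elegans screens.
FUNNEL_COLUMNS = {
    "total": "Total tags",
    "mappable": "Mappable tags",
    "non_transcriptome": "Non-transcriptome tags",
    "frequency": "Tags with frequency count >3",
    "position": "Tags absent from gene boundaries and introns",
    "gc": "Tags with appropriate GC content",
    "primerable": "Tags that can serve as primers",
}

PASS = "pass"
FAIL = "fail"
NOT_EVALUATED = "not_evaluated"


@dataclass(frozen=True)
class Verdict:
    status: str
    reason: str = ""

    @property
    def passed(self) -> bool:
        return self.status == PASS


@dataclass
class CandidateRecord:
    """One tag's passage through the cascade."""

    tag: SageTag
    mappings: list[TagMapping] = field(default_factory=list)
    verdicts: dict[str, Verdict] = field(default_factory=dict)
    primer: primers_mod.PrimerCandidate | None = None

    @property
    def mapping(self) -> TagMapping | None:
        return self.mappings[0] if len(self.mappings) == 1 else None

    @property
    def passed(self) -> bool:
        return all(
            self.verdicts.get(stage, Verdict(NOT_EVALUATED)).passed for stage in STAGES
        )


@dataclass
class FunnelReport:
    """Ordered per-stage survivor counts (non-increasing by construction)."""

    stages: list[tuple[str, int]]

    @property
    def counts(self) -> list[int]:
        return [c for _, c in self.stages]

    @property
    def is_monotonic(self) -> bool:
        counts = self.counts
        return all(a >= b for a, b in zip(counts, counts[1:]))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(FUNNEL_COLUMNS.get(name, name) for name, _ in self.stages))
            fh.write("\n")
            fh.write("\t".join(str(c) for c in self.counts))
            fh.write("\n")


def filter_non_transcriptome(
    record: CandidateRecord,
    virtual_transcriptome: dict[str, str],
    index: AnnotationIndex,
    _joined: str | None = None,
) -> Verdict:
    """Fail tags explained by known transcription.

    A tag fails when its genomic interval overlaps any annotated exon (any
    biotype), or when the tag — or its reverse complement — occurs in any
    spliced transcript (which catches exon-junction tags that do not map to
    the genome contiguously).
    """
    m = record.mapping
    if m is not None and index.exons.overlapping(m.chrom, m.start, m.end):
        return Verdict(FAIL, "exon_overlap")
    joined = _joined if _joined is not None else "#".join(virtual_transcriptome.values())
    seq = record.tag.sequence
    if seq in joined or revcomp(seq) in joined:
        return Verdict(FAIL, "transcriptome_hit")
    return Verdict(PASS)


def filter_frequency(
    record: CandidateRecord, library_size: int, threshold: float = 3.0
) -> Verdict:
    """Pass iff the tag reaches ``threshold`` per 100,000 reads (inclusive)."""
    freq = normalized_frequency(record.tag.count, library_size)
    if freq >= threshold:
        return Verdict(PASS)
    return Verdict(FAIL, f"frequency {freq:.2f} < {threshold}")


def filter_position(
    record: CandidateRecord,
    index: AnnotationIndex,
    min_boundary_distance: int = 500,
    boundary_biotypes: tuple[str, ...] | None = None,
) -> Verdict:
    """Fail tags in introns or within 500 bp of an annotated gene boundary."""
    m = record.mapping
    if m is None:
        return Verdict(FAIL, "no unique mapping")
    if index.introns.overlapping(m.chrom, m.start, m.end):
        return Verdict(FAIL, "intron")
    dist = distance_to_nearest_gene_boundary(
        m.chrom, m.start, m.end, index, biotypes=boundary_biotypes
    )
    if dist < min_boundary_distance:
        return Verdict(FAIL, f"near_boundary ({dist} bp)")
    return Verdict(PASS)


def filter_gc(record: CandidateRecord, gc_min: float = 35.0, gc_max: float = 45.0) -> Verdict:
    """Pass iff GC content of the full tag lies in [gc_min, gc_max] (inclusive)."""
    gc = gc_percent(record.tag.sequence)
    if gc_min <= gc <= gc_max:
        return Verdict(PASS)
    return Verdict(FAIL, f"GC {gc:.1f}% outside [{gc_min}, {gc_max}]")


def filter_primerable(
    record: CandidateRecord, constraints: PrimerConstraints | None = None
) -> Verdict:
    """Pass iff a trimmed reverse-complement primer passes every screen."""
    candidate = primers_mod.derive_primer(
        record.tag.sequence, constraints or primers_mod.DEFAULT_CONSTRAINTS
    )
    if candidate is None:
        return Verdict(FAIL, "no admissible trim")
    record.primer = candidate
    return Verdict(PASS)


def run_cascade(
    library: TagLibrary,
    genome: GenomeSequence,
    annotation_index: AnnotationIndex,
    virtual_transcriptome: dict[str, str],
    genome_index: GenomeIndex | None = None,
    constraints: PrimerConstraints | None = None,
    frequency_threshold: float = 3.0,
    min_boundary_distance: int = 500,
    gc_bounds: tuple[float, float] = (35.0, 45.0),
    boundary_biotypes: tuple[str, ...] | None = None,
) -> tuple[list[CandidateRecord], FunnelReport]:
    """Run the full cascade over a library; return records plus the funnel.

    Stages run in the fixed order mappable -> non_transcriptome -> frequency
    -> position -> gc -> primerable. The funnel has one count per stage plus
    the initial total.
    """
    records: list[CandidateRecord] = []
    counts = {name: 0 for name in STAGES}
    tag_sequences = sorted(library.tags)
    if tag_sequences and genome_index is None:
        genome_index = GenomeIndex(genome, len(tag_sequences[0]))
    joined = "#".join(virtual_transcriptome.values())

    mappability = (
        classify_mappability(tag_sequences, genome_index) if tag_sequences else None
    )

    for seq in tag_sequences:
        tag = SageTag(sequence=seq, count=library.tags[seq], source_library=library.name)
        record = CandidateRecord(tag=tag, mappings=mappability.mappings[seq])
        records.append(record)

        if mappability.status[seq] != "unique":
            record.verdicts["mappable"] = Verdict(FAIL, mappability.status[seq])
            continue
        record.verdicts["mappable"] = Verdict(PASS)
        counts["mappable"] += 1

        v = filter_non_transcriptome(record, virtual_transcriptome, annotation_index, joined)
        record.verdicts["non_transcriptome"] = v
        if not v.passed:
            continue
        counts["non_transcriptome"] += 1

        v = filter_frequency(record, library.library_size, frequency_threshold)
        record.verdicts["frequency"] = v
        if not v.passed:
            continue
        counts["frequency"] += 1

        v = filter_position(record, annotation_index, min_boundary_distance, boundary_biotypes)
        record.verdicts["position"] = v
        if not v.passed:
            continue
        counts["position"] += 1

        v = filter_gc(record, *gc_bounds)
        record.verdicts["gc"] = v
        if not v.passed:
            continue
        counts["gc"] += 1

        v = filter_primerable(record, constraints)
        record.verdicts["primerable"] = v
        if v.passed:
            counts["primerable"] += 1

    funnel = FunnelReport(
        stages=[("total", len(tag_sequences))] + [(name, counts[name]) for name in STAGES]
    )
    return records, funnel


def survivors(records: list[CandidateRecord]) -> list[CandidateRecord]:
    return [r for r in records if r.passed]


def write_candidates_tsv(records: list[CandidateRecord], library_size: int, path) -> None:
    """Per-tag report: mapping, frequency, GC and the stage verdicts."""
    with open(path, "w") as fh:
        fh.write(
            "tag\tchrom\tstart\tstrand\tcount\tfrequency_per_100k\tgc_percent\t"
            + "\t".join(STAGES)
            + "\tfinal\n"
        )
        for r in records:
            m = r.mapping
            loc = (m.chrom, str(m.start + 1), m.strand) if m else (".", ".", ".")
            freq = normalized_frequency(r.tag.count, library_size)
            verdicts = []
            for stage in STAGES:
                v = r.verdicts.get(stage)
                if v is None:
                    verdicts.append(NOT_EVALUATED)
                elif v.passed:
                    verdicts.append(PASS)
                else:
                    verdicts.append(f"{FAIL}({v.reason})")
            fh.write(
                f"{r.tag.sequence}\t{loc[0]}\t{loc[1]}\t{loc[2]}\t{r.tag.count}\t"
                f"{freq:.3f}\t{gc_percent(r.tag.sequence):.1f}\t"
                + "\t".join(verdicts)
                + f"\t{'pass' if r.passed else 'fail'}\n"
            )


def write_candidates_bed(records: list[CandidateRecord], path) -> None:
    """BED6 of surviving tag intervals."""
    with open(path, "w") as fh:
        for r in survivors(records):
            m = r.mapping
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{r.tag.sequence}\t{r.tag.count}\t{m.strand}\n"
            )


def write_primer_tsv(records: list[CandidateRecord], path) -> None:
    """Primer report for every tag that reached the primer stage."""
    with open(path, "w") as fh:
        fh.write(
            "tag\tprimer\ttrim_left\ttrim_right\tgc_percent\ttm\t"
            "hairpin_stem\thomodimer_run\tverdict\n"
        )
        for r in records:
            v = r.verdicts.get("primerable")
            if v is None:
                continue
            if r.primer is not None:
                p = r.primer
                fh.write(
                    f"{r.tag.sequence}\t{p.sequence}\t{p.trim_left}\t{p.trim_right}\t"
                    f"{p.gc:.1f}\t{p.tm:.2f}\t{p.hairpin_stem}\t{p.homodimer.max_run}\tpass\n"
                )
            else:
                fh.write(f"{r.tag.sequence}\t.\t.\t.\t.\t.\t.\t.\tfail({v.reason})\n")
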