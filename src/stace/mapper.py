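"""Exact tag-to-genome mapping on both strands.

A tag anchors a gene-specific primer only if it identifies one genomic
locus, so mapping is exact full-length matching (no mismatches, no gaps):
tags carrying sequencing errors are handled by the downstream frequency
filter, not by mismatch rescue. Ambiguity bases (N) in the genome never
match anything.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .genome import GenomeSequence
from .primers import revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TagMapping:
    """One exact genomic occurrence of a tag (0-based start)."""

    tag: str
    chrom: str
    start: int
    strand: str

    @property
    def end(self) -> int:
        return self.start + len(self.tag)

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


class GenomeIndex:
    """k-mer hash over the forward strand; minus-strand hits come from
    looking up the reverse complement of the query."""

    def __init__(self, genome: GenomeSequence, k: int):
        if not genome.chrom_names or all(genome.length(c) == 0 for c in genome.chrom_names):
            raise ValueError("cannot index an empty genome")
        shortest = min(genome.length(c) for c in genome.chrom_names)
        if k > shortest:
            warnings.warn(
                f"k={k} exceeds the shortest chromosome ({shortest} bp); "
                "tags cannot map there"
            )
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom in genome.chrom_names:
            seq = genome.sequences[chrom]
            for i in range(0, len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((chrom, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def build_index(genome: GenomeSequence, k: int) -> GenomeIndex:
    return GenomeIndex(genome, k)


def map_tag(tag: str, index: GenomeIndex) -> list[TagMapping]:
    """All exact full-length occurrences of a tag, both strands.

    Sorted by (chrom, start, strand). A tag containing N yields no mappings
    (logged). A plus-strand hit means the genome carries the tag verbatim; a
    minus-strand hit means it carries the reverse complement.
    """
    tag = tag.upper()
    if len(tag) != index.k:
        raise ValueError(f"tag length {len(tag)} != index k {index.k}")
    if set(tag) - set("ACGT"):
        logger.info("tag %s contains ambiguity bases; unmapped", tag)
        return []
    hits = [TagMapping(tag, c, s, "+") for c, s in index.lookup(tag)]
    rc = revcomp(tag)
    hits += [TagMapping(tag, c, s, "-") for c, s in index.lookup(rc)]
    hits.sort(key=lambda m: (m.chrom, m.start, m.strand))
    return hits


@dataclass
class MappabilityReport:
    """Tags partitioned into unmapped / unique / multi-mapped."""

    status: dict[str, str] = field(default_factory=dict)
    mappings: dict[str, list[TagMapping]] = field(default_factory=dict)

    @property
    def n_unique(self) -> int:
        return sum(1 for s in self.status.values() if s == "unique")

    @property
    def n_unmapped(self) -> int:
        return sum(1 for s in self.status.values() if s == "unmapped")

    @property
    def n_multi(self) -> int:
        return sum(1 for s in self.status.values() if s == "multi")

    def unique_mapping(self, tag: str) -> TagMapping | None:
        if self.status.get(tag) == "unique":
            return self.mappings[tag][0]
        return None


def classify_mappability(tags, index: GenomeIndex) -> MappabilityReport:
    """Partition tags by their number of exact genomic occurrences.

    Only uniquely mapping tags count as "mappable" for the screening
    funnel: a multi-locus tag cannot anchor a gene-specific primer.
    """
    report = MappabilityReport()
    for tag in tags:
        hits = map_tag(tag, index)
        report.mappings[tag] = hits
        if not hits:
            report.status[tag] = "unmapped"
        elif len(hits) == 1:
            report.status[tag] = "unique"
        else:
            report.status[tag] = "multi"
    return report


def write_mapping_report(report: MappabilityReport, path) -> None:
    """TSV: tag, status, chrom, start (1-based), strand."""
    with open(path, "w") as fh:
        fh.write("tag\tstatus\tchrom\tstart\tstrand\n")
        for tag in report.status:
            status = report.status[tag]
            if status == "unmapped":
                fh.write(f"{tag}\t{status}\t.\t.\t.\n")
            else:
                for m in report.mappings[tag]:
                    fh.write(f"{tag}\t{status}\t{m.chrom}\t{m.start + 1}\t{m.strand}\n")
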