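"""Genome and annotation handling.

Loads a reference genome (FASTA) and gene annotations (GFF3), builds the
virtual transcriptome (spliced cDNA of every annotated transcript) and
answers the interval queries the tag-screening cascade needs: exon overlap,
intron overlap, and distance to the nearest annotated gene boundary.

Coordinates are 0-based half-open internally; every user-facing report is
1-based inclusive (the convention of GFF3 and of genome-browser positions).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import gffutils
import numpy as np
from Bio import SeqIO

from .primers import revcomp

logger = logging.getLogger(__name__)

BIOTYPES = ("protein_coding", "pseudogene", "ncRNA", "other")

# GFF3 feature types recognised at the gene and transcript levels.
_GENE_TYPES = {"gene", "pseudogene", "ncRNA_gene"}
_TRANSCRIPT_TYPES = {"mRNA", "transcript", "ncRNA", "pseudogenic_transcript", "lnc_RNA"}
_TYPE_BIOTYPE = {
    "pseudogene": "pseudogene",
    "ncRNA_gene": "ncRNA",
    "ncRNA": "ncRNA",
    "pseudogenic_transcript": "pseudogene",
}


def to_gff_coords(start: int, end: int) -> tuple[int, int]:
    """Internal 0-based half-open -> GFF 1-based inclusive."""
    return start + 1, end


def from_gff_coords(start: int, end: int) -> tuple[int, int]:
    """GFF 1-based inclusive -> internal 0-based half-open."""
    return start - 1, end


@dataclass
class GenomeSequence:
    """Chromosome sequences, uppercased, with a soft-mask flag per position."""

    chrom_names: list[str]
    sequences: dict[str, str]
    softmask: dict[str, np.ndarray] = field(default_factory=dict)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Subsequence at internal coordinates [start, end)."""
        return self.sequences[chrom][start:end]


def load_genome(fasta_path) -> GenomeSequence:
    """Read a genome FASTA; uppercase, noting soft-masked (lowercase) runs.

    Duplicate chromosome names and empty records are hard errors. Characters
    outside ACGTN are normalised to N.
    """
    names: list[str] = []
    seqs: dict[str, str] = {}
    masks: dict[str, np.ndarray] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        raw = str(record.seq)
        if record.id in seqs:
            raise ValueError(f"duplicate chromosome name {record.id!r} in {fasta_path}")
        if not raw:
            raise ValueError(f"empty sequence for chromosome {record.id!r}")
        mask = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
        masks[record.id] = (mask >= ord("a")) & (mask <= ord("z"))
        upper = raw.upper()
        cleaned = "".join(c if c in "ACGTN" else "N" for c in upper)
        names.append(record.id)
        seqs[record.id] = cleaned
    if not names:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return GenomeSequence(chrom_names=names, sequences=seqs, softmask=masks)


@dataclass
class GeneModel:
    """A gene: one or more transcripts, each an ordered chain of exons.

    Exons are genomic intervals (0-based half-open), sorted by coordinate
    and non-overlapping within a transcript. The gene span is the union of
    its transcript spans.
    """

    gene_id: str
    chrom: str
    strand: str
    biotype: str = "protein_coding"
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def span(self) -> tuple[int, int]:
        starts = [ex[0] for exons in self.transcripts.values() for ex in exons]
        ends = [ex[1] for exons in self.transcripts.values() for ex in exons]
        return min(starts), max(ends)

    def introns(self, transcript_id: str) -> list[tuple[int, int]]:
        """Gaps between consecutive exons of one transcript."""
        exons = self.transcripts[transcript_id]
        return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


class IntervalIndex:
    """Minimal per-chromosome interval store with overlap queries.

    Intervals are 0-based half-open. Linear scan per chromosome — adequate
    for the toy/validation scale this tool targets.
    """

    def __init__(self):
        self._by_chrom: dict[str, list[tuple[int, int, object]]] = {}

    def add(self, chrom: str, start: int, end: int, payload=None) -> None:
        self._by_chrom.setdefault(chrom, []).append((start, end, payload))

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[int, int, object]]:
        return [
            (s, e, p)
            for (s, e, p) in self._by_chrom.get(chrom, [])
            if s < end and start < e
        ]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())


@dataclass
class AnnotationIndex:
    """Interval indexes over exons, introns and gene spans."""

    exons: IntervalIndex
    introns: IntervalIndex
    genes: IntervalIndex
    chrom_names: list[str]

    @classmethod
    def build(cls, gene_models: list[GeneModel], chrom_names: list[str]) -> "AnnotationIndex":
        exons, introns, genes = IntervalIndex(), IntervalIndex(), IntervalIndex()
        for gene in gene_models:
            for tid, exon_list in gene.transcripts.items():
                for s, e in exon_list:
                    exons.add(gene.chrom, s, e, (gene.gene_id, tid))
                for s, e in gene.introns(tid):
                    introns.add(gene.chrom, s, e, (gene.gene_id, tid))
            gs, ge = gene.span
            genes.add(gene.chrom, gs, ge, gene)
        return cls(exons=exons, introns=introns, genes=genes, chrom_names=list(chrom_names))

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        return [p for (_, _, p) in self.genes.overlapping(chrom, start, end)]


def _biotype_of(feature) -> str:
    if "biotype" in feature.attributes:
        value = feature.attributes["biotype"][0]
        return value if value in BIOTYPES else "other"
    return _TYPE_BIOTYPE.get(feature.featuretype, "protein_coding")


def load_annotations(gff3_path, genome: GenomeSequence):
    """Parse a GFF3 into gene models plus an interval index.

    Accepts gene/mRNA(or transcript)/exon hierarchies; biotype comes from
    the feature type column (``pseudogene``, ``ncRNA_gene``) or a ``biotype``
    attribute, defaulting to protein_coding. Orphan exons are skipped with a
    warning; an exon outside its chromosome is a hard error.
    """
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type(tuple(_GENE_TYPES)):
        if gene.seqid not in genome:
            raise ValueError(f"gene {gene.id!r} on unknown chromosome {gene.seqid!r}")
        model = GeneModel(
            gene_id=gene.id, chrom=gene.seqid, strand=gene.strand, biotype=_biotype_of(gene)
        )
        transcripts = [
            t for t in db.children(gene, level=1) if t.featuretype in _TRANSCRIPT_TYPES
        ]
        if transcripts:
            for t in transcripts:
                exons = _collect_exons(db, t, genome)
                if exons:
                    model.transcripts[t.id] = exons
        else:
            # exons directly under the gene: treat as a single transcript
            exons = _collect_exons(db, gene, genome)
            if exons:
                model.transcripts[f"{gene.id}.t1"] = exons
        if model.transcripts:
            models.append(model)
        else:
            warnings.warn(f"gene {gene.id!r} has no exons; skipped")
    for exon in db.features_of_type("exon"):
        if "Parent" not in exon.attributes:
            warnings.warn(f"orphan exon at {exon.seqid}:{exon.start}-{exon.end}; skipped")
    index = AnnotationIndex.build(models, genome.chrom_names)
    return models, index


def _collect_exons(db, parent, genome: GenomeSequence) -> list[tuple[int, int]]:
    exons = []
    for exon in db.children(parent, featuretype="exon", level=1):
        start, end = from_gff_coords(exon.start, exon.end)
        if start < 0 or end > genome.length(exon.seqid):
            raise ValueError(
                f"exon of {parent.id!r} at {exon.seqid}:{exon.start}-{exon.end} "
                f"outside chromosome bounds"
            )
        exons.append((start, end))
    exons.sort()
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping exons in transcript {parent.id!r}")
    return exons


def build_virtual_transcriptome(
    genome: GenomeSequence, gene_models: list[GeneModel]
) -> dict[str, str]:
    """Spliced cDNA sequence of every annotated transcript, in mRNA sense.

    Exons are concatenated in genomic order; minus-strand transcripts are
    reverse-complemented so the result reads 5'->3' along the mRNA.
    """
    transcriptome: dict[str, str] = {}
    for gene in gene_models:
        for tid, exons in gene.transcripts.items():
            spliced = "".join(genome.fetch(gene.chrom, s, e) for s, e in exons)
            if gene.strand == "-":
                spliced = revcomp(spliced)
            transcriptome[tid] = spliced
    return transcriptome


def distance_to_nearest_gene_boundary(
    chrom: str,
    start: int,
    end: int,
    index: AnnotationIndex,
    biotypes: tuple[str, ...] | None = None,
) -> float:
    """Gap (bp) between an interval and the nearest annotated gene span.

    Zero when the interval overlaps or abuts any gene span; ``math.inf``
    when the chromosome carries no (qualifying) genes. ``biotypes`` limits
    which gene biotypes count as boundaries (default: all).
    """
    if chrom not in index.chrom_names:
        raise ValueError(f"unknown chromosome {chrom!r}")
    best = math.inf
    for gs, ge, gene in index.genes._by_chrom.get(chrom, []):
        if biotypes is not None and gene.biotype not in biotypes:
            continue
        if gs < end and start < ge:
            return 0
        gap = gs - end if gs >= end else start - ge
        best = min(best, max(gap, 0))
    return best


def write_gff3(gene_models: list[GeneModel], path) -> None:
    """Emit gene/mRNA/exon rows, 1-based inclusive, deterministic order."""
    type_for = {"pseudogene": "pseudogene", "ncRNA": "ncRNA_gene"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in gene_models:
            gs, ge = gene.span
            g1, g2 = to_gff_coords(gs, ge)
            gtype = type_for.get(gene.biotype, "gene")
            fh.write(
                f"{gene.chrom}\tstace\t{gtype}\t{g1}\t{g2}\t.\t{gene.strand}\t.\t"
                f"ID={gene.gene_id};biotype={gene.biotype}\n"
            )
            for tid in sorted(gene.transcripts):
                exons = gene.transcripts[tid]
                t1, t2 = to_gff_coords(exons[0][0], exons[-1][1])
                ttype = "mRNA" if gene.biotype == "protein_coding" else "transcript"
                fh.write(
                    f"{gene.chrom}\tstace\t{ttype}\t{t1}\t{t2}\t.\t{gene.strand}\t.\t"
                    f"ID={tid};Parent={gene.gene_id}\n"
                )
                for i, (s, e) in enumerate(exons, 1):
                    e1, e2 = to_gff_coords(s, e)
                    fh.write(
                        f"{gene.chrom}\tstace\texon\t{e1}\t{e2}\t.\t{gene.strand}\t.\t"
                        f"ID={tid}.exon{i};Parent={tid}\n"
                    )


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    """Plain FASTA writer with fixed line wrapping (deterministic output)."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
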