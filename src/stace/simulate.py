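"""Deterministic toy-world simulator.

Generates a small multi-chromosome genome carrying annotated multi-exon
genes (optionally one pseudogene and one ncRNA), plus *planted* novel genes
that are present in the sequence and expressed in the tag library but
absent from the emitted annotation — the situation the screening cascade is
designed to detect. Every gene's transcript carries an engineered
CATG-anchored tag with GC content inside the screening band; introns are
canonical GT..AG. SAGE libraries draw tag counts proportional to a per-gene
expression level, with substitution errors injected at a configurable rate
(noise tags are constructed to stay below the frequency threshold, so
cascade behaviour on noise is deterministic by design). Amplicons carry the
SL1 leader, spliced exons, a polyA tail and the 3' adapter.

All randomness flows from one seeded generator per invocation; the same
seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .classifier import POLYA_ADAPTER
from .genome import GeneModel, GenomeSequence, write_fasta, write_gff3
from .primers import SL1_PRIMER, DEFAULT_CONSTRAINTS, PrimerConstraints, derive_primer, revcomp
from .sage import TagLibrary, extract_expected_tag, normalized_frequency

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """The stated world of the simulator (defaults are the test conditions)."""

    seed: int
    n_chromosomes: int = 2
    chrom_length: int = 60000
    n_annotated_genes: int = 8
    n_planted_novel_genes: int = 3
    include_pseudogene: bool = True
    include_ncrna: bool = True
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (90, 260)
    intron_length: tuple[int, int] = (40, 120)
    min_intron: int = 30
    min_intergenic_gap: int = 1200  # > 2x the 500 bp boundary rule
    tag_length: int = 21
    library_size: int = 100000
    annotated_expression: tuple[int, int] = (5, 40)
    novel_expression: tuple[int, int] = (8, 30)
    tag_error_rate: float = 0.02
    background_gc: float = 0.36  # C. elegans-like base composition
    polya_length: int = 16
    sl1_fraction: float = 1.0
    frequency_threshold: float = 3.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("exons_per_gene", "exon_length", "intron_length",
                     "annotated_expression", "novel_expression"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
            setattr(self, name, (int(lo), int(hi)))
        if self.intron_length[0] < self.min_intron:
            raise ValueError("intron_length minimum must be >= min_intron")
        if self.tag_length < 5:
            raise ValueError("tag_length must be >= 5")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class GeneInfo:
    """Ground-truth record of one simulated gene (annotated or hidden)."""

    gene_id: str
    chrom: str
    strand: str
    biotype: str
    annotated: bool
    exons: list[tuple[int, int]]  # genomic, 0-based half-open, sorted
    transcript: str  # spliced, mRNA sense
    tag: str
    tag_offset: int  # offset of the tag within the transcript
    tag_interval: tuple[int, int]  # genomic
    expression: int

    def to_gene_model(self) -> GeneModel:
        return GeneModel(
            gene_id=self.gene_id,
            chrom=self.chrom,
            strand=self.strand,
            biotype=self.biotype,
            transcripts={f"{self.gene_id}.t1": list(self.exons)},
        )


@dataclass
class GroundTruth:
    """Everything needed to score every pipeline stage exactly."""

    genes: list[GeneInfo] = field(default_factory=list)
    expected_survivors: list[str] = field(default_factory=list)
    noise_tags: dict[str, int] = field(default_factory=dict)
    amplicon_sources: dict[str, str] = field(default_factory=dict)

    @property
    def novel_genes(self) -> list[GeneInfo]:
        return [g for g in self.genes if not g.annotated]

    @property
    def annotated_genes(self) -> list[GeneInfo]:
        return [g for g in self.genes if g.annotated]

    def gene(self, gene_id: str) -> GeneInfo:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def to_json(self, path) -> None:
        payload = {
            "genes": [asdict(g) for g in self.genes],
            "expected_survivors": self.expected_survivors,
            "noise_tags": self.noise_tags,
            "amplicon_sources": self.amplicon_sources,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p))


def _make_tag(
    rng: np.random.Generator,
    tag_length: int,
    constrain_primer: bool,
    constraints: PrimerConstraints,
    forbidden: set[str],
    max_tries: int = 2000,
) -> str:
    """Engineer a CATG-anchored tag with screening-band GC content.

    The 3'-most-anchor invariant requires no second CATG after position 0.
    When ``constrain_primer`` is set the tag is rejection-sampled until a
    primer can actually be derived from it (the situation the screen selects
    for); the screening thresholds themselves are untouched.
    """
    n_var = tag_length - 4
    # target total GC strictly inside [35%, 45%] of the full tag (CATG has 2)
    lo = int(np.ceil(0.35 * tag_length))
    hi = int(np.floor(0.45 * tag_length))
    for _ in range(max_tries):
        n_gc = int(rng.integers(lo, hi + 1)) - 2
        if n_gc < 0 or n_gc > n_var:
            continue
        arr = np.array(["."] * n_var)
        gc_pos = rng.choice(n_var, size=n_gc, replace=False)
        is_gc = np.zeros(n_var, dtype=bool)
        is_gc[gc_pos] = True
        arr[is_gc] = rng.choice(np.array(["G", "C"]), size=n_gc)
        arr[~is_gc] = rng.choice(np.array(["A", "T"]), size=n_var - n_gc)
        tag = "CATG" + "".join(arr)
        if tag.find("CATG", 1) != -1:
            continue
        if tag in forbidden:
            continue
        if constrain_primer and derive_primer(tag, constraints) is None:
            continue
        return tag
    raise RuntimeError("could not engineer a qualifying tag; loosen the configuration")


@dataclass
class _GenePlan:
    pre_mrna: str  # transcript sense, introns included
    transcript: str
    exon_offsets: list[tuple[int, int]]  # within pre_mrna, transcript sense
    tag: str
    tag_offset: int
    strand: str


def _plan_gene(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    constrain_primer: bool,
    forbidden: set[str],
) -> _GenePlan:
    n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exon_lens = [
        int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1)) for _ in range(n_ex)
    ]
    tail_len = int(rng.integers(6, 30))
    min_last = cfg.tag_length + tail_len + 10
    if exon_lens[-1] < min_last:
        exon_lens[-1] = min_last
    tag = _make_tag(rng, cfg.tag_length, constrain_primer, DEFAULT_CONSTRAINTS, forbidden)

    chunks = []
    for i, l in enumerate(exon_lens):
        if i < n_ex - 1:
            chunks.append(_random_seq(rng, l, cfg.background_gc))
        else:
            # last exon: random prefix + tag + CATG-free tail keeps the
            # engineered anchor 3'-most in the transcript; the terminal base
            # is never A so the polyA boundary stays unambiguous
            prefix = _random_seq(rng, l - cfg.tag_length - tail_len, cfg.background_gc)
            while True:
                tail = _random_seq(rng, tail_len, cfg.background_gc)
                if (tag + tail).find("CATG", 1) == -1 and tail[-1] != "A":
                    break
            chunks.append(prefix + tag + tail)
    introns = [
        "GT"
        + _random_seq(
            rng,
            int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1)) - 4,
            cfg.background_gc,
        )
        + "AG"
        for _ in range(n_ex - 1)
    ]
    pre = []
    offsets = []
    pos = 0
    for i, c in enumerate(chunks):
        pre.append(c)
        offsets.append((pos, pos + len(c)))
        pos += len(c)
        if i < n_ex - 1:
            pre.append(introns[i])
            pos += len(introns[i])
    pre_mrna = "".join(pre)
    transcript = "".join(chunks)
    tag_offset = transcript.rfind(tag)
    strand = str(rng.choice(np.array(["+", "-"])))
    return _GenePlan(pre_mrna, transcript, offsets, tag, tag_offset, strand)


def generate_toy_genome(config: SimulationConfig, rng: np.random.Generator | None = None):
    """Build the genome, the annotated gene models, and the ground truth.

    Hidden (novel) genes are placed with the same machinery but withheld
    from the annotation; intergenic gaps exceed twice the 500 bp boundary
    rule so planted tags are never disqualified by proximity alone.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_total = config.n_annotated_genes + config.n_planted_novel_genes
    biotypes = []
    for i in range(config.n_annotated_genes):
        if i == 0 and config.include_pseudogene:
            biotypes.append("pseudogene")
        elif i == 1 and config.include_ncrna:
            biotypes.append("ncRNA")
        else:
            biotypes.append("protein_coding")

    used_tags: set[str] = set()
    plans: list[tuple[str, bool, str, _GenePlan]] = []  # (gene_id, annotated, biotype, plan)
    for i in range(config.n_annotated_genes):
        plan = _plan_gene(rng, config, constrain_primer=False, forbidden=used_tags)
        used_tags.add(plan.tag)
        plans.append((f"gene{i + 1:02d}", True, biotypes[i], plan))
    for i in range(config.n_planted_novel_genes):
        plan = _plan_gene(rng, config, constrain_primer=True, forbidden=used_tags)
        used_tags.add(plan.tag)
        plans.append((f"novel{i + 1:02d}", False, "protein_coding", plan))

    # interleave annotated and hidden genes along the chromosomes
    order = rng.permutation(len(plans))
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    pieces: dict[str, list[str]] = {c: [] for c in chrom_names}
    cursors = {c: 0 for c in chrom_names}
    placements = []  # (gene_id, annotated, biotype, plan, chrom, start)
    for j, idx in enumerate(order):
        gene_id, annotated, biotype, plan = plans[idx]
        chrom = chrom_names[j % config.n_chromosomes]
        gap = config.min_intergenic_gap + int(rng.integers(0, 400))
        seg = plan.pre_mrna if plan.strand == "+" else revcomp(plan.pre_mrna)
        start = cursors[chrom] + gap
        if start + len(seg) + config.min_intergenic_gap > config.chrom_length:
            raise ValueError(
                f"infeasible packing: {n_total} genes do not fit in "
                f"{config.n_chromosomes} x {config.chrom_length} bp"
            )
        pieces[chrom].append(_random_seq(rng, gap, config.background_gc))
        pieces[chrom].append(seg)
        cursors[chrom] = start + len(seg)
        placements.append((gene_id, annotated, biotype, plan, chrom, start))
    for chrom in chrom_names:
        pad = config.chrom_length - cursors[chrom]
        pieces[chrom].append(_random_seq(rng, pad, config.background_gc))
    sequences = {c: "".join(pieces[c]) for c in chrom_names}
    genome = GenomeSequence(
        chrom_names=chrom_names,
        sequences=sequences,
        softmask={c: np.zeros(len(sequences[c]), dtype=bool) for c in chrom_names},
    )

    truth = GroundTruth()
    for gene_id, annotated, biotype, plan, chrom, start in placements:
        L = len(plan.pre_mrna)
        if plan.strand == "+":
            exons = [(start + a, start + b) for a, b in plan.exon_offsets]
        else:
            exons = sorted((start + L - b, start + L - a) for a, b in plan.exon_offsets)
        expr_range = (
            config.annotated_expression if annotated else config.novel_expression
        )
        expression = int(rng.integers(expr_range[0], expr_range[1] + 1))
        seq = genome.sequences[chrom]
        probe = plan.tag if plan.strand == "+" else revcomp(plan.tag)
        tpos = seq.find(probe, start)
        truth.genes.append(
            GeneInfo(
                gene_id=gene_id,
                chrom=chrom,
                strand=plan.strand,
                biotype=biotype,
                annotated=annotated,
                exons=exons,
                transcript=plan.transcript,
                tag=plan.tag,
                tag_offset=plan.tag_offset,
                tag_interval=(tpos, tpos + config.tag_length),
                expression=expression,
            )
        )

    _verify_tag_uniqueness(genome, truth)
    annotated_models = [g.to_gene_model() for g in truth.annotated_genes]
    return genome, annotated_models, truth


def _verify_tag_uniqueness(genome: GenomeSequence, truth: GroundTruth) -> None:
    for g in truth.genes:
        hits = 0
        for chrom in genome.chrom_names:
            seq = genome.sequences[chrom]
            hits += len(_findall(seq, g.tag)) + len(_findall(seq, revcomp(g.tag)))
        if hits != 1:
            raise RuntimeError(
                f"planted tag {g.tag} of {g.gene_id} occurs {hits} times; "
                "re-run with a different seed"
            )
    # sanity: every transcript reproduces its tag at the recorded offset
    for g in truth.genes:
        extracted = extract_expected_tag(g.transcript, len(g.tag))
        if extracted != g.tag:
            raise RuntimeError(f"tag extraction mismatch for {g.gene_id}")


def _findall(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def simulate_sage_library(
    truth: GroundTruth, config: SimulationConfig, rng: np.random.Generator
) -> TagLibrary:
    """Sample a tag library with abundance-proportional counts plus noise.

    Each transcript contributes its expected tag ``expression`` times; each
    copy is independently corrupted (one substitution outside the CATG
    anchor) with probability ``tag_error_rate``. Any single noise tag is
    capped at 2 observations — below the 3-per-100k threshold at the default
    library size — so the cascade's treatment of noise is deterministic.
    """
    true_tags = {g.tag for g in truth.genes}
    counts: dict[str, int] = {}
    noise: dict[str, int] = {}
    for g in truth.genes:
        kept = 0
        for _ in range(g.expression):
            if rng.random() < config.tag_error_rate:
                mutant = _mutate_tag(rng, g.tag, true_tags, noise)
                if mutant is not None:
                    noise[mutant] = noise.get(mutant, 0) + 1
            else:
                kept += 1
        if kept:
            counts[g.tag] = counts.get(g.tag, 0) + kept
    for tag, c in noise.items():
        counts[tag] = counts.get(tag, 0) + c
    truth.noise_tags = dict(noise)
    truth.expected_survivors = sorted(
        g.tag
        for g in truth.novel_genes
        if normalized_frequency(counts.get(g.tag, 0), config.library_size)
        >= config.frequency_threshold
    )
    return TagLibrary(name="simulated", tags=counts, library_size=config.library_size)


def _mutate_tag(rng, tag: str, true_tags: set[str], noise: dict[str, int], cap: int = 2):
    for _ in range(20):
        pos = int(rng.integers(4, len(tag)))
        base = str(rng.choice(BASES[BASES != tag[pos]]))
        mutant = tag[:pos] + base + tag[pos + 1 :]
        if mutant in true_tags or noise.get(mutant, 0) >= cap:
            continue
        return mutant
    return None  # drop the copy rather than breach the noise cap


def simulate_amplicons(
    gene: GeneInfo, tag: str, config: SimulationConfig, leadered: bool = True
) -> tuple[str, str]:
    """The two STACE PCR products for one tag, in mRNA sense.

    The upstream product runs from the transcript 5' end (with the SL1
    leader when the mRNA is trans-spliced) through the end of the tag; the
    downstream product runs from the start of the tag through the 3' end,
    the polyA tail and the reverse-transcription adapter. The two reads
    overlap exactly over the tag.
    """
    o = gene.transcript.find(tag)
    if o == -1:
        raise ValueError(f"tag {tag} does not occur in transcript of {gene.gene_id}")
    leader = SL1_PRIMER if leadered else ""
    upstream = leader + gene.transcript[: o + len(tag)]
    downstream = (
        gene.transcript[o:] + "A" * config.polya_length + POLYA_ADAPTER
    )
    return upstream, downstream


@dataclass
class Simulation:
    """One fully materialised toy world."""

    config: SimulationConfig
    genome: GenomeSequence
    annotated_models: list[GeneModel]
    library: TagLibrary
    amplicons: list[tuple[str, str]]  # (id, sequence)
    truth: GroundTruth


def simulate(config: SimulationConfig) -> Simulation:
    """Run the full generator: genome, annotation, library, amplicons."""
    rng = np.random.default_rng(config.seed)
    genome, annotated_models, truth = generate_toy_genome(config, rng)
    library = simulate_sage_library(truth, config, rng)
    amplicons = []
    for g in truth.novel_genes:
        leadered = bool(rng.random() < config.sl1_fraction)
        up, down = simulate_amplicons(g, g.tag, config, leadered=leadered)
        for direction, read in (("up", up), ("down", down)):
            amp_id = f"{g.gene_id}|tag={g.tag}|dir={direction}"
            amplicons.append((amp_id, read))
            truth.amplicon_sources[amp_id] = g.gene_id
    return Simulation(
        config=config,
        genome=genome,
        annotated_models=annotated_models,
        library=library,
        amplicons=amplicons,
        truth=truth,
    )


def write_fixture(sim: Simulation, outdir) -> dict[str, str]:
    """Write the toy world as plain-text files; byte-stable per seed."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fasta"),
        "annotations": os.path.join(outdir, "annotations.gff3"),
        "tags": os.path.join(outdir, "tags.tsv"),
        "amplicons": os.path.join(outdir, "amplicons.fasta"),
        "ground_truth": os.path.join(outdir, "ground_truth.json"),
        "config": os.path.join(outdir, "config.yaml"),
    }
    write_fasta(sim.genome.sequences, paths["genome"])
    write_gff3(sim.annotated_models, paths["annotations"])
    with open(paths["tags"], "w") as fh:
        fh.write(f"#library_size={sim.library.library_size}\n")
        for tag in sorted(sim.library.tags):
            fh.write(f"{tag}\t{sim.library.tags[tag]}\n")
    write_fasta(dict(sim.amplicons), paths["amplicons"])
    sim.truth.to_json(paths["ground_truth"])
    sim.config.to_yaml(paths["config"])
    return paths
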