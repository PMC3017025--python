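# stace

SAGE-tag screening, primer design and STACE amplicon classification for
novel-gene discovery.

## The problem

Gene prediction misses real genes, and low-abundance transcripts are
under-represented in cDNA sequencing projects. Expression tag libraries —
serial analysis of gene expression (SAGE) — record short, cheap fingerprints
of transcripts: a longSAGE tag is the 3'-most NlaIII site (`CATG`) of a
transcript plus the following 17 bases. Tags that map cleanly to the genome
but correspond to no annotated transcript are evidence of unannotated
transcription. *Sequence tag-based amplification of cDNA ends* (STACE) turns
such a tag into a full-length cDNA: a gene-specific primer derived from the
tag is paired with a primer on the trans-spliced leader SL1 (found at the 5'
end of ~half of *C. elegans* mRNAs) to amplify the upstream product, and with
a primer on the reverse-transcription adapter behind the polyA tail to
amplify the downstream product. The two sequenced amplicons overlap over the
tag and merge into a complete gene model.

This package implements the computational half of that workflow, for
anyone screening expressed-tag libraries against an annotated genome:

- **screen** — map tags exactly to the genome (both strands), discard tags
  explained by annotated transcription (exon overlap or presence in the
  *virtual transcriptome*, the spliced cDNA of every annotated transcript),
  require an expression frequency of at least 3 per 100,000 reads, reject
  tags inside introns or within 500 bp of an annotated gene boundary, keep
  GC content within [35%, 45%], and derive a trimmed reverse-complement
  primer that passes Tm, hairpin and dimer screens. Per-stage survivor
  counts form the *funnel report*.
- **classify** — strip SL1 leaders, polyA tails and the 3' adapter from
  sequenced amplicons, spliced-align them to the genome (or ingest BED12/PSL
  alignments), call *true positives* (alignment span overlaps the seeding
  tag), validate GT–AG splice signals, categorise results as novel gene /
  annotation extension / non-protein-coding overlap, and merge amplicon
  pairs into full-length cDNA models.
- **simulate** — a seeded generator of toy genomes with planted novel genes,
  tag libraries with injected errors, and amplicon reads, providing exact
  ground truth for every stage.

## Worked example

```bash
stace simulate --seed 1 --out world/
stace screen --genome world/genome.fasta --annotations world/annotations.gff3 \
             --tags world/tags.tsv --out screened/
stace classify --genome world/genome.fasta --annotations world/annotations.gff3 \
               --amplicons world/amplicons.fasta --out classified/
```

The screen step prints the funnel:

```
funnel: total=15 -> mappable=11 -> non_transcriptome=3 -> frequency=3 -> position=3 -> gc=3 -> primerable=3
```

Fifteen distinct tags were observed (eleven genuine plus four low-count
error tags); the eleven genuine tags map uniquely to the toy genome; three are not explained by
annotated transcription — exactly the three planted novel genes — and all
three survive the frequency, position, GC and primer screens. The classify
step then reports:

```
6 amplicons, 6 true positives, 3 merged models
```

Each planted gene's upstream/downstream amplicon pair is a true positive,
and each pair merges into a full-length model whose exons reproduce the
planted gene exactly (`classified/models.gff3`, `classified/models.fasta`).

The same operations are available as a library:

```python
from stace import SimulationConfig, simulate, run_cascade
from stace.genome import AnnotationIndex, build_virtual_transcriptome

sim = simulate(SimulationConfig(seed=1))
index = AnnotationIndex.build(sim.annotated_models, sim.genome.chrom_names)
vt = build_virtual_transcriptome(sim.genome, sim.annotated_models)
records, funnel = run_cascade(sim.library, sim.genome, index, vt)
```

## Validation data

`stace.datasets` packages the outcomes of the original *C. elegans* STACE
experiments: the 14 recovered SL1-trans-spliced cDNAs with their tag
locations and mapping boundaries, the per-set result classifications, and
the per-set screening funnels. The test suite checks the package's decision
rules against them (true-positive containment, full-length calls,
success-rate arithmetic, funnel monotonicity).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch — simulate, screen, derive primers,
classify amplicons, assemble models — verifies the packaged validation
computations, prints a summary, and writes its JSON results object to
`--out`.

## Methods

See `docs/methods.md` for the model, the thresholds and their defaults, the
simulator's stated world, numerical choices and known limitations.
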