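# Methods

## Overview

The package implements the computational side of tag-anchored cDNA-end
amplification: selecting SAGE tags that suggest unannotated genes, turning
them into gene-specific PCR primers, and interpreting the sequenced
amplicons. Everything is deterministic; the only randomness is the seeded
simulator.

## Coordinates and containers

Internal coordinates are 0-based half-open everywhere; user-facing reports
(TSV, GFF3, funnel, boundaries) are 1-based inclusive, the convention of
genome browsers and of the validation records in `stace.datasets`. Genomes
are loaded with Biopython, annotations with gffutils (in-memory database);
interval queries use a small per-chromosome linear-scan index, which is
ample at the tool's intended toy/validation scale (an external interval-tree
dependency was deliberately avoided).

"Gene boundary" means the outermost span of a gene across all of its
transcripts, a conservative reading of the distance rule; by default every
biotype (including pseudogenes and ncRNAs) contributes boundaries, and the
set is configurable. Unannotated biotypes default to `protein_coding`, which
is conservative for the exon-overlap filter.

## The screening cascade

Stages, in fixed order, each applied only to survivors of the previous one:

| stage | rule | default |
|---|---|---|
| mappable | exactly one exact full-length genomic occurrence, either strand | — |
| non_transcriptome | no annotated-exon overlap AND absent (both orientations) from the virtual transcriptome | — |
| frequency | count × 100000 / library_size ≥ threshold (inclusive) | 3.0 per 100k |
| position | no intron overlap; distance to nearest gene span ≥ threshold | 500 bp |
| gc | GC% of the full tag within the window, bounds inclusive | [35, 45] % |
| primerable | a trimmed reverse-complement primer passes every screen below | — |

Mapping is exact: sequencing errors are handled by the frequency filter, not
by mismatch rescue, and multi-mapped tags fail (they cannot anchor a
gene-specific primer; `classify_mappability` still records their loci).
Because the filters are independent predicates, reordering them changes the
per-stage counts but never the final survivor set — a property the test
suite asserts. Funnel counts are therefore non-increasing by construction.

## Primer derivation

The primer is the reverse complement of the (possibly trimmed) tag. The
search enumerates all trims with `left + right ≤ 4` and resulting length
≥ 17 nt, smallest total trim first, ties to the smallest left trim; the
first candidate passing every screen wins, making the output fully
deterministic. Screens and defaults:

- GC ∈ [35, 45] % of the trimmed primer;
- Tm ∈ [55, 65] °C, nearest-neighbour (Biopython `Tm_NN`, unified
  parameters) at 50 mM monovalent salt, 1.5 mM Mg²⁺, 0.2 mM dNTPs, 250 nM
  primer with the Owczarzy salt correction. The window brackets the
  protocol's 60 °C annealing step. The buffer conditions were fixed by
  requiring that the twelve gene-specific primers actually used in the
  validated experiments (19–21 nt, GC 35–48 %) fall inside the window; under
  monovalent-only conditions they all score 51–54 °C, which would
  contradict the window, so PCR-typical divalent conditions are the
  package's default (a unit test pins all twelve primers inside [55, 65]).
- hairpin: longest self-complementary stem with a loop ≥ 3 nt, flagged at
  stem ≥ 4; sequences shorter than `2·stem + loop` are clean by definition;
- homodimer / heterodimer (vs the fixed SL1 and universal primers): longest
  ungapped complementary run over all offsets against the reversed partner,
  flagged at ≥ 5, or ≥ 3 when the run includes either 3' terminus (a
  3'-anchored duplex is polymerase-extendable). These are explicit string
  heuristics, not thermodynamic folding: deterministic, configurable, and
  validated against exhaustive-search oracles in the tests.

## Amplicon interpretation

Reads are mRNA-sense. SL1 detection accepts any exact suffix of the 22-nt
leader of length ≥ 12 as a read prefix; polyA detection first strips the
3' adapter (reverse complement of the universal primer) if present, then
requires a terminal A-run ≥ 10. Both minima are configurable.

The built-in spliced aligner is a greedy exact seed-and-chain search
(seed 16 nt): maximal exact extension, recursive chaining with inter-block
gaps ≥ 30 bp treated as introns, and backtracking over junction shifts
(window 12 nt) because maximal extension can overshoot a junction whenever
the intron begins with the next exon's bases. After chaining, each junction
is slid within its ambiguity window onto a GT..AG placement when an
equivalent placement exists. Full read coverage is required; with
`max_mismatch > 0` the extension may absorb that many internal
substitutions. This is a toy-scale stand-in for a spliced aligner such as
BLAT — external BED12/PSL alignments are accepted equivalently — and is
validated by round-tripping simulator amplicons to their planted exons.

True positive: the closed span between the two outermost mapping boundaries
intersects the tag interval, min/max-normalised so minus-strand results
(printed 5' > 3') need no special-casing. Categories for true positives:
overlap (≥ 1 bp against a gene span) with a pseudogene or ncRNA →
`non_coding_overlap`; else overlap with any gene → `annotation_extension`
(the tag was non-transcriptome, so the amplicon necessarily adds sequence);
else `novel_gene`. Non-coding overlap takes precedence when both a coding
and a non-coding gene are overlapped — a documented package decision, made
to match the validated pseudogene call, not a rule stated by the original
experimenters. Splice signals are strand-adjusted; non-canonical introns
are flagged, never rejected.

Merging an upstream/downstream pair requires the same chromosome and
strand, exact agreement of the exon chains over the genomic overlap, and
that the overlap contain the tag; `full_length` requires SL1 evidence
upstream AND polyA evidence downstream. One missing half yields a 5'
partial model, mirroring the seven partial cDNAs among the validation
records.

## Validation records

`stace.datasets` transcribes the outcomes of the original *C. elegans*
experiments: 14 recovered cDNAs (tag locations, mapping boundaries,
full-length/partial labels), per-set result classifications (12 candidate
cDNAs over 144 tested primers; success percentages under
round-half-away-from-zero), and per-set screening funnels. One record's
printed 5' boundary is typographically corrupt (an extra digit placing it
tens of megabases from its own tag); it is stored as missing and the
containment span falls back to the tag-side coordinate. The absolute funnel
counts of the original screens required the original genome release and
tag libraries and are not reproduced; only their monotone shape is
asserted.

## The simulator's stated world

Defaults: 2 chromosomes × 60 kb, 8 annotated genes (one pseudogene, one
ncRNA), 3 hidden novel genes, 2–4 exons of 90–260 bp, introns 40–120 bp
(all GT..AG), intergenic gaps ≥ 1200 bp (over twice the boundary rule, so
planted tags are never disqualified by proximity), tag length 21, library
size 100,000, expression 5–40 (annotated) and 8–30 (novel) counts per
transcript, per-copy substitution error rate 0.02, polyA 16 nt, SL1
fraction 1.0, background GC 36 % (roughly the *C. elegans* genome). One
`numpy` generator seeded per invocation drives everything; identical seeds
give byte-identical files.

Construction guarantees, chosen so that ground truth is exact rather than
probabilistic: every transcript carries an engineered tag whose anchor is
the 3'-most CATG (no CATG downstream of it); tag GC is forced into the
screening band; novel-gene tags are rejection-sampled until a primer can be
derived from them (the screen selects for primer-able tags — emulating that
selection is part of the stated world; no threshold was moved); each noise
tag is capped at 2 observations, below the frequency threshold at the
default library size; transcripts never end in A, keeping the polyA
boundary unambiguous so round-trip reconstruction can be exact; planted-tag
uniqueness in the genome is verified after assembly (a 1-in-10⁵ collision
would raise, not silently skew results).

What the simulator does **not** model: realistic base composition beyond a
global GC fraction, quality scores, indel errors, alternative isoforms,
trans-spliced operons, repeat structure, or multi-mapping tag families. A
green round-trip therefore establishes the correctness of the pipeline's
logic and coordinate arithmetic, not its robustness to repeat-rich genomes
or noisy long reads.

## Known limitations

- The k-mer index and linear interval scans target toy/validation scale
  (≤ a few Mb); genome-scale screening would need an FM-index and an
  interval tree.
- The aligner requires full read coverage and exact matches (optionally a
  small substitution budget); it is not a general spliced aligner.
- Structure screens are string heuristics; no ΔG folding.
- Tag length is configurable (15–25) but uniform within a library; the
  validated experiments mixed 19–21 nt effective lengths across sets, which
  is why the containment records carry per-record primer lengths.
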