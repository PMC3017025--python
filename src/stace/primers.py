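"""Gene-specific primer derivation from SAGE tags.

A candidate tag becomes a primer by reverse complementation (the tag reads in
mRNA sense; the primer must anneal to the cDNA template). Because the raw
21-mer is fixed by the genome, the only degree of freedom is trimming bases
from either end before reverse-complementing. Each trimmed candidate is
screened on GC content, nearest-neighbour melting temperature and simple
secondary-structure heuristics (hairpin, homodimer, and heterodimer against
the two fixed amplification primers).

The structure screens are deliberately explicit string heuristics rather than
thermodynamic folding: they are deterministic, fast, and easy to validate
against exhaustive search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as mt

# Fixed amplification primers of the STACE protocol. SL1 is the C. elegans
# trans-spliced leader found at the 5' end of ~half of all mRNAs; the
# universal primer matches the constant region of the modified oligo-d(T)
# primer used to prime reverse transcription at the polyA tail.
SL1_PRIMER = "GGTTTAATTACCCAAGTTTGAG"
UNIVERSAL_PRIMER = "CACTATGCTCATACGACGCAGT"
RT_PRIMER = "CCAGACACTATGCTCATACGACGCAGT" + "T" * 16 + "VN"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(sequence: str) -> str:
    """Watson-Crick reverse complement over the ACGTN alphabet."""
    if not set(sequence) <= set("ACGTNacgtn"):
        bad = sorted(set(sequence) - set("ACGTNacgtn"))
        raise ValueError(f"cannot reverse-complement characters {bad!r}")
    return sequence.translate(_COMPLEMENT)[::-1]


def gc_percent(sequence: str) -> float:
    """GC content in percent of sequence length."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def _comp(base: str) -> str:
    return base.translate(_COMPLEMENT)


def hairpin_score(sequence: str, min_stem: int = 4, min_loop: int = 3) -> tuple[int, bool]:
    """Longest self-complementary stem with a loop of >= ``min_loop`` bases.

    Scans every pair of end positions (i, j) and extends inward while
    sequence[i+k] pairs sequence[j-k]; the usable stem length is capped so
    that at least ``min_loop`` unpaired bases remain in the loop. Returns
    ``(stem_length, flagged)`` with ``flagged`` true when the stem reaches
    ``min_stem``. Sequences too short to fold (< 2*min_stem + min_loop)
    are clean by definition.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 2 * min_stem + min_loop:
        return 0, False
    best = 0
    for i in range(n):
        for j in range(i + 1, n):
            l = 0
            while i + l < j - l and seq[i + l] == _comp(seq[j - l]):
                l += 1
            usable = min(l, (j - i + 1 - min_loop) // 2)
            if usable > best:
                best = usable
    return best, best >= min_stem


@dataclass(frozen=True)
class DimerScore:
    """Longest ungapped complementary run between two primers."""

    max_run: int
    anchored_run: int  # longest run that includes either primer's 3' terminus
    flagged: bool


def dimer_score(seq_a: str, seq_b: str, min_run: int = 5) -> DimerScore:
    """Duplex screen: slide ``seq_a`` along the reverse of ``seq_b``.

    The score is the longest ungapped run of complementary base pairs over
    all relative offsets. Runs that involve the 3' terminus of either primer
    are the ones extendable by polymerase, so they are flagged at a stricter
    threshold (``min_run - 2``). A homodimer check is ``dimer_score(s, s)``.
    """
    if not seq_a or not seq_b:
        raise ValueError("dimer_score requires two non-empty sequences")
    a = seq_a.upper()
    rb = seq_b.upper()[::-1]  # b reversed: rb[0] is b's 3' terminus
    la, lb = len(a), len(rb)
    best = 0
    best_anchored = 0
    for off in range(-(lb - 1), la):
        run = 0
        anchored = False
        for j in range(lb):
            i = off + j
            if 0 <= i < la and a[i] == _comp(rb[j]):
                run += 1
                anchored = anchored or i == la - 1 or j == 0
                if run > best:
                    best = run
                if anchored and run > best_anchored:
                    best_anchored = run
            else:
                run = 0
                anchored = False
    flagged = best >= min_run or best_anchored >= max(1, min_run - 2)
    return DimerScore(best, best_anchored, flagged)


def tm_estimate(sequence: str) -> float:
    """Nearest-neighbour melting temperature under fixed PCR-like conditions.

    Unified NN parameters, 50 mM monovalent salt, 1.5 mM Mg2+, 0.2 mM dNTPs,
    250 nM primer (Owczarzy salt correction). Deterministic; used only to
    rank trim variants against the annealing window.
    """
    if len(sequence) < 8:
        raise ValueError("Tm estimate requires at least 8 bases")
    return float(
        mt.Tm_NN(sequence.upper(), Na=50, Mg=1.5, dNTPs=0.2, dnac1=250, dnac2=0, saltcorr=7)
    )


@dataclass(frozen=True)
class PrimerConstraints:
    """Screening thresholds for derived primers (all configurable)."""

    gc_min: float = 35.0
    gc_max: float = 45.0
    tm_min: float = 55.0
    tm_max: float = 65.0
    min_length: int = 17
    max_trim: int = 4
    hairpin_min_stem: int = 4
    hairpin_min_loop: int = 3
    dimer_min_run: int = 5


DEFAULT_CONSTRAINTS = PrimerConstraints()


@dataclass
class PrimerCandidate:
    """A derived gene-specific primer with its diagnostics."""

    sequence: str
    source_tag: str
    trim_left: int
    trim_right: int
    gc: float
    tm: float
    hairpin_stem: int
    hairpin_flag: bool
    homodimer: DimerScore
    heterodimers: dict[str, DimerScore] = field(default_factory=dict)


def screen_primer(primer: str, constraints: PrimerConstraints = DEFAULT_CONSTRAINTS):
    """Run every individual screen on a primer sequence.

    Returns ``(ok, diagnostics)`` where diagnostics carries each measured
    quantity so a caller can re-validate or report the failure reason.
    """
    gc = gc_percent(primer)
    tm_c = tm_estimate(primer)
    stem, hflag = hairpin_score(
        primer, constraints.hairpin_min_stem, constraints.hairpin_min_loop
    )
    homo = dimer_score(primer, primer, constraints.dimer_min_run)
    heteros = {
        "SL1": dimer_score(primer, SL1_PRIMER, constraints.dimer_min_run),
        "universal": dimer_score(primer, UNIVERSAL_PRIMER, constraints.dimer_min_run),
    }
    ok = (
        constraints.gc_min <= gc <= constraints.gc_max
        and constraints.tm_min <= tm_c <= constraints.tm_max
        and not hflag
        and not homo.flagged
        and not any(d.flagged for d in heteros.values())
    )
    diagnostics = {
        "gc": gc,
        "tm": tm_c,
        "hairpin_stem": stem,
        "hairpin_flag": hflag,
        "homodimer": homo,
        "heterodimers": heteros,
    }
    return ok, diagnostics


def derive_primer(
    tag: str, constraints: PrimerConstraints = DEFAULT_CONSTRAINTS
) -> PrimerCandidate | None:
    """Derive a gene-specific primer from a tag, trimming if needed.

    Enumerates every (left, right) trim with ``left + right <= max_trim``
    and resulting length >= ``min_length``, in deterministic order: smallest
    total trim first (hence longest primer first), ties broken by smallest
    left trim. The first trim whose reverse complement passes every screen
    wins; returns ``None`` when no trim passes.
    """
    tag = tag.upper()
    n = len(tag)
    for total in range(0, constraints.max_trim + 1):
        if n - total < constraints.min_length:
            break
        for left in range(0, total + 1):
            right = total - left
            trimmed = tag[left : n - right]
            primer = revcomp(trimmed)
            ok, diag = screen_primer(primer, constraints)
            if ok:
                return PrimerCandidate(
                    sequence=primer,
                    source_tag=tag,
                    trim_left=left,
                    trim_right=right,
                    gc=diag["gc"],
                    tm=diag["tm"],
                    hairpin_stem=diag["hairpin_stem"],
                    hairpin_flag=diag["hairpin_flag"],
                    homodimer=diag["homodimer"],
                    heterodimers=diag["heterodimers"],
                )
    return None
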