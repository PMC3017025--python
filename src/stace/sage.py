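"""SAGE tag libraries.

A (long)SAGE tag is an expressed-sequence fingerprint: the 3'-most NlaIII
site (CATG) of a transcript plus the following bases, 21 nt in total for
longSAGE. Counts are normalised to tags per 100,000 sequenced reads so that
libraries of different depth are comparable.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

ANCHOR = "CATG"
DEFAULT_TAG_LENGTH = 21  # CATG + 17 (longSAGE); configurable 15-25


@dataclass(frozen=True)
class SageTag:
    """One tag observation: anchored sequence, raw count, source library."""

    sequence: str
    count: int
    source_library: str = ""

    def __post_init__(self):
        if not re.fullmatch(rf"{ANCHOR}[ACGT]+", self.sequence):
            raise ValueError(f"tag {self.sequence!r} is not CATG-anchored ACGT")
        if self.count < 0:
            raise ValueError("tag count must be non-negative")


@dataclass
class TagLibrary:
    """A tag->count mapping plus the library's total sequencing depth.

    ``library_size`` is the sequencing total reported with the library; it
    is not required to equal the sum of listed counts.
    """

    name: str
    tags: dict[str, int] = field(default_factory=dict)
    library_size: int = 0

    def __post_init__(self):
        if self.library_size <= 0:
            raise ValueError("library_size must be a positive integer")
        lengths = {len(t) for t in self.tags}
        if len(lengths) > 1:
            raise ValueError(f"mixed tag lengths in library {self.name!r}: {sorted(lengths)}")

    @property
    def tag_length(self) -> int | None:
        return len(next(iter(self.tags))) if self.tags else None

    def frequency(self, tag: str) -> float:
        return normalized_frequency(self.tags.get(tag, 0), self.library_size)


def normalized_frequency(count: int, library_size: int) -> float:
    """Tags per 100,000 reads."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return count * 100000.0 / library_size


def read_tag_library(tsv_path, name: str | None = None):
    """Read a tag TSV (``tag<TAB>count``) with a ``#library_size=N`` header.

    Invalid rows (bad anchor, non-ACGT characters, bad counts) are not
    silently dropped: they are returned as a rejects list alongside the
    library. Duplicate tag rows have their counts summed with a warning.

    Returns ``(TagLibrary, rejects)`` where each reject is
    ``(line_number, raw_line, reason)``.
    """
    library_size = None
    tags: dict[str, int] = {}
    rejects: list[tuple[int, str, str]] = []
    name = name or str(tsv_path)
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*library_size\s*=\s*(\d+)", line)
                if m:
                    library_size = int(m.group(1))
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                rejects.append((lineno, line, "missing count column"))
                continue
            tag, count_str = parts[0].strip().upper(), parts[1].strip()
            if tag in ("TAG",):  # header row
                continue
            try:
                count = int(count_str)
            except ValueError:
                rejects.append((lineno, line, f"non-integer count {count_str!r}"))
                continue
            if count < 0:
                rejects.append((lineno, line, "negative count"))
                continue
            if not re.fullmatch(rf"{ANCHOR}[ACGT]+", tag):
                rejects.append((lineno, line, "tag not CATG-anchored ACGT"))
                continue
            if tag in tags:
                logger.warning("duplicate tag %s in %s; counts summed", tag, name)
            tags[tag] = tags.get(tag, 0) + count
    if library_size is None:
        raise ValueError(f"{tsv_path}: missing '#library_size=<int>' header")
    return TagLibrary(name=name, tags=tags, library_size=library_size), rejects


def write_rejects(rejects, path) -> None:
    with open(path, "w") as fh:
        fh.write("line\traw\treason\n")
        for lineno, raw, reason in rejects:
            fh.write(f"{lineno}\t{raw}\t{reason}\n")


def merge_libraries(libraries: list[TagLibrary], name: str = "merged") -> TagLibrary:
    """Pool libraries into a meta-library: counts and depths summed."""
    if not libraries:
        raise ValueError("cannot merge an empty list of libraries")
    lengths = {lib.tag_length for lib in libraries if lib.tag_length is not None}
    if len(lengths) > 1:
        raise ValueError(f"cannot merge libraries with mixed tag lengths {sorted(lengths)}")
    tags: dict[str, int] = {}
    for lib in libraries:
        for tag, count in lib.tags.items():
            tags[tag] = tags.get(tag, 0) + count
    provenance = "+".join(lib.name for lib in libraries)
    return TagLibrary(
        name=f"{name}({provenance})",
        tags=tags,
        library_size=sum(lib.library_size for lib in libraries),
    )


def extract_expected_tag(
    spliced_cdna: str, tag_length: int = DEFAULT_TAG_LENGTH, allow_fallback: bool = False
) -> str | None:
    """Tag a transcript would yield: 3'-most CATG plus the following bases.

    Returns ``None`` when there is no CATG or fewer than ``tag_length - 4``
    bases follow the 3'-most site (a modelled polyA tail counts as sequence).
    With ``allow_fallback`` the next upstream CATG with enough downstream
    sequence is used instead of discarding the transcript.
    """
    if tag_length < 5:
        raise ValueError("tag_length must be at least 5")
    seq = spliced_cdna.upper()
    pos = seq.rfind(ANCHOR)
    while pos != -1:
        if len(seq) - pos >= tag_length:
            return seq[pos : pos + tag_length]
        if not allow_fallback:
            return None
        pos = seq.rfind(ANCHOR, 0, pos)
    return None
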