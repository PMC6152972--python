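"""Raw small-RNA read cleanup.

Adapter trimming at the 3' end, boundary-inclusive 18-30 nt length
filtering, collapsing to unique tags with per-library counts, and removal of
tags matching known ncRNA / known-miRNA reference sets by exact substring
containment (consistent with zero-mismatch mapping downstream).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio import SeqIO

from .seqcore import reverse_complement, rna_to_dna

MIN_LEN = 18
MAX_LEN = 30

#: when a tag hits multiple reference classes, the first class here wins
ANNOTATION_PRECEDENCE = ("known_miRNA", "rRNA", "tRNA", "snRNA", "snoRNA")


@dataclass
class ReadTag:
    """A collapsed unique small-RNA sequence with per-library counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)
    annotation: str = "clean"

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def trim_adapter(read: str, adapter: str, min_overlap: int = 4) -> str:
    """Remove the 3' adapter, allowing a terminal partial match.

    The leftmost full adapter occurrence is cut; otherwise the longest read
    suffix matching an adapter prefix of >= ``min_overlap`` bases is cut.
    Reads with no adapter evidence pass through unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read = read.upper()
    adapter = adapter.upper()
    idx = read.find(adapter)
    if idx >= 0:
        return read[:idx]
    max_ov = min(len(adapter) - 1, len(read))
    for ov in range(max_ov, min_overlap - 1, -1):
        if read.endswith(adapter[:ov]):
            return read[:-ov]
    return read


def length_filter(sequences: list[str], min_len: int = MIN_LEN,
                  max_len: int = MAX_LEN) -> list[str]:
    """Keep sequences with min_len <= length <= max_len (boundaries kept)."""
    return [s for s in sequences if min_len <= len(s) <= max_len]


def collapse(reads_per_library: dict[str, list[str]]) -> list[ReadTag]:
    """Collapse reads to unique tags with per-library counts.

    Tags are sorted by total count descending, then lexicographically, so
    the output is deterministic and count-conserving.
    """
    counters = {lib: Counter(reads) for lib, reads in reads_per_library.items()}
    sequences = sorted(set().union(*[set(c) for c in counters.values()])
                       if counters else set())
    tags = [
        ReadTag(seq, {lib: counters[lib][seq] for lib in counters
                      if counters[lib][seq] > 0})
        for seq in sequences
    ]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def load_reference_sets(paths: dict[str, str]) -> dict[str, dict[str, str]]:
    """Read one FASTA per known-RNA class; missing files raise naming the
    class."""
    refs = {}
    for cls, path in paths.items():
        try:
            records = {r.id: rna_to_dna(str(r.seq).upper())
                       for r in SeqIO.parse(str(path), "fasta")}
        except FileNotFoundError as exc:
            raise FileNotFoundError(
                f"reference FASTA for class {cls!r} not found: {path}"
            ) from exc
        refs[cls] = records
    return refs


def annotate_known(tags: list[ReadTag],
                   references: dict[str, dict[str, str]]) -> list[ReadTag]:
    """Set ``annotation`` on tags contained in a reference sequence (either
    strand); unmatched tags stay ``clean``. Annotation follows the class
    precedence order, so a tag hitting both the known-miRNA and an ncRNA set
    is labeled known_miRNA."""
    haystacks = {}
    for cls, records in references.items():
        joined = "#".join(rna_to_dna(s.upper()) for s in records.values())
        haystacks[cls] = joined + "#" + reverse_complement(joined)
    for tag in tags:
        if tag.annotation != "clean":
            continue
        for cls in ANNOTATION_PRECEDENCE:
            if cls in haystacks and tag.sequence in haystacks[cls]:
                tag.annotation = cls
                break
    return tags


def clean_tags(tags: list[ReadTag]) -> list[ReadTag]:
    """Tags that survive reference-set removal (annotation == clean)."""
    return [t for t in tags if t.annotation == "clean"]


def run_preprocess(reads_per_library: dict[str, list[str]],
                   adapter: str | None = None, min_overlap: int = 4,
                   references: dict[str, dict[str, str]] | None = None,
                   min_len: int = MIN_LEN, max_len: int = MAX_LEN
                   ) -> tuple[list[ReadTag], dict[str, dict[str, int]]]:
    """Full cleanup: trim -> length filter -> collapse -> annotate.

    Returns (all tags with annotations, per-library accounting of reads in /
    kept / dropped-by-length)."""
    stats: dict[str, dict[str, int]] = {}
    filtered = {}
    for lib, reads in reads_per_library.items():
        if adapter:
            reads = [trim_adapter(r, adapter, min_overlap) for r in reads]
        kept = length_filter(reads, min_len, max_len)
        filtered[lib] = kept
        stats[lib] = {"input": len(reads), "kept": len(kept),
                      "dropped_length": len(reads) - len(kept)}
    tags = collapse(filtered)
    if references:
        tags = annotate_known(tags, references)
    return tags, stats
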