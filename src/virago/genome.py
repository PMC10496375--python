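"""Segmented viral genomes as ordered collections of sequence segments.

Genomes handled here are RNA viruses, but sequences are stored in the DNA
alphabet (T rather than U), matching the convention of deposited cDNA
sequences. All coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement in the DNA alphabet (N maps to N)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ORF:
    """An open reading frame on a segment.

    ``start``/``end`` are 0-based half-open coordinates on the forward
    strand of the stored sequence and include the stop codon; ``aa_len``
    is the encoded protein length excluding the stop.
    """

    start: int
    end: int
    frame: int
    strand: str  # "+" or "-"
    aa_len: int


@dataclass
class Segment:
    """One genomic segment: a named sequence with optional ORF annotation."""

    name: str
    sequence: str
    orfs: list[ORF] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SegmentedGenome:
    """A viral genome as an ordered list of segments."""

    name: str
    segments: list[Segment]
    meta: dict = field(default_factory=dict)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.segments)

    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(f"no segment named {name!r} in genome {self.name!r}")
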