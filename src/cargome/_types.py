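"""Core domain types shared across the pipeline.

All coordinates in this package are 0-based, half-open (BED/UCSC
convention).  Converting from a 1-based inclusive source subtracts 1
from the start only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_BASES = frozenset("ACGTNacgtn")


class GenomeSequence:
    """Per-chromosome nucleotide strings.

    Alphabet is A, C, G, T, N; lowercase letters denote soft-masked
    bases.  Chromosome names are unique (dict keyed by name).
    """

    def __init__(self, chroms: dict[str, str]):
        for name, seq in chroms.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r}: invalid characters {sorted(bad)}"
                )
        self.chroms = dict(chroms)

    def __getitem__(self, name: str) -> str:
        return self.chroms[name]

    def __contains__(self, name: str) -> bool:
        return name in self.chroms

    def __iter__(self):
        return iter(self.chroms)

    def __len__(self) -> int:
        return len(self.chroms)

    def items(self):
        return self.chroms.items()

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    def upper(self) -> "GenomeSequence":
        """Return a copy with soft-masking removed (all uppercase)."""
        return GenomeSequence({n: s.upper() for n, s in self.chroms.items()})


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional BED name/score."""

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlap in bp with another interval (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class Transcript:
    """One transcript: strand, ordered exons, and the derived TSS.

    Exons are stored sorted by genomic start; ``exons_5to3`` yields them
    in transcription order.  The TSS is the strand-appropriate end of
    the first exon: smallest start on '+', largest end on '-'.
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"transcript {self.transcript_id!r}: unknown strand "
                f"{self.strand!r}"
            )
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id!r} has no exons")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(
                    f"transcript {self.transcript_id!r}: overlapping exons"
                )

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.exons[0][0]
        return self.exons[-1][1]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exons_5to3(self) -> list[tuple[int, int]]:
        """Exons in transcription order (5' to 3' along the strand)."""
        if self.strand == "+":
            return list(self.exons)
        return list(reversed(self.exons))

    def introns_5to3(self) -> list[tuple[int, int]]:
        introns = [
            (e1_end, e2_start)
            for (_, e1_end), (e2_start, _) in zip(self.exons, self.exons[1:])
        ]
        if self.strand == "-":
            introns.reverse()
        return introns


@dataclass
class GeneModel:
    """A gene: one or more transcripts on a shared chromosome."""

    gene_id: str
    chrom: str
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self):
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id!r} has no transcripts")

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def tss(self) -> int:
        """Representative TSS (first transcript's)."""
        return self.transcripts[0].tss

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)
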