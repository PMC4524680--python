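"""CArG-box permutation table and genome scanner.

The CArG box is the 10-bp serum response factor (SRF) binding element
CC(A/T)6GG: positions 1-2 are CC, positions 3-8 are A or T (the "W
core"), positions 9-10 are GG.  There are 2^6 = 64 consensus
sequences.  Single-mismatch ("CArG-like") elements deviate from the
nearest consensus sequence at exactly one position.

The scanner tests every 10-bp window on the forward strand for
membership in the permutation table.  Because the table is closed
under reverse complement, a forward-strand scan sees every CArG locus
exactly once regardless of which strand SRF would read it on, which
is what makes genome-wide counts well defined.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from ._types import GeneModel, GenomeSequence, GenomicInterval

CONSENSUS = "consensus"
SINGLE_MISMATCH = "single_mismatch"

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

BOX_LENGTH = 10
# per-position allowed bases of the CC(A/T)6GG consensus
_CONSENSUS_SLOTS = ("C", "C", "AT", "AT", "AT", "AT", "AT", "AT", "G", "G")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def consensus_distance(seq: str) -> int:
    """Minimum Hamming distance from ``seq`` to the consensus set.

    The consensus set is positionally independent (each position has
    its own allowed alphabet), so the distance to the *set* is the
    number of positions whose base is outside that position's slot.
    """
    return sum(base not in slot for base, slot in zip(seq, _CONSENSUS_SLOTS))


@dataclass(frozen=True)
class PermutationEntry:
    sequence: str
    match_class: str  # CONSENSUS or SINGLE_MISMATCH
    mismatch_position: int | None  # 1-based, None for consensus


class PermutationTable:
    """The set of allowed CArG 10-mers with per-sequence match class."""

    def __init__(self, entries: dict[str, PermutationEntry]):
        self.entries = entries
        self._sequences = frozenset(entries)

    def __contains__(self, seq: str) -> bool:
        return seq in self._sequences

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, seq: str) -> PermutationEntry:
        return self.entries[seq]

    @property
    def sequences(self) -> frozenset[str]:
        return self._sequences

    def is_rc_closed(self) -> bool:
        return all(reverse_complement(s) in self._sequences for s in self._sequences)

    def rc_violations(self) -> list[str]:
        return sorted(
            s for s in self._sequences if reverse_complement(s) not in self._sequences
        )


def _classify(seq: str) -> PermutationEntry:
    dist = consensus_distance(seq)
    if dist == 0:
        return PermutationEntry(seq, CONSENSUS, None)
    if dist == 1:
        pos = next(
            i + 1
            for i, (base, slot) in enumerate(zip(seq, _CONSENSUS_SLOTS))
            if base not in slot
        )
        return PermutationEntry(seq, SINGLE_MISMATCH, pos)
    raise ValueError(f"{seq!r} is {dist} mismatches from the consensus set")


def consensus_sequences() -> list[str]:
    """All 64 CC(A/T)6GG sequences."""
    return [
        "CC" + "".join(core) + "GG"
        for core in itertools.product("AT", repeat=6)
    ]


def generate_permutations(max_mismatch: int) -> PermutationTable:
    """Build the CArG permutation table.

    max_mismatch=0 gives the 64 consensus sequences; max_mismatch=1
    additionally admits every 10-mer at Hamming distance 1 from some
    consensus sequence.  Larger deviations are not defined.
    """
    if max_mismatch not in (0, 1):
        raise ValueError(f"max_mismatch must be 0 or 1, got {max_mismatch}")
    seqs = set(consensus_sequences())
    if max_mismatch == 1:
        for cons in consensus_sequences():
            for i in range(BOX_LENGTH):
                for base in _BASES:
                    if base != cons[i]:
                        seqs.add(cons[:i] + base + cons[i + 1:])
    return PermutationTable({s: _classify(s) for s in sorted(seqs)})


def load_permutations(path, strict_rc: bool = False) -> PermutationTable:
    """Load a permutation table from a file of one 10-mer per line.

    Lines starting with '#' are comments.  Match class is assigned by
    Hamming distance to the consensus set.  A reverse-complement
    closure violation makes the forward-strand scan strand-dependent;
    it raises under ``strict_rc``, otherwise warns.
    """
    import warnings

    seqs: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip().upper()
            if not line or line.startswith("#"):
                continue
            if len(line) != BOX_LENGTH or set(line) - set(_BASES):
                raise ValueError(
                    f"{path}:{lineno}: {line!r} is not a 10-mer over ACGT"
                )
            seqs.append(line)
    table = PermutationTable({s: _classify(s) for s in sorted(set(seqs))})
    violations = table.rc_violations()
    if violations:
        msg = (
            f"{path}: table not closed under reverse complement; scanning "
            f"becomes strand-dependent (offending sequences: "
            f"{violations[:5]}{'...' if len(violations) > 5 else ''})"
        )
        if strict_rc:
            raise ValueError(msg)
        warnings.warn(msg)
    return table


def write_permutations(table: PermutationTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("# CArG permutation table: one 10-mer per line\n")
        for seq in sorted(table.sequences):
            fh.write(seq + "\n")


@dataclass(frozen=True)
class CArGBox:
    """A single CArG-box hit: a 10-bp interval plus its match class."""

    chrom: str
    start: int
    sequence: str
    match_class: str
    mismatch_position: int | None = None

    @property
    def end(self) -> int:
        return self.start + BOX_LENGTH

    def interval(self) -> GenomicInterval:
        score = 0 if self.match_class == CONSENSUS else (self.mismatch_position or 0)
        return GenomicInterval(self.chrom, self.start, self.end, self.sequence, score)


def scan_chromosome(
    name: str, seq: str, table: PermutationTable, skip_softmask: bool = False
) -> list[CArGBox]:
    """Scan one chromosome; windows containing N (or lowercase when
    ``skip_softmask``) are skipped; overlapping hits are all reported."""
    if not skip_softmask:
        seq = seq.upper()
    boxes: list[CArGBox] = []
    n = len(seq)
    sequences = table.sequences
    for p in range(n - BOX_LENGTH + 1):
        window = seq[p : p + BOX_LENGTH]
        if window in sequences:
            entry = table[window]
            boxes.append(
                CArGBox(name, p, window, entry.match_class, entry.mismatch_position)
            )
    return boxes


def scan_genome(
    genome: GenomeSequence, table: PermutationTable, skip_softmask: bool = False
) -> list[CArGBox]:
    """Find every CArG box in the genome, sorted by (chrom, start).

    Forward strand only: the table's reverse-complement closure makes
    this equivalent to a double-strand scan with each locus counted
    once.
    """
    boxes: list[CArGBox] = []
    for name in sorted(genome):
        boxes.extend(scan_chromosome(name, genome[name], table, skip_softmask))
    return boxes


def boxes_to_intervals(boxes: list[CArGBox]) -> list[GenomicInterval]:
    return [b.interval() for b in boxes]


def boxes_from_bed(intervals: list[GenomicInterval]) -> list[CArGBox]:
    """Rebuild CArG boxes from BED5 rows written by the scan CLI."""
    boxes = []
    for iv in intervals:
        if len(iv) != BOX_LENGTH:
            raise ValueError(
                f"{iv.chrom}:{iv.start}-{iv.end}: CArG records must span 10 bp"
            )
        mismatch = int(iv.score)
        boxes.append(
            CArGBox(
                iv.chrom,
                iv.start,
                iv.name,
                CONSENSUS if mismatch == 0 else SINGLE_MISMATCH,
                None if mismatch == 0 else mismatch,
            )
        )
    return boxes


def distance_to_tss(box: CArGBox, gene: GeneModel) -> int:
    """Signed strand-aware distance from the box 5' edge to the TSS.

    Negative values are upstream of the TSS (promoter side), matching
    the convention of quoting promoter CArG positions like -313 bp.
    """
    if box.chrom != gene.chrom:
        raise ValueError(
            f"box on {box.chrom} but gene {gene.gene_id} on {gene.chrom}"
        )
    if gene.strand == "+":
        return box.start - gene.tss
    # on '-', the 5' edge of the box is its genomic end; upstream is rightward
    return gene.tss - box.end
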