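"""Cross-species CArG conservation through a block coordinate map.

Conservation is assessed positionally: a source-genome CArG box is
conserved when its liftover-style projection through an alignment
block map lands on (overlaps by at least ``min_overlap`` bp) a CArG
box found in the target genome.  Sequence identity is deliberately
not required — the projected locus carrying a CArG box in both
genomes is the criterion, and the overlap requirement is exposed as a
parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._types import GenomicInterval
from .scan import BOX_LENGTH, CArGBox


@dataclass(frozen=True)
class AlignmentBlock:
    """One gapless alignment block: equal-length source and target spans."""

    src_chrom: str
    src_start: int
    src_end: int
    tgt_chrom: str
    tgt_start: int
    tgt_end: int
    tgt_strand: str = "+"

    def __post_init__(self):
        if self.src_end - self.src_start != self.tgt_end - self.tgt_start:
            raise ValueError(
                f"block {self.src_chrom}:{self.src_start}-{self.src_end}: "
                "source and target lengths differ"
            )
        if self.tgt_strand not in ("+", "-"):
            raise ValueError(f"unknown target strand {self.tgt_strand!r}")


class CoordinateMap:
    """Ordered, non-overlapping alignment blocks keyed by source chrom."""

    def __init__(self, blocks: list[AlignmentBlock]):
        self.blocks = sorted(blocks, key=lambda b: (b.src_chrom, b.src_start))
        prev: AlignmentBlock | None = None
        for block in self.blocks:
            if (
                prev is not None
                and block.src_chrom == prev.src_chrom
                and block.src_start < prev.src_end
            ):
                raise ValueError(
                    f"overlapping source blocks on {block.src_chrom} at "
                    f"{prev.src_start}-{prev.src_end} and "
                    f"{block.src_start}-{block.src_end}"
                )
            prev = block

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)


def read_coordinate_map(path) -> CoordinateMap:
    """Read a tab-separated block map (src_chrom, src_start, src_end,
    tgt_chrom, tgt_start, tgt_end, tgt_strand)."""
    blocks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            blocks.append(
                AlignmentBlock(
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[3],
                    int(fields[4]),
                    int(fields[5]),
                    fields[6],
                )
            )
    return CoordinateMap(blocks)


def write_coordinate_map(cmap: CoordinateMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("#src_chrom\tsrc_start\tsrc_end\ttgt_chrom\ttgt_start\ttgt_end\ttgt_strand\n")
        for b in cmap:
            fh.write(
                f"{b.src_chrom}\t{b.src_start}\t{b.src_end}\t{b.tgt_chrom}\t"
                f"{b.tgt_start}\t{b.tgt_end}\t{b.tgt_strand}\n"
            )


def map_interval(
    interval: GenomicInterval, cmap: CoordinateMap
) -> GenomicInterval | None:
    """Project a source interval to target coordinates.

    The interval must lie entirely within a single block; intervals
    that are unmapped or straddle block boundaries return None (no
    partial projections).  Minus-strand blocks reverse coordinates
    within the block.
    """
    for block in cmap:
        if block.src_chrom != interval.chrom:
            continue
        if block.src_start <= interval.start and interval.end <= block.src_end:
            offset = interval.start - block.src_start
            length = len(interval)
            if block.tgt_strand == "+":
                start = block.tgt_start + offset
            else:
                start = block.tgt_end - offset - length
            return GenomicInterval(
                block.tgt_chrom, start, start + length, interval.name, interval.score
            )
    return None


@dataclass(frozen=True)
class ConservedCArG:
    """A source box whose projection overlaps target-genome boxes."""

    source: CArGBox
    mapped: GenomicInterval
    target_matches: tuple[CArGBox, ...]


def find_conserved(
    source_boxes: list[CArGBox],
    target_boxes: list[CArGBox],
    cmap: CoordinateMap,
    min_overlap: int = 1,
) -> list[ConservedCArG]:
    """Select source boxes conserved in the target genome.

    A source box is conserved iff its interval projects cleanly
    through the map and the projection overlaps at least one target
    box by >= ``min_overlap`` bp.  Output preserves source order, so
    the conserved set is always a sublist of the input.
    """
    if not 1 <= min_overlap <= BOX_LENGTH:
        raise ValueError(f"min_overlap must be in [1, {BOX_LENGTH}]")
    by_chrom: dict[str, list[CArGBox]] = {}
    for box in target_boxes:
        by_chrom.setdefault(box.chrom, []).append(box)

    conserved: list[ConservedCArG] = []
    for box in source_boxes:
        projected = map_interval(box.interval(), cmap)
        if projected is None:
            continue
        matches = tuple(
            t
            for t in by_chrom.get(projected.chrom, [])
            if min(projected.end, t.end) - max(projected.start, t.start)
            >= min_overlap
        )
        if matches:
            conserved.append(ConservedCArG(box, projected, matches))
    return conserved
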