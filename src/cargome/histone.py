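"""Histone-mark profiling of gene TSS windows and signature calls.

Three marks are read jointly: H3K4me3 (active or poised promoters),
H3K27ac (active), and H3K27me3 (silenced).  Each gene's per-mark
signal value is the average of the minimum and maximum ChIP signal
over a window centred on the TSS.  The joint low/high pattern across
the three marks classifies a gene:

    H3K4me3  H3K27ac  H3K27me3   class
    low      low      high       restricted_active  (active only in the
                                 profiled cell type, silenced elsewhere
                                 in the tissue; the Cnn1-like pattern)
    high     high     low        ubiquitous_active  (the Ubb-like pattern)
    low      low      low        silenced
    anything else                ambiguous

Only the first two patterns have a biological reading anchored in
marker genes; all-low as "silenced" is a convention and every other
combination is deliberately left ambiguous rather than guessed.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np

from ._types import GeneModel

MARKS = ("H3K4me3", "H3K27ac", "H3K27me3")

RESTRICTED_ACTIVE = "restricted_active"
UBIQUITOUS_ACTIVE = "ubiquitous_active"
SILENCED = "silenced"
AMBIGUOUS = "ambiguous"

LOW, HIGH = "low", "high"

DEFAULT_WINDOW_BP = 2000

# (H3K4me3, H3K27ac, H3K27me3) level triple -> class; total over all 8
SIGNATURE_MAP: dict[tuple[str, str, str], str] = {
    (LOW, LOW, HIGH): RESTRICTED_ACTIVE,
    (HIGH, HIGH, LOW): UBIQUITOUS_ACTIVE,
    (LOW, LOW, LOW): SILENCED,
    (LOW, HIGH, LOW): AMBIGUOUS,
    (LOW, HIGH, HIGH): AMBIGUOUS,
    (HIGH, LOW, LOW): AMBIGUOUS,
    (HIGH, LOW, HIGH): AMBIGUOUS,
    (HIGH, HIGH, HIGH): AMBIGUOUS,
}


class SignalTrack:
    """Per-chromosome piecewise-constant signal (bedGraph blocks).

    Positions not covered by any block have signal 0.
    """

    def __init__(self, blocks: dict[str, list[tuple[int, int, float]]]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, blist in blocks.items():
            blist = sorted(blist)
            for (s1, e1, _), (s2, _, _) in zip(blist, blist[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping bedGraph blocks on {chrom}")
            self._starts[chrom] = np.array([b[0] for b in blist], dtype=np.int64)
            self._ends[chrom] = np.array([b[1] for b in blist], dtype=np.int64)
            self._values[chrom] = np.array([b[2] for b in blist], dtype=float)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base signal over [start, end)."""
        if start >= end:
            raise ValueError("empty window")
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._starts:
            return out
        starts, ends, vals = self._starts[chrom], self._ends[chrom], self._values[chrom]
        i = max(0, bisect_right(starts, start) - 1)
        for j in range(i, len(starts)):
            if starts[j] >= end:
                break
            lo, hi = max(start, int(starts[j])), min(end, int(ends[j]))
            if lo < hi:
                out[lo - start : hi - start] = vals[j]
        return out


def signal_value(window_signal: np.ndarray) -> float:
    """(min + max) / 2 of the ChIP signal over a window."""
    arr = np.asarray(window_signal, dtype=float)
    if arr.size == 0:
        raise ValueError("empty signal window")
    return float((arr.min() + arr.max()) / 2.0)


@dataclass(frozen=True)
class HistoneProfile:
    gene_id: str
    signal_values: dict[str, float]  # mark -> (min+max)/2 over the TSS window

    def __getitem__(self, mark: str) -> float:
        return self.signal_values[mark]


def profile_genes(
    genes: list[GeneModel],
    tracks: dict[str, SignalTrack],
    window_bp: int = DEFAULT_WINDOW_BP,
    chrom_lengths: dict[str, int] | None = None,
) -> list[HistoneProfile]:
    """Per-gene signal values over [TSS - window_bp, TSS + window_bp).

    The window is symmetric about the TSS, so it is identical for the
    two strands.  Windows extending past chromosome ends are clipped
    (with a warning) when ``chrom_lengths`` is supplied.
    """
    import warnings

    missing = [m for m in MARKS if m not in tracks]
    if missing:
        raise ValueError(f"missing tracks for marks: {missing}")
    profiles = []
    for gene in genes:
        start, end = gene.tss - window_bp, gene.tss + window_bp
        clipped_start = max(0, start)
        clipped_end = end
        if chrom_lengths is not None and gene.chrom in chrom_lengths:
            clipped_end = min(end, chrom_lengths[gene.chrom])
        if (clipped_start, clipped_end) != (start, end):
            warnings.warn(
                f"gene {gene.gene_id}: TSS window clipped to chromosome bounds"
            )
        values = {
            mark: signal_value(
                tracks[mark].values(gene.chrom, clipped_start, clipped_end)
            )
            for mark in MARKS
        }
        profiles.append(HistoneProfile(gene.gene_id, values))
    return profiles


@dataclass(frozen=True)
class SignatureCall:
    gene_id: str
    levels: tuple[str, str, str]  # (H3K4me3, H3K27ac, H3K27me3)
    signature: str


@dataclass(frozen=True)
class MarkThresholds:
    """Absolute per-mark low/high split points.

    A signal strictly below the threshold is ``low``; at or above is
    ``high``.
    """

    thresholds: dict[str, float]

    def level(self, mark: str, value: float) -> str:
        return HIGH if value >= self.thresholds[mark] else LOW


def quantile_thresholds(
    profiles: list[HistoneProfile],
    low_q: float = 0.25,
    high_q: float = 0.75,
) -> MarkThresholds:
    """Cohort-derived thresholds: the midpoint of the low and high
    quantiles per mark, so values at or below the low quantile are
    called low and at or above the high quantile high, with the
    in-between mass split at the midpoint (nearest side; exact
    midpoint falls to low by the strict-below rule)."""
    thresholds = {}
    for mark in MARKS:
        values = np.array([p[mark] for p in profiles], dtype=float)
        lo, hi = np.quantile(values, [low_q, high_q])
        midpoint = (lo + hi) / 2.0
        thresholds[mark] = np.nextafter(midpoint, np.inf)
    return MarkThresholds(thresholds)


def classify_signature(
    profile: HistoneProfile, thresholds: MarkThresholds
) -> SignatureCall:
    """Call a gene's chromatin signature from its three mark levels."""
    levels = tuple(thresholds.level(mark, profile[mark]) for mark in MARKS)
    return SignatureCall(profile.gene_id, levels, SIGNATURE_MAP[levels])


def classify_cohort(
    profiles: list[HistoneProfile],
    thresholds: MarkThresholds | None = None,
) -> list[SignatureCall]:
    if thresholds is None:
        thresholds = quantile_thresholds(profiles)
    return [classify_signature(p, thresholds) for p in profiles]
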