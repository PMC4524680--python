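"""SRF ChIP peak filtering and annotation against CArG boxes, CpG
islands, and gene models.

A peak passes the signal filter when its peak height is strictly
greater than the threshold (default 1.5 signal value).  Each retained
peak is then scored for: the number of CArG boxes fully contained in
the peak; whether any of those boxes is cross-species conserved;
whether the peak overlaps a CpG island; and its location relative to
the nearest gene (promoter, exon 1, intron 1, other exon, other
intron, or intergenic), using the peak midpoint.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from ._types import GeneModel, GenomicInterval
from .scan import CArGBox

PROMOTER = "promoter"
EXON1 = "exon1"
INTRON1 = "intron1"
EXON_OTHER = "exon_other"
INTRON_OTHER = "intron_other"
INTERGENIC = "intergenic"

# genic classes in decreasing precedence
LOCATION_PRECEDENCE = (PROMOTER, EXON1, INTRON1, EXON_OTHER, INTRON_OTHER)
LOCATION_CLASSES = LOCATION_PRECEDENCE + (INTERGENIC,)

DEFAULT_MIN_SIGNAL = 1.5
DEFAULT_PROMOTER_BP = 5000


@dataclass(frozen=True)
class SRFPeak:
    """A ChIP interval with its enrichment signal value (peak height)."""

    chrom: str
    start: int
    end: int
    name: str = ""
    signal_value: float = 0.0

    def __post_init__(self):
        if self.signal_value < 0:
            raise ValueError(f"peak {self.name!r}: negative signal value")

    def interval(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.start, self.end, self.name, self.signal_value
        )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def peaks_from_bed(intervals: list[GenomicInterval]) -> list[SRFPeak]:
    """BED5 rows to peaks; the score column carries the signal value."""
    return [
        SRFPeak(iv.chrom, iv.start, iv.end, iv.name, iv.score) for iv in intervals
    ]


def read_narrowpeak(path) -> list[SRFPeak]:
    """Read ENCODE narrowPeak: signalValue is column 7."""
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: expected >=7 narrowPeak columns")
            peaks.append(
                SRFPeak(
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[3],
                    float(fields[6]),
                )
            )
    return peaks


def filter_peaks(peaks: list[SRFPeak], min_signal: float = DEFAULT_MIN_SIGNAL) -> list[SRFPeak]:
    """Retain peaks with signal strictly above ``min_signal``; order kept."""
    return [p for p in peaks if p.signal_value > min_signal]


@dataclass(frozen=True)
class PeakAnnotation:
    peak: SRFPeak
    carg_count: int
    has_conserved_carg: bool
    in_cpg_island: bool
    gene_id: str | None
    location_class: str

    def __post_init__(self):
        if (self.location_class == INTERGENIC) != (self.gene_id is None):
            raise ValueError("intergenic iff no associated gene")


def _transcript_class(midpoint: int, tx, promoter_bp: int) -> str | None:
    """Location of a point relative to one transcript, or None."""
    # promoter window immediately upstream of the TSS, strand-adjusted
    if tx.strand == "+":
        if tx.tss - promoter_bp <= midpoint < tx.tss:
            promoter_hit = True
        else:
            promoter_hit = False
    else:
        promoter_hit = tx.tss <= midpoint < tx.tss + promoter_bp
    if promoter_hit:
        return PROMOTER
    exons = tx.exons_5to3()
    for rank, (start, end) in enumerate(exons, start=1):
        if start <= midpoint < end:
            return EXON1 if rank == 1 else EXON_OTHER
    for rank, (start, end) in enumerate(tx.introns_5to3(), start=1):
        if start <= midpoint < end:
            return INTRON1 if rank == 1 else INTRON_OTHER
    return None


def classify_location(
    peak: SRFPeak, genes: list[GeneModel], promoter_bp: int = DEFAULT_PROMOTER_BP
) -> tuple[str | None, str]:
    """Assign a peak to a gene and a location class via its midpoint.

    Each gene's class is the highest-precedence class over its
    transcripts (promoter > exon1 > intron1 > exon_other >
    intron_other).  Among genes achieving the best class, the one
    with the smallest |midpoint - TSS| wins, ties broken by gene id.
    No gene context at all gives (None, intergenic).
    """
    if promoter_bp <= 0:
        raise ValueError("promoter_bp must be positive")
    midpoint = peak.midpoint
    rank = {cls: i for i, cls in enumerate(LOCATION_PRECEDENCE)}
    candidates: list[tuple[int, int, str, str]] = []
    for gene in genes:
        if gene.chrom != peak.chrom:
            continue
        classes = [
            c
            for tx in gene.transcripts
            if (c := _transcript_class(midpoint, tx, promoter_bp)) is not None
        ]
        if not classes:
            continue
        best = min(classes, key=rank.__getitem__)
        candidates.append(
            (rank[best], abs(midpoint - gene.tss), gene.gene_id, best)
        )
    if not candidates:
        return None, INTERGENIC
    _, _, gene_id, cls = min(candidates)
    return gene_id, cls


def annotate_peak(
    peak: SRFPeak,
    boxes: list[CArGBox],
    conserved: set[CArGBox],
    islands: list[GenomicInterval],
    genes: list[GeneModel],
    promoter_bp: int = DEFAULT_PROMOTER_BP,
    carg_rule: str = "contained",
) -> PeakAnnotation:
    """Annotate one peak.

    CArG association requires the 10-bp box to be fully contained in
    the peak interval (``carg_rule="contained"``, the default) or to
    merely overlap it (``carg_rule="overlap"``).  CpG association is
    any overlap >= 1 bp.
    """
    if carg_rule not in ("contained", "overlap"):
        raise ValueError(f"unknown carg_rule {carg_rule!r}")
    piv = peak.interval()
    if carg_rule == "contained":
        in_peak = [b for b in boxes if piv.contains(b.interval())]
    else:
        in_peak = [b for b in boxes if piv.overlap(b.interval()) > 0]
    has_conserved = any(b in conserved for b in in_peak)
    in_cpg = any(piv.overlap(isl) > 0 for isl in islands)
    gene_id, location = classify_location(peak, genes, promoter_bp)
    return PeakAnnotation(peak, len(in_peak), has_conserved, in_cpg, gene_id, location)


def annotate_peaks(
    peaks: list[SRFPeak],
    boxes: list[CArGBox],
    conserved: set[CArGBox],
    islands: list[GenomicInterval],
    genes: list[GeneModel],
    promoter_bp: int = DEFAULT_PROMOTER_BP,
    carg_rule: str = "contained",
) -> list[PeakAnnotation]:
    by_chrom: dict[str, list[CArGBox]] = {}
    for b in boxes:
        by_chrom.setdefault(b.chrom, []).append(b)
    islands_by_chrom: dict[str, list[GenomicInterval]] = {}
    for isl in islands:
        islands_by_chrom.setdefault(isl.chrom, []).append(isl)
    return [
        annotate_peak(
            p,
            by_chrom.get(p.chrom, []),
            conserved,
            islands_by_chrom.get(p.chrom, []),
            genes,
            promoter_bp,
            carg_rule,
        )
        for p in peaks
    ]


@dataclass
class AssociationSummary:
    """Counts behind the association proportions over a peak set."""

    n_peaks: int
    n_with_carg: int
    n_with_conserved_carg: int
    n_in_cpg: int
    n_gene_associated: int
    genes_associated: set[str] = field(default_factory=set)
    location_histogram: dict[str, int] = field(default_factory=dict)

    def proportions(self) -> dict[str, float]:
        if self.n_peaks == 0:
            return {k: 0.0 for k in ("carg", "conserved_carg", "cpg", "gene")}
        return {
            "carg": self.n_with_carg / self.n_peaks,
            "conserved_carg": self.n_with_conserved_carg / self.n_peaks,
            "cpg": self.n_in_cpg / self.n_peaks,
            "gene": self.n_gene_associated / self.n_peaks,
        }

    def to_dict(self) -> dict:
        return {
            "n_peaks": self.n_peaks,
            "n_with_carg": self.n_with_carg,
            "n_with_conserved_carg": self.n_with_conserved_carg,
            "n_in_cpg": self.n_in_cpg,
            "n_gene_associated": self.n_gene_associated,
            "n_distinct_genes": len(self.genes_associated),
            "genes_associated": sorted(self.genes_associated),
            "location_histogram": dict(self.location_histogram),
            "proportions": self.proportions(),
        }


def summarize(annotations: list[PeakAnnotation]) -> AssociationSummary:
    hist = Counter(a.location_class for a in annotations)
    genes = {a.gene_id for a in annotations if a.gene_id is not None}
    return AssociationSummary(
        n_peaks=len(annotations),
        n_with_carg=sum(a.carg_count > 0 for a in annotations),
        n_with_conserved_carg=sum(a.has_conserved_carg for a in annotations),
        n_in_cpg=sum(a.in_cpg_island for a in annotations),
        n_gene_associated=sum(a.gene_id is not None for a in annotations),
        genes_associated=genes,
        location_histogram={cls: hist.get(cls, 0) for cls in LOCATION_CLASSES},
    )


DOWN_REGULATED = "down_regulated"
NOT_DETECTED = "not_detected"
UNCHANGED = "unchanged"
PROTEIN_STATUSES = (DOWN_REGULATED, NOT_DETECTED, UNCHANGED)


def _normalize_symbol(symbol: str) -> str:
    # case-insensitive match with isoform suffixes (Gene-201, Gene.1) stripped
    sym = symbol.strip().lower()
    for sep in (".", "-"):
        head, _, tail = sym.rpartition(sep)
        if head and tail.isdigit():
            sym = head
    return sym


def intersect_srf_genes_with_proteins(
    srf_genes: set[str], protein_table: dict[str, str]
) -> dict[str, int]:
    """Partition SRF-associated genes by proteomics status.

    ``protein_table`` maps gene symbol to one of down_regulated /
    not_detected / unchanged; genes absent from the table count as
    not_detected.  The three counts always sum to ``len(srf_genes)``.
    """
    table = {}
    for symbol, status in protein_table.items():
        if status not in PROTEIN_STATUSES:
            raise ValueError(f"unknown protein status {status!r} for {symbol!r}")
        table[_normalize_symbol(symbol)] = status
    counts = {status: 0 for status in PROTEIN_STATUSES}
    for gene in srf_genes:
        counts[table.get(_normalize_symbol(gene), NOT_DETECTED)] += 1
    return counts
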