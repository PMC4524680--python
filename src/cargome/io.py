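"""Readers and writers for the external formats the pipeline touches.

Formats: multi-record FASTA, BED3/5/6 and BED12, minimal GTF (exon
features only), UCSC custom-track headers, and the tab-separated
isoform/gene expression tables (tracking_id, gene_id, locus, length,
fpkm, fpkm_conf_lo, fpkm_conf_hi).

Coordinate conventions: everything is 0-based half-open internally.
GTF is the only 1-based inclusive source; its starts are decremented
by one on read.
"""

from __future__ import annotations

import io as _stdio
import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._types import VALID_BASES, GeneModel, GenomeSequence, GenomicInterval, Transcript

EXPRESSION_COLUMNS = [
    "tracking_id",
    "gene_id",
    "locus",
    "length",
    "fpkm",
    "fpkm_conf_lo",
    "fpkm_conf_hi",
]


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# FASTA

def _find_bad_fasta_line(path) -> tuple[int, str] | None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            if set(line) - VALID_BASES:
                return lineno, line
    return None


def read_fasta(path, uppercase: bool = True) -> GenomeSequence:
    """Read a multi-record FASTA into a :class:`GenomeSequence`.

    Soft-masked (lowercase) bases are uppercased by default; pass
    ``uppercase=False`` to preserve masking for mask-aware scanning.
    """
    chroms: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chroms:
            raise ParseError(f"{path}: duplicate chromosome name {record.id!r}")
        seq = str(record.seq)
        if set(seq) - VALID_BASES:
            located = _find_bad_fasta_line(path)
            where = f"line {located[0]}" if located else f"record {record.id!r}"
            raise ParseError(
                f"{path}: invalid nucleotide characters at {where} "
                "(alphabet is A,C,G,T,N)"
            )
        chroms[record.id] = seq.upper() if uppercase else seq
    if not chroms:
        raise ParseError(f"{path}: no FASTA records found")
    return GenomeSequence(chroms)


def write_fasta(genome: GenomeSequence, path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED

def _is_header_line(line: str) -> bool:
    return line.startswith(("track", "browser", "#"))


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3+ records; track/browser/comment lines are skipped."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or _is_header_line(line):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ParseError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 else ""
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            intervals.append(GenomicInterval(chrom, start, end, name, score))
    return intervals


def _format_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(score)


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                f"{_format_score(iv.score)}\n"
            )


def write_custom_track(
    intervals: list[GenomicInterval], track_name: str, path
) -> None:
    """Write a UCSC custom track: one ``track name=...`` header, then BED5."""
    with open(path, "w") as fh:
        fh.write(f'track name="{track_name}"\n')
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                f"{_format_score(iv.score)}\n"
            )


# ---------------------------------------------------------------------------
# Gene models (minimal GTF or BED12)

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _read_gtf_models(path) -> list[GeneModel]:
    # exons keyed by (gene_id, transcript_id); other feature types ignored
    exons: dict[tuple[str, str], dict] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: fewer than 9 GTF columns")
            chrom, _, feature, start, end, _, strand, _, attrs = fields[:9]
            if feature != "exon":
                continue
            attr = dict(_GTF_ATTR.findall(attrs))
            try:
                gene_id = attr["gene_id"]
                transcript_id = attr["transcript_id"]
            except KeyError as exc:
                raise ParseError(
                    f"{path}:{lineno}: exon missing {exc.args[0]} attribute"
                ) from exc
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            key = (gene_id, transcript_id)
            entry = exons.setdefault(
                key, {"chrom": chrom, "strand": strand, "exons": []}
            )
            # GTF is 1-based inclusive
            entry["exons"].append((int(start) - 1, int(end)))

    genes: dict[str, GeneModel] = {}
    for (gene_id, transcript_id), entry in exons.items():
        tx = Transcript(
            transcript_id, entry["chrom"], entry["strand"], entry["exons"]
        )
        if gene_id in genes:
            genes[gene_id].transcripts.append(tx)
        else:
            genes[gene_id] = GeneModel(gene_id, entry["chrom"], [tx])
    return list(genes.values())


def _read_bed12_models(path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or _is_header_line(line):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"{path}:{lineno}: fewer than 12 BED12 columns")
            chrom, start = fields[0], int(fields[1])
            name, strand = fields[3], fields[5]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            block_count = int(fields[9])
            if block_count == 0:
                raise ParseError(f"{path}:{lineno}: transcript with zero exons")
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            exon_list = [
                (start + off, start + off + size)
                for off, size in zip(starts, sizes)
            ]
            # BED12 name doubles as transcript id; gene id before the
            # first '.' if present, else the name itself
            gene_id = name.split(".")[0] if "." in name else name
            tx = Transcript(name, chrom, strand, exon_list)
            if gene_id in genes:
                genes[gene_id].transcripts.append(tx)
            else:
                genes[gene_id] = GeneModel(gene_id, chrom, [tx])
    return list(genes.values())


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from a minimal GTF or a BED12 file.

    The dialect is chosen by extension (.gtf/.gff → GTF, otherwise
    BED12).  Only ``exon`` features with gene_id/transcript_id
    attributes are consulted in GTF.
    """
    suffix = Path(path).suffix.lower()
    if suffix in (".gtf", ".gff"):
        return _read_gtf_models(path)
    return _read_bed12_models(path)


def write_gtf(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                for start, end in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{tx.transcript_id}";'
                    )
                    fh.write(
                        f"{gene.chrom}\tcargome\texon\t{start + 1}\t{end}\t.\t"
                        f"{tx.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# Expression tables (S2/S3-shaped isoform tables; S4/S5-shaped gene tables)

def read_expression_table(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a tab-separated isoform expression table.

    Columns: tracking_id, gene_id, locus, length, fpkm, fpkm_conf_lo,
    fpkm_conf_hi.  A ``sample_id`` column is attached when given.
    Confidence bounds must bracket the FPKM estimate.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    bad = df[
        (df["fpkm_conf_lo"] > df["fpkm"]) | (df["fpkm"] > df["fpkm_conf_hi"])
    ]
    if len(bad):
        raise ParseError(
            f"{path}: {len(bad)} rows violate conf_lo <= fpkm <= conf_hi "
            f"(first tracking_id {bad.iloc[0]['tracking_id']!r})"
        )
    if sample_id is not None:
        df = df.assign(sample_id=sample_id)
    return df


def write_expression_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=EXPRESSION_COLUMNS)


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(path) -> dict[str, list[tuple[int, int, float]]]:
    """Read a bedGraph file into per-chromosome sorted block lists."""
    blocks: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or _is_header_line(line):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: fewer than 4 bedGraph columns")
            chrom, start, end, value = (
                fields[0],
                int(fields[1]),
                int(fields[2]),
                float(fields[3]),
            )
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start {start} >= end {end}")
            blocks.setdefault(chrom, []).append((start, end, value))
    for chrom in blocks:
        blocks[chrom].sort()
    return blocks


def write_bedgraph(
    blocks: dict[str, list[tuple[int, int, float]]], path, track_name: str | None = None
) -> None:
    with open(path, "w") as fh:
        if track_name is not None:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        for chrom in sorted(blocks):
            for start, end, value in sorted(blocks[chrom]):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
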