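"""Seeded generators for every pipeline input, with ground-truth
manifests.

Each generator returns both the data objects and a
:class:`TruthManifest` that fully determines the expected output of
every downstream stage, so scan/conservation/annotation/expression/
signature results can be checked exactly against the design.  All
randomness flows from one ``numpy`` Generator seeded explicitly; the
same (parameters, seed) pair reproduces identical data.

Background sequence is "scrubbed": any 10-bp window that happens to
match the CArG permutation table is redrawn until the only matches
in the genome are the planted ones, which is what makes exact-
recovery tests possible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._types import GeneModel, GenomeSequence, GenomicInterval, Transcript
from . import peaks as pk
from .conserve import AlignmentBlock, CoordinateMap
from .io import EXPRESSION_COLUMNS
from .histone import (
    AMBIGUOUS,
    HIGH,
    LOW,
    MARKS,
    RESTRICTED_ACTIVE,
    SIGNATURE_MAP,
    SILENCED,
    UBIQUITOUS_ACTIVE,
    MarkThresholds,
)
from .scan import (
    BOX_LENGTH,
    CONSENSUS,
    SINGLE_MISMATCH,
    CArGBox,
    PermutationTable,
    consensus_sequences,
    generate_permutations,
    reverse_complement,
)

_BASES = np.array(list("ACGT"))


@dataclass
class TruthManifest:
    """Ground truth for one generated dataset."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    records: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "seed": self.seed,
                "params": self.params,
                "records": self.records,
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def read(cls, path) -> "TruthManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["kind"], d["seed"], d["params"], d["records"])


# ---------------------------------------------------------------------------
# Genome with planted CArG boxes


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _match_positions(seq_arr: np.ndarray, table: PermutationTable) -> list[int]:
    s = "".join(seq_arr)
    return [
        p
        for p in range(len(s) - BOX_LENGTH + 1)
        if s[p : p + BOX_LENGTH] in table.sequences
    ]


def _scrub(
    seq_arr: np.ndarray,
    table: PermutationTable,
    rng: np.random.Generator,
    gc: float,
    protected: np.ndarray,
    allowed_starts: set[int],
    max_rounds: int = 200,
) -> np.ndarray:
    """Redraw unprotected bases inside any table-matching window whose
    start is not in ``allowed_starts``, until none remain."""
    for _ in range(max_rounds):
        extra = [p for p in _match_positions(seq_arr, table) if p not in allowed_starts]
        if not extra:
            return seq_arr
        for p in extra:
            idx = np.arange(p, p + BOX_LENGTH)
            idx = idx[~protected[idx]]
            if idx.size == 0:
                raise RuntimeError(
                    f"cannot scrub accidental match at {p}: window fully "
                    "inside planted sequence"
                )
            seq_arr[idx] = _random_bases(rng, idx.size, gc)
    raise RuntimeError("background scrubbing did not converge")


def _draw_box_sequence(
    rng: np.random.Generator, single_mismatch: bool
) -> tuple[str, str, int | None]:
    """A planted 10-mer: consensus, or exactly one mismatch from it."""
    cons = consensus_sequences()[rng.integers(64)]
    if not single_mismatch:
        return cons, CONSENSUS, None
    slots = ("C", "C", "AT", "AT", "AT", "AT", "AT", "AT", "G", "G")
    pos = int(rng.integers(BOX_LENGTH))
    # replacement base outside the slot keeps Hamming distance exactly 1
    choices = [b for b in "ACGT" if b not in slots[pos]]
    base = choices[rng.integers(len(choices))]
    seq = cons[:pos] + base + cons[pos + 1:]
    return seq, SINGLE_MISMATCH, pos + 1


def _choose_positions(
    rng: np.random.Generator, length: int, n: int, min_gap: int = 20
) -> list[int]:
    chosen: list[int] = []
    for _ in range(200 * max(n, 1)):
        if len(chosen) == n:
            break
        cand = int(rng.integers(BOX_LENGTH, length - 2 * BOX_LENGTH))
        if all(abs(cand - c) >= min_gap for c in chosen):
            chosen.append(cand)
    if len(chosen) < n:
        raise RuntimeError(
            f"could not place {n} non-overlapping boxes in {length} bp"
        )
    return sorted(chosen)


def make_genome(
    length_bp: int,
    gc_fraction: float = 0.42,
    n_planted: int = 0,
    mismatch_fraction: float = 0.5,
    seed: int = 0,
    chrom: str = "chr1",
    positions: list[int] | None = None,
    box_specs: list[tuple[str, str, int | None]] | None = None,
    table: PermutationTable | None = None,
) -> tuple[GenomeSequence, TruthManifest]:
    """A single-chromosome genome with planted CArG boxes.

    The background is i.i.d. with the requested GC fraction, then
    scrubbed so that no window outside the planted set matches the
    permutation table.  ``mismatch_fraction`` of the planted boxes
    carry a single mismatch; the rest are consensus.  Explicit
    ``positions`` (and optionally ``box_specs``) override random
    placement, which other generators use to control peak/box
    geometry.
    """
    if not 0 < gc_fraction < 1:
        raise ValueError("gc_fraction must be in (0, 1)")
    if positions is None and length_bp < 50 * n_planted:
        raise ValueError(
            f"{length_bp} bp is too short to plant {n_planted} boxes"
        )
    rng = np.random.default_rng(seed)
    if table is None:
        table = generate_permutations(1)

    if positions is None:
        positions = _choose_positions(rng, length_bp, n_planted)
    else:
        positions = sorted(positions)
        for a, b in zip(positions, positions[1:]):
            if b - a < BOX_LENGTH:
                raise ValueError("planted positions overlap")
    if box_specs is None:
        n_mm = int(round(len(positions) * mismatch_fraction))
        mm_flags = np.zeros(len(positions), dtype=bool)
        mm_flags[rng.choice(len(positions), size=n_mm, replace=False)] = True
        box_specs = [_draw_box_sequence(rng, bool(f)) for f in mm_flags]
    if len(box_specs) != len(positions):
        raise ValueError("box_specs and positions length mismatch")

    seq_arr = _random_bases(rng, length_bp, gc_fraction)
    protected = np.zeros(length_bp, dtype=bool)
    for pos, (boxseq, _, _) in zip(positions, box_specs):
        seq_arr[pos : pos + BOX_LENGTH] = list(boxseq)
        protected[pos : pos + BOX_LENGTH] = True
    seq_arr = _scrub(
        seq_arr, table, rng, gc_fraction, protected, set(positions)
    )

    genome = GenomeSequence({chrom: "".join(seq_arr)})
    boxes = [
        {
            "chrom": chrom,
            "start": int(pos),
            "sequence": boxseq,
            "match_class": cls,
            "mismatch_position": mmpos,
        }
        for pos, (boxseq, cls, mmpos) in zip(positions, box_specs)
    ]
    manifest = TruthManifest(
        kind="genome",
        seed=int(seed),
        params={
            "length_bp": length_bp,
            "gc_fraction": gc_fraction,
            "n_planted": len(positions),
            "mismatch_fraction": mismatch_fraction,
            "chrom": chrom,
        },
        records={"boxes": boxes},
    )
    return genome, manifest


def manifest_boxes(manifest: TruthManifest) -> list[CArGBox]:
    return [
        CArGBox(
            b["chrom"],
            b["start"],
            b["sequence"],
            b["match_class"],
            b["mismatch_position"],
        )
        for b in manifest.records["boxes"]
    ]


# ---------------------------------------------------------------------------
# Regulatory layout: genes, SRF peaks, CpG islands, cross-species map

DEFAULT_LOCATION_FRACTIONS = {
    pk.PROMOTER: 0.40,
    pk.EXON1: 0.15,
    pk.INTRON1: 0.15,
    pk.EXON_OTHER: 0.10,
    pk.INTRON_OTHER: 0.10,
    pk.INTERGENIC: 0.10,
}

_TERRITORY_BP = 12000
_PEAK_HALF = 150


@dataclass
class RegulatoryLayout:
    """One synthetic Fig-4-style dataset: everything peak annotation needs."""

    genome: GenomeSequence
    target_genome: GenomeSequence
    boxes: list[CArGBox]
    genes: list[GeneModel]
    peaks: list[pk.SRFPeak]
    islands: list[GenomicInterval]
    coordinate_map: CoordinateMap
    manifest: TruthManifest


def _apportion(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n items to the fractions."""
    total = sum(fractions.values())
    raw = {k: n * v / total for k, v in fractions.items()}
    counts = {k: int(v) for k, v in raw.items()}
    remainder = n - sum(counts.values())
    order = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:remainder]:
        counts[k] += 1
    return counts


def make_regulatory_layout(
    n_peaks: int = 200,
    seed: int = 0,
    carg_fraction: float = 0.6,
    conserved_fraction: float = 0.5,
    cpg_fraction: float = 0.4,
    above_signal_fraction: float = 0.7,
    location_fractions: dict[str, float] | None = None,
    mismatch_fraction: float = 0.5,
    gc_fraction: float = 0.42,
) -> RegulatoryLayout:
    """Genes, SRF peaks, CpG islands and a two-genome coordinate map
    with fully designed peak/CArG/CpG/gene relationships.

    The chromosome is divided into one territory per peak; the peak,
    its optional planted CArG box, its optional CpG island and its
    optional gene all live inside that territory, so every designed
    association is unambiguous.  ``conserved_fraction`` of the
    CArG-containing peaks have their box copied into a second genome
    through an alignment-block map (alternating target strands).
    """
    if location_fractions is None:
        location_fractions = DEFAULT_LOCATION_FRACTIONS
    unknown = set(location_fractions) - set(pk.LOCATION_CLASSES)
    if unknown:
        raise ValueError(f"unknown location classes {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    T = _TERRITORY_BP
    length = n_peaks * T

    loc_counts = _apportion(n_peaks, location_fractions)
    loc_assign: list[str] = []
    for cls in pk.LOCATION_CLASSES:
        loc_assign.extend([cls] * loc_counts.get(cls, 0))
    rng.shuffle(loc_assign)

    n_carg = int(round(n_peaks * carg_fraction))
    carg_flags = np.zeros(n_peaks, dtype=bool)
    carg_flags[rng.choice(n_peaks, size=n_carg, replace=False)] = True
    carg_idx = np.flatnonzero(carg_flags)
    n_cons = int(round(n_carg * conserved_fraction))
    conserved_flags = np.zeros(n_peaks, dtype=bool)
    if n_cons:
        conserved_flags[rng.choice(carg_idx, size=n_cons, replace=False)] = True
    cpg_flags = np.zeros(n_peaks, dtype=bool)
    n_cpg = int(round(n_peaks * cpg_fraction))
    cpg_flags[rng.choice(n_peaks, size=n_cpg, replace=False)] = True
    above_flags = np.zeros(n_peaks, dtype=bool)
    n_above = int(round(n_peaks * above_signal_fraction))
    above_flags[rng.choice(n_peaks, size=n_above, replace=False)] = True

    genes: list[GeneModel] = []
    peaks: list[pk.SRFPeak] = []
    islands: list[GenomicInterval] = []
    positions: list[int] = []
    peak_truth: list[dict] = []

    for i in range(n_peaks):
        s = i * T
        strand = "+" if i % 2 == 0 else "-"
        cls = loc_assign[i]
        gene_id = None
        if cls == pk.INTERGENIC:
            mid = s + T // 2
        else:
            gene_id = f"G{i:05d}"
            if strand == "+":
                tss = s + 6000
                exons = [
                    (tss, tss + 300),
                    (tss + 600, tss + 900),
                    (tss + 1200, tss + 1500),
                ]
                offsets = {
                    pk.PROMOTER: -150,
                    pk.EXON1: 150,
                    pk.INTRON1: 450,
                    pk.EXON_OTHER: 750,
                    pk.INTRON_OTHER: 1050,
                }
                mid = tss + offsets[cls]
            else:
                tss = s + 6000
                exons = [
                    (tss - 1500, tss - 1200),
                    (tss - 900, tss - 600),
                    (tss - 300, tss),
                ]
                offsets = {
                    pk.PROMOTER: 150,
                    pk.EXON1: -150,
                    pk.INTRON1: -450,
                    pk.EXON_OTHER: -750,
                    pk.INTRON_OTHER: -1050,
                }
                mid = tss + offsets[cls]
            genes.append(
                GeneModel(
                    gene_id,
                    "chr1",
                    [Transcript(f"{gene_id}.t1", "chr1", strand, exons)],
                )
            )

        start, end = mid - _PEAK_HALF, mid + _PEAK_HALF
        signal = (
            float(rng.uniform(1.6, 10.0))
            if above_flags[i]
            else float(rng.uniform(0.1, 1.4))
        )
        peaks.append(pk.SRFPeak("chr1", start, end, f"peak{i:05d}", signal))
        if carg_flags[i]:
            positions.append(mid - BOX_LENGTH // 2)
        if cpg_flags[i]:
            islands.append(
                GenomicInterval("chr1", start - 100, start + 100, f"cpg{i:05d}")
            )
        peak_truth.append(
            {
                "name": f"peak{i:05d}",
                "start": int(start),
                "end": int(end),
                "signal_above": bool(above_flags[i]),
                "contains_carg": bool(carg_flags[i]),
                "conserved": bool(conserved_flags[i]),
                "in_cpg": bool(cpg_flags[i]),
                "gene_id": gene_id,
                "location_class": cls,
            }
        )

    genome, genome_manifest = make_genome(
        length,
        gc_fraction=gc_fraction,
        seed=int(rng.integers(2**31)),
        positions=positions,
        box_specs=[
            _draw_box_sequence(rng, bool(rng.random() < mismatch_fraction))
            for _ in positions
        ],
    )
    boxes = manifest_boxes(genome_manifest)
    box_by_start = {b.start: b for b in boxes}

    # second genome: copy a 200-bp block around each conserved box,
    # separated by scrubbed random spacers; alternate target strands
    table = generate_permutations(1)
    spacer = 500
    blocks: list[AlignmentBlock] = []
    tgt_parts: list[str] = []
    tgt_pos = 0
    conserved_boxes: list[CArGBox] = []
    for i in np.flatnonzero(conserved_flags):
        mid = peak_truth[i]["start"] + _PEAK_HALF
        src_start, src_end = mid - 100, mid + 100
        tgt_strand = "+" if len(blocks) % 4 != 3 else "-"
        src_seq = genome["chr1"][src_start:src_end]
        sp = "".join(_random_bases(rng, spacer, gc_fraction))
        tgt_parts.append(sp)
        tgt_pos += spacer
        blocks.append(
            AlignmentBlock(
                "chr1", src_start, src_end, "chr1", tgt_pos, tgt_pos + 200, tgt_strand
            )
        )
        tgt_parts.append(
            src_seq if tgt_strand == "+" else reverse_complement(src_seq)
        )
        tgt_pos += 200
        conserved_boxes.append(box_by_start[mid - BOX_LENGTH // 2])
    tgt_parts.append("".join(_random_bases(rng, spacer, gc_fraction)))
    tgt_pos += spacer

    tgt_arr = np.array(list("".join(tgt_parts)))
    tgt_protected = np.zeros(len(tgt_arr), dtype=bool)
    tgt_allowed: set[int] = set()
    for block, box in zip(blocks, conserved_boxes):
        if block.tgt_strand == "+":
            bstart = block.tgt_start + (box.start - block.src_start)
        else:
            bstart = block.tgt_end - (box.start - block.src_start) - BOX_LENGTH
        tgt_allowed.add(bstart)
        tgt_protected[block.tgt_start : block.tgt_end] = True
    tgt_arr = _scrub(
        tgt_arr, table, rng, gc_fraction, tgt_protected, tgt_allowed
    )
    target_genome = GenomeSequence({"chr1": "".join(tgt_arr)})

    manifest = TruthManifest(
        kind="regulatory_layout",
        seed=int(seed),
        params={
            "n_peaks": n_peaks,
            "carg_fraction": carg_fraction,
            "conserved_fraction": conserved_fraction,
            "cpg_fraction": cpg_fraction,
            "above_signal_fraction": above_signal_fraction,
            "location_fractions": dict(location_fractions),
            "territory_bp": T,
            "peak_width": 2 * _PEAK_HALF,
        },
        records={
            "peaks": peak_truth,
            "boxes": genome_manifest.records["boxes"],
            "conserved_box_starts": sorted(b.start for b in conserved_boxes),
            "n_above_signal": int(n_above),
            "n_carg": int(n_carg),
            "n_conserved": int(n_cons),
            "n_cpg": int(n_cpg),
            "location_counts": {
                cls: int(loc_counts.get(cls, 0)) for cls in pk.LOCATION_CLASSES
            },
        },
    )
    return RegulatoryLayout(
        genome,
        target_genome,
        boxes,
        genes,
        peaks,
        islands,
        CoordinateMap(blocks),
        manifest,
    )


# ---------------------------------------------------------------------------
# Expression tables

EXPRESSION_SAMPLES = ("SMC_J", "SMC_C", "ICC", "PDGFRA")

_UNRELIABLE_CAP = 0.02  # designed max FPKM of the unreliable population
_RELIABLE_FLOOR = 0.1  # designed min positive FPKM of reliable transcripts


def make_expression(
    n_genes: int = 2000,
    isoforms_per_gene_mean: float = 3.0,
    n_specific: int = 20,
    noise_sd: float = 0.25,
    seed: int = 0,
    n_unreliable: int = 500,
    specific_fpkm: float = 200.0,
    pseudocount_background: float = 0.02,
) -> tuple[dict[str, pd.DataFrame], TruthManifest]:
    """Isoform FPKM tables for the four cell populations.

    Designed structure:

    * ``n_specific`` smooth-muscle-specific genes: FPKM around
      ``specific_fpkm`` in the two SMC samples, near zero (a small
      uniform background below ``pseudocount_background``) in ICC and
      PDGFRa+ cells, so they occupy the top specificity ranks.
    * The remaining genes are ubiquitous: a shared log-normal base
      level with per-sample multiplicative noise exp(N(0, noise_sd)).
    * ``n_unreliable`` spurious low-abundance transcripts per sample
      (their own gene ids) with FPKM below 0.02 and a zero lower
      confidence bound; reliable transcripts are floored at 0.1 FPKM,
      so a reliability cutoff with zero false positive and false
      negative rates exists in between by design.

    Gene FPKM is split over 1+Poisson isoforms by a Dirichlet draw,
    preserving the designed gene totals.
    """
    if n_specific >= n_genes:
        raise ValueError("n_specific must be smaller than n_genes")
    rng = np.random.default_rng(seed)
    # gene ids share the regulatory layout's G%05d namespace so a
    # simulated ChIP study and expression study describe the same genes
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    specific = set(gene_ids[:n_specific])

    base = np.exp(rng.normal(np.log(10.0), 1.5, size=n_genes))
    designed: dict[str, dict[str, float]] = {}
    for gi, gid in enumerate(gene_ids):
        if gid in specific:
            smc = specific_fpkm * float(np.exp(rng.normal(0, 0.3)))
            bg_i = float(rng.uniform(0, pseudocount_background))
            bg_p = float(rng.uniform(0, pseudocount_background))
            designed[gid] = {
                "SMC_J": smc,
                "SMC_C": smc * float(np.exp(rng.normal(0, 0.1))),
                "ICC": bg_i,
                "PDGFRA": bg_p,
            }
        else:
            designed[gid] = {s: float(base[gi]) for s in EXPRESSION_SAMPLES}

    n_iso = 1 + rng.poisson(max(isoforms_per_gene_mean - 1.0, 0.0), size=n_genes)
    shares = [rng.dirichlet(np.ones(k) * 5.0) for k in n_iso]

    noise = {
        s: np.exp(rng.normal(0.0, noise_sd, size=n_genes)) if noise_sd > 0
        else np.ones(n_genes)
        for s in EXPRESSION_SAMPLES
    }

    tables: dict[str, pd.DataFrame] = {}
    tcons_counter = 0
    tcons_ids: dict[tuple[int, int], str] = {}
    for gi in range(n_genes):
        for k in range(int(n_iso[gi])):
            tcons_counter += 1
            tcons_ids[(gi, k)] = f"TCONS_{tcons_counter:08d}"

    unrel_fpkm = {
        s: np.minimum(
            np.exp(rng.normal(np.log(0.005), 0.5, size=n_unreliable)),
            _UNRELIABLE_CAP * 0.99,
        )
        for s in EXPRESSION_SAMPLES
    }

    for s in EXPRESSION_SAMPLES:
        rows = []
        for gi, gid in enumerate(gene_ids):
            gene_total = designed[gid][s] * float(noise[s][gi])
            for k in range(int(n_iso[gi])):
                fpkm = gene_total * float(shares[gi][k])
                # specific-gene background in the comparator cell types is
                # part of the designed unreliable population
                reliable = fpkm > 0 and (
                    gid not in specific or s in ("SMC_J", "SMC_C")
                )
                if reliable:
                    fpkm = max(fpkm, _RELIABLE_FLOOR)
                elif fpkm > 0:
                    fpkm = min(fpkm, _UNRELIABLE_CAP * 0.99)
                conf_lo = 0.5 * fpkm if reliable else 0.0
                conf_hi = 1.5 * fpkm
                rows.append(
                    (
                        tcons_ids[(gi, k)],
                        gid,
                        f"chr1:{gi * 1000}-{gi * 1000 + 900}",
                        900,
                        fpkm,
                        conf_lo,
                        conf_hi,
                    )
                )
        for u in range(n_unreliable):
            fpkm = float(unrel_fpkm[s][u])
            rows.append(
                (
                    f"TCONS_U{u:07d}",
                    f"GENEU{u:05d}",
                    f"chr1:{(n_genes + u) * 1000}-{(n_genes + u) * 1000 + 900}",
                    900,
                    fpkm,
                    0.0,
                    3.0 * fpkm,
                )
            )
        tables[s] = pd.DataFrame(rows, columns=EXPRESSION_COLUMNS)

    manifest = TruthManifest(
        kind="expression",
        seed=int(seed),
        params={
            "n_genes": n_genes,
            "isoforms_per_gene_mean": isoforms_per_gene_mean,
            "n_specific": n_specific,
            "noise_sd": noise_sd,
            "n_unreliable": n_unreliable,
            "specific_fpkm": specific_fpkm,
        },
        records={
            "specific_genes": sorted(specific),
            "designed_gene_fpkm": designed,
            "isoform_counts": {g: int(k) for g, k in zip(gene_ids, n_iso)},
            "unreliable_tracking_prefix": "TCONS_U",
            "separation_interval": [_UNRELIABLE_CAP, _RELIABLE_FLOOR],
        },
    )
    return tables, manifest


# ---------------------------------------------------------------------------
# Histone tracks


def make_gene_cohort(
    n_genes: int, spacing_bp: int = 10000, seed: int = 0, chrom: str = "chr1"
) -> list[GeneModel]:
    """Equally spaced two-exon genes for histone profiling tests."""
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_genes):
        tss = (i + 1) * spacing_bp
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            exons = [(tss, tss + 400), (tss + 800, tss + 1200)]
        else:
            exons = [(tss - 1200, tss - 800), (tss - 400, tss)]
        gid = f"HG{i:04d}"
        genes.append(
            GeneModel(gid, chrom, [Transcript(f"{gid}.t1", chrom, strand, exons)])
        )
    return genes


_LEVEL_BANDS = {LOW: (0.5, 2.0), HIGH: (8.0, 12.0)}
_DESIGNED_THRESHOLD = 5.0

_CLASS_LEVELS = {
    RESTRICTED_ACTIVE: (LOW, LOW, HIGH),
    UBIQUITOUS_ACTIVE: (HIGH, HIGH, LOW),
    SILENCED: (LOW, LOW, LOW),
    AMBIGUOUS: (HIGH, LOW, HIGH),
}


def make_histone_tracks(
    genes: list[GeneModel],
    designed_classes: list[str],
    seed: int = 0,
    window_bp: int = 2000,
) -> tuple[dict[str, dict[str, list[tuple[int, int, float]]]], TruthManifest]:
    """bedGraph blocks for the three marks over each gene's TSS window.

    Signals are drawn from well-separated bands (low: 0.5-2, high:
    8-12) around a designed threshold of 5, according to each gene's
    designed class, so classification at the designed thresholds
    recovers every class exactly.  Windows must not overlap between
    genes.
    """
    if len(genes) != len(designed_classes):
        raise ValueError("one designed class per gene required")
    bad = set(designed_classes) - set(_CLASS_LEVELS)
    if bad:
        raise ValueError(f"unknown designed classes {sorted(bad)}")
    order = sorted(genes, key=lambda g: (g.chrom, g.tss))
    for a, b in zip(order, order[1:]):
        if a.chrom == b.chrom and b.tss - a.tss < 2 * window_bp:
            raise ValueError(
                f"TSS windows of {a.gene_id} and {b.gene_id} overlap"
            )
    rng = np.random.default_rng(seed)
    tracks: dict[str, dict[str, list[tuple[int, int, float]]]] = {
        m: {} for m in MARKS
    }
    truth = []
    for gene, cls in zip(genes, designed_classes):
        levels = _CLASS_LEVELS[cls]
        start, end = gene.tss - window_bp, gene.tss + window_bp
        rec = {"gene_id": gene.gene_id, "class": cls, "levels": {}}
        for mark, level in zip(MARKS, levels):
            lo, hi = _LEVEL_BANDS[level]
            # three sub-blocks with independent values inside the band
            third = (end - start) // 3
            cuts = [start, start + third, start + 2 * third, end]
            vals = rng.uniform(lo, hi, size=3)
            blocks = tracks[mark].setdefault(gene.chrom, [])
            for (bs, be), v in zip(zip(cuts, cuts[1:]), vals):
                blocks.append((int(bs), int(be), float(v)))
            rec["levels"][mark] = level
        truth.append(rec)
    for mark in MARKS:
        for chrom in tracks[mark]:
            tracks[mark][chrom].sort()
    manifest = TruthManifest(
        kind="histone",
        seed=int(seed),
        params={"window_bp": window_bp, "threshold": _DESIGNED_THRESHOLD},
        records={"genes": truth},
    )
    return tracks, manifest


def designed_thresholds() -> MarkThresholds:
    """The generator's designed low/high separation point per mark."""
    return MarkThresholds({m: _DESIGNED_THRESHOLD for m in MARKS})
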