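"""End-to-end pipeline: scan -> conserve -> associate -> express ->
signature, with a JSON report and a UCSC custom-track bundle.

The report mirrors the association summary (peak proportions with
CArG boxes, conserved CArG boxes, CpG islands and genes, plus the
location histogram), the expression stage (reliability cutoff,
isoforms per gene, SRF-target nomination) and, when histone tracks
are supplied, the signature calls.  Every output embeds the resolved
configuration and package version, so re-running the same config on
the same inputs reproduces the report byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__, expression as ex, histone as hs, io, peaks as pk
from .conserve import find_conserved, read_coordinate_map
from .scan import boxes_to_intervals, generate_permutations, load_permutations, scan_genome


@dataclass
class PipelineConfig:
    """All stage parameters and input paths for one pipeline run."""

    fasta: str
    peaks: str
    genes: str
    out_dir: str
    target_fasta: str | None = None
    coordinate_map: str | None = None
    cpg: str | None = None
    permutations: str | None = None
    isoform_tables: dict[str, str] = field(default_factory=dict)
    histone_tracks: dict[str, str] = field(default_factory=dict)
    min_signal: float = pk.DEFAULT_MIN_SIGNAL
    promoter_bp: int = pk.DEFAULT_PROMOTER_BP
    min_overlap: int = 1
    pseudocount: float = ex.DEFAULT_PSEUDOCOUNT
    min_fpkm: float = ex.DEFAULT_MIN_FPKM
    window_bp: int = hs.DEFAULT_WINDOW_BP
    fpkm_cutoff: str | float = "auto"
    max_mismatch: int = 1

    def to_dict(self) -> dict:
        return asdict(self)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage and write the report bundle.

    Outputs land in ``config.out_dir``: carg_boxes.bed and
    srf_peaks.bed custom tracks (plus conserved_carg.bed when a
    target genome and map are given), annotated_peaks.tsv,
    gene_fpkm.tsv / specificity.tsv when expression tables are given,
    signature_calls.tsv when histone tracks are given, and
    report.json.  Any stage failure removes partial outputs and
    raises :class:`StageError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
    }

    def _emit(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        written.append(path)
        return path

    try:
        stage = "scan"
        for path in (config.fasta, config.peaks, config.genes):
            if not Path(path).exists():
                raise FileNotFoundError(f"input not found: {path}")
        table = (
            load_permutations(config.permutations)
            if config.permutations
            else generate_permutations(config.max_mismatch)
        )
        genome = io.read_fasta(config.fasta)
        boxes = scan_genome(genome, table)
        _emit(
            "carg_boxes.bed",
            lambda p: io.write_custom_track(boxes_to_intervals(boxes), "CArGome", p),
        )
        report["scan"] = {
            "n_boxes": len(boxes),
            "n_consensus": sum(b.match_class == "consensus" for b in boxes),
            "n_single_mismatch": sum(
                b.match_class == "single_mismatch" for b in boxes
            ),
        }

        stage = "conserve"
        conserved_set = set()
        if config.target_fasta and config.coordinate_map:
            target = io.read_fasta(config.target_fasta)
            target_boxes = scan_genome(target, table)
            cmap = read_coordinate_map(config.coordinate_map)
            conserved = find_conserved(
                boxes, target_boxes, cmap, config.min_overlap
            )
            conserved_set = {c.source for c in conserved}
            _emit(
                "conserved_carg.bed",
                lambda p: io.write_custom_track(
                    boxes_to_intervals([c.source for c in conserved]),
                    "Conserved_CArG",
                    p,
                ),
            )
            report["conserve"] = {
                "n_target_boxes": len(target_boxes),
                "n_conserved": len(conserved),
                "min_overlap": config.min_overlap,
            }

        stage = "associate"
        raw_peaks = pk.peaks_from_bed(io.read_bed(config.peaks))
        kept = pk.filter_peaks(raw_peaks, config.min_signal)
        islands = io.read_bed(config.cpg) if config.cpg else []
        genes = io.read_gene_models(config.genes)
        annotations = pk.annotate_peaks(
            kept,
            boxes,
            conserved_set,
            islands,
            genes,
            config.promoter_bp,
        )
        summary = pk.summarize(annotations)
        _emit(
            "srf_peaks.bed",
            lambda p: io.write_custom_track(
                [q.interval() for q in kept], "SRF_peaks", p
            ),
        )

        def _write_annotations(path):
            with open(path, "w") as fh:
                fh.write(
                    "chrom\tstart\tend\tname\tsignal_value\tcarg_count\t"
                    "has_conserved_carg\tin_cpg_island\tgene_id\tlocation_class\n"
                )
                for a in annotations:
                    fh.write(
                        f"{a.peak.chrom}\t{a.peak.start}\t{a.peak.end}\t"
                        f"{a.peak.name}\t{a.peak.signal_value:g}\t{a.carg_count}\t"
                        f"{int(a.has_conserved_carg)}\t{int(a.in_cpg_island)}\t"
                        f"{a.gene_id or '.'}\t{a.location_class}\n"
                    )

        _emit("annotated_peaks.tsv", _write_annotations)
        report["associate"] = {
            "n_input_peaks": len(raw_peaks),
            "n_retained_peaks": len(kept),
            **summary.to_dict(),
        }

        stage = "express"
        if config.isoform_tables:
            tables = {
                sample: io.read_expression_table(path, sample)
                for sample, path in config.isoform_tables.items()
            }
            import pandas as pd

            combined = pd.concat(tables.values(), ignore_index=True)
            if config.fpkm_cutoff == "auto":
                cutoff = ex.reliability_cutoff(combined)
            else:
                cutoff = float(config.fpkm_cutoff)
            censored = {s: ex.apply_cutoff(t, cutoff) for s, t in tables.items()}
            gene_tables = {
                s: ex.aggregate_gene_fpkm(t) for s, t in censored.items()
            }
            report["express"] = {
                "fpkm_cutoff": cutoff,
                "isoforms_per_gene": ex.isoforms_per_gene(
                    pd.concat(censored.values(), ignore_index=True)
                ),
            }
            first = next(iter(gene_tables))
            _emit(
                "gene_fpkm.tsv",
                lambda p: pd.concat(
                    [t.assign(sample_id=s) for s, t in gene_tables.items()],
                    ignore_index=True,
                ).to_csv(p, sep="\t", index=False),
            )
            smc_like = [s for s in gene_tables if s.upper().startswith("SMC")]
            if {"ICC", "PDGFRA"} <= set(gene_tables) and smc_like:
                spec = ex.specificity_table(
                    gene_tables[smc_like[0]],
                    gene_tables["ICC"],
                    gene_tables["PDGFRA"],
                    config.pseudocount,
                )
                _emit(
                    "specificity.tsv",
                    lambda p: spec.to_csv(p, sep="\t", index=False),
                )
                report["express"]["specificity_sample"] = smc_like[0]
            targets = ex.nominate_srf_targets(
                gene_tables[first],
                summary.genes_associated,
                config.min_fpkm,
            )
            report["express"]["srf_targets"] = targets
            report["express"]["n_srf_targets"] = len(targets)

        stage = "signature"
        if config.histone_tracks:
            missing = [m for m in hs.MARKS if m not in config.histone_tracks]
            if missing:
                raise ValueError(f"missing histone tracks for {missing}")
            tracks = {
                m: hs.SignalTrack(io.read_bedgraph(p))
                for m, p in config.histone_tracks.items()
            }
            profiles = hs.profile_genes(genes, tracks, config.window_bp)
            calls = hs.classify_cohort(profiles)

            def _write_calls(path):
                with open(path, "w") as fh:
                    fh.write(
                        "gene_id\tH3K4me3\tH3K27ac\tH3K27me3\tsignature\n"
                    )
                    for c in calls:
                        fh.write(
                            f"{c.gene_id}\t{c.levels[0]}\t{c.levels[1]}\t"
                            f"{c.levels[2]}\t{c.signature}\n"
                        )

            _emit("signature_calls.tsv", _write_calls)
            from collections import Counter

            report["signature"] = {
                "window_bp": config.window_bp,
                "class_counts": dict(
                    Counter(c.signature for c in calls)
                ),
            }

        stage = "report"
        report_path = out_dir / "report.json"
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(report_path)
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise StageError(stage, exc) from exc
    return report
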