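"""Generate the synthetic study inputs for the downstream analyses.

Writes a regulatory layout (genome with planted CArG boxes, SRF
peaks, CpG islands, gene models, a cross-species block map and a
second genome), four-sample isoform FPKM tables, and histone-mark
bedGraph tracks, each with its ground-truth manifest, under
results/sim/.
"""

import argparse
from pathlib import Path

from cargome import io
from cargome.conserve import write_coordinate_map
from cargome.histone import MARKS
from cargome.synthetic import (
    make_expression,
    make_gene_cohort,
    make_histone_tracks,
    make_regulatory_layout,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=20150923)
parser.add_argument("--n-peaks", type=int, default=150)
parser.add_argument("--n-genes", type=int, default=2000)
parser.add_argument("--out", type=Path, default=Path("results/sim"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

layout = make_regulatory_layout(n_peaks=args.n_peaks, seed=args.seed)
io.write_fasta(layout.genome, args.out / "genome.fa")
io.write_fasta(layout.target_genome, args.out / "target_genome.fa")
io.write_bed([p.interval() for p in layout.peaks], args.out / "peaks.bed")
io.write_bed(layout.islands, args.out / "cpg.bed")
io.write_gtf(layout.genes, args.out / "genes.gtf")
write_coordinate_map(layout.coordinate_map, args.out / "map.tsv")
layout.manifest.write(args.out / "regulatory.manifest.json")
print(
    f"regulatory layout: {args.n_peaks} peaks over "
    f"{len(layout.genome['chr1']):,} bp; {len(layout.boxes)} planted CArG "
    f"boxes, {layout.manifest.records['n_conserved']} designed conserved"
)

tables, expr_manifest = make_expression(n_genes=args.n_genes, seed=args.seed)
for sample, df in tables.items():
    io.write_expression_table(df, args.out / f"isoforms_{sample}.tsv")
expr_manifest.write(args.out / "expression.manifest.json")
print(
    f"expression: {args.n_genes} genes x 4 samples, "
    f"{expr_manifest.params['n_specific']} designed SMC-specific, "
    f"{expr_manifest.params['n_unreliable']} designed unreliable transcripts"
)

genes = make_gene_cohort(100, seed=args.seed)
classes = [
    ["restricted_active", "ubiquitous_active", "silenced", "ambiguous"][i % 4]
    for i in range(len(genes))
]
tracks, hist_manifest = make_histone_tracks(genes, classes, seed=args.seed)
io.write_gtf(genes, args.out / "histone_genes.gtf")
for mark in MARKS:
    io.write_bedgraph(tracks[mark], args.out / f"{mark}.bedgraph")
hist_manifest.write(args.out / "histone.manifest.json")
print(f"histone: {len(genes)} genes across 4 designed chromatin classes")
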