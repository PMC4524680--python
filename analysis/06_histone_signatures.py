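"""Classify gene chromatin signatures from the three histone marks.

Profiles each gene's TSS window ((min+max)/2 of the ChIP signal per
mark), calls the joint H3K4me3/H3K27ac/H3K27me3 signature at the
generator's designed thresholds, writes the calls and checks them
against the designed classes.
"""

import argparse
from collections import Counter
from pathlib import Path

from cargome import histone as hs, io
from cargome.synthetic import TruthManifest, designed_thresholds

parser = argparse.ArgumentParser()
parser.add_argument("--sim", type=Path, default=Path("results/sim"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

genes = io.read_gene_models(args.sim / "histone_genes.gtf")
tracks = {
    m: hs.SignalTrack(io.read_bedgraph(args.sim / f"{m}.bedgraph"))
    for m in hs.MARKS
}
profiles = hs.profile_genes(genes, tracks)
calls = hs.classify_cohort(profiles, designed_thresholds())

with open(args.out / "signature_calls.tsv", "w") as fh:
    fh.write("gene_id\tH3K4me3\tH3K27ac\tH3K27me3\tsignature\n")
    for c in calls:
        fh.write(
            f"{c.gene_id}\t{c.levels[0]}\t{c.levels[1]}\t{c.levels[2]}\t"
            f"{c.signature}\n"
        )

manifest = TruthManifest.read(args.sim / "histone.manifest.json")
truth = {g["gene_id"]: g["class"] for g in manifest.records["genes"]}
correct = sum(c.signature == truth[c.gene_id] for c in calls)
print(f"signature calls: {dict(Counter(c.signature for c in calls))}")
print(f"designed classes recovered: {correct}/{len(calls)}")
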