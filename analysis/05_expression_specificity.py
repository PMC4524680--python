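"""FPKM reliability cutoff, gene aggregation, correlations, Venn
counts, cell-specificity ranking and SRF-target nomination.

Determines the reliability cutoff where false-positive and
false-negative rates cross, censors sub-cutoff FPKM to zero,
aggregates isoforms to genes, compares the two SMC samples, ranks
genes by SMC specificity, nominates SRF targets above 100 FPKM among
the peak-associated genes, and translates the longest ORF of an
example transcript.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cargome import expression as ex, io
from cargome.synthetic import TruthManifest

parser = argparse.ArgumentParser()
parser.add_argument("--sim", type=Path, default=Path("results/sim"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--pseudocount", type=float, default=0.01)
parser.add_argument("--min-fpkm", type=float, default=100.0)
args = parser.parse_args()

samples = ("SMC_J", "SMC_C", "ICC", "PDGFRA")
tables = {
    s: io.read_expression_table(args.sim / f"isoforms_{s}.tsv", s)
    for s in samples
}
combined = pd.concat(tables.values(), ignore_index=True)

cutoff = ex.reliability_cutoff(combined)
fp, fn = ex.reliability_rates(combined, cutoff)
censored = {s: ex.apply_cutoff(t, cutoff) for s, t in tables.items()}
print(f"reliability cutoff: {cutoff:.4g} FPKM (FP={fp:.3f}, FN={fn:.3f})")

ipg = ex.isoforms_per_gene(pd.concat(censored.values(), ignore_index=True))
print(f"isoforms per expressed gene: {ipg:.2f}")

genes = {s: ex.aggregate_gene_fpkm(t) for s, t in censored.items()}
r = ex.expression_correlation(genes["SMC_J"], genes["SMC_C"])
print(f"JSMC vs CSMC correlation (Pearson on log10(FPKM+1)): {r:.3f}")

expressed = {
    s: set(g.loc[g["fpkm"] > 0, "gene_id"]) for s, g in genes.items()
}
venn = ex.venn_counts({"JSMC": expressed["SMC_J"], "CSMC": expressed["SMC_C"]})
print(f"expressed-gene Venn (JSMC vs CSMC): {venn}")

spec = ex.specificity_table(
    genes["SMC_J"], genes["ICC"], genes["PDGFRA"], args.pseudocount
)
spec.to_csv(args.out / "specificity.tsv", sep="\t", index=False)
manifest = TruthManifest.read(args.sim / "expression.manifest.json")
truth = set(manifest.records["specific_genes"])
top = set(spec.head(len(truth))["gene_id"])
print(
    f"top-{len(truth)} specificity ranks recover designed SMC-specific "
    f"genes: {len(top & truth)}/{len(truth)}"
)

with open(args.out / "association_summary.json") as fh:
    srf_genes = set(json.load(fh)["genes_associated"])
targets = ex.nominate_srf_targets(genes["SMC_J"], srf_genes, args.min_fpkm)
pd.DataFrame({"gene_id": targets}).to_csv(
    args.out / "srf_targets.tsv", sep="\t", index=False
)
print(
    f"SRF targets: {len(targets)} of {len(srf_genes)} peak-associated "
    f"genes exceed {args.min_fpkm:g} FPKM (strict)"
)

example = "CCC" + "ATG" + "GAA" * 40 + "TAA" + "GGG"
peptide = ex.longest_orf_translate(example)
print(
    f"example ORF translation: {len(example)} nt transcript -> "
    f"{len(peptide)} aa peptide ({peptide[:10]}...)"
)
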