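"""FPKM reliability filtering, gene aggregation, cell-specificity
scoring, SRF-target nomination, and ORF translation.

Expression tables are pandas DataFrames with the isoform-table
columns (tracking_id, gene_id, fpkm, fpkm_conf_lo, fpkm_conf_hi, plus
sample_id when multiple samples are combined).  A transcript is
"reliable" when the lower bound of its 95% FPKM confidence interval
is above zero, and "unreliable" when that bound is exactly zero; the
reliability cutoff is the FPKM threshold at which the false-positive
rate (unreliable transcripts kept) equals the false-negative rate
(reliable transcripts discarded), and FPKM values below the cutoff
are censored to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_GRID_POINTS = 1000
DEFAULT_PSEUDOCOUNT = 0.01
DEFAULT_MIN_FPKM = 100.0


def reliability_labels(transcripts: pd.DataFrame) -> pd.Series:
    """True for reliable transcripts (conf_lo > 0)."""
    return transcripts["fpkm_conf_lo"] > 0


def reliability_rates(
    transcripts: pd.DataFrame, cutoff: float
) -> tuple[float, float]:
    """(FP, FN) at a candidate cutoff.

    FP = fraction of unreliable transcripts with fpkm >= cutoff (kept
    although untrustworthy); FN = fraction of reliable transcripts
    with fpkm < cutoff (censored although trustworthy).
    """
    reliable = reliability_labels(transcripts)
    fpkm = transcripts["fpkm"].to_numpy(dtype=float)
    n_unrel = int((~reliable).sum())
    n_rel = int(reliable.sum())
    fp = float((fpkm[~reliable.to_numpy()] >= cutoff).mean()) if n_unrel else 0.0
    fn = float((fpkm[reliable.to_numpy()] < cutoff).mean()) if n_rel else 0.0
    return fp, fn


def candidate_grid(transcripts: pd.DataFrame, grid_points: int) -> np.ndarray:
    fpkm = transcripts["fpkm"].to_numpy(dtype=float)
    positive = fpkm[fpkm > 0]
    if positive.size == 0:
        raise ValueError("no positive FPKM values to place the grid on")
    lo, hi = positive.min(), positive.max()
    if lo == hi:
        return np.array([lo])
    return np.logspace(np.log10(lo), np.log10(hi), grid_points)


def reliability_cutoff(
    transcripts: pd.DataFrame,
    grid_points: int = DEFAULT_GRID_POINTS,
    exhaustive: bool = False,
) -> float:
    """FPKM cutoff equalising false-positive and false-negative rates.

    Candidate thresholds are log-spaced over the positive FPKM range
    (or, with ``exhaustive=True``, every distinct positive FPKM
    value); the returned cutoff minimises |FP - FN|, taking the
    smallest threshold on ties.  Requires at least one reliable and
    one unreliable transcript, otherwise the crossing is undefined.
    """
    reliable = reliability_labels(transcripts)
    if reliable.all() or (~reliable).all():
        raise ValueError(
            "reliability cutoff undefined: need both reliable (conf_lo > 0) "
            "and unreliable (conf_lo = 0) transcripts"
        )
    if exhaustive:
        fpkm = transcripts["fpkm"].to_numpy(dtype=float)
        grid = np.unique(fpkm[fpkm > 0])
    else:
        grid = candidate_grid(transcripts, grid_points)

    fpkm = transcripts["fpkm"].to_numpy(dtype=float)
    rel = reliable.to_numpy()
    unrel_fpkm = np.sort(fpkm[~rel])
    rel_fpkm = np.sort(fpkm[rel])
    # FP(t) = frac unreliable >= t; FN(t) = frac reliable < t
    fp = 1.0 - np.searchsorted(unrel_fpkm, grid, side="left") / unrel_fpkm.size
    fn = np.searchsorted(rel_fpkm, grid, side="left") / rel_fpkm.size
    gap = np.abs(fp - fn)
    best = int(np.argmin(gap))  # argmin returns the first (smallest t) on ties
    return float(grid[best])


def apply_cutoff(transcripts: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Censor FPKM values strictly below the cutoff to zero."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    out = transcripts.copy()
    out.loc[out["fpkm"] < cutoff, "fpkm"] = 0.0
    return out


def aggregate_gene_fpkm(transcripts: pd.DataFrame) -> pd.DataFrame:
    """Sum isoform FPKM per gene (and per sample when present).

    A gene's combined expression is the sum over all its
    transcriptional variants.
    """
    keys = ["gene_id"]
    if "sample_id" in transcripts.columns:
        keys.append("sample_id")
    return (
        transcripts.groupby(keys, as_index=False)["fpkm"]
        .sum()
        .sort_values(keys, ignore_index=True)
    )


def isoforms_per_gene(
    transcripts: pd.DataFrame, expressed_only: bool = True
) -> float:
    """Mean isoform count per gene.

    With ``expressed_only`` (default), only isoforms with fpkm > 0
    and genes with at least one expressed isoform are counted;
    otherwise all annotated isoforms and genes count.
    """
    if len(transcripts) == 0:
        raise ValueError("empty expression table")
    df = transcripts[transcripts["fpkm"] > 0] if expressed_only else transcripts
    if len(df) == 0:
        raise ValueError("no expressed isoforms")
    n_isoforms = df["tracking_id"].nunique()
    n_genes = df["gene_id"].nunique()
    return n_isoforms / n_genes


def expression_correlation(
    a: pd.DataFrame, b: pd.DataFrame, log_transform: bool = True
) -> float:
    """Pearson correlation between two gene-level expression tables.

    Computed over the union of gene ids (a gene absent from one table
    contributes 0 there), on log10(FPKM + 1) by default.
    """
    sa = a.set_index("gene_id")["fpkm"]
    sb = b.set_index("gene_id")["fpkm"]
    shared = sa.index.intersection(sb.index)
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared genes; need >= 3 for a correlation"
        )
    union = sa.index.union(sb.index)
    xa = sa.reindex(union, fill_value=0.0).to_numpy(dtype=float)
    xb = sb.reindex(union, fill_value=0.0).to_numpy(dtype=float)
    if log_transform:
        xa = np.log10(xa + 1.0)
        xb = np.log10(xb + 1.0)
    return float(stats.pearsonr(xa, xb).statistic)


def venn_counts(gene_sets: dict[str, set[str]]) -> dict[str, int]:
    """Counts for every non-empty region of a 2-4 set Venn partition.

    Keys are '&'-joined set names in input order (e.g. "A&B" for the
    region in A and B but no other set); values sum to the size of
    the union.
    """
    if not 2 <= len(gene_sets) <= 4:
        raise ValueError("venn_counts requires between 2 and 4 sets")
    names = list(gene_sets)
    counts: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for members in combinations(names, r):
            inside = set.intersection(*(gene_sets[n] for n in members))
            outside = set.union(
                set(), *(gene_sets[n] for n in names if n not in members)
            )
            counts["&".join(members)] = len(inside - outside)
    return counts


@dataclass(frozen=True)
class SpecificityScore:
    gene_id: str
    score: float


def specificity_score(
    gene_id: str,
    fpkm_smc: float,
    fpkm_icc: float,
    fpkm_pdgfra: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> SpecificityScore:
    """Cell-specificity of a gene for smooth muscle cells.

    score = SMC_FPKM / (ICC_FPKM + PDGFRa_FPKM + pseudocount); the
    pseudocount stabilises genes silent in both comparator cell
    types (interstitial cells of Cajal and PDGFRa+ cells).
    """
    if min(fpkm_smc, fpkm_icc, fpkm_pdgfra) < 0 or pseudocount < 0:
        raise ValueError("FPKM values and pseudocount must be non-negative")
    denom = fpkm_icc + fpkm_pdgfra + pseudocount
    if denom == 0:
        raise ValueError(
            f"gene {gene_id!r}: zero denominator; set a positive pseudocount"
        )
    return SpecificityScore(gene_id, fpkm_smc / denom)


def specificity_table(
    smc: pd.DataFrame,
    icc: pd.DataFrame,
    pdgfra: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Specificity scores for every gene in the SMC table, sorted by
    descending score (gene id as tiebreak)."""
    s = smc.set_index("gene_id")["fpkm"]
    i = icc.set_index("gene_id")["fpkm"].reindex(s.index, fill_value=0.0)
    p = pdgfra.set_index("gene_id")["fpkm"].reindex(s.index, fill_value=0.0)
    scores = s / (i + p + pseudocount)
    out = pd.DataFrame(
        {
            "gene_id": s.index,
            "fpkm_smc": s.to_numpy(),
            "fpkm_icc": i.to_numpy(),
            "fpkm_pdgfra": p.to_numpy(),
            "specificity": scores.to_numpy(),
        }
    )
    return out.sort_values(
        ["specificity", "gene_id"], ascending=[False, True], ignore_index=True
    )


def nominate_srf_targets(
    gene_fpkm: pd.DataFrame,
    srf_gene_ids: set[str],
    min_fpkm: float = DEFAULT_MIN_FPKM,
) -> list[str]:
    """SRF-bound genes highly expressed in SMCs.

    Selects genes that carry an SRF binding site and whose combined
    FPKM is strictly above ``min_fpkm`` (default 100), sorted by
    descending FPKM with gene id as tiebreak.
    """
    df = gene_fpkm[
        gene_fpkm["gene_id"].isin(srf_gene_ids) & (gene_fpkm["fpkm"] > min_fpkm)
    ]
    df = df.sort_values(["fpkm", "gene_id"], ascending=[False, True])
    return df["gene_id"].tolist()


# ---------------------------------------------------------------------------
# ORF translation

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))


def _translate(seq: str) -> str:
    aas = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        aas.append("X" if "N" in codon else _CODON_TABLE[codon])
    return "".join(aas)


def longest_orf_translate(transcript_sequence: str) -> str:
    """Translate the longest ATG-initiated ORF of a transcript.

    Searches the three forward frames only (assembled transcripts are
    already oriented).  An ORF runs from an ATG to the first in-frame
    stop codon, or to the end of the sequence when no stop occurs.
    Ties on length pick the leftmost start; the stop is not
    translated; codons containing N translate to 'X'.  Returns the
    empty string when the sequence has no ATG.
    """
    seq = transcript_sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("transcript sequence must be over A,C,G,T,N")
    best_start, best_len = None, -1
    n = len(seq)
    for start in range(n - 2):
        if seq[start : start + 3] != "ATG":
            continue
        end = n - (n - start) % 3  # last full-codon boundary in this frame
        for i in range(start, end, 3):
            if seq[i : i + 3] in STOP_CODONS:
                end = i
                break
        orf_len = end - start
        if orf_len > best_len:
            best_start, best_len = start, orf_len
    if best_start is None:
        return ""
    return _translate(seq[best_start : best_start + best_len])
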