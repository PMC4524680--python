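"""Peak filtering, annotation, location classes, proteomics overlap."""

import numpy as np
import pytest

from cargome._types import GeneModel, GenomicInterval, Transcript
from cargome import peaks as pk
from cargome.scan import CONSENSUS, CArGBox


def _peak(start, end, signal=2.0, name="p"):
    return pk.SRFPeak("chr1", start, end, name, signal)


def _box(start):
    return CArGBox("chr1", start, "CCAAATTTGG", CONSENSUS)


class TestFilterPeaks:
    def test_strict_inequality_at_threshold(self):
        peaks = [_peak(0, 10, s) for s in (1.0, 1.5, 1.6)]
        kept = pk.filter_peaks(peaks, 1.5)
        assert [p.signal_value for p in kept] == [1.6]

    def test_empty_input(self):
        assert pk.filter_peaks([], 1.5) == []

    def test_monotone_and_idempotent(self):
        rng = np.random.default_rng(0)
        peaks = [_peak(i * 20, i * 20 + 10, float(s)) for i, s in enumerate(rng.uniform(0, 5, 50))]
        sizes = [len(pk.filter_peaks(peaks, t)) for t in (0.5, 1.5, 2.5, 3.5)]
        assert sizes == sorted(sizes, reverse=True)
        once = pk.filter_peaks(peaks, 1.5)
        assert pk.filter_peaks(once, 1.5) == once


class TestAnnotatePeak:
    def test_counts_fully_contained_boxes(self):
        ann = pk.annotate_peak(
            _peak(100, 200), [_box(150), _box(190)], set(), [], []
        )
        assert ann.carg_count == 2

    def test_partially_overlapping_box_not_counted(self):
        ann = pk.annotate_peak(_peak(100, 200), [_box(195)], set(), [], [])
        assert ann.carg_count == 0

    def test_overlap_rule_flag_counts_partial_box(self):
        ann = pk.annotate_peak(
            _peak(100, 200), [_box(195)], set(), [], [], carg_rule="overlap"
        )
        assert ann.carg_count == 1

    def test_conserved_flag_requires_contained_conserved_box(self):
        boxes = [_box(150)]
        ann = pk.annotate_peak(_peak(100, 200), boxes, set(boxes), [], [])
        assert ann.has_conserved_carg
        ann2 = pk.annotate_peak(_peak(100, 200), boxes, set(), [], [])
        assert not ann2.has_conserved_carg

    def test_cpg_overlap_one_bp_suffices(self):
        isl = [GenomicInterval("chr1", 199, 250)]
        assert pk.annotate_peak(_peak(100, 200), [], set(), isl, []).in_cpg_island
        isl2 = [GenomicInterval("chr1", 200, 250)]
        assert not pk.annotate_peak(_peak(100, 200), [], set(), isl2, []).in_cpg_island


def _gene(gene_id, tss, strand="+", n_exons=3, exon_bp=200, intron_bp=300):
    exons = []
    pos = tss
    for _ in range(n_exons):
        if strand == "+":
            exons.append((pos, pos + exon_bp))
            pos += exon_bp + intron_bp
        else:
            exons.append((pos - exon_bp, pos))
            pos -= exon_bp + intron_bp
    return GeneModel(
        gene_id, "chr1", [Transcript(f"{gene_id}.t1", "chr1", strand, exons)]
    )


class TestClassifyLocation:
    def test_promoter_upstream_of_tss(self):
        gene = _gene("G", 10_000)
        gid, cls = pk.classify_location(_peak(9_700, 10_000), [gene], 5000)
        assert (gid, cls) == ("G", pk.PROMOTER)

    def test_midpoint_in_first_exon(self):
        gene = _gene("G", 10_000, n_exons=1)
        gid, cls = pk.classify_location(_peak(10_000, 10_100), [gene])
        assert (gid, cls) == ("G", pk.EXON1)

    def test_no_gene_context_is_intergenic(self):
        gid, cls = pk.classify_location(_peak(0, 100), [])
        assert (gid, cls) == (None, pk.INTERGENIC)

    def test_nearest_tss_breaks_gene_ties(self):
        # midpoint 10,050 sits in exon1 of G1 (TSS 10,000) and in the
        # promoter of G2 (TSS 12,000); promoter precedence wins
        g1 = _gene("G1", 10_000)
        g2 = _gene("G2", 12_000)
        gid, cls = pk.classify_location(_peak(10_000, 10_100), [g1, g2], 5000)
        assert (gid, cls) == ("G2", pk.PROMOTER)

    def test_agrees_with_exhaustive_region_oracle(self):
        rng = np.random.default_rng(9)
        genes = []
        for i in range(12):
            tss = int(rng.integers(20_000, 180_000))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                _gene(
                    f"G{i:02d}", tss, strand,
                    n_exons=int(rng.integers(1, 5)),
                )
            )
        for _ in range(400):
            start = int(rng.integers(0, 200_000))
            peak = _peak(start, start + int(rng.integers(50, 400)))
            got = pk.classify_location(peak, genes, 5000)
            assert got == _oracle_classify(peak, genes, 5000)


def _oracle_classify(peak, genes, promoter_bp):
    """Brute force: enumerate every region of every gene as an explicit
    interval, collect all hits of the midpoint, resolve by the stated
    precedence / distance / id rules."""
    mid = peak.midpoint
    precedence = {c: i for i, c in enumerate(pk.LOCATION_PRECEDENCE)}
    hits = []
    for gene in genes:
        regions = []
        for tx in gene.transcripts:
            if tx.strand == "+":
                regions.append((tx.tss - promoter_bp, tx.tss, pk.PROMOTER))
            else:
                regions.append((tx.tss, tx.tss + promoter_bp, pk.PROMOTER))
            ordered = tx.exons_5to3()
            for k, (s, e) in enumerate(ordered):
                regions.append((s, e, pk.EXON1 if k == 0 else pk.EXON_OTHER))
            introns = tx.introns_5to3()
            for k, (s, e) in enumerate(introns):
                regions.append((s, e, pk.INTRON1 if k == 0 else pk.INTRON_OTHER))
        classes = [c for s, e, c in regions if s <= mid < e]
        if classes:
            best = min(classes, key=precedence.__getitem__)
            hits.append((precedence[best], abs(mid - gene.tss), gene.gene_id, best))
    if not hits:
        return None, pk.INTERGENIC
    _, _, gid, cls = min(hits)
    return gid, cls


class TestSummarize:
    def test_proportions_from_counts(self):
        anns = [
            pk.annotate_peak(_peak(100, 200), [_box(150)], set(), [], []),
            pk.annotate_peak(_peak(300, 400), [_box(350)], set(), [], []),
            pk.annotate_peak(_peak(500, 600), [], set(), [], []),
            pk.annotate_peak(_peak(700, 800), [], set(), [], []),
        ]
        s = pk.summarize(anns)
        assert s.n_peaks == 4 and s.n_with_carg == 2
        assert s.proportions()["carg"] == 0.5

    def test_all_intergenic_means_no_genes(self):
        anns = [pk.annotate_peak(_peak(0, 100), [], set(), [], [])]
        s = pk.summarize(anns)
        assert s.n_gene_associated == 0 and s.genes_associated == set()

    def test_count_ordering_invariant(self, layout, mismatch_table):
        from cargome.scan import scan_genome
        from cargome.conserve import find_conserved

        boxes = scan_genome(layout.genome, mismatch_table)
        target = scan_genome(layout.target_genome, mismatch_table)
        conserved = {
            c.source
            for c in find_conserved(boxes, target, layout.coordinate_map)
        }
        anns = pk.annotate_peaks(
            layout.peaks, boxes, conserved, layout.islands, layout.genes
        )
        s = pk.summarize(anns)
        assert s.n_with_conserved_carg <= s.n_with_carg <= s.n_peaks
        assert sum(s.location_histogram.values()) == s.n_peaks


def test_layout_annotations_match_manifest(layout, mismatch_table):
    from cargome.scan import scan_genome
    from cargome.conserve import find_conserved

    boxes = scan_genome(layout.genome, mismatch_table)
    target = scan_genome(layout.target_genome, mismatch_table)
    conserved = {
        c.source for c in find_conserved(boxes, target, layout.coordinate_map)
    }
    anns = pk.annotate_peaks(
        layout.peaks, boxes, conserved, layout.islands, layout.genes
    )
    for ann, truth in zip(anns, layout.manifest.records["peaks"]):
        assert (ann.carg_count > 0) == truth["contains_carg"]
        assert ann.has_conserved_carg == truth["conserved"]
        assert ann.in_cpg_island == truth["in_cpg"]
        assert ann.gene_id == truth["gene_id"]
        assert ann.location_class == truth["location_class"]


class TestProteomicsOverlap:
    def test_partition_counts(self):
        counts = pk.intersect_srf_genes_with_proteins(
            {"a", "b"}, {"a": pk.DOWN_REGULATED}
        )
        assert counts == {
            pk.DOWN_REGULATED: 1,
            pk.NOT_DETECTED: 1,
            pk.UNCHANGED: 0,
        }

    def test_empty_gene_set(self):
        counts = pk.intersect_srf_genes_with_proteins({}, {"a": pk.UNCHANGED})
        assert sum(counts.values()) == 0

    def test_symbol_matching_case_insensitive_isoform_stripped(self):
        counts = pk.intersect_srf_genes_with_proteins(
            {"Acta2", "MYH11.2", "Tagln-201"},
            {"ACTA2": pk.DOWN_REGULATED, "myh11": pk.UNCHANGED, "Tagln": pk.DOWN_REGULATED},
        )
        assert counts[pk.DOWN_REGULATED] == 2
        assert counts[pk.UNCHANGED] == 1

    def test_counts_always_sum_to_input_size(self):
        rng = np.random.default_rng(4)
        genes = {f"g{i}" for i in range(100)}
        statuses = list(pk.PROTEIN_STATUSES)
        table = {
            f"g{i}": statuses[int(rng.integers(3))]
            for i in range(0, 100, 2)
        }
        counts = pk.intersect_srf_genes_with_proteins(genes, table)
        assert sum(counts.values()) == 100

    def test_unknown_status_rejected(self):
        with pytest.raises(ValueError, match="status"):
            pk.intersect_srf_genes_with_proteins({"a"}, {"a": "up"})
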