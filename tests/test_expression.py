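"""Reliability cutoff, aggregation, specificity, Venn, ORF translation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cargome import expression as ex


def _table(fpkm, conf_lo=None, gene_ids=None, tracking=None):
    fpkm = list(map(float, fpkm))
    n = len(fpkm)
    return pd.DataFrame(
        {
            "tracking_id": tracking or [f"T{i}" for i in range(n)],
            "gene_id": gene_ids or [f"G{i}" for i in range(n)],
            "locus": ["chr1:0-100"] * n,
            "length": [100] * n,
            "fpkm": fpkm,
            "fpkm_conf_lo": conf_lo if conf_lo is not None else [f / 2 for f in fpkm],
            "fpkm_conf_hi": [f * 2 + 1 for f in fpkm],
        }
    )


class TestReliabilityCutoff:
    def test_separable_case_attains_zero_rates(self):
        unreliable = _table([0.001, 0.004, 0.008], conf_lo=[0, 0, 0])
        reliable = _table([2.0, 5.0, 9.0])
        df = pd.concat([unreliable, reliable], ignore_index=True)
        cutoff = ex.reliability_cutoff(df)
        fp, fn = ex.reliability_rates(df, cutoff)
        assert fp == 0.0 and fn == 0.0
        assert 0.008 < cutoff <= 2.0

    def test_grid_minimum_equals_exhaustive_oracle_minimum(self):
        rng = np.random.default_rng(12)
        unrel = np.exp(rng.normal(np.log(0.005), 0.5, size=300))
        rel = np.exp(rng.normal(np.log(0.5), 0.5, size=700))
        df = pd.concat(
            [
                _table(unrel, conf_lo=[0] * len(unrel)),
                _table(rel),
            ],
            ignore_index=True,
        )
        got = ex.reliability_cutoff(df)
        # oracle: evaluate |FP-FN| at every distinct positive FPKM value
        fpkm = df["fpkm"].to_numpy()
        labels = (df["fpkm_conf_lo"] > 0).to_numpy()
        gaps = {}
        for t in np.unique(fpkm[fpkm > 0]):
            fp = (fpkm[~labels] >= t).mean()
            fn = (fpkm[labels] < t).mean()
            gaps[t] = abs(fp - fn)
        best_gap = min(gaps.values())
        fp, fn = ex.reliability_rates(df, got)
        assert abs(fp - fn) <= best_gap + 1e-12

    def test_exhaustive_mode_returns_smallest_minimizing_value(self):
        rng = np.random.default_rng(13)
        unrel = np.exp(rng.normal(np.log(0.005), 0.5, size=100))
        rel = np.exp(rng.normal(np.log(0.5), 0.5, size=100))
        df = pd.concat(
            [_table(unrel, conf_lo=[0] * 100), _table(rel)], ignore_index=True
        )
        got = ex.reliability_cutoff(df, exhaustive=True)
        fpkm = df["fpkm"].to_numpy()
        labels = (df["fpkm_conf_lo"] > 0).to_numpy()
        candidates = np.unique(fpkm[fpkm > 0])
        gaps = np.array(
            [
                abs((fpkm[~labels] >= t).mean() - (fpkm[labels] < t).mean())
                for t in candidates
            ]
        )
        assert got == candidates[np.argmin(gaps)]

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(14)
        unrel = np.exp(rng.normal(np.log(0.005), 0.5, size=50))
        rel = np.exp(rng.normal(np.log(0.5), 0.5, size=50))
        df = pd.concat(
            [_table(unrel, conf_lo=[0] * 50), _table(rel)], ignore_index=True
        )
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        assert ex.reliability_cutoff(df) == ex.reliability_cutoff(shuffled)

    def test_single_class_input_rejected(self):
        with pytest.raises(ValueError, match="cutoff undefined"):
            ex.reliability_cutoff(_table([1.0, 2.0]))
        with pytest.raises(ValueError, match="cutoff undefined"):
            ex.reliability_cutoff(_table([1.0, 2.0], conf_lo=[0, 0]))


class TestApplyCutoff:
    def test_below_cutoff_censored_boundary_kept(self):
        df = _table([0.01, 0.025, 0.5])
        out = ex.apply_cutoff(df, 0.025)
        assert out["fpkm"].tolist() == [0.0, 0.025, 0.5]

    def test_idempotent_and_never_increases(self):
        rng = np.random.default_rng(5)
        df = _table(rng.uniform(0, 1, 200))
        once = ex.apply_cutoff(df, 0.1)
        twice = ex.apply_cutoff(once, 0.1)
        pd.testing.assert_frame_equal(once, twice)
        assert (once["fpkm"] <= df["fpkm"]).all()
        assert ((once["fpkm"] == 0) | (once["fpkm"] >= 0.1)).all()

    def test_positive_cutoff_required(self):
        with pytest.raises(ValueError):
            ex.apply_cutoff(_table([1.0]), 0.0)


class TestAggregate:
    def test_single_isoform_passthrough(self):
        df = _table([7.0], gene_ids=["G"])
        assert ex.aggregate_gene_fpkm(df)["fpkm"].tolist() == [7.0]

    def test_sums_isoforms(self):
        df = _table([2.0, 3.0, 5.0], gene_ids=["G", "G", "G"])
        assert ex.aggregate_gene_fpkm(df)["fpkm"].tolist() == [10.0]

    def test_matches_naive_group_sum(self):
        rng = np.random.default_rng(6)
        genes = [f"G{int(i)}" for i in rng.integers(0, 30, 300)]
        df = _table(rng.uniform(0, 10, 300), gene_ids=genes)
        got = ex.aggregate_gene_fpkm(df)
        naive = {}
        for g, f in zip(genes, df["fpkm"]):
            naive[g] = naive.get(g, 0.0) + f
        assert dict(zip(got["gene_id"], got["fpkm"])) == pytest.approx(naive)

    def test_gene_fpkm_at_least_max_isoform(self):
        df = _table([2.0, 3.0], gene_ids=["G", "G"])
        assert ex.aggregate_gene_fpkm(df)["fpkm"].iloc[0] >= 3.0


class TestIsoformsPerGene:
    def test_six_isoforms_two_genes(self):
        df = _table([1.0] * 6, gene_ids=["A"] * 3 + ["B"] * 3)
        assert ex.isoforms_per_gene(df) == 3.0

    def test_single_isoform_genes(self):
        df = _table([1.0, 1.0], gene_ids=["A", "B"])
        assert ex.isoforms_per_gene(df) == 1.0

    def test_expressed_only_convention(self):
        df = _table([1.0, 0.0, 1.0], gene_ids=["A", "A", "B"])
        assert ex.isoforms_per_gene(df, expressed_only=True) == 1.0
        assert ex.isoforms_per_gene(df, expressed_only=False) == 1.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ex.isoforms_per_gene(_table([]))


def _gene_table(values: dict):
    return pd.DataFrame(
        {"gene_id": list(values), "fpkm": [float(v) for v in values.values()]}
    )


class TestExpressionCorrelation:
    def test_self_correlation_is_one(self):
        a = _gene_table({f"G{i}": i + 1 for i in range(50)})
        assert ex.expression_correlation(a, a) == pytest.approx(1.0)

    def test_permuted_labels_near_zero(self):
        rng = np.random.default_rng(8)
        n = 4000
        vals = np.exp(rng.normal(2, 1, n))
        a = _gene_table({f"G{i}": vals[i] for i in range(n)})
        perm = rng.permutation(n)
        b = _gene_table({f"G{i}": vals[perm[i]] for i in range(n)})
        r = ex.expression_correlation(a, b)
        assert abs(r) < 3 / np.sqrt(n)

    def test_doubled_fpkm_high_but_below_one(self):
        rng = np.random.default_rng(9)
        vals = np.exp(rng.normal(1, 1.5, 200))
        a = _gene_table({f"G{i}": vals[i] for i in range(200)})
        b = _gene_table({f"G{i}": 2 * vals[i] for i in range(200)})
        r = ex.expression_correlation(a, b)
        # closed-form recomputation on the log10(x+1) transform
        xa = np.log10(vals + 1)
        xb = np.log10(2 * vals + 1)
        want = np.corrcoef(xa, xb)[0, 1]
        assert r == pytest.approx(want, abs=1e-12)
        assert 0.9 < r < 1.0

    def test_absent_genes_count_as_zero(self):
        a = _gene_table({"G1": 1, "G2": 2, "G3": 3, "G4": 4})
        b = _gene_table({"G1": 1, "G2": 2, "G3": 3, "G5": 9})
        xa = np.log10(np.array([1, 2, 3, 4, 0]) + 1.0)
        xb = np.log10(np.array([1, 2, 3, 0, 9]) + 1.0)
        want = np.corrcoef(xa, xb)[0, 1]
        assert ex.expression_correlation(a, b) == pytest.approx(want)

    def test_too_few_shared_genes_rejected(self):
        a = _gene_table({"G1": 1, "G2": 2})
        with pytest.raises(ValueError, match="shared genes"):
            ex.expression_correlation(a, a)


class TestVennCounts:
    def test_two_set_partition(self):
        counts = ex.venn_counts({"A": {"x", "y"}, "B": {"y", "z"}})
        assert counts == {"A": 1, "B": 1, "A&B": 1}

    def test_four_identical_sets(self):
        s = {"a", "b", "c"}
        counts = ex.venn_counts({k: set(s) for k in "ABCD"})
        assert counts["A&B&C&D"] == 3
        assert sum(v for k, v in counts.items() if k != "A&B&C&D") == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.sets(st.integers(0, 30).map(str), max_size=20),
            min_size=2,
            max_size=4,
        )
    )
    def test_counts_sum_to_union(self, sets):
        named = {f"S{i}": s for i, s in enumerate(sets)}
        counts = ex.venn_counts(named)
        assert sum(counts.values()) == len(set.union(*sets) if sets else set())


class TestSpecificity:
    def test_balanced_ratio(self):
        assert ex.specificity_score("g", 10, 5, 5, 0).score == 1.0

    def test_silent_gene_scores_zero(self):
        assert ex.specificity_score("g", 0, 5, 5, 0).score == 0.0

    def test_pseudocount_bounds_exclusive_gene(self):
        assert ex.specificity_score("g", 100, 0, 0, 0.01).score == pytest.approx(10_000)

    def test_zero_denominator_without_pseudocount(self):
        with pytest.raises(ValueError, match="pseudocount"):
            ex.specificity_score("g", 1, 0, 0, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(0.01, 1e4),
        st.floats(0.01, 1e4),
        st.floats(0.01, 1e4),
        st.floats(0.1, 100),
    )
    def test_scale_invariant_at_zero_pseudocount(self, smc, icc, pdg, c):
        base = ex.specificity_score("g", smc, icc, pdg, 0).score
        scaled = ex.specificity_score("g", c * smc, c * icc, c * pdg, 0).score
        assert scaled == pytest.approx(base, rel=1e-9)


class TestNominateTargets:
    def test_threshold_is_strict(self):
        genes = _gene_table({"A": 100.0, "B": 100.1})
        assert ex.nominate_srf_targets(genes, {"A", "B"}, 100) == ["B"]

    def test_empty_srf_set(self):
        genes = _gene_table({"A": 500.0})
        assert ex.nominate_srf_targets(genes, set(), 100) == []

    def test_sorted_by_descending_fpkm_then_id(self):
        genes = _gene_table({"B": 300.0, "A": 300.0, "C": 500.0})
        got = ex.nominate_srf_targets(genes, {"A", "B", "C"}, 100)
        assert got == ["C", "A", "B"]


class TestOrfTranslation:
    @pytest.mark.parametrize(
        "seq,peptide",
        [
            ("ATGAAATAA", "MK"),
            ("CCCATGTTTTGA", "MF"),
            ("ATGAAA", "MK"),  # no stop: runs to sequence end
            ("CCCCCC", ""),  # no ATG
            ("ATGANATAA", "MX"),  # N codon translates to X
        ],
    )
    def test_known_translations(self, seq, peptide):
        assert ex.longest_orf_translate(seq) == peptide

    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            ex.longest_orf_translate("ATGXXX")

    def test_matches_bruteforce_scanner(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=1000))
            assert ex.longest_orf_translate(seq) == _oracle_orf(seq)


def _oracle_orf(seq: str) -> str:
    """Brute force: enumerate every ATG in every frame, walk codon by
    codon with Biopython's translator."""
    from Bio.Seq import Seq

    best = ""
    for start in range(len(seq)):  # ascending start => ties stay leftmost
        if seq[start : start + 3] != "ATG":
            continue
        orf = []
        for i in range(start, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in ("TAA", "TAG", "TGA"):
                break
            orf.append(codon)
        peptide = str(Seq("".join(orf)).translate())
        if len(peptide) > len(best):
            best = peptide
    return best
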