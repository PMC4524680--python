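import pytest

from cargome.scan import generate_permutations
from cargome.synthetic import (
    make_expression,
    make_gene_cohort,
    make_histone_tracks,
    make_regulatory_layout,
)

# Positional slots of the CC(A/T)6GG consensus, used by the test-side
# oracles so they never consult the implementation's permutation table.
CONSENSUS_SLOTS = ("C", "C", "AT", "AT", "AT", "AT", "AT", "AT", "G", "G")


def oracle_match(window: str, max_mismatch: int):
    """Naive per-position CArG membership test (independent oracle).

    Returns (match_class, mismatch_position) or None, by counting
    positions whose base falls outside the consensus slot.
    """
    if len(window) != 10 or any(c not in "ACGT" for c in window):
        return None
    dist, mpos = 0, None
    for i, (base, slot) in enumerate(zip(window, CONSENSUS_SLOTS)):
        if base not in slot:
            dist += 1
            mpos = i + 1
    if dist == 0:
        return "consensus", None
    if dist == 1 and max_mismatch >= 1:
        return "single_mismatch", mpos
    return None


def oracle_scan(seq: str, max_mismatch: int):
    """Exhaustive positional scan of one sequence."""
    hits = []
    for p in range(len(seq) - 9):
        res = oracle_match(seq[p : p + 10], max_mismatch)
        if res is not None:
            hits.append((p, seq[p : p + 10], res[0], res[1]))
    return hits


@pytest.fixture(scope="session")
def consensus_table():
    return generate_permutations(0)


@pytest.fixture(scope="session")
def mismatch_table():
    return generate_permutations(1)


@pytest.fixture(scope="session")
def layout():
    """A 60-peak regulatory layout with designed associations."""
    return make_regulatory_layout(n_peaks=60, seed=11)


@pytest.fixture(scope="session")
def expression_data():
    """Four-sample isoform tables with designed specific genes and a
    designed unreliable transcript population."""
    return make_expression(
        n_genes=400, n_specific=10, noise_sd=0.25, seed=5, n_unreliable=200
    )


@pytest.fixture(scope="session")
def histone_cohort():
    genes = make_gene_cohort(40, seed=2)
    classes = [
        "restricted_active",
        "ubiquitous_active",
        "silenced",
        "ambiguous",
    ] * 10
    tracks, manifest = make_histone_tracks(genes, classes, seed=2)
    return genes, classes, tracks, manifest
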