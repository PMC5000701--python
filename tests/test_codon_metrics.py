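import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonuse.codon_metrics import (
    cai,
    cai_weights,
    enc,
    expected_enc,
    gc_partition,
    optimal_codons,
    preferred_codons,
    rscu,
)
from codonuse.genetic_code import CODONS, FAMILIES
from codonuse.sequence_io import CodonCountTable

# ---------------------------------------------------------------------------
# Independent oracles, written from first principles against a hardcoded
# family table so they share no code path with the implementation.

ORACLE_FAMILIES = {
    "F": ["TTT", "TTC"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "Y": ["TAT", "TAC"],
    "H": ["CAT", "CAC"],
    "Q": ["CAA", "CAG"],
    "N": ["AAT", "AAC"],
    "K": ["AAA", "AAG"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "C": ["TGT", "TGC"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
}


def oracle_wright_enc(table: CodonCountTable) -> float:
    """Brute-force Wright estimator: loop families, average F per class."""
    by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for fam in ORACLE_FAMILIES.values():
        ns = [table[c] for c in fam]
        n = sum(ns)
        if n < 2:
            continue
        f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
        if f > 0:
            by_class[len(fam)].append(f)
    fbar = {k: sum(v) / len(v) for k, v in by_class.items() if v}
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    value = 2 + 9 / fbar[2] + 1 / fbar[3] + 5 / fbar[4] + 3 / fbar[6]
    return min(max(value, 20.0), 61.0)


def oracle_position_gc(table: CodonCountTable, position: int, excluded: set[str]) -> float:
    num = den = 0
    for codon in CODONS:
        if codon in excluded:
            continue
        n = table[codon]
        den += n
        if codon[position] in "GC":
            num += n
    return num / den


def oracle_chi2_2x2(a, b, c, d) -> float:
    n = a + b + c + d
    expected = [
        [(a + b) * (a + c) / n, (a + b) * (b + d) / n],
        [(c + d) * (a + c) / n, (c + d) * (b + d) / n],
    ]
    obs = [[a, b], [c, d]]
    return sum(
        (obs[i][j] - expected[i][j]) ** 2 / expected[i][j] for i in range(2) for j in range(2)
    )


# ---------------------------------------------------------------------------
# RSCU

class TestRscu:
    def test_two_fold_family_formula(self, make_counts):
        v = rscu(make_counts({"AAA": 3, "AAG": 1}))
        assert v["AAA"] == pytest.approx(1.5)
        assert v["AAG"] == pytest.approx(0.5)

    def test_equal_usage_gives_one(self, uniform_usage_table):
        v = rscu(uniform_usage_table)
        sense = v.drop(["TAA", "TAG", "TGA"])
        assert np.allclose(sense.dropna(), 1.0)

    def test_single_codon_concentration(self, make_counts):
        v = rscu(make_counts({"AAA": 7, "AAG": 0}))
        assert v["AAA"] == pytest.approx(2.0)
        assert v["AAG"] == pytest.approx(0.0)

    def test_unobserved_family_is_missing_not_zero(self, make_counts):
        v = rscu(make_counts({"AAA": 1}))
        assert math.isnan(v["TGT"])  # Cys never observed

    def test_stop_codons_form_a_family_of_three(self, make_counts):
        v = rscu(make_counts({"TAA": 2, "TAG": 1, "TGA": 1}))
        assert v[["TAA", "TAG", "TGA"]].sum() == pytest.approx(3.0)
        assert "TAA" not in rscu(make_counts({"TAA": 2}), include_stops=False).index

    def test_preferred_codons_threshold(self, make_counts):
        v = rscu(make_counts({"AAA": 3, "AAG": 1, "TTT": 1, "TTC": 1}))
        assert preferred_codons(v) == {"AAA"}


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_rscu_family_sums_equal_degeneracy(seed):
    rng = np.random.default_rng(seed)
    counts = {c: int(rng.integers(0, 30)) for c in CODONS}
    v = rscu(CodonCountTable.from_mapping(counts))
    for aa, fam in FAMILIES.items():
        total = sum(counts[c] for c in fam)
        if total > 0:
            assert sum(v[c] for c in fam) == pytest.approx(len(fam), abs=1e-9)
        else:
            assert all(math.isnan(v[c]) for c in fam)


# ---------------------------------------------------------------------------
# GC partitions

class TestGcPartition:
    def test_all_at_codon(self, make_counts):
        part = gc_partition(make_counts({"AAA": 10}))
        assert part.p3 == 0.0 and part.gc3s == 0.0 and part.gc == 0.0

    def test_all_gc_codon(self, make_counts):
        part = gc_partition(make_counts({"GGC": 5}))
        assert (part.p1, part.p2, part.p3, part.gc3s) == (1.0, 1.0, 1.0, 1.0)

    def test_p12_is_mean_of_p1_p2(self, random_count_table):
        part = gc_partition(random_count_table())
        assert part.p12 == pytest.approx((part.p1 + part.p2) / 2)

    def test_exclusion_sets_differ_for_ata(self, make_counts):
        # ATA is dropped from P3 but kept for GC3s (Ile is synonymous)
        part = gc_partition(make_counts({"ATA": 5, "GGC": 5}))
        assert part.p3 == 1.0  # only GGC survives the P-exclusions
        assert part.gc3s == pytest.approx(0.5)  # ATA's A counts in the GC3s pool

    def test_matches_per_position_oracle(self, random_count_table):
        excl_p = {"ATG", "TGG", "ATA", "TAA", "TAG", "TGA"}
        excl_3s = {"ATG", "TGG", "TAA", "TAG", "TGA"}
        for _ in range(10):
            t = random_count_table(include_stops=True)
            part = gc_partition(t)
            assert part.p1 == pytest.approx(oracle_position_gc(t, 0, excl_p), abs=1e-12)
            assert part.p2 == pytest.approx(oracle_position_gc(t, 1, excl_p), abs=1e-12)
            assert part.p3 == pytest.approx(oracle_position_gc(t, 2, excl_p), abs=1e-12)
            assert part.gc3s == pytest.approx(oracle_position_gc(t, 2, excl_3s), abs=1e-12)

    def test_empty_after_exclusions_is_missing(self, make_counts):
        part = gc_partition(make_counts({"ATG": 4, "TGG": 2}))
        assert math.isnan(part.p1) and math.isnan(part.gc3s)


# ---------------------------------------------------------------------------
# ENc

class TestEnc:
    def test_extreme_bias_is_20(self, one_codon_per_family_table):
        assert enc(one_codon_per_family_table).enc == pytest.approx(20.0)

    def test_uniform_usage_caps_at_61(self, uniform_usage_table):
        assert enc(uniform_usage_table).enc == pytest.approx(61.0)

    def test_agrees_with_bruteforce_oracle_on_random_genes(self, rng):
        for _ in range(200):
            counts = {c: int(rng.integers(0, 25)) for c in CODONS}
            t = CodonCountTable.from_mapping(counts)
            mine = enc(t).enc
            assert mine == pytest.approx(oracle_wright_enc(t), abs=1e-9)

    def test_monotone_from_uniform_to_single_codon(self, make_counts):
        # interpolate Lys usage 30/30 -> 60/0 with other families fixed uniform
        base = {c: 20 for aa, fam in FAMILIES.items() if aa != "*" for c in fam}
        prev = math.inf
        for biased in (30, 40, 50, 60):
            base["AAA"], base["AAG"] = biased, 60 - biased
            value = enc(make_counts(base)).enc
            assert value <= prev + 1e-12
            prev = value

    def test_unscorable_gene_flagged(self, make_counts):
        result = enc(make_counts({"ATG": 10}))
        assert math.isnan(result.enc)
        assert result.note

    def test_missing_ile_imputed(self, make_counts):
        m = {FAMILIES[aa][0]: 5 for aa in "FLVSPTAYHQNKDECRG"}
        result = enc(make_counts(m))
        assert "F3 imputed" in result.note
        assert result.enc == pytest.approx(20.0)


class TestExpectedEnc:
    def test_landmark_values(self):
        assert expected_enc(0.0) == pytest.approx(31.0)
        assert expected_enc(0.5) == pytest.approx(60.5)
        assert expected_enc(1.0) == pytest.approx(32.0)

    def test_end_point_difference_is_one(self):
        assert expected_enc(1.0) - expected_enc(0.0) == pytest.approx(1.0)

    def test_matches_independent_expression_on_grid(self):
        s = np.linspace(0, 1, 201)
        independent = 2 + s + 29 * (s * s + (1 - s) * (1 - s)) ** -1.0
        assert np.allclose(expected_enc(s), independent, atol=1e-12)

    def test_maximum_near_half(self):
        # the +s term nudges the peak slightly above s = 0.5 (max ~60.5011)
        s = np.linspace(0, 1, 2001)
        values = expected_enc(s)
        assert values.max() == pytest.approx(60.5, abs=0.002)
        assert s[values.argmax()] == pytest.approx(0.5, abs=0.01)

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            expected_enc(1.2)


# ---------------------------------------------------------------------------
# CAI

class TestCai:
    def test_weights_ratio_to_family_max(self, make_counts):
        model = cai_weights([make_counts({"AAA": 90, "AAG": 10})])
        assert model.weights["AAA"] == pytest.approx(1.0)
        assert model.weights["AAG"] == pytest.approx(1 / 9)

    def test_uniform_reference_all_ones(self, uniform_usage_table):
        model = cai_weights([uniform_usage_table])
        assert np.allclose(model.weights, 1.0)

    def test_zero_count_codon_floored(self, make_counts):
        model = cai_weights([make_counts({"AAA": 8})])
        assert model.weights["AAG"] == pytest.approx(0.5 / 8)
        assert "AAG" in model.floored

    def test_absent_family_neutral_and_flagged(self, make_counts):
        model = cai_weights([make_counts({"AAA": 8})])
        assert model.weights["TGT"] == pytest.approx(1.0)
        assert "C" in model.absent_families

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            cai_weights([])

    def test_geometric_mean(self, make_counts):
        model = cai_weights([make_counts({"AAA": 4, "AAG": 1, "TTT": 4, "TTC": 4})])
        # gene of 2 codons: w = 1.0 (AAA) and 0.25 (AAG) -> sqrt(0.25) = 0.5
        assert cai(make_counts({"AAA": 1, "AAG": 1}), model) == pytest.approx(0.5)
        # gene using only w=1 codons
        assert cai(make_counts({"AAA": 3, "TTT": 2}), model) == pytest.approx(1.0)

    def test_met_trp_stops_not_scored(self, make_counts):
        model = cai_weights([make_counts({"AAA": 4, "AAG": 1})])
        with_extras = make_counts({"AAA": 2, "ATG": 5, "TGG": 5, "TAA": 1})
        assert cai(with_extras, model) == pytest.approx(1.0)

    def test_length_invariance(self, make_counts, rng):
        model = cai_weights([make_counts({c: int(rng.integers(1, 50)) for c in CODONS})])
        gene = {"AAA": 3, "AAG": 2, "TTT": 1, "CTG": 4}
        doubled = {c: 2 * n for c, n in gene.items()}
        assert cai(make_counts(gene), model) == pytest.approx(
            cai(make_counts(doubled), model), abs=1e-12
        )

    def test_no_scored_codons_is_missing(self, make_counts):
        model = cai_weights([make_counts({"AAA": 4})])
        assert math.isnan(cai(make_counts({"ATG": 3}), model))


# ---------------------------------------------------------------------------
# Optimal codons

class TestOptimalCodons:
    def test_hand_computed_contrast(self, make_counts):
        high = [make_counts({"AAA": 100, "AAG": 10})]
        low = [make_counts({"AAA": 50, "AAG": 50})]
        result = optimal_codons(high, low, alpha=0.01)
        assert "AAA" in result.optimal_set
        assert "AAG" not in result.optimal_set
        chi2 = result.table.loc["AAA", "chi2"]
        assert chi2 == pytest.approx(oracle_chi2_2x2(100, 10, 50, 50), abs=1e-9)

    def test_identical_groups_nothing_flagged(self, random_count_table):
        t = random_count_table()
        result = optimal_codons([t], [t])
        assert result.optimal_set == set()

    def test_label_swap_symmetry(self, make_counts):
        high = [make_counts({"AAA": 100, "AAG": 10, "TTT": 5, "TTC": 50})]
        low = [make_counts({"AAA": 50, "AAG": 50, "TTT": 30, "TTC": 30})]
        forward = optimal_codons(high, low)
        backward = optimal_codons(low, high)
        # swapping group labels turns the optimal set into the codons
        # enriched in the other group
        assert forward.optimal_set == {"AAA", "TTC"}
        assert backward.optimal_set == {"AAG", "TTT"}

    def test_degenerate_table_skipped(self, make_counts):
        result = optimal_codons([make_counts({"AAA": 10})], [make_counts({"AAA": 5})])
        assert bool(result.table.loc["AAA", "skipped"])

    def test_empty_group_rejected(self, make_counts):
        with pytest.raises(ValueError):
            optimal_codons([], [make_counts({"AAA": 1})])
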