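import numpy as np
import pytest

from codonuse.genetic_code import CODONS, ENC_CLASSES, FAMILIES
from codonuse.sequence_io import CodonCountTable


@pytest.fixture
def rng():
    return np.random.default_rng(20160810)


@pytest.fixture
def make_counts():
    def _make(mapping, label="test"):
        return CodonCountTable.from_mapping(mapping, label)

    return _make


@pytest.fixture
def random_count_table(rng):
    """Factory for random count tables covering every sense family."""

    def _make(max_count=40, label="rand", include_stops=False, rng=rng):
        counts = {}
        for aa, fam in FAMILIES.items():
            if aa == "*" and not include_stops:
                continue
            for c in fam:
                counts[c] = int(rng.integers(0, max_count))
        return CodonCountTable.from_mapping(counts, label)

    return _make


@pytest.fixture
def one_codon_per_family_table(make_counts):
    """Extreme bias: a single codon used (n=3) in every ENc-scored family."""
    m = {FAMILIES[aa][0]: 3 for aas in ENC_CLASSES.values() for aa in aas}
    return make_counts(m, "one-per-family")


@pytest.fixture
def uniform_usage_table(make_counts):
    """No bias: every sense codon observed exactly 12 times."""
    m = {c: 12 for aa, fam in FAMILIES.items() if aa != "*" for c in fam}
    return make_counts(m, "uniform")
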