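import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from codonscreen import (
    CodonUsageTable,
    default_usage_table,
)
from codonscreen.codon_engine import SENSE_CODONS, SYNONYMOUS_FAMILIES


@pytest.fixture(scope="session")
def dmel_table() -> CodonUsageTable:
    return default_usage_table()


@pytest.fixture(scope="session")
def gly_table() -> CodonUsageTable:
    """Full 61-codon table, uniform everywhere except the Gly family
    {GGA: 0.2, GGC: 0.4, GGG: 0.2, GGT: 0.2}.
    """
    usage = {}
    for codons in SYNONYMOUS_FAMILIES.values():
        for c in codons:
            usage[c] = 1.0 / len(codons)
    usage.update({"GGA": 0.2, "GGC": 0.4, "GGG": 0.2, "GGT": 0.2})
    total = sum(usage.values())
    return CodonUsageTable(
        "gly-test", usage, {c: usage[c] / total for c in SENSE_CODONS}
    )


@pytest.fixture(scope="session")
def uniform_table() -> CodonUsageTable:
    usage = {}
    for codons in SYNONYMOUS_FAMILIES.values():
        for c in codons:
            usage[c] = 1.0 / len(codons)
    total = sum(usage.values())
    return CodonUsageTable(
        "uniform", usage, {c: usage[c] / total for c in SENSE_CODONS}
    )


def random_table(rng: np.random.Generator) -> CodonUsageTable:
    """Random valid usage table for property tests."""
    usage = {}
    for codons in SYNONYMOUS_FAMILIES.values():
        weights = rng.uniform(0.05, 1.0, size=len(codons))
        weights /= weights.sum()
        for c, w in zip(codons, weights):
            usage[c] = float(w)
    total = sum(usage.values())
    return CodonUsageTable(
        "random", usage, {c: usage[c] / total for c in SENSE_CODONS}
    )
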