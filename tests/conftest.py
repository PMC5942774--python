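"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths: the
genetic code is taken straight from Biopython's tables and the statistics
are computed by literal enumeration, so they can serve as independent
cross-checks.
"""

import math

import numpy as np
import pytest
from Bio.Data import CodonTable

from cibkit.codons import load_genetic_code


@pytest.fixture(scope="session")
def code():
    return load_genetic_code(11)


def brute_force_cib_components(counts: dict[str, int], base: float = math.e):
    """Independent CIB numerator/denominator by family enumeration.

    Builds its own codon->amino-acid map from Biopython and evaluates the
    weighted Kullback-Leibler divergence from uniform synonymous usage
    term by term: KL_a = sum_c q(c|a) * log(q(c|a) * n(a)).
    """
    fwd = CodonTable.unambiguous_dna_by_id[11].forward_table
    families: dict[str, list[str]] = {}
    for codon, aa in fwd.items():
        families.setdefault(aa, []).append(codon)
    total = sum(counts.values())
    num = 0.0
    den = 0.0
    for aa, fam in families.items():
        aa_count = sum(counts.get(c, 0) for c in fam)
        if aa_count == 0 or len(fam) == 1:
            continue
        p_a = aa_count / total
        kl = 0.0
        for c in fam:
            q = counts.get(c, 0) / aa_count
            if q > 0:
                kl += q * math.log(q * len(fam), base)
        num += p_a * kl
        den += p_a * math.log(len(fam), base)
    return num, den


def brute_force_cib(counts: dict[str, int], base: float = math.e) -> float:
    num, den = brute_force_cib_components(counts, base)
    return num / den if den > 0 else float("nan")


def ad_continuous_double_sum(x, y) -> float:
    """Direct double-sum evaluation of the continuous k=2 AD statistic.

    A = (1/N) * sum_i (1/n_i) * sum_{j=1}^{N-1} (N*M_ij - j*n_i)^2 / (j*(N-j))
    over the pooled sorted points, assuming no ties.
    """
    pooled = sorted(list(x) + list(y))
    N = len(pooled)
    assert len(set(pooled)) == N, "oracle assumes untied data"
    total = 0.0
    for sample in (x, y):
        n_i = len(sample)
        inner = 0.0
        for j in range(1, N):
            m_ij = sum(1 for v in sample if v <= pooled[j - 1])
            inner += (N * m_ij - j * n_i) ** 2 / (j * (N - j))
        total += inner / n_i
    return total / N


def random_count_table(rng: np.random.Generator, max_aas: int = 20,
                       max_count: int = 50) -> dict[str, int]:
    """A random sense-codon count table over a random amino-acid subset."""
    fwd = CodonTable.unambiguous_dna_by_id[11].forward_table
    families: dict[str, list[str]] = {}
    for codon, aa in fwd.items():
        families.setdefault(aa, []).append(codon)
    aas = rng.choice(sorted(families), size=rng.integers(1, max_aas + 1),
                     replace=False)
    counts = {}
    for aa in aas:
        for c in families[aa]:
            n = int(rng.integers(0, max_count + 1))
            if n:
                counts[c] = n
    if not counts:  # ensure at least one codon
        counts["GGA"] = 1
    return counts
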