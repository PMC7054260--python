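"""Shared fixtures: small synthetic corpora and hand-built call matrices."""

from __future__ import annotations

import math
from fractions import Fraction

import pandas as pd
import pytest

from phenorules import CallMatrix, SimulationConfig, generate_call_matrix


def exact_fisher_two_tailed(n11: int, n10: int, n01: int, n00: int) -> float:
    """Brute-force two-tailed Fisher p by exact rational enumeration.

    Enumerates every table with the observed margins, computes each
    table's hypergeometric probability as an exact integer numerator over
    the common denominator C(N, c1), and sums those no more probable than
    the observed table.  Pure integer arithmetic: an independent oracle
    for the float implementation.
    """
    r1 = n11 + n10
    r2 = n01 + n00
    c1 = n11 + n01
    N = r1 + r2
    if N == 0 or r1 == 0 or r1 == N or c1 == 0 or c1 == N:
        return 1.0
    kmin = max(0, c1 - r2)
    kmax = min(r1, c1)
    numerators = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(kmin, kmax + 1)}
    obs = numerators[n11]
    total = sum(v for v in numerators.values() if v <= obs)
    return float(Fraction(total, math.comb(N, c1)))


@pytest.fixture(scope="session")
def small_null_matrix() -> CallMatrix:
    """60 phenotypes x 400 strains, no planted structure."""
    cm, _ = generate_call_matrix(
        SimulationConfig(n_phenotypes=60, n_strains=400, planted_pairs=[], seed=11)
    )
    return cm


@pytest.fixture(scope="session")
def planted_matrix():
    """40 phenotypes x 2000 strains with 10 strongly coupled pairs."""
    pairs = [(2 * i, 2 * i + 1, 5.0) for i in range(10)]
    cfg = SimulationConfig(
        n_phenotypes=40, n_strains=2000, planted_pairs=pairs, seed=5
    )
    return generate_call_matrix(cfg)


@pytest.fixture
def tiny_calls() -> CallMatrix:
    """Hand-built 2-phenotype matrix matching the worked cross-table example."""
    df = pd.DataFrame(
        {
            "s1": ["A", "A"],
            "s2": ["A", "N"],
            "s3": ["N", "A"],
            "s4": ["N", "N"],
            "s5": ["NT", "A"],
            "s6": ["A", "NT"],
        },
        index=["X", "Y"],
    )
    return CallMatrix(df)
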