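import numpy as np
import pandas as pd
import pytest

from retqtl.sim import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default desk-scale two-tissue cohort, shared across tests."""
    return simulate_cohort(SimConfig(seed=42))


@pytest.fixture(scope="session")
def nsr_bundle(small_cohort):
    return small_cohort.bundles["NSR"]


def hwe_enumeration_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-rational brute-force HWE p-value by enumerating het counts.

    Conditional on allele counts, P(het = h) is proportional to
    2^h / (hom_rare! h! hom_common!); all arithmetic is exact Fractions so
    tie decisions are unambiguous.
    """
    from fractions import Fraction
    from math import factorial

    n = n_hom_ref + n_het + n_hom_alt
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0
    weights = {}
    for h in range(n_rare % 2, n_rare + 1, 2):
        hom_rare = (n_rare - h) // 2
        hom_common = n - h - hom_rare
        weights[h] = Fraction(2**h, factorial(hom_rare) * factorial(h) * factorial(hom_common))
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))
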