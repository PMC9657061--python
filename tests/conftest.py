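import pytest

from isawtheta import enumerate_bruteforce, enumerate_reduced


@pytest.fixture(scope="session")
def reduced_tables():
    """Symmetry-reduced tables for N = 1..13 (shared; ~1 s of enumeration)."""
    return {n: enumerate_reduced(n) for n in range(1, 14)}


@pytest.fixture(scope="session")
def brute_tables():
    """Naive-oracle tables for N = 1..8."""
    return {n: enumerate_bruteforce(n) for n in range(1, 9)}
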