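import pytest

from coidiet.simulate import simulate_reference_db


@pytest.fixture(scope="session")
def small_refdb():
    """20-species synthetic reference (tree + sequences + taxonomy)."""
    refdb, truth = simulate_reference_db(n_species=20, seq_len=120, seed=3)
    return refdb, truth


@pytest.fixture(scope="session")
def refdb50():
    """50-species synthetic reference used by the placement stress tests."""
    refdb, truth = simulate_reference_db(n_species=50, seq_len=130, seed=1)
    return refdb, truth
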