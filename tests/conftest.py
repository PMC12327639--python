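import numpy as np
import pytest

from contactgo import synthetic_data as sd


@pytest.fixture(scope="session")
def small_benchmark():
    """A 40-protein benchmark, shared across tests that only read it."""
    return sd.build_benchmark(sd.SyntheticConfig(n_proteins=40, seed=1))


@pytest.fixture()
def tiny_graph():
    """One deterministic 5-residue protein graph with features and labels."""
    cfg = sd.SyntheticConfig(n_proteins=1, length_range=(5, 5), seed=3)
    return sd.generate_protein("TINY", cfg, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
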