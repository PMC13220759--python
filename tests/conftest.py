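import numpy as np
import pytest

from epiburden import simulate


@pytest.fixture(scope="session")
def small_cohort():
    """Small null cohort reused across IO / round-trip tests."""
    return simulate.simulate_background(
        n_samples=120,
        n_genes=40,
        n_pairs=150,
        seed=20240915,
        # denser than the experiment defaults so that even 60 cases carry
        # enough co-mutated pairs for a toy end-to-end fit
        variants_per_bp=1.0 / 60.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
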