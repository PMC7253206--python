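import numpy as np
import pandas as pd
import pytest

from cistrans import classify, simulate


UNIFORM_MIX = {c: 1.0 / 6.0 for c in simulate.CATEGORIES}


@pytest.fixture(scope="session")
def uniform_sim():
    """150 genes, 25 per category, the study's count structure (seeded)."""
    cfg = simulate.SimulationConfig(
        n_genes=150, seed=5, category_mix=dict(UNIFORM_MIX)
    )
    profile, truth = simulate.simulate_ase_counts(cfg)
    return profile, truth


@pytest.fixture(scope="session")
def uniform_calls(uniform_sim):
    """Classifier output on the uniform-mix simulation (computed once)."""
    profile, truth = uniform_sim
    calls = classify.classify_all(profile)
    return calls, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
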