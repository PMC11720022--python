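import numpy as np
import pandas as pd
import pytest

from interactome.synthio import SimulationConfig, generate_bundle


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast, fully-featured cohort for cross-module tests."""
    return SimulationConfig(
        n_genes=120,
        n_samples=60,
        n_pairs=40,
        n_planted_per_axis=2,
        noise_sigma=0.05,
        n_prognostic=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_profiles(e_tumor, e_stroma, genes=None) -> pd.DataFrame:
    genes = genes or [f"g{i}" for i in range(len(e_tumor))]
    return pd.DataFrame(
        {"e_tumor": e_tumor, "e_stroma": e_stroma},
        index=pd.Index(genes, name="gene"),
    )
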