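import numpy as np
import pandas as pd
import pytest

from phenosig import SyntheticConfig, simulate_cohort


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A reduced cohort for fast unit tests (same structure as default)."""
    base = dict(
        n_sensitive=25,
        n_resistant=25,
        n_discordant=10,
        n_genes=250,
        n_signature_up=8,
        n_signature_down=8,
        seed=seed,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config(seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort, shared across tests that need the real scale."""
    return simulate_cohort(SyntheticConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def labels_series(cohort) -> pd.Series:
    """Truth labels restricted to the two modelled classes."""
    lab = cohort.truth_labels
    return lab[lab != "discordant"].astype(str)
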