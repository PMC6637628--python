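import numpy as np
import pandas as pd
import pytest

from microtraj import AbundanceProfile, SampleMetadata, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced cohort (4 groups x 4 rats x 5 TPs, 60 species) for fast tests."""
    return SimConfig(
        n_rats_per_group=4,
        n_species=60,
        n_signal_species=3,
        n_drift_species=12,
        n_modules=8,
        kos_per_module=3,
        n_background_kos=10,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size study cohort (4 x 7 x 5, 200 species)."""
    return simulate_cohort(SimConfig(seed=42))


@pytest.fixture()
def toy_profile() -> AbundanceProfile:
    data = pd.DataFrame(
        {
            "k__B|s__A": [50.0, 25.0, 0.0, 10.0],
            "k__B|s__B": [50.0, 75.0, 0.0, 40.0],
            "k__B|s__C": [0.0, 0.0, 100.0, 50.0],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return AbundanceProfile(data)


@pytest.fixture()
def toy_metadata() -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "rat_id": ["r1", "r1", "r2", "r2"],
                "group": ["normal", "normal", "model", "model"],
                "timepoint": ["TP1", "TP2", "TP1", "TP2"],
                "weight": [60.0, 80.0, 61.0, 79.0],
                "arthritis_score": [0.0, 0.0, 2.0, 5.0],
            }
        )
    )


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
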