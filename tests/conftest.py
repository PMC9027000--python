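import numpy as np
import pytest

import sterolkin as sk


@pytest.fixture(scope="session")
def reference():
    return sk.REFERENCE_COEFFICIENTS


@pytest.fixture(scope="session")
def full_grid_dataset(reference):
    """Noise-free dataset on the full factorial grid with 72-day series for
    every water activity (13 sampling times each), single replicate."""
    design = sk.build_storage_design(
        temperatures=(12.0, 18.0, 24.0, 30.0),
        water_activities=(0.75, 0.80, 0.85, 0.90),
        sampling_interval=6.0,
        replicates=1,
        duration_rule=lambda aw: 72.0,
    )
    return sk.simulate_degradation(design, reference, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def paper_count_dataset(reference):
    """A dataset whose role counts reproduce 243/108/117 after the 70:30 split:
    12 experiments of 72 days in triplicate (9 build = 351 rows, 3 validation
    = 117 rows)."""
    design = sk.build_storage_design(
        temperatures=(12.0, 18.0, 24.0, 30.0),
        water_activities=(0.75, 0.78, 0.81),
        sampling_interval=6.0,
        replicates=3,
        validation_conditions=[(30.0, 0.75), (30.0, 0.78), (30.0, 0.81)],
    )
    return sk.simulate_degradation(design, reference, noise_sd=0.1, seed=42)


@pytest.fixture(scope="session")
def split_dataset(paper_count_dataset):
    return sk.split_learning_test(paper_count_dataset, 0.7, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
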