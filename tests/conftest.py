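import numpy as np
import pandas as pd
import pytest

from retscreen import SimulationConfig, cohort_to_frames, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    """A 300-patient cohort at defaults, shared across tests."""
    recs = simulate_cohort(SimulationConfig(n_patients=300, seed=11))
    return cohort_to_frames(recs)


@pytest.fixture(scope="session")
def noise_free_config() -> SimulationConfig:
    """Degenerate generator: every rater reproduces the truth exactly and
    every image is gradable."""
    return SimulationConfig(
        n_patients=150,
        seed=5,
        expert_noise_sd=(0.0, 0.0, 0.0),
        ai_bias=0.0,
        ai_noise_sd=0.0,
        resident_slope=1.0,
        resident_noise_sd=0.0,
        gradability_rates={"ai": 1.0, "expert": 1.0, "resident": 1.0, "ai_retinal": 1.0},
        ungated_ai_extra_noise_sd=0.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
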