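import numpy as np
import pytest

from cometpool.model_core import preset_params
from cometpool.synthetic_data import CohortSpec, NoiseModel, generate_cohort


@pytest.fixture(scope="session")
def disassembly_deduced():
    return preset_params("disassembly_deduced")


@pytest.fixture(scope="session")
def recycling_deduced():
    return preset_params("recycling_deduced")


@pytest.fixture(scope="session")
def noiseless_recycling_cohort():
    """Small noiseless recycling cohort shared by recovery tests."""
    spec = CohortSpec(
        preset="recycling",
        n_tracks=2,
        duration_h=10.0,
        noise=NoiseModel(observation_cv=0.0, param_cv=0.0, frame_interval_min=5.0, seed=11),
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def noisy_recycling_cohort():
    """16-track recycling cohort with 10% observation noise."""
    spec = CohortSpec(
        preset="recycling",
        n_tracks=16,
        duration_h=10.0,
        noise=NoiseModel(observation_cv=0.10, param_cv=0.0, frame_interval_min=5.0, seed=7),
    )
    return generate_cohort(spec)
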