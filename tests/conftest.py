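import numpy as np
import pytest

from focalspike.epoching import EpochingConfig
from focalspike.synth import SynthCohortConfig, simulate_cohort


def scaled_cohort_config(**overrides) -> SynthCohortConfig:
    """Desk-scale cohort: short recordings, modest per-patient IED counts."""
    defaults = dict(
        n_frontal=2,
        n_temporal=2,
        n_occipital=2,
        n_controls=4,
        recording_duration_s=60.0,
        ieds_per_patient_mean={"frontal": 8.0, "temporal": 8.0, "occipital": 8.0},
        seed=11,
    )
    defaults.update(overrides)
    return SynthCohortConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    """2+2+2 patients and 4 controls, 60-s recordings, ~8 IEDs per patient."""
    return simulate_cohort(scaled_cohort_config())


@pytest.fixture(scope="session")
def occipital_subject(tiny_cohort):
    return next(s for s in tiny_cohort if s.metadata["region"] == "occipital")


@pytest.fixture()
def epoch_config():
    return EpochingConfig(augment_factor=3, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
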