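import numpy as np
import pytest

from typoclust.config import ExperimentConfig
from typoclust.pipeline import prepare_feature_map, run_m1
from typoclust.simulate import CohortSpec, TypologyEffect, generate_cohort

# strongly separated fear-response typologies used wherever a test needs
# clean latent structure
STRONG_EFFECTS = (
    TypologyEffect(30.0, 8.0, 1.2, -0.5),
    TypologyEffect(2.0, 0.5, 0.05, 0.0),
    TypologyEffect(-18.0, 4.0, 0.5, 0.4),
    TypologyEffect(14.0, 2.0, 0.8, 0.2),
)


def strong_spec(n_volunteers=12, n_typologies=3, stimuli=8, duration=30.0, seed=7,
                **kw):
    return CohortSpec(
        n_volunteers=n_volunteers,
        n_typologies=n_typologies,
        stimuli_per_volunteer=stimuli,
        stimulus_duration=duration,
        typology_effects=STRONG_EFFECTS[:n_typologies],
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def small_spec():
    return strong_spec()


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_config():
    return ExperimentConfig(n_volunteers=12, n_typologies=3,
                            stimuli_per_volunteer=8, stimulus_duration=30.0)


@pytest.fixture(scope="session")
def feature_map(small_cohort, small_config):
    """Volunteer-normalized feature map of the shared small cohort."""
    return prepare_feature_map(small_cohort, small_config)


@pytest.fixture(scope="session")
def m1_result(small_cohort, small_config):
    """Full M1 + M2 fit on the shared cohort, no holdout."""
    return run_m1(small_cohort, small_config, seed=7, holdout=False)


@pytest.fixture(scope="session")
def truth_of(small_cohort):
    return {r.volunteer_id: r.typology_truth for r in small_cohort}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
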