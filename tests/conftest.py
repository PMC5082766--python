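import numpy as np
import pytest

from adipobrain import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (473 subjects, 10-year true shift)."""
    return generate_cohort(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort generated with no group difference (zero age shift)."""
    return generate_cohort(GeneratorConfig(seed=2, true_age_shift=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
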