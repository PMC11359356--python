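import numpy as np
import pytest

from articulab.profiles import (
    ArticulationClass,
    ClassProfile,
    CohortConfig,
    Sibilant,
    make_default_profiles,
)
from articulab.synthcorpus import generate_cohort


@pytest.fixture(scope="session")
def s_profiles():
    return make_default_profiles(Sibilant.S)


@pytest.fixture(scope="session")
def sh_profiles():
    return make_default_profiles(Sibilant.SH)


@pytest.fixture(scope="session")
def tiny_s_config():
    """A miniature /s/ cohort configuration for fast pipeline tests."""
    return CohortConfig(
        sibilant=Sibilant.S,
        group_sizes={
            ArticulationClass.DENTAL: 4,
            ArticulationClass.INTERDENTAL: 3,
        },
        words_per_speaker=2,
        segment_duration_range_s=(0.12, 0.2),
        seed=123,
    )


@pytest.fixture(scope="session")
def tiny_s_cohort(tiny_s_config):
    return generate_cohort(tiny_s_config)


@pytest.fixture(scope="session")
def tiny_corpus_dir(tiny_s_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("corpus")
    generate_cohort(tiny_s_config, out_dir=out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
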