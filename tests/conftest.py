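import numpy as np
import pytest

from tsldmf.data import build_observations, fit_minmax
from tsldmf.simulate import draw_subject_profile, generate_subject_sequence


@pytest.fixture(scope="session")
def walk_profile():
    return draw_subject_profile("S01", np.random.default_rng(11))


@pytest.fixture(scope="session")
def short_recordings(walk_profile):
    """Five short walking recordings from one synthetic subject."""
    return [generate_subject_sequence(walk_profile, "walk", duration_s=8.0,
                                      seed=100 + i) for i in range(5)]


@pytest.fixture(scope="session")
def cohort_scaling(short_recordings):
    return fit_minmax(short_recordings)


@pytest.fixture(scope="session")
def short_observations(short_recordings, cohort_scaling):
    return [build_observations(r, cohort_scaling) for r in short_recordings]
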