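import numpy as np
import pytest

from movecoda.clpm import build_model_frame
from movecoda.synthgen import GeneratorParams, generate_cohort

#: Reference geometric-mean composition used across tests (min/day,
#: V/M/L/SB/Sl); sums to 1441 so closure is exercised.
CENTRE = (10.0, 55.0, 346.0, 512.0, 518.0)


@pytest.fixture(scope="session")
def cohort_201():
    """A fixed analytical-sample-sized synthetic cohort."""
    return generate_cohort(GeneratorParams(n=201, seed=20240901))


@pytest.fixture(scope="session")
def model_frame_201(cohort_201):
    return build_model_frame(cohort_201)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
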