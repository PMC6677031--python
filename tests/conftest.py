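import warnings

import numpy as np
import pytest

from tapmark.pipeline import make_fixtures
from tapmark.simulate import generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small deterministic cohort shared across tests (3 subjects/group,
    5-s waveforms, 40 volumes)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_cohort(make_fixtures("tiny", seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
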