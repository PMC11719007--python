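import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-patient synthetic cohort shared across tests."""
    from riskpipe.synthetic import CohortSpec, generate_cohort

    return generate_cohort(CohortSpec(n_patients=24, seed=11))


@pytest.fixture()
def disk_mask():
    """Centered rasterized disk of radius 12 in a 64x64 frame."""
    yy, xx = np.indices((64, 64))
    return (yy - 32) ** 2 + (xx - 32) ** 2 <= 12 ** 2
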