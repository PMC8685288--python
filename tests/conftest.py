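import logging

import pytest

from gistcea.model import default_model

# perturbed curves legitimately produce PFS>OS clamping; keep test logs quiet
logging.getLogger("gistcea").setLevel(logging.ERROR)
logging.getLogger("gistcea.cohort").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def calibrated_model():
    """Base-case model with the occupancy fixture (shared, read-only)."""
    return default_model(calibrated=True)


@pytest.fixture(scope="session")
def raw_model():
    """Base-case model evaluated from the pure Weibull traces."""
    return default_model(calibrated=False)
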