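import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from _oracles import make_timeline  # noqa: E402


@pytest.fixture
def patient_a():
    """Continuing patient: index visit at day 0, returns at days 14 and 30,
    next appointment still pending at the cutoff."""
    return make_timeline(
        "A", visits=[0, 14, 30], kept=[], pending=[75], cutoff=130
    )


@pytest.fixture
def patient_c():
    """Discontinuing patient: visits at 0/20/40, misses the day-60
    appointment and never returns within the 60-day threshold."""
    return make_timeline("C", visits=[0, 20, 40], missed=[60], cutoff=130)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
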