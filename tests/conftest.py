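from datetime import datetime

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from deskbreak import EpochSeries

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[
        HealthCheck.too_slow,
        # make_series is a stateless factory, safe to share across examples
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("default")

START = datetime(2024, 1, 8, 9, 0)


@pytest.fixture
def make_series():
    """Build an EpochSeries from a plain array of counts (15 s grid)."""

    def _make(cpe, start=START, epoch_length_s=15):
        return EpochSeries.from_counts(start, np.asarray(cpe), epoch_length_s)

    return _make
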