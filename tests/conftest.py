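import numpy as np
import pytest

from audphon import ObserverProfile


@pytest.fixture
def make_profile():
    """Factory for observer profiles with sensible defaults."""

    def _make(**kw):
        defaults = dict(
            participant_id="obs-001",
            group="control",
            rtd_x707_ms=60.0,
            rtd_width_log=0.3,
            id_midpoint=5.5,
            id_width=1.0,
            id_guess=0.05,
            id_lapse=0.02,
            hearing_fletcher_db=30.0,
            cognition_z=0.0,
            phonology_screeling=20.0,
            fluency_count=15,
        )
        defaults.update(kw)
        return ObserverProfile(**defaults)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
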