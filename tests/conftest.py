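import numpy as np
import pytest

from swisc.io import ROLES, Recording
from swisc.synth import SynthConfig, generate_subject


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def short_recording(rng):
    """10 s, 4-channel, 2 kHz recording of colored noise."""
    n = 20_000
    signals = rng.standard_normal((4, n))
    return Recording(signals=signals, rate=2000.0, roles=ROLES,
                     subject_id="m01")


@pytest.fixture(scope="session")
def small_subject():
    """A short synthetic subject whose seeded track visits all five states
    (session-cached)."""
    cfg = SynthConfig(hours=0.3, seed=8, seizure_rate_per_h=6.0)
    rec, track, labels = generate_subject(cfg, "m-synth", seed=8)
    return cfg, rec, track, labels
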