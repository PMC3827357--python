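import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from finstart import synth  # noqa: E402
from finstart.fusion import FusionParams, fuse  # noqa: E402


@pytest.fixture(scope="session")
def event_sim():
    """A medium synthetic track with 6 escape + 6 feeding events (session
    scope: simulation plus fusion is the expensive part of the suite)."""
    events = synth.schedule_events(6, 6, spacing=2.6, seed=11)
    params = synth.SimParams(
        duration=events[-1][0] + 3.0, events=events, seed=11
    )
    rec, truth = synth.simulate(params)
    return params, rec, truth


@pytest.fixture(scope="session")
def fused_event_sim(event_sim):
    params, rec, truth = event_sim
    return params, rec, truth, fuse(rec, FusionParams())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
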