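import pytest
from hypothesis import HealthCheck, settings

from tsi import AreaScheme, BrushingEvent, BrushingSession

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scheme_all():
    return AreaScheme.all_areas()


@pytest.fixture
def complete_session(scheme_all):
    """Complete isochronal reference session: each of the 16 areas visited
    once for 210/16 s, giving 15 changes over 210 s."""
    dwell = 210.0 / 16
    events = [
        BrushingEvent(onset=j * dwell, offset=(j + 1) * dwell, area=area)
        for j, area in enumerate(scheme_all)
    ]
    return BrushingSession(events)


def make_session(area_sequence, duration=10.0, gap=0.0):
    """Contiguous (or gapped) unit-duration session over the given areas."""
    events = []
    t = 0.0
    for area in area_sequence:
        events.append(BrushingEvent(onset=t, offset=t + duration, area=area))
        t += duration + gap
    return BrushingSession(events)
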