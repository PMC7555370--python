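import numpy as np
import pytest

from neoqeeg import bandpass, detect_seizures
from neoqeeg.syngen import Segment, StateSchedule, compose_recording


@pytest.fixture(scope="session")
def seizure_recording():
    """A 10-min, 9-lead recording with one scheduled 7 Hz seizure at 240-300 s."""
    schedule = StateSchedule([
        Segment("continuous", 0.0, 240.0),
        Segment("seizure", 240.0, 60.0),
        Segment("continuous", 300.0, 300.0),
    ])
    recording, truth = compose_recording(schedule, n_leads=9, seed=42)
    return recording, truth


@pytest.fixture(scope="session")
def detected_events(seizure_recording):
    recording, _ = seizure_recording
    return detect_seizures(bandpass(recording))


def interval_jaccard(a: tuple[float, float], b: tuple[float, float]) -> float:
    inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union > 0 else 0.0


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
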