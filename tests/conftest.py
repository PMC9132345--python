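import numpy as np
import pytest

from spiketypes.session import SpikeTrain, StimulusDescriptor, UnitRecording
from spiketypes.synth import generate_benchmark_session


@pytest.fixture(scope="session")
def bench_session():
    """Full-protocol benchmark session used by the closed-loop tests."""
    return generate_benchmark_session(
        {"RS": 16, "FS": 10, "Bu1": 7, "Bu2": 7}, rng_seed=1
    )


@pytest.fixture(scope="session")
def pattern_session():
    """Timing-protocol session used by the temporal-coding pattern tests."""
    return generate_benchmark_session(
        {"RS": 18, "FS": 4, "Bu1": 8, "Bu2": 8},
        protocols=("duration_series", "SAM_series", "vocal_list"),
        rng_seed=2,
    )


@pytest.fixture
def tiny_unit():
    """One unit, one stimulus, two trials, with a prestimulus epoch."""
    stim = StimulusDescriptor(stimulus_id="S1", kind="tone", duration=0.2)
    trains = [
        SpikeTrain(np.array([-0.15, 0.02, 0.05]), (-0.2, 0.5), "S1", 0),
        SpikeTrain(np.array([-0.19, -0.01, 0.03]), (-0.2, 0.5), "S1", 1),
    ]
    return UnitRecording(
        unit_id="u0", trains=trains, stimuli={"S1": stim}, prestim_duration=0.2
    )
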