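import pytest

from hyposcape.config import SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """A scaled-down study used by fast unit tests."""
    return SimulationConfig(
        seed=11,
        n_transcripts=400,
        n_windows=600,
        cnv_segments=((100, 180, 2), (350, 450, 4)),
        n_patients=30,
    )


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7)
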