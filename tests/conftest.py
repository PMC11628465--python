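import numpy as np
import pytest

from microsig.flow import EventTable
from microsig.synthetic import default_design, simulate_event_sample


@pytest.fixture(scope="session")
def design():
    return default_design(seed=7)


@pytest.fixture(scope="session")
def ig_events(design):
    """A mixed immunoglobulin-panel event cloud (5000 events)."""
    return simulate_event_sample(
        design, design.base_weights["immunoglobulin"], "immunoglobulin",
        5000, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_events(intensities, panel="immunoglobulin", sample_id="s1"):
    from microsig.flow import PANEL_CHANNELS

    intensities = np.asarray(intensities, dtype=float)
    return EventTable(sample_id=sample_id, panel=panel,
                      channels=list(PANEL_CHANNELS[panel]),
                      intensities=intensities)
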