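import numpy as np
import pytest

from neuroculture.containers import SpikeTrain
from neuroculture.synthdata import (
    MEARenderConfig,
    NetworkSimConfig,
    simulate_spike_trains,
)


@pytest.fixture(scope="session")
def burster_truth():
    """Default bursting-network ground truth (Chx10-like)."""
    return simulate_spike_trains(NetworkSimConfig(seed=11))


@pytest.fixture(scope="session")
def tonic_truth():
    """Default tonic-population ground truth (HB9-like)."""
    return simulate_spike_trains(NetworkSimConfig(phenotype="tonic", seed=12))


@pytest.fixture(scope="session")
def coculture_truth():
    """Mixed 5:2 tonic:burster culture with silent cells."""
    return simulate_spike_trains(
        NetworkSimConfig(phenotype="mixture", n_units=21, silent_fraction=0.2, seed=13)
    )


def truth_to_trains(truth):
    return [
        SpikeTrain(times=t, duration=truth.duration, channel_id=f"u{i}")
        for i, t in enumerate(truth.unit_times)
    ]


@pytest.fixture(scope="session")
def small_render():
    """A 4-unit, 10 s rendered recording plus its ground truth."""
    from neuroculture.synthdata import render_mea

    truth = simulate_spike_trains(NetworkSimConfig(n_units=4, duration=10.0, seed=2))
    rec = render_mea(truth, MEARenderConfig(n_electrodes=4, seed=3))
    return truth, rec
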