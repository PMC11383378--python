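import numpy as np
import pytest

from psiacx import make_tone_protocol
from psiacx.fluorescence import CellTraces
from psiacx.synthetic import SynthNeuralConfig, simulate_experiment


@pytest.fixture(scope="session")
def protocol10():
    """The canonical 10-frequency protocol (2-45 kHz, 2 tones/octave, 20 reps)."""
    return make_tone_protocol(2, 45, 2, repeats=20, seed=0)


@pytest.fixture(scope="session")
def small_protocol():
    """A fast 4-frequency protocol with short ISIs for unit tests."""
    return make_tone_protocol(4, 32, 1, repeats=5, isi_choices_s=(5.0,), seed=1)


@pytest.fixture(scope="session")
def noiseless_experiment(small_protocol):
    """A deterministic-amplitude experiment (no trial noise)."""
    cfg = SynthNeuralConfig(
        n_neurons=6,
        trial_noise_sd=0.0,
        condition_gain={"Pre": 1.0},
        seed=11,
    )
    return simulate_experiment(cfg, small_protocol)


def corrected_traces(session, frame_rate=30.0, coeff=0.7):
    return CellTraces(
        C_raw=session.raw_somatic, N=session.neuropil, frame_rate_hz=frame_rate
    ).corrected(coeff)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
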