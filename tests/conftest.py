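import numpy as np
import pytest

import cawave as cw


@pytest.fixture(scope="session")
def noiseless_truth():
    """Clean two-filter experiment truth: no noise, no shifts, no bleaching."""
    return cw.make_truth(
        (96, 96),
        velocity=5.0,
        amplitude=0.5,
        tau=20.0,
        stimulus_frame=10,
        frame_period=1.25,
        noise_sigma=0.0,
        decay_340=np.inf,
        decay_380=np.inf,
    )


@pytest.fixture(scope="session")
def noiseless_seq(noiseless_truth):
    seq, _ = cw.generate_experiment(
        (96, 96), n_frames=40, frame_period=1.25, truth=noiseless_truth, seed=7
    )
    return seq


@pytest.fixture(scope="session")
def default_truth():
    """Study-condition experiment: default noise, texture and bleaching."""
    return cw.make_truth((96, 96), velocity=5.0, stimulus_frame=10, frame_period=1.25)


@pytest.fixture(scope="session")
def default_seq(default_truth):
    seq, _ = cw.generate_experiment(
        (96, 96), n_frames=40, frame_period=1.25, truth=default_truth, seed=11
    )
    return seq


@pytest.fixture(scope="session")
def calibrated(noiseless_seq):
    return cw.calibrate(noiseless_seq, register=False, decay_correct=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
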