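import numpy as np
import pytest

from pmkit import synthgen as sg


@pytest.fixture
def humanoid_labels():
    return sg.humanoid_labels()


@pytest.fixture
def humanoid_base():
    return sg.humanoid_base_posture()


def make_planted_model(n_modes=3, variances=(10.0, 3.0, 1.0), noise_sd=0.0,
                       duration=10.0, sampling_rate=100.0, seed=0):
    """Planted model on the 28-marker scaffold with sinusoidal amplitudes.

    Frequencies are whole cycles over the duration so amplitude series are
    exactly zero-mean and mutually orthogonal in time.
    """
    labels = sg.humanoid_labels()
    base = sg.humanoid_base_posture()
    modes = sg.random_orthonormal_modes(n_modes, base.size, seed=seed)
    rng = np.random.default_rng(seed + 77)
    specs = []
    for i, v in enumerate(variances[:n_modes]):
        cycles = 3 + 2 * i  # integer cycles in `duration`
        specs.append(sg.SineAmplitude(frequency=cycles / duration,
                                      amplitude=float(np.sqrt(2 * v)),
                                      phase=float(rng.uniform(0, 2 * np.pi))))
    return sg.PlantedModel(base_posture=base, modes=modes,
                           amplitude_specs=specs, marker_labels=labels,
                           noise_sd=noise_sd, sampling_rate=sampling_rate,
                           duration=duration, seed=seed)


@pytest.fixture
def planted_model():
    return make_planted_model()


@pytest.fixture
def noisy_model():
    # noise at 1% of the smallest mode's RMS (sqrt(1.0))
    return make_planted_model(noise_sd=0.01)


@pytest.fixture
def small_trial():
    """Tiny 2-marker trial for direct-value tests."""
    from pmkit import MarkerDataset
    data = np.array([
        [1.0, 0.0, 0.0, 2.0, 1.0, -1.0],
        [2.0, 1.0, 0.0, 3.0, 1.0, -1.0],
        [3.0, 0.0, 1.0, 4.0, 1.0, -1.0],
        [4.0, 1.0, 1.0, 5.0, 1.0, -1.0],
    ])
    return MarkerDataset(subject_id="s1", trial_id="t1", sampling_rate=100.0,
                         marker_labels=["m1", "m2"], data=data)
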