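import numpy as np
import pytest

import radarvitals as rv


@pytest.fixture(scope="session")
def radar_cfg():
    return rv.RadarConfig()


@pytest.fixture(scope="session")
def pipeline_cfg():
    return rv.PipelineConfig()


@pytest.fixture(scope="session")
def worked_truth():
    """Noiseless chest motion at the worked-example rates (0.29 / 1.35 Hz)."""
    return rv.VitalTruth(noise_snr_db=None)


@pytest.fixture(scope="session")
def noiseless_cube(radar_cfg, worked_truth):
    return rv.simulate_if_cube(radar_cfg, worked_truth, 60.0)


@pytest.fixture(scope="session")
def diff_phase_signal(noiseless_cube, pipeline_cfg):
    """Differenced thoracic phase of the noiseless worked-example cube."""
    profile = rv.range_fft(rv.remove_dc(noiseless_cube))
    b = rv.select_target_bin(profile)
    return rv.diff_phase(rv.unwrap_phase(rv.extract_phase(profile, b)))


@pytest.fixture(scope="session")
def eigensystem(diff_phase_signal):
    return rv.decompose(rv.embed(diff_phase_signal, 100))


def make_sine(freq, fs=20.0, duration=60.0, amp=1.0, phase=0.0):
    t = np.arange(int(round(duration * fs))) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase), t
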