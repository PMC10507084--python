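import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")

from swemg import (
    ActionLabel,
    BurstTemplate,
    NoiseModel,
    Recording,
    default_templates,
    make_grid,
    simulate_recording,
)


@pytest.fixture(scope="session")
def grid():
    return make_grid()


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture()
def quiet_noise():
    """Baseline noise only, no hum or artifacts."""
    return NoiseModel(baseline_rms=1.7, hum_amplitude=0.0, artifact_rate=0.0)


@pytest.fixture()
def silent_noise():
    return NoiseModel(baseline_rms=0.0, hum_amplitude=0.0, artifact_rate=0.0)


@pytest.fixture()
def burst_recording(grid, silent_noise):
    """Clean single-burst epoch: 300 uV symmetric burst, no noise terms."""
    tpl = {ActionLabel.dry_swallow: BurstTemplate(onset=0.6, duration=0.8, peak_amplitude=300.0)}
    return simulate_recording(
        ActionLabel.dry_swallow, "S1", grid=grid, templates=tpl, noise=silent_noise, seed=11
    )


@pytest.fixture()
def sine_recording_factory():
    """Recording holding one pure sinusoid on all 16 channels."""

    def make(freq_hz: float, amplitude_uv: float = 100.0, fs: float = 1000.0, dur_s: float = 2.0):
        t = np.arange(int(fs * dur_s)) / fs
        wave = amplitude_uv * np.sin(2 * np.pi * freq_hz * t)
        data = np.tile(wave, (16, 1))
        return Recording(data=data, fs=fs, subject="synth", label=ActionLabel.dry_swallow)

    return make
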