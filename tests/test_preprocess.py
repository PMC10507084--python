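import numpy as np
import pytest
from scipy import signal as sps

from swemg import (
    ActionLabel,
    BurstTemplate,
    FilterSpec,
    NoiseModel,
    Recording,
    bandpass,
    notch_harmonics,
    preprocess_chain,
    simulate_recording,
    snr_db,
    wavelet_denoise,
)


def band_power(x, fs, f0, half_width=2.0):
    freqs, psd = sps.welch(x, fs=fs, nperseg=1024)
    sel = (freqs >= f0 - half_width) & (freqs <= f0 + half_width)
    return psd[sel].sum()


def line_power(x, fs, f0):
    """Power of the spectral line at f0 over the epoch interior.

    Single DFT-bin projection on the central 1.5 s: the narrow IIR
    notches ring for ~0.2 s at each epoch edge, so steady-state
    suppression is what the interior shows."""
    x = x[int(0.25 * fs) : -int(0.25 * fs)]
    t = np.arange(len(x)) / fs
    coef = np.abs(np.vdot(np.exp(2j * np.pi * f0 * t), x)) / len(x)
    return coef**2


class TestBandpass:
    def test_stopband_10hz_suppressed_20db(self, sine_recording_factory):
        rec = sine_recording_factory(10.0)
        out = bandpass(rec)
        ratio = np.sqrt((out.data**2).mean() / (rec.data**2).mean())
        assert 20 * np.log10(ratio) <= -20.0

    def test_passband_100hz_unity(self, sine_recording_factory):
        rec = sine_recording_factory(100.0)
        out = bandpass(rec)
        # ignore filtfilt edge transients
        sl = slice(200, -200)
        gain_db = 20 * np.log10(np.sqrt((out.data[:, sl] ** 2).mean() / (rec.data[:, sl] ** 2).mean()))
        assert abs(gain_db) <= 1.0

    def test_zero_in_zero_out(self, grid):
        rec = Recording(np.zeros((16, 2000)), 1000.0, "s", ActionLabel.dry_swallow)
        assert np.all(bandpass(rec).data == 0)

    def test_invalid_band_edges(self, sine_recording_factory):
        rec = sine_recording_factory(100.0)
        with pytest.raises(ValueError):
            bandpass(rec, FilterSpec(band_low=0.0))
        with pytest.raises(ValueError):
            bandpass(rec, FilterSpec(band_low=30.0, band_high=20.0))
        with pytest.raises(ValueError):
            bandpass(rec, FilterSpec(band_high=600.0))  # beyond Nyquist at 1 kHz


class TestNotchHarmonics:
    def test_50hz_residual_under_10_percent(self, sine_recording_factory):
        rec = sine_recording_factory(50.0)
        out = notch_harmonics(rec)
        assert np.sqrt((out.data**2).mean()) <= 0.10 * np.sqrt((rec.data**2).mean())

    def test_150hz_needs_third_harmonic(self, sine_recording_factory):
        rec = sine_recording_factory(150.0)
        sl = slice(200, -200)
        attenuated = notch_harmonics(rec, FilterSpec(notch_harmonics=3))
        passed = notch_harmonics(rec, FilterSpec(notch_harmonics=1))
        assert np.sqrt((attenuated.data[:, sl] ** 2).mean()) < 0.1 * np.sqrt((rec.data[:, sl] ** 2).mean())
        assert np.sqrt((passed.data[:, sl] ** 2).mean()) == pytest.approx(
            np.sqrt((rec.data[:, sl] ** 2).mean()), rel=0.05
        )

    def test_harmonic_above_nyquist_rejected(self, sine_recording_factory):
        rec = sine_recording_factory(50.0)
        with pytest.raises(ValueError):
            notch_harmonics(rec, FilterSpec(notch_harmonics=10))  # 500 Hz = Nyquist

    def test_zero_in_zero_out(self):
        rec = Recording(np.zeros((4, 2000)), 1000.0, "s", ActionLabel.dry_swallow)
        assert np.all(notch_harmonics(rec).data == 0)


class TestWaveletDenoise:
    def test_improves_snr_on_noisy_burst(self, burst_recording):
        clean = burst_recording.data
        rng = np.random.default_rng(0)
        noise_sd = np.sqrt((clean**2).mean()) / np.sqrt(10)  # ~10 dB input SNR
        noisy = burst_recording.copy_with(clean + noise_sd * rng.standard_normal(clean.shape))
        den = wavelet_denoise(noisy)
        snr_in = snr_db(clean.ravel(), (noisy.data - clean).ravel())
        snr_out = snr_db(clean.ravel(), (den.data - clean).ravel())
        assert snr_out >= snr_in

    def test_near_identity_on_clean_signal(self, burst_recording):
        den = wavelet_denoise(burst_recording)
        rel = np.linalg.norm(den.data - burst_recording.data) / np.linalg.norm(burst_recording.data)
        assert rel < 0.05

    def test_constant_signal_preserved(self):
        rec = Recording(np.full((2, 2000), 7.0), 1000.0, "s", ActionLabel.dry_swallow)
        assert np.allclose(wavelet_denoise(rec).data, 7.0, atol=1e-8)

    def test_too_short_recording_rejected(self):
        rec = Recording(np.zeros((2, 8)), 1000.0, "s", ActionLabel.dry_swallow)
        with pytest.raises(ValueError):
            wavelet_denoise(rec, FilterSpec(decomposition_level=4))


class TestChain:
    @pytest.fixture()
    def contaminated(self, grid):
        noise = NoiseModel(baseline_rms=1.7, hum_amplitude=15.0, n_harmonics=3, artifact_rate=0.0)
        tpl = {ActionLabel.dry_swallow: BurstTemplate(onset=0.6, duration=0.8, peak_amplitude=300.0)}
        rec = simulate_recording(ActionLabel.dry_swallow, "S1", grid=grid, templates=tpl, noise=noise, seed=9)
        t = np.arange(rec.n_samples) / rec.fs
        rec.data += 80.0 * np.sin(2 * np.pi * 10.0 * t)[None, :]  # low-frequency artifact
        return rec

    def test_hum_and_artifact_suppressed_20db(self, contaminated):
        out = preprocess_chain(contaminated)
        for f0 in (50.0, 10.0):
            before = line_power(contaminated.data[0], contaminated.fs, f0)
            after = line_power(out.data[0], out.fs, f0)
            assert 10 * np.log10(after / before) <= -20.0

    def test_residual_50hz_energy_below_1_percent(self, contaminated):
        out = preprocess_chain(contaminated)
        assert line_power(out.data[0], out.fs, 50.0) <= 0.01 * line_power(
            contaminated.data[0], contaminated.fs, 50.0
        )

    def test_zero_phase_burst_alignment(self, burst_recording):
        out = preprocess_chain(burst_recording)
        xc = sps.correlate(out.data[0], burst_recording.data[0], mode="full")
        lag = np.argmax(xc) - (len(burst_recording.data[0]) - 1)
        assert abs(lag) <= 1

    def test_shape_fs_label_preserved_and_deterministic(self, contaminated):
        a = preprocess_chain(contaminated)
        b = preprocess_chain(contaminated)
        assert a.data.shape == contaminated.data.shape
        assert a.fs == contaminated.fs and a.label == contaminated.label
        assert np.array_equal(a.data, b.data)

    def test_zero_in_zero_out(self):
        rec = Recording(np.zeros((16, 2000)), 1000.0, "s", ActionLabel.dry_swallow)
        assert np.all(preprocess_chain(rec).data == 0)
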