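import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swemg import (
    ActionLabel,
    BurstTemplate,
    NoiseModel,
    Recording,
    amplitude_force_summary,
    crosstalk_rate,
    energy_map,
    rms,
    simulate_recording,
    snr_db,
)
from swemg.metrics import asymmetry_index, fold_changes


class TestSnr:
    def test_tenfold_rms_is_20db(self):
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(500)
        assert snr_db(10 * noise, noise) == pytest.approx(20.0)

    def test_equal_windows_zero_db(self):
        x = np.array([1.0, -2.0, 3.0])
        assert snr_db(x, x) == pytest.approx(0.0)

    def test_hand_worked_example(self):
        # root-sum-square: sqrt(9+16)/sqrt(1+0) = 5 -> 20 log10 5
        assert snr_db([3.0, 4.0], [1.0, 0.0]) == pytest.approx(13.979, abs=1e-3)

    def test_zero_noise_energy_rejected(self):
        with pytest.raises(ValueError):
            snr_db([1.0], [0.0])

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 100))
    def test_scale_invariance_and_additivity(self, scale, seed):
        rng = np.random.default_rng(seed)
        s, n = rng.standard_normal(64), rng.standard_normal(64)
        base = snr_db(s, n)
        assert snr_db(scale * s, scale * n) == pytest.approx(base, abs=1e-9)
        assert snr_db(10 * s, n) == pytest.approx(base + 20.0, abs=1e-9)


class TestRms:
    def test_constant_vector(self):
        assert rms(np.full(10, -3.0)) == pytest.approx(3.0)

    def test_hand_worked_example(self):
        assert rms([3.0, -4.0, 0.0]) == pytest.approx(np.sqrt(25 / 3), abs=1e-9)

    def test_zero_vector(self):
        assert rms(np.zeros(5)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rms([])


class TestCrosstalkRate:
    def test_limits(self):
        assert crosstalk_rate(0.0, 50.0) == 0.0
        assert crosstalk_rate(50.0, 50.0) == 100.0

    def test_zero_active_rejected(self):
        with pytest.raises(ValueError):
            crosstalk_rate(1.0, 0.0)

    def test_rescaling_invariance(self):
        assert crosstalk_rate(3.0, 12.0) == crosstalk_rate(300.0, 1200.0)

    def test_distance_decay_fixture_matches_mixing_model(self, grid, silent_noise):
        """Two point sources 20 mm apart with a 10 mm space constant leak
        exp(-2) ~ 13.5 % of the active muscle's amplitude."""
        pos = grid.working_positions()
        # a working contact exactly 24 mm from contact 0 sits on the same arm
        src = tuple(pos[0])
        tpl = {ActionLabel.dry_swallow: BurstTemplate(onset=0.2, duration=1.5, peak_amplitude=300.0)}
        rec = simulate_recording(
            ActionLabel.dry_swallow, "S1", grid=grid, templates=tpl, noise=silent_noise,
            seed=3, source_pos=src, space_constant_mm=10.0,
        )
        em = energy_map(rec, grid)
        d = np.linalg.norm(pos - np.asarray(src), axis=1)
        far = int(np.argmin(np.abs(d - 20.0)))  # nearest available contact to 20 mm
        rate = crosstalk_rate(em[far], em[0])
        assert rate == pytest.approx(100 * np.exp(-d[far] / 10.0), abs=3.0)


class TestEnergyMap:
    def test_allzero_recording_allzero_map(self, grid):
        rec = Recording(np.zeros((16, 2000)), 1000.0, "s", ActionLabel.dry_swallow)
        assert np.all(energy_map(rec, grid) == 0)

    def test_channel_count_mismatch_rejected(self, grid):
        rec = Recording(np.zeros((4, 100)), 1000.0, "s", ActionLabel.dry_swallow)
        with pytest.raises(ValueError):
            energy_map(rec, grid)

    def test_permutation_equivariance(self, grid, burst_recording):
        em = energy_map(burst_recording, grid)
        perm = np.random.default_rng(0).permutation(16)
        rec_p = burst_recording.copy_with(burst_recording.data[perm])
        assert np.allclose(energy_map(rec_p, grid), em[perm])

    def test_symmetric_fixture_near_zero_asymmetry(self, grid, burst_recording):
        assert abs(asymmetry_index(burst_recording, grid)) <= 0.05

    def test_head_left_negative_asymmetry(self, grid, silent_noise):
        tpl = {ActionLabel.head_left: BurstTemplate(onset=0.5, duration=1.0, peak_amplitude=300.0, laterality=-1.0)}
        rec = simulate_recording(ActionLabel.head_left, "S1", grid=grid, templates=tpl,
                                 noise=silent_noise, seed=4)
        assert asymmetry_index(rec, grid) < -0.5


class TestAmplitudeForceSummary:
    def levels_fixture(self, grid, peaks=(150.0, 350.0, 505.0)):
        # a faint baseline keeps the pre-burst SNR window defined without
        # blurring the peak-amplitude ratios between force levels
        noise = NoiseModel(baseline_rms=0.2, hum_amplitude=0.0, artifact_rate=0.0)
        out = {}
        for force, peak in zip((10.0, 24.0, 35.0), peaks):
            tpl = {ActionLabel.dry_swallow: BurstTemplate(onset=0.5, duration=1.0, peak_amplitude=peak)}
            out[force] = [
                simulate_recording(ActionLabel.dry_swallow, "S1", grid=grid, templates=tpl,
                                   noise=noise, seed=100)  # same seed -> same source waveform
            ]
        return out

    def test_printed_peak_fold_changes(self, grid):
        df = amplitude_force_summary(self.levels_fixture(grid))
        assert round(df["peak_fold"].iloc[1], 1) == 2.3
        assert round(df["peak_fold"].iloc[2], 1) == 3.4

    def test_snr_monotone_in_force(self, grid):
        df = amplitude_force_summary(self.levels_fixture(grid))
        assert df["snr_db"].is_monotonic_increasing

    def test_identical_levels_unit_ratio(self, grid):
        df = amplitude_force_summary(self.levels_fixture(grid, peaks=(300.0, 300.0, 300.0)))
        assert np.allclose(df["peak_fold"], 1.0)

    def test_single_level_single_row(self, grid):
        fixture = {10.0: self.levels_fixture(grid)[10.0]}
        assert len(amplitude_force_summary(fixture)) == 1


class TestFoldChanges:
    def test_printed_amplitude_and_snr_ratios(self):
        peak_folds = fold_changes([150.0, 350.0, 505.0])
        snr_folds = fold_changes([25.0, 30.0, 34.0])
        assert round(peak_folds[1], 1) == 2.3 and round(peak_folds[2], 1) == 3.4
        assert round(snr_folds[1], 1) == 1.2 and round(snr_folds[2], 2) == 1.36

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            fold_changes([0.0, 1.0])
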