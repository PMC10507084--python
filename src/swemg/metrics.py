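"""Electrode characterization statistics: SNR, RMS noise, crosstalk rate,
spatial energy maps and amplitude/SNR-vs-force summaries.

SNR follows the root-sum-square convention
``SNR(dB) = 20 log10( sqrt(sum V_signal^2) / sqrt(sum V_noise^2) )``;
the crosstalk rate is the amplitude recorded over an inactive muscle as a
percentage of that over the active one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from swemg.grid import ElectrodeGrid
from swemg.simulate import Recording

__all__ = [
    "snr_db",
    "rms",
    "crosstalk_rate",
    "energy_map",
    "asymmetry_index",
    "amplitude_force_summary",
    "fold_changes",
]


def rms(x) -> float:
    """Root-mean-square of a sample vector (uV in, uV out)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("rms of an empty vector is undefined")
    return float(np.sqrt(np.mean(np.square(x))))


def snr_db(signal_samples, noise_samples) -> float:
    """Signal-to-noise ratio in dB from two sample windows.

    20 * log10 of the ratio of root-sum-square amplitudes.  Scale
    invariant under common rescaling; multiplying the signal by 10 adds
    exactly 20 dB.
    """
    s = np.asarray(signal_samples, dtype=float)
    n = np.asarray(noise_samples, dtype=float)
    if s.size == 0 or n.size == 0:
        raise ValueError("signal and noise windows must be nonempty")
    noise_energy = float(np.sum(n**2))
    if noise_energy == 0:
        raise ValueError("noise window has zero energy; SNR undefined")
    return float(20.0 * np.log10(np.sqrt(np.sum(s**2)) / np.sqrt(noise_energy)))


def crosstalk_rate(inactive_amp: float, active_amp: float) -> float:
    """Crosstalk in percent: 100 * inactive / active signal amplitude."""
    if active_amp <= 0:
        raise ValueError(f"active amplitude must be positive, got {active_amp}")
    if inactive_amp < 0:
        raise ValueError("amplitudes must be non-negative")
    return 100.0 * inactive_amp / active_amp


def energy_map(rec: Recording, grid: ElectrodeGrid) -> np.ndarray:
    """Per-contact RMS over the epoch, in working-contact (channel) order."""
    if rec.n_channels != grid.n_channels:
        raise ValueError(
            f"recording has {rec.n_channels} channels but grid has {grid.n_channels} working contacts"
        )
    return np.sqrt(np.mean(rec.data**2, axis=1))


def asymmetry_index(rec: Recording, grid: ElectrodeGrid) -> float:
    """(L - R) / (L + R) over the summed per-contact RMS of each grid half.

    Negative when the left half (contact x < 0) is quieter, as for a
    left-turned head; 0 for symmetric activation; 0/0 maps to 0.
    """
    em = energy_map(rec, grid)
    x = grid.working_positions()[:, 0]
    left, right = em[x < 0].sum(), em[x > 0].sum()
    total = left + right
    return float((left - right) / total) if total > 0 else 0.0


def amplitude_force_summary(
    recordings_by_level: dict[float, list[Recording]],
    baseline_s: float = 0.25,
) -> pd.DataFrame:
    """Peak amplitude and SNR per contraction-force level.

    For each level the peak |amplitude| over all channels/recordings and
    the SNR of the whole epoch against the pre-burst baseline (first
    ``baseline_s`` seconds, a window assumed to precede activation) are
    reported, together with fold changes relative to the lowest level.
    """
    if not recordings_by_level:
        raise ValueError("need at least one force level")
    rows = []
    for level in sorted(recordings_by_level):
        recs = recordings_by_level[level]
        if not recs:
            raise ValueError(f"no recordings for level {level}")
        peaks, snrs = [], []
        for rec in recs:
            n_base = int(round(baseline_s * rec.fs))
            if n_base < 1 or n_base >= rec.n_samples:
                raise ValueError("baseline window empty or covering the whole epoch")
            peaks.append(float(np.abs(rec.data).max()))
            snrs.append(snr_db(rec.data.ravel(), rec.data[:, :n_base].ravel()))
        rows.append({"level": level, "peak_uv": float(np.mean(peaks)), "snr_db": float(np.mean(snrs))})
    df = pd.DataFrame(rows)
    df["peak_fold"] = df["peak_uv"] / df["peak_uv"].iloc[0]
    df["snr_fold"] = df["snr_db"] / df["snr_db"].iloc[0]
    return df


def fold_changes(values) -> np.ndarray:
    """Each value as a multiple of the first (e.g. peaks 150/350/505 uV
    give 1.0, 2.33, 3.37)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or v[0] == 0:
        raise ValueError("need a nonzero reference value")
    return v / v[0]
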