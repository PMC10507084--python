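"""Synthetic chin HD-sEMG forward model and impedance-spectrum generator.

A recording epoch is 2 s of 16-channel surface EMG at 1000 Hz.  Each of
the eleven swallowing actions is encoded by a burst template: a
band-limited (20-450 Hz) Gaussian interference-pattern source, shaped by
a Hann envelope of action-specific onset/duration/peak amplitude, spread
to the electrode grid by exponential volume-conduction decay
``gain = exp(-d / lambda)`` and an action-specific left/right laterality
weighting.  On top of the source the generator adds Gaussian baseline
noise (default 1.7 uV RMS), 50 Hz powerline hum with harmonics, and
occasional low-frequency motion-artifact transients.

The default templates are the study conditions: per-action peak
amplitudes spread over roughly 150-505 uV, head-turn actions suppress
one side of the grid (laterality +/-0.8), and the open-mouth / cough
actions use distinctly different burst durations, so the eleven classes
are separable by design.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy import signal as sps

from swemg.grid import ElectrodeGrid, make_grid

__all__ = [
    "ActionLabel",
    "BurstTemplate",
    "NoiseModel",
    "Recording",
    "default_templates",
    "volume_conduction_gains",
    "laterality_weights",
    "simulate_recording",
    "simulate_corpus",
]

FS_DEFAULT = 1000.0  # Hz
EPOCH_S_DEFAULT = 2.0  # s
SOURCE_BAND = (20.0, 450.0)  # Hz, band of the interference-pattern source


class ActionLabel(str, Enum):
    """The eleven swallowing actions."""

    dry_swallow = "dry_swallow"
    water_5ml = "water_5ml"
    water_10ml = "water_10ml"
    water_15ml = "water_15ml"
    low_viscosity = "low_viscosity"
    high_viscosity = "high_viscosity"
    banana = "banana"
    head_left = "head_left"
    head_right = "head_right"
    open_mouth = "open_mouth"
    cough = "cough"


@dataclass(frozen=True)
class BurstTemplate:
    """Parametric description of one action's muscle activation burst.

    laterality in [-1, 1]: -1 fully suppresses the left half of the grid,
    +1 the right half, 0 is symmetric.
    """

    onset: float  # s
    duration: float  # s
    peak_amplitude: float  # uV
    laterality: float = 0.0
    epoch: float = EPOCH_S_DEFAULT

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if self.onset + self.duration > self.epoch + 1e-12:
            raise ValueError("burst must fit inside the epoch")
        if self.peak_amplitude < 0:
            raise ValueError("peak_amplitude must be >= 0")
        if not -1.0 <= self.laterality <= 1.0:
            raise ValueError("laterality must lie in [-1, 1]")

    def envelope(self, fs: float, n_samples: int) -> np.ndarray:
        """Unimodal (Hann) envelope sampled on the epoch grid, peak = 1."""
        env = np.zeros(n_samples)
        i0 = int(round(self.onset * fs))
        n_burst = int(round(self.duration * fs))
        if n_burst > 0:
            env[i0 : i0 + n_burst] = np.hanning(n_burst)
        return env


@dataclass(frozen=True)
class NoiseModel:
    """Additive disturbances: baseline noise, powerline hum, motion artifacts."""

    baseline_rms: float = 1.7  # uV, matches a low-noise gel electrode at rest
    hum_amplitude: float = 10.0  # uV, 50 Hz fundamental peak amplitude
    hum_fundamental: float = 50.0  # Hz
    n_harmonics: int = 3  # 50, 100, 150 Hz by default
    artifact_rate: float = 0.3  # expected events per epoch
    artifact_amplitude: float = 200.0  # uV, half-sine transient peak
    artifact_duration: float = 0.15  # s  (-> fundamental well below 20 Hz)

    def __post_init__(self) -> None:
        for name in ("baseline_rms", "hum_amplitude", "n_harmonics", "artifact_rate", "artifact_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.hum_fundamental <= 0:
            raise ValueError("hum_fundamental must be positive")


@dataclass
class Recording:
    """One labeled epoch: channels x samples, microvolts."""

    data: np.ndarray  # (n_channels, n_samples), uV
    fs: float  # Hz
    subject: str
    label: ActionLabel
    seed: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(data=np.asarray(data), fs=self.fs, subject=self.subject,
                         label=self.label, seed=self.seed)


def default_templates(epoch: float = EPOCH_S_DEFAULT) -> dict[ActionLabel, BurstTemplate]:
    """Study-condition burst templates, one per action.

    Peak amplitudes span the 150-505 uV range seen across submental
    contraction levels; durations grade from a brief mouth opening to a
    long effortful swallow; the two head-turn actions suppress one grid
    half with laterality +/-0.8.
    """
    A = ActionLabel
    spec = {
        #                 onset  dur   peak  laterality
        A.dry_swallow:   (0.60, 0.70, 150.0, 0.0),
        A.water_5ml:     (0.55, 0.85, 210.0, 0.0),
        A.water_10ml:    (0.50, 1.00, 270.0, 0.0),
        A.water_15ml:    (0.45, 1.15, 330.0, 0.0),
        A.low_viscosity: (0.40, 1.30, 390.0, 0.0),
        A.high_viscosity:(0.35, 1.45, 440.0, 0.0),
        A.banana:        (0.30, 1.60, 505.0, 0.0),
        A.head_left:     (0.50, 1.00, 300.0, -0.8),
        A.head_right:    (0.50, 1.00, 300.0, +0.8),
        A.open_mouth:    (0.70, 0.50, 480.0, 0.0),
        A.cough:         (0.10, 1.85, 460.0, 0.0),
    }
    return {
        a: BurstTemplate(onset=o, duration=d, peak_amplitude=p, laterality=l, epoch=epoch)
        for a, (o, d, p, l) in spec.items()
    }


def volume_conduction_gains(
    grid: ElectrodeGrid,
    source_pos: tuple[float, float],
    space_constant_mm: float = 10.0,
    source_depth_mm: float = 0.0,
) -> np.ndarray:
    """Per-channel gain exp(-d / lambda) for a point source.

    d is the contact-to-source distance in mm (planar distance to
    ``source_pos`` plus optional depth below the skin).  Nearer contacts
    always see at least as much signal as farther ones.
    """
    if space_constant_mm <= 0:
        raise ValueError("space constant must be positive")
    pos = grid.working_positions()
    d_planar = np.linalg.norm(pos - np.asarray(source_pos, dtype=float), axis=1)
    d = np.hypot(d_planar, source_depth_mm)
    return np.exp(-d / space_constant_mm)


def laterality_weights(grid: ElectrodeGrid, laterality: float) -> np.ndarray:
    """Left/right suppression weights per channel.

    Channels with contact x < 0 (left arm) are scaled by 1 + min(L, 0),
    channels with x > 0 by 1 - max(L, 0); L = -1 silences the left half.
    """
    x = grid.working_positions()[:, 0]
    w_left = 1.0 + min(laterality, 0.0)
    w_right = 1.0 - max(laterality, 0.0)
    return np.where(x < 0, w_left, w_right)


def _bandlimited_source(rng: np.random.Generator, fs: float, n: int) -> np.ndarray:
    """Unit-free interference-pattern surrogate: white noise band-passed to
    the source band, rescaled so its peak magnitude is 1."""
    low, high = SOURCE_BAND
    if fs <= 2 * high:
        high = 0.98 * fs / 2  # keep the design valid at low sampling rates
    if fs <= 2 * low:
        raise ValueError(f"fs={fs} too low to synthesize a {low}-{high} Hz source")
    white = rng.standard_normal(n)
    sos = sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    src = sps.sosfiltfilt(sos, white)
    peak = np.abs(src).max()
    return src / peak if peak > 0 else src


def simulate_recording(
    label: ActionLabel,
    subject: str,
    grid: ElectrodeGrid | None = None,
    templates: dict[ActionLabel, BurstTemplate] | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    fs: float = FS_DEFAULT,
    epoch: float = EPOCH_S_DEFAULT,
    source_pos: tuple[float, float] | None = None,
    space_constant_mm: float = 10.0,
    source_depth_mm: float = 0.0,
    gain_jitter_sd: float = 0.05,
) -> Recording:
    """Forward-simulate one labeled epoch.

    The template-modulated band-limited stochastic source is mixed onto
    the grid and weighted by the action's laterality, then baseline
    noise, powerline hum and motion artifacts are added.  By default the
    swallowing muscle sheet is taken to lie directly beneath the working
    contacts (unit conduction gain everywhere, up to a small seeded
    per-channel jitter), so the recorded peak equals the template peak.
    Passing ``source_pos`` switches to a point source mixed by
    exponential volume-conduction decay exp(-d / lambda), which is what
    the crosstalk and distance-decay analyses exercise.  Identical
    arguments and seed give bit-identical output.
    """
    label = ActionLabel(label)
    grid = grid if grid is not None else make_grid()
    templates = templates if templates is not None else default_templates(epoch)
    noise = noise if noise is not None else NoiseModel()
    if label not in templates:
        raise KeyError(f"no template for action {label}")
    tpl = templates[label]

    rng = np.random.default_rng(seed)
    n = int(round(fs * epoch))
    n_ch = grid.n_channels

    if source_pos is None:
        gains = np.exp(-source_depth_mm / space_constant_mm) * np.ones(n_ch)
        if gain_jitter_sd > 0:
            gains = gains * (1.0 + gain_jitter_sd * rng.standard_normal(n_ch))
    else:
        gains = volume_conduction_gains(grid, source_pos, space_constant_mm, source_depth_mm)
    gains = gains * laterality_weights(grid, tpl.laterality)

    if tpl.peak_amplitude > 0:
        src = _bandlimited_source(rng, fs, n) * tpl.envelope(fs, n) * tpl.peak_amplitude
    else:
        src = np.zeros(n)
    data = gains[:, None] * src[None, :]

    if noise.baseline_rms > 0:
        data += noise.baseline_rms * rng.standard_normal((n_ch, n))

    if noise.hum_amplitude > 0 and noise.n_harmonics > 0:
        t = np.arange(n) / fs
        phase = rng.uniform(0, 2 * np.pi)
        hum = np.zeros(n)
        for k in range(1, noise.n_harmonics + 1):
            f_k = k * noise.hum_fundamental
            if f_k >= fs / 2:
                break
            hum += (noise.hum_amplitude / k) * np.sin(2 * np.pi * f_k * t + phase)
        # hum is common-mode across the grid up to small per-channel gain spread
        ch_gain = 1.0 + 0.05 * rng.standard_normal(n_ch)
        data += ch_gain[:, None] * hum[None, :]

    if noise.artifact_rate > 0 and noise.artifact_amplitude > 0:
        n_events = rng.poisson(noise.artifact_rate)
        width = max(int(round(noise.artifact_duration * fs)), 2)
        half_sine = np.sin(np.pi * np.arange(width) / (width - 1))
        for _ in range(n_events):
            start = rng.integers(0, max(n - width, 1))
            ch = rng.integers(0, n_ch)
            sign = rng.choice([-1.0, 1.0])
            data[ch, start : start + width] += sign * noise.artifact_amplitude * half_sine[: n - start]

    return Recording(data=data, fs=fs, subject=subject, label=label, seed=seed)


def simulate_corpus(
    n_subjects: int = 5,
    n_reps: int = 10,
    seed: int = 0,
    grid: ElectrodeGrid | None = None,
    templates: dict[ActionLabel, BurstTemplate] | None = None,
    noise: NoiseModel | None = None,
    fs: float = FS_DEFAULT,
    epoch: float = EPOCH_S_DEFAULT,
    amplitude_subject_sd: float = 0.08,
    onset_jitter_sd: float = 0.05,
) -> list[Recording]:
    """Generate the full labeled corpus: n_subjects x 11 actions x n_reps.

    Each subject draws a multiplicative amplitude offset (lognormal-ish,
    sd ``amplitude_subject_sd``) and each repetition jitters the burst
    onset by a clipped Gaussian (sd ``onset_jitter_sd`` s), emulating
    inter-subject and trial-to-trial variability.  Deterministic in seed.
    """
    if n_subjects < 1 or n_reps < 1:
        raise ValueError("n_subjects and n_reps must be >= 1")
    grid = grid if grid is not None else make_grid()
    templates = templates if templates is not None else default_templates(epoch)
    noise = noise if noise is not None else NoiseModel()

    master = np.random.default_rng(seed)
    corpus: list[Recording] = []
    for s in range(n_subjects):
        subj_rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        amp_scale = float(np.exp(amplitude_subject_sd * subj_rng.standard_normal()))
        for label in ActionLabel:
            tpl = templates[label]
            for r in range(n_reps):
                jit = float(np.clip(onset_jitter_sd * subj_rng.standard_normal(), -tpl.onset,
                                    max(tpl.epoch - tpl.onset - tpl.duration, 0.0)))
                tpl_r = replace(tpl, onset=tpl.onset + jit,
                                peak_amplitude=tpl.peak_amplitude * amp_scale)
                rec_seed = int(subj_rng.integers(0, 2**31 - 1))
                corpus.append(
                    simulate_recording(
                        label, subject=f"S{s + 1}", grid=grid,
                        templates={label: tpl_r}, noise=noise, seed=rec_seed,
                        fs=fs, epoch=epoch,
                    )
                )
    return corpus
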