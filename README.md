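# swemg — swallowing-activity analysis for chin HD-sEMG

Dysphagia screening and rehabilitation call for a noninvasive readout of
the swallowing muscles.  A high-density surface-EMG (HD-sEMG) patch worn
under the chin — a V-shaped array of 24 contacts, 16 of them recording
channels — captures the submental muscle activity of eleven swallowing
actions (dry swallow, 5/10/15 ml water, low/high-viscosity liquid,
banana, left/right head turn, open mouth, cough).  `swemg` implements
the full analysis pipeline for such recordings, together with a
synthetic forward model that makes every stage testable without human
data:

1. **Simulation** — labeled 16-channel, 2 s, 1 kHz epochs: band-limited
   stochastic bursts with action-specific amplitude (150–505 µV),
   duration and left/right laterality, exponential volume-conduction
   crosstalk `exp(−d/λ)`, Gaussian baseline noise, 50 Hz hum with
   harmonics, and motion-artifact transients.
2. **Denoising** — zero-phase 20–500 Hz Butterworth bandpass, a bank of
   50·k Hz IIR notches, and SURE-thresholded wavelet shrinkage (db4).
3. **Segmentation** — 125 ms windows with 62.5 ms overlap → the
   16 × 31 × 125 tensor; a segment is *active* when its mean |amplitude|
   exceeds 30 % of the epoch maximum.
4. **Classification** — a residual CNN (three conv stages with identity
   shortcuts, two poolings, two 512-node FC layers, softmax over 11),
   written in pure NumPy with verified gradients; recordings from all
   subjects are scrambled and split 60/20/20 at recording level.
5. **Electrode metrics** — SNR in dB
   (`20·log10(√ΣV²_signal / √ΣV²_noise)`), RMS baseline noise, crosstalk
   rate (inactive/active amplitude, %), spatial energy maps with a
   left/right asymmetry index.
6. **Impedance fitting** — the five-element electrode–skin equivalent
   circuit `Z(f) = R_e + R_s/(1+j2πf·R_s·C_s) + R_d/(1+j2πf·R_d·C_d)`,
   fit by relative-error least squares with Bode/Nyquist utilities and
   a parameter-recovery study.

See `docs/methods.md` for the models, defaults and design rationale.

## Worked example

```python
import numpy as np
from swemg import (ActionLabel, simulate_corpus, preprocess_chain, segment,
                   activity_mask, split_corpus, SplitSpec, ClassifierConfig,
                   build_model, train, CircuitParams, synth_impedance, fit_circuit)

# the study-scale corpus: 5 subjects x 11 actions x 10 reps
corpus = [preprocess_chain(r) for r in simulate_corpus(5, 10, seed=0)]
print(len(corpus))                        # 550

t = segment(corpus[0])
print(t.data.shape)                       # (16, 31, 125)
print(int(activity_mask(t).sum()))        # ~7 active segments for a dry swallow

parts = split_corpus(corpus, SplitSpec(seed=0))
print([len(p) for p in parts])            # [330, 110, 110]

cfg = ClassifierConfig(seed=0)            # ~10 min on one CPU core
report = train(build_model(cfg), parts, cfg)
print(round(report.overall_accuracy, 3))  # 0.955
print(min(report.per_class_accuracy, key=report.per_class_accuracy.get))
# 'high_viscosity' — the viscous-liquid class is the hardest here too

# impedance: fit a 1%-noise spectrum synthesized from known parameters
spec = synth_impedance(CircuitParams(), freqs=np.logspace(0, 3, 30),
                       noise_sd=0.01, seed=0)
fit = fit_circuit(spec)
print(round(fit.params.R_d / 1e3, 1), round(fit.params.C_d / 1e-9, 1))
# 21.7 kOhm, 97.5 nF  (true: 22 kOhm, 95 nF)
```

The corpus numbers mean: 550 labeled epochs exist, each segmented into
the 31 × 125 tensor the CNN consumes; the 60/20/20 split is exact; the
classifier separates the eleven synthetic actions well above the 80 %
reported for real recordings (synthetic classes are separable by
construction — see the methods note for what that does and does not
show), with the viscous-liquid classes nevertheless the least separable
because they sit mid-ladder in both amplitude and duration; and the
circuit fitter recovers the interface parameters from a noisy spectrum
to a few percent.

## Analysis drivers

Numbered scripts under `analysis/` narrate the study end to end and
write their tables to `results/`:

| script | what it does |
|---|---|
| `01_simulate_corpus.py` | generate 550 epochs, per-action amplitude/asymmetry table |
| `02_preprocess.py` | stage-by-stage line suppression, wavelet SNR gain |
| `03_segment_activity.py` | tensor geometry, active-segment counts vs burst duration |
| `04_train_classifier.py` | full CNN training run, confusion matrix (slow) |
| `05_electrode_metrics.py` | energy maps, crosstalk vs distance, amplitude–force summary |
| `06_fit_impedance.py` | circuit fits and the 50-seed recovery study |

Each takes `--seed` and `--out-dir` (default `results/`).

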