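#!/usr/bin/env python
"""Demonstrate the denoising chain (20-500 Hz bandpass -> 50 Hz notch bank
-> wavelet shrinkage) on contaminated fixtures and quantify what each
guarantee buys: powerline-line suppression, motion-artifact removal, and
the SNR gain of the wavelet stage at low input SNR.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from swemg import (
    ActionLabel,
    BurstTemplate,
    NoiseModel,
    bandpass,
    make_grid,
    notch_harmonics,
    preprocess_chain,
    simulate_recording,
    snr_db,
    wavelet_denoise,
)


def line_power(x, fs, f0):
    xc = x[int(0.25 * fs) : -int(0.25 * fs)]  # epoch interior: steady state
    tt = np.arange(len(xc)) / fs
    return (np.abs(np.vdot(np.exp(2j * np.pi * f0 * tt), xc)) / len(xc)) ** 2


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    grid = make_grid()
    tpl = {ActionLabel.dry_swallow: BurstTemplate(onset=0.6, duration=0.8, peak_amplitude=300.0)}
    hum_noise = NoiseModel(baseline_rms=1.7, hum_amplitude=15.0, n_harmonics=3, artifact_rate=0.0)
    rec = simulate_recording(ActionLabel.dry_swallow, "S1", grid=grid, templates=tpl,
                             noise=hum_noise, seed=args.seed)
    rec.data = rec.data + 80.0 * np.sin(2 * np.pi * 10.0 * rec.times)[None, :]

    stages = {
        "raw": rec,
        "bandpass": bandpass(rec),
        "bandpass+notch": notch_harmonics(bandpass(rec)),
        "full chain": preprocess_chain(rec),
    }
    rows = []
    for name, r in stages.items():
        rows.append({
            "stage": name,
            "p50_rel_db": 10 * np.log10(line_power(r.data[0], r.fs, 50.0)
                                        / line_power(rec.data[0], rec.fs, 50.0)),
            "p10_rel_db": 10 * np.log10(line_power(r.data[0], r.fs, 10.0)
                                        / line_power(rec.data[0], rec.fs, 10.0)),
            "rms_uv": float(np.sqrt((r.data**2).mean())),
        })
    df = pd.DataFrame(rows)
    print(df.round(2).to_string(index=False))

    silent = NoiseModel(baseline_rms=0.0, hum_amplitude=0.0, artifact_rate=0.0)
    clean = simulate_recording(ActionLabel.dry_swallow, "S1", grid=grid, templates=tpl,
                               noise=silent, seed=11)
    rng = np.random.default_rng(args.seed)
    gains = []
    for target_db in (25.0, 10.0):
        sd = np.sqrt((clean.data**2).mean()) / 10 ** (target_db / 20)
        noisy = clean.copy_with(clean.data + sd * rng.standard_normal(clean.data.shape))
        den = wavelet_denoise(noisy)
        s_in = snr_db(clean.data.ravel(), (noisy.data - clean.data).ravel())
        s_out = snr_db(clean.data.ravel(), (den.data - clean.data).ravel())
        gains.append({"input_snr_db": s_in, "output_snr_db": s_out, "gain_db": s_out - s_in})
        print(f"wavelet stage at {s_in:.1f} dB input SNR -> {s_out:.1f} dB "
              f"({s_out - s_in:+.1f} dB)")

    args.out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out_dir / "preprocessing_stages.csv", index=False)
    pd.DataFrame(gains).to_csv(args.out_dir / "wavelet_snr_gain.csv", index=False)
    print(f"tables written under {args.out_dir}/")


if __name__ == "__main__":
    main()
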