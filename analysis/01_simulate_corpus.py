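#!/usr/bin/env python
"""Generate the study-scale synthetic corpus and summarize what it looks
like: 5 subjects x 11 swallowing actions x 10 repetitions of 2 s,
16-channel, 1 kHz epochs.  Writes a per-action amplitude/asymmetry table
and two example recordings (one EDF, one HDF5) for inspection.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from swemg import ActionLabel, make_grid, simulate_corpus, write_recording
from swemg.metrics import asymmetry_index, energy_map


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    grid = make_grid()
    corpus = simulate_corpus(n_subjects=5, n_reps=10, seed=args.seed)
    print(f"generated {len(corpus)} recordings "
          f"({len({r.subject for r in corpus})} subjects x {len(ActionLabel)} actions x 10 reps)")

    rows = []
    for label in ActionLabel:
        recs = [r for r in corpus if r.label == label]
        peaks = [float(np.abs(r.data).max()) for r in recs]
        asyms = [asymmetry_index(r, grid) for r in recs]
        rows.append({
            "action": label.value,
            "n": len(recs),
            "peak_uv_mean": np.mean(peaks),
            "peak_uv_sd": np.std(peaks),
            "asymmetry_mean": np.mean(asyms),
            "channel_rms_uv": np.mean([energy_map(r, grid).mean() for r in recs]),
        })
    df = pd.DataFrame(rows)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out_dir / "corpus_summary.csv", index=False)
    print(df.round(2).to_string(index=False))
    print("\nhead-turn actions show the expected lateral suppression "
          "(asymmetry < 0 for head_left, > 0 for head_right); all other "
          "actions are near-symmetric.")

    examples = args.out_dir / "example_recordings"
    write_recording(corpus[0], examples / "example.edf", dialect="edf")
    write_recording(corpus[0], examples / "example.h5", dialect="h5")
    print(f"example recordings written under {examples}/")


if __name__ == "__main__":
    main()
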