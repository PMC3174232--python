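#!/usr/bin/env python
"""Track C-loop closure on a synthetic relaxation trajectory.

Builds a two-anchor trajectory whose Cα–Cα distance relaxes from an
open antagonist-like 15 Å to a closed agonist-like 8 Å with 0.3 Å
measurement noise — the signature of agonist-induced loop closure —
then classifies every frame against the calibrated state ranges and
writes the per-frame series, its 50-point sliding average and the
summary table under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from namsite import (
    Atom,
    NumberingMap,
    ResidueKey,
    gen_distance_trajectory,
    run_descriptor_suite,
    sliding_average,
)
from namsite.structure_io import Chain, Residue, StructureModel, Trajectory

SEED = 1
N_FRAMES = 500
BASE = Path(__file__).resolve().parent.parent / "results"


def build_trajectory(distances: np.ndarray) -> Trajectory:
    frames = []
    for i, d in enumerate(distances):
        res_a = Residue(ResidueKey("A", 191), "CYS", [Atom("CA", "C", [0, 0, 0])])
        res_b = Residue(ResidueKey("B", 58), "THR", [Atom("CA", "C", [0, 0, float(d)])])
        frames.append(
            StructureModel([Chain("A", [res_a]), Chain("B", [res_b])], frame_index=i)
        )
    return Trajectory(frames, frame_interval_ps=10.0)


def main() -> None:
    BASE.mkdir(parents=True, exist_ok=True)
    profile = lambda i: 15.0 + (8.0 - 15.0) * min(i / (N_FRAMES * 0.6), 1.0)
    distances = gen_distance_trajectory(profile, 0.3, N_FRAMES, SEED)
    distances = np.clip(distances, 0.0, None)
    trajectory = build_trajectory(distances)

    nmap = NumberingMap()
    nmap.add("alpha:C191", ResidueKey("A", 191))
    nmap.add("beta:58", ResidueKey("B", 58))
    per_frame, summary = run_descriptor_suite(
        trajectory, nmap, [("alpha:C191", "A", "beta:58", "B")]
    )
    means, sds = sliding_average(distances, 50)
    smoothed = pd.DataFrame(
        {"window_start": np.arange(len(means)), "mean": means, "sd": sds}
    )
    per_frame.to_csv(BASE / "cloop_series.tsv", sep="\t", index=False)
    smoothed.to_csv(BASE / "cloop_sliding50.tsv", sep="\t", index=False)
    summary.to_csv(BASE / "cloop_summary.tsv", sep="\t", index=False)

    states = per_frame["state"]
    print(f"C-loop closure over {N_FRAMES} frames: {summary.loc[0, 'mean_sd']} Å "
          f"(min {summary.loc[0, 'min']:.2f} Å)")
    print(f"state of the series mean: {summary.loc[0, 'state_of_mean']}")
    first = states.iloc[:50].mode()[0]
    last = states.iloc[-50:].mode()[0]
    print(f"dominant state, first 50 frames: {first}; last 50 frames: {last}")


if __name__ == "__main__":
    main()
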