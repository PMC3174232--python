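#!/usr/bin/env python
"""Identify consensus docking sites across the ensemble.

Reads the synthetic ensemble and pose clouds written by 01_simulate.py,
runs centroid leader clustering (4 Å) per conformation, keeps the four
most populous clusters, fingerprints them (5 Å contacts) and merges
fingerprints across conformations at 65% overlap.  Reports how many
consensus sites exceed 5% of all dockings and how well they match the
planted sites.
"""

from pathlib import Path

import pandas as pd

from namsite import read_pose_set, read_structure, run_consensus_pipeline

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = BASE / "synthetic"
    if not data.exists():
        raise SystemExit("run analysis/01_simulate.py first")
    ensemble = read_structure(data / "ensemble.pdb")
    pose_sets = [
        read_pose_set(path, conformation_id=f"conf{i:03d}")
        for i, path in enumerate(sorted(data.glob("poses_conf*.pdb")))
    ]
    sites, sites_df, clusters_df = run_consensus_pipeline(
        ensemble, {"ligand": pose_sets}
    )
    sites_df.to_csv(BASE / "consensus_sites.tsv", sep="\t", index=False)
    clusters_df.to_csv(BASE / "clusters.tsv", sep="\t", index=False)

    prov = pd.read_csv(data / "provenance.tsv", sep="\t")
    total = len(prov)
    major = sites_df[sites_df["population_fraction"] >= 0.05]
    print(f"{len(sites_df)} consensus sites from {total} dockings; "
          f"{len(major)} above the 5% population threshold:")
    for _, row in major.iterrows():
        print(f"  {row.site_id}: {100 * row.population_fraction:.1f}% of dockings, "
              f"recurrence {100 * row.recurrence:.1f}%, "
              f"{row.n_member_clusters} member clusters")


if __name__ == "__main__":
    main()
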