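"""Residue-contact fingerprints and cross-conformation consensus sites.

Clusters from different receptor conformations cannot be compared in
Cartesian space — the receptor drifts and rotates between snapshots —
so each cluster is reduced to the set of receptor residues any of its
poses touches (heavy-atom distance within a cutoff, 5 Å by default).
Clusters whose residue lists share at least a 65% intersection are
treated as the same docking position; merging is by single-linkage
connected components over that pairwise rule.  The overlap denominator
is configurable: ``min`` (containment-like, default — merges nested
contact zones of differently sized clusters at one pocket) or
``jaccard``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .clustering import PoseCluster
from .structure_io import ResidueKey, StructureModel

__all__ = [
    "ContactFingerprint",
    "ClusterRecord",
    "ConsensusSite",
    "contact_fingerprint",
    "overlap_fraction",
    "merge_across_conformations",
    "site_statistics",
    "site_report",
]


@dataclass(frozen=True)
class ContactFingerprint:
    """Receptor residues within ``cutoff`` Å of a cluster's poses."""

    residues: frozenset[ResidueKey]
    cutoff: float
    source: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ClusterRecord:
    """A top-k cluster tagged with its ligand, ready for merging."""

    ligand_id: str
    cluster: PoseCluster
    fingerprint: ContactFingerprint


@dataclass
class ConsensusSite:
    """Clusters merged across conformations/ligands into one docking position."""

    members: list[ClusterRecord]
    fingerprint: frozenset[ResidueKey]
    population: int
    population_fraction: float | None = None
    recurrence: float | None = None
    site_id: str = ""

    @property
    def contributing_pairs(self) -> set[tuple[str, str]]:
        return {(m.ligand_id, m.cluster.conformation_id) for m in self.members}


def contact_fingerprint(
    cluster: PoseCluster,
    receptor_frame: StructureModel,
    cutoff: float = 5.0,
    mode: str = "union",
    conformation_id: str | None = None,
) -> ContactFingerprint:
    """Residues with any heavy atom within ``cutoff`` of any ligand heavy atom.

    ``mode="union"`` (default) pools contacts over all member poses;
    ``mode="intersection"`` keeps only residues contacted by every pose.
    Hydrogens are ignored on both sides.  The frame must be the
    conformation the cluster was docked to; an empty fingerprint (poses
    far from the receptor) is permitted and left to the caller to flag.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if mode not in ("union", "intersection"):
        raise ValueError("mode must be 'union' or 'intersection'")
    frame_id = conformation_id
    if frame_id is None and receptor_frame.frame_index is not None:
        frame_id = f"conf{receptor_frame.frame_index:03d}"
    if frame_id is not None and cluster.conformation_id and frame_id != cluster.conformation_id:
        raise ValueError(
            f"cluster belongs to {cluster.conformation_id!r} but frame is {frame_id!r}"
        )
    coords, owners = receptor_frame.heavy_atom_table()
    if len(coords) == 0:
        return ContactFingerprint(frozenset(), cutoff, source=cluster.cluster_id)
    tree = cKDTree(coords)
    per_pose: list[set[ResidueKey]] = []
    for pose in cluster.members:
        hits: set[ResidueKey] = set()
        for idxs in tree.query_ball_point(pose.heavy_coords, r=cutoff):
            hits.update(owners[i] for i in idxs)
        per_pose.append(hits)
    residues = set.union(*per_pose) if mode == "union" else set.intersection(*per_pose)
    return ContactFingerprint(frozenset(residues), cutoff, source=cluster.cluster_id)


def overlap_fraction(
    a: ContactFingerprint, b: ContactFingerprint, denominator: str = "min"
) -> float:
    """Fraction of shared residues between two fingerprints, in [0, 1].

    ``min``: |a ∩ b| / min(|a|, |b|); ``jaccard``: |a ∩ b| / |a ∪ b|.
    Symmetric in its arguments.  Empty fingerprints are an error — they
    carry no contact information to compare.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot compare an empty contact fingerprint")
    inter = len(a.residues & b.residues)
    if denominator == "min":
        return inter / min(len(a), len(b))
    if denominator == "jaccard":
        return inter / len(a.residues | b.residues)
    raise ValueError("denominator must be 'min' or 'jaccard'")


def merge_across_conformations(
    records: list[ClusterRecord],
    threshold: float = 0.65,
    denominator: str = "min",
) -> list[ConsensusSite]:
    """Merge top-k clusters across conformations into consensus sites.

    Builds a graph with clusters as nodes and edges wherever the
    fingerprint overlap reaches the threshold; consensus sites are the
    connected components (single-linkage closure of the pairwise rule).
    Clusters with empty fingerprints cannot be compared and become
    singleton sites.  Output is sorted by population, descending.
    """
    if not records:
        raise ValueError("no cluster records to merge")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    cutoffs = {r.fingerprint.cutoff for r in records}
    if len(cutoffs) > 1:
        raise ValueError(f"fingerprints computed at mixed cutoffs: {sorted(cutoffs)}")
    graph = nx.Graph()
    graph.add_nodes_from(range(len(records)))
    comparable = [i for i, r in enumerate(records) if len(r.fingerprint) > 0]
    for ii, i in enumerate(comparable):
        for j in comparable[ii + 1:]:
            if overlap_fraction(records[i].fingerprint, records[j].fingerprint,
                                denominator) >= threshold:
                graph.add_edge(i, j)
    sites = []
    for component in nx.connected_components(graph):
        members = [records[i] for i in sorted(component)]
        union: frozenset[ResidueKey] = frozenset().union(
            *(m.fingerprint.residues for m in members)
        )
        sites.append(
            ConsensusSite(
                members=members,
                fingerprint=union,
                population=sum(m.cluster.population for m in members),
            )
        )
    sites.sort(key=lambda s: (-s.population, s.members[0].cluster.cluster_id))
    for i, site in enumerate(sites):
        site.site_id = f"site{i:02d}"
    return sites


def site_statistics(
    sites: list[ConsensusSite],
    total_dockings: int,
    ligand_conformation_pairs: int,
) -> list[ConsensusSite]:
    """Annotate sites with population fraction and recurrence.

    ``population_fraction`` — site poses over all dockings performed;
    ``recurrence`` — fraction of (ligand, conformation) pairs that
    contributed at least one member cluster to the site.
    """
    if total_dockings <= 0 or ligand_conformation_pairs <= 0:
        raise ValueError("totals must be positive")
    for site in sites:
        site.population_fraction = site.population / total_dockings
        site.recurrence = len(site.contributing_pairs) / ligand_conformation_pairs
    sites.sort(key=lambda s: (-(s.population_fraction or 0.0), s.site_id))
    return sites


def site_report(sites: list[ConsensusSite]) -> pd.DataFrame:
    """Tabular consensus-site summary (TSV-ready)."""
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in sites],
            "population": [s.population for s in sites],
            "population_fraction": [s.population_fraction for s in sites],
            "recurrence": [s.recurrence for s in sites],
            "n_member_clusters": [len(s.members) for s in sites],
            "member_clusters": [
                ";".join(m.cluster.cluster_id for m in s.members) for s in sites
            ],
            "fingerprint_residues": [
                ";".join(str(k) for k in sorted(s.fingerprint)) for s in sites
            ],
        }
    )
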