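"""Leader clustering of docked poses within one receptor conformation.

Blind-docking pose sets are grouped by centroid proximity with a 4 Å
tolerance; focused-docking sets by all-atom coordinate RMSD (no
superposition — docked poses already share the receptor frame) with a
2 Å tolerance.  Both use a deterministic greedy leader scheme visiting
poses best-docking-energy-first, matching the energy-ordered greedy
clustering of standard docking engines: a pose joins the first existing
cluster within tolerance, else founds a new one.  The centroid variant
tests against the cluster's running-mean centroid (updated as members
join); the RMSD variant tests against the founder pose, since an RMSD
to an averaged rigid shape is ill-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure_io import Pose, PoseSet

__all__ = [
    "PoseCluster",
    "pose_centroid",
    "cluster_poses_centroid",
    "cluster_poses_rmsd",
    "top_k_clusters",
    "cluster_report",
]


def pose_centroid(pose: Pose) -> np.ndarray:
    """Unweighted mean of heavy-atom coordinates (hydrogens excluded)."""
    heavy = pose.heavy_coords
    if len(heavy) == 0:
        raise ValueError(f"pose {pose.pose_id!r} has no heavy atoms")
    return heavy.mean(axis=0)


@dataclass
class PoseCluster:
    """A group of poses from one conformation with population statistics."""

    members: list[Pose]
    centroid: np.ndarray
    conformation_id: str = ""
    founder_order: int = 0
    cluster_id: str = ""
    method: str = "centroid"  # recorded so reports state the rule used

    @property
    def population(self) -> int:
        return len(self.members)

    @property
    def mean_energy(self) -> float | None:
        energies = [p.docking_energy for p in self.members if p.docking_energy is not None]
        if not energies:
            return None
        return float(np.mean(energies))


def _visit_order(poses: list[Pose]) -> list[int]:
    """Best-energy-first; poses without an energy keep input order, last."""
    return sorted(
        range(len(poses)),
        key=lambda i: (poses[i].docking_energy is None,
                       poses[i].docking_energy if poses[i].docking_energy is not None else 0.0,
                       i),
    )


def _finalize(clusters: list[PoseCluster]) -> list[PoseCluster]:
    clusters.sort(key=lambda c: (-c.population, c.founder_order))
    for i, c in enumerate(clusters):
        c.cluster_id = f"{c.conformation_id or 'c'}:{i:02d}"
    return clusters


def cluster_poses_centroid(pose_set: PoseSet, tolerance: float = 4.0) -> list[PoseCluster]:
    """Leader clustering of pose centroids with a distance tolerance (Å).

    A pose joins the first cluster whose *current* (running mean)
    centroid lies within tolerance of the pose centroid; otherwise it
    founds a new cluster.  Output is sorted by population, descending.
    """
    poses = list(pose_set.poses)
    if not poses:
        raise ValueError("pose set is empty")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    centroids = [pose_centroid(p) for p in poses]
    clusters: list[PoseCluster] = []
    sums: list[np.ndarray] = []
    for idx in _visit_order(poses):
        c = centroids[idx]
        for j, cluster in enumerate(clusters):
            if np.linalg.norm(cluster.centroid - c) <= tolerance:
                cluster.members.append(poses[idx])
                sums[j] += c
                cluster.centroid = sums[j] / cluster.population
                break
        else:
            clusters.append(
                PoseCluster([poses[idx]], c.copy(),
                            conformation_id=pose_set.conformation_id,
                            founder_order=len(clusters), method="centroid")
            )
            sums.append(c.copy())
    return _finalize(clusters)


def cluster_poses_rmsd(pose_set: PoseSet, tolerance: float = 2.0) -> list[PoseCluster]:
    """Leader clustering by all-atom RMSD to each cluster's founder pose.

    All poses must share atom count and order; no superposition is
    applied because docked poses share the receptor coordinate frame.
    """
    poses = list(pose_set.poses)
    if not poses:
        raise ValueError("pose set is empty")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    coords = [p.all_coords for p in poses]
    n_atoms = len(coords[0])
    for p, xyz in zip(poses, coords):
        if len(xyz) != n_atoms:
            raise ValueError(
                f"pose {p.pose_id!r} has {len(xyz)} atoms, expected {n_atoms}"
            )
    clusters: list[PoseCluster] = []
    founders: list[np.ndarray] = []
    for idx in _visit_order(poses):
        xyz = coords[idx]
        for j, cluster in enumerate(clusters):
            rmsd = float(np.sqrt(np.mean(np.sum((xyz - founders[j]) ** 2, axis=1))))
            if rmsd <= tolerance:
                cluster.members.append(poses[idx])
                break
        else:
            clusters.append(
                PoseCluster([poses[idx]], pose_centroid(poses[idx]),
                            conformation_id=pose_set.conformation_id,
                            founder_order=len(clusters), method="rmsd")
            )
            founders.append(xyz)
    for cluster in clusters:
        cluster.centroid = np.mean([pose_centroid(p) for p in cluster.members], axis=0)
    return _finalize(clusters)


def top_k_clusters(clusters: list[PoseCluster], k: int = 4) -> list[PoseCluster]:
    """The k most populous clusters.

    Ties are broken by lower mean docking energy, then by earlier
    founder; fewer than k clusters are returned as-is.
    """
    if not clusters:
        raise ValueError("no clusters given")
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(
        clusters,
        key=lambda c: (
            -c.population,
            c.mean_energy if c.mean_energy is not None else np.inf,
            c.founder_order,
        ),
    )
    return ranked[:k]


def cluster_report(clusters: list[PoseCluster]) -> pd.DataFrame:
    """Tabular cluster summary (TSV-ready)."""
    return pd.DataFrame(
        {
            "conformation_id": [c.conformation_id for c in clusters],
            "cluster_id": [c.cluster_id for c in clusters],
            "population": [c.population for c in clusters],
            "centroid_x": [c.centroid[0] for c in clusters],
            "centroid_y": [c.centroid[1] for c in clusters],
            "centroid_z": [c.centroid[2] for c in clusters],
            "mean_energy": [c.mean_energy for c in clusters],
            "method": [c.method for c in clusters],
        }
    )
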