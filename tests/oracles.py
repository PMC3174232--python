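"""Independent brute-force reference implementations used by the tests.

These deliberately share no code with the package: plain-Python loops
over plain lists, so they can serve as oracles for the vectorised /
tree-based implementations.
"""

from __future__ import annotations

import math


def brute_centroid(coords: list[tuple[float, float, float]]) -> tuple[float, float, float]:
    n = len(coords)
    return (
        sum(c[0] for c in coords) / n,
        sum(c[1] for c in coords) / n,
        sum(c[2] for c in coords) / n,
    )


def brute_dist(a, b) -> float:
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def brute_leader_centroid(centroids: list[tuple], order: list[int], tolerance: float):
    """Greedy leader clustering with running-mean centroids.

    Returns a list of member-index lists, in founding order.
    """
    clusters: list[list[int]] = []
    means: list[tuple] = []
    for idx in order:
        c = centroids[idx]
        for j in range(len(clusters)):
            if brute_dist(means[j], c) <= tolerance:
                clusters[j].append(idx)
                members = [centroids[i] for i in clusters[j]]
                means[j] = brute_centroid(members)
                break
        else:
            clusters.append([idx])
            means.append(c)
    return clusters


def brute_leader_rmsd(pose_coords: list[list[tuple]], order: list[int], tolerance: float):
    """Greedy leader clustering by coordinate RMSD to the founder pose."""
    clusters: list[list[int]] = []
    founders: list[list[tuple]] = []
    for idx in order:
        xyz = pose_coords[idx]
        for j in range(len(clusters)):
            sq = sum(brute_dist(a, b) ** 2 for a, b in zip(xyz, founders[j]))
            if math.sqrt(sq / len(xyz)) <= tolerance:
                clusters[j].append(idx)
                break
        else:
            clusters.append([idx])
            founders.append(xyz)
    return clusters


def brute_contacts(ligand_coords, residue_atoms: dict, cutoff: float) -> set:
    """All-pairs distance scan: residues with any atom within cutoff."""
    hits = set()
    for key, atoms in residue_atoms.items():
        for ra in atoms:
            for la in ligand_coords:
                if brute_dist(ra, la) <= cutoff:
                    hits.add(key)
                    break
            if key in hits:
                break
    return hits


def brute_overlap_min(a: set, b: set) -> float:
    return len(a & b) / min(len(a), len(b))


def brute_overlap_jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b)
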