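"""Synthetic inputs with the statistical structure the pipeline assumes.

The generators emulate, at toy scale, the data an ensemble blind-docking
study produces: a pentameric ring of chains standing in for a receptor
extracellular domain, conformational ensembles with Gaussian jitter,
pose clouds concentrated at planted binding sites plus uniform decoys in
the pore lumen, distance traces with a deterministic profile plus noise,
and per-frame energy series with a decaying equilibration drift.  True
site labels are retained on every pose so downstream recovery can be
scored exactly.  All randomness flows from the scenario seed; the same
scenario and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .energy import EnergySeries
from .structure_io import (
    Atom,
    Chain,
    Pose,
    PoseSet,
    Residue,
    ResidueKey,
    StructureModel,
    Trajectory,
)

__all__ = [
    "PlantedSiteSpec",
    "SyntheticScenario",
    "gen_receptor",
    "gen_conformation_ensemble",
    "gen_pose_cloud",
    "gen_distance_trajectory",
    "gen_energy_series",
    "default_sites",
    "provenance_table",
]

# Rigid 5-atom ligand template: 4 heavy atoms with centroid at the origin
# plus one hydrogen (excluded from centroid logic).
_LIGAND_TEMPLATE = (
    ("N1", "N", np.array([1.2, 0.0, 0.0])),
    ("C1", "C", np.array([-0.4, 0.8, 0.3])),
    ("C2", "C", np.array([-0.4, -0.8, 0.3])),
    ("C3", "C", np.array([-0.4, 0.0, -0.6])),
    ("H1", "H", np.array([1.8, 0.0, 0.9])),
)

# Mean synthetic docking energies (kcal/mol): planted poses score better
# than decoys, echoing the magnitude separation seen on an AutoDock scale.
_PLANTED_ENERGY = (-7.0, 0.5)
_DECOY_ENERGY = (-4.0, 0.5)

# Decoy shell: spherical annulus spanning the pore lumen, as fractions of
# the ring radius, so decoys sit inside the doughnut without touching the
# protein wall.
_DECOY_SHELL = (0.25, 0.70)


@dataclass
class PlantedSiteSpec:
    """One planted binding site: centre, share of non-decoy poses, spread."""

    center: np.ndarray
    weight: float
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("site center must be a 3-vector")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("site weight must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("site noise_sd must be positive")


def default_sites(ring_radius: float = 30.0) -> list[PlantedSiteSpec]:
    """Three well-separated sites at the inner wall of the ring.

    Weights (0.5, 0.3, 0.2) and 1 Å isotropic noise; centres sit 3 Å
    inside the Cα ring so every site contacts receptor residues, and at
    angles far enough apart that contact fingerprints are disjoint.
    """
    r = ring_radius - 3.0
    angles = np.deg2rad([36.0, 180.0, 288.0])
    weights = (0.5, 0.3, 0.2)
    return [
        PlantedSiteSpec(
            center=np.array([r * np.cos(a), r * np.sin(a), 1.5]),
            weight=w,
            noise_sd=1.0,
        )
        for a, w in zip(angles, weights)
    ]


@dataclass
class SyntheticScenario:
    """Full description of one synthetic study.

    Defaults are the standard conditions exercised throughout: a
    pentameric ring, 26 conformations, 100 docking poses per
    conformation with 20% decoys, and three planted sites with weights
    (0.5, 0.3, 0.2) and 1 Å noise.
    """

    n_chains: int = 5
    residues_per_chain: int = 20
    n_conformations: int = 26
    conformation_jitter_sd: float = 0.3
    n_poses_per_conformation: int = 100
    decoy_fraction: float = 0.2
    sites: list[PlantedSiteSpec] = field(default_factory=default_sites)
    seed: int = 0
    ring_radius: float = 30.0

    def __post_init__(self) -> None:
        for name in ("n_chains", "residues_per_chain", "n_conformations",
                     "n_poses_per_conformation"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_chains > 26:
            raise ValueError("at most 26 chains (single-letter chain ids)")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise ValueError("decoy_fraction must lie in [0, 1]")
        if self.conformation_jitter_sd < 0:
            raise ValueError("conformation_jitter_sd must be >= 0")
        if not self.sites:
            raise ValueError("at least one planted site required")
        total = sum(s.weight for s in self.sites)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"site weights must sum to 1 (got {total})")


def gen_receptor(scenario: SyntheticScenario) -> StructureModel:
    """Deterministic ring of chains with rigid pseudo-residues.

    Chains are laid out on arcs of a circle of ``ring_radius``; each
    residue carries a designated Cα, a backbone O displaced toward the
    pore, a sidechain pseudo-atom displaced outward, and one hydrogen.
    Residue numbering is 1-based per chain.  No randomness is used.
    """
    R = scenario.ring_radius
    n_chains = scenario.n_chains
    n_res = scenario.residues_per_chain
    arc = 2 * np.pi / n_chains
    margin = 0.04 * arc
    chains = []
    for c in range(n_chains):
        chain = Chain(string.ascii_uppercase[c])
        start = c * arc + margin
        span = arc - 2 * margin
        for i in range(1, n_res + 1):
            theta = start + (i - 0.5) * span / n_res
            direction = np.array([np.cos(theta), np.sin(theta), 0.0])
            z = 1.5 * ((i - 1) % 3)
            ca = R * direction + np.array([0.0, 0.0, z])
            res = Residue(ResidueKey(chain.chain_id, i), "ALA")
            res.atoms = [
                Atom("CA", "C", ca),
                Atom("O", "O", (R - 1.23) * direction + np.array([0.0, 0.0, z])),
                Atom("CB", "C", (R + 1.5) * direction + np.array([0.0, 0.0, z])),
                Atom("HA", "H", ca + np.array([0.0, 0.0, 1.0])),
            ]
            chain.residues.append(res)
        chains.append(chain)
    return StructureModel(chains, frame_index=0)


def gen_conformation_ensemble(
    receptor: StructureModel,
    n_conformations: int,
    jitter_sd: float,
    seed: int,
) -> Trajectory:
    """Ensemble whose frame 0 is the input; later frames add i.i.d.
    Gaussian displacement per atom coordinate.  Topology is shared
    exactly across frames."""
    if n_conformations < 1:
        raise ValueError("n_conformations must be >= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = receptor.coordinate_array()
    frames = []
    for i in range(n_conformations):
        frame = receptor.copy()
        frame.frame_index = i
        if i > 0 and jitter_sd > 0:
            frame.set_coordinates(base + rng.normal(0.0, jitter_sd, size=base.shape))
        frames.append(frame)
    return Trajectory(frames)


def _pose_from_centroid(
    centroid: np.ndarray, rotation: Rotation, pose_id: str, conformation_id: str,
    energy: float, site_label: str,
) -> Pose:
    atoms = [
        Atom(name, element, rotation.apply(offset) + centroid)
        for name, element, offset in _LIGAND_TEMPLATE
    ]
    return Pose(atoms, docking_energy=energy, pose_id=pose_id,
                conformation_id=conformation_id, site_label=site_label)


def gen_pose_cloud(scenario: SyntheticScenario, conformation_index: int) -> PoseSet:
    """Docked-pose cloud for one conformation.

    Each pose is the rigid 5-atom ligand, randomly oriented.  With
    probability ``1 − decoy_fraction`` its centroid is drawn from a
    planted site (site chosen by weight, isotropic Gaussian noise);
    otherwise the centroid is uniform in a spherical annulus spanning
    the pore lumen.  Planted poses receive better synthetic docking
    energies than decoys, and every pose keeps its true label.
    """
    if not scenario.sites:
        raise ValueError("scenario has no planted sites")
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=scenario.seed, spawn_key=(conformation_index,))
    )
    conf_id = f"conf{conformation_index:03d}"
    weights = np.array([s.weight for s in scenario.sites])
    r_in, r_out = (f * scenario.ring_radius for f in _DECOY_SHELL)
    poses = []
    for i in range(scenario.n_poses_per_conformation):
        rotation = Rotation.random(rng=rng)
        if rng.random() < scenario.decoy_fraction:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radius = (rng.random() * (r_out**3 - r_in**3) + r_in**3) ** (1.0 / 3.0)
            centroid = radius * direction
            energy = rng.normal(*_DECOY_ENERGY)
            label = "decoy"
        else:
            k = int(rng.choice(len(scenario.sites), p=weights))
            site = scenario.sites[k]
            centroid = site.center + rng.normal(0.0, site.noise_sd, size=3)
            energy = rng.normal(*_PLANTED_ENERGY)
            label = f"site{k}"
        poses.append(
            _pose_from_centroid(centroid, rotation, f"{conf_id}_{i:03d}", conf_id,
                                float(energy), label)
        )
    return PoseSet(poses, conformation_id=conf_id)


def gen_distance_trajectory(
    profile: Callable[[int], float] | Sequence[float],
    noise_sd: float,
    n_frames: int,
    seed: int,
) -> np.ndarray:
    """Scalar distance series: deterministic profile plus Gaussian noise."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if callable(profile):
        base = np.array([profile(i) for i in range(n_frames)], dtype=float)
    else:
        base = np.asarray(profile, dtype=float)[:n_frames]
        if len(base) != n_frames:
            raise ValueError("profile sequence shorter than n_frames")
    rng = np.random.default_rng(seed)
    return base + rng.normal(0.0, noise_sd, size=n_frames)


def gen_energy_series(
    asymptote: float,
    drift_amplitude: float,
    drift_decay: float,
    noise_sd: float,
    n_frames: int,
    seed: int,
    label: str = "free_energy",
) -> EnergySeries:
    """Energy trace ``asymptote + amplitude·exp(−i/decay) + N(0, sd)``.

    Emulates a per-frame binding-energy component that relaxes toward
    its equilibrium value during early sampling.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if drift_decay <= 0:
        raise ValueError("drift_decay must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    i = np.arange(n_frames)
    rng = np.random.default_rng(seed)
    values = asymptote + drift_amplitude * np.exp(-i / drift_decay)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=n_frames)
    return EnergySeries(values=values, frame_interval_ps=1.0, label=label)


def provenance_table(pose_sets: Sequence[PoseSet]):
    """True-label provenance for generated pose clouds as a DataFrame."""
    import pandas as pd

    rows = [
        {
            "pose_id": p.pose_id,
            "conformation": ps.conformation_id,
            "site_label": p.site_label,
            "energy": p.docking_energy,
        }
        for ps in pose_sets
        for p in ps.poses
    ]
    return pd.DataFrame(rows)
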