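"""Geometric descriptors of agonist binding and C-loop closure.

The C loop of the nicotinic-receptor agonist site closes over bound
agonists and is held open by antagonists; its degree of closure is
quantified as the Cα–Cα distance between the cysteine at the loop tip
(canonical α C191) and residue 58 on the complementary face.  Calibrated
against agonist-, partial-agonist-, antagonist- and peptide-bound AChBP
crystal structures, that single distance classifies the pharmacological
state of a conformation.  Agonist anchoring is tracked through two
distances: the charged amine to the Trp148 backbone carbonyl oxygen
(hydrogen bond) and to the mass-weighted centre of the Trp148 indole
(cation-π).  RMSD utilities support per-residue profiles and whole-
domain traces with flexible regions (e.g. the Cys loop) excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure_io import Atom, ResidueKey, StructureModel, Trajectory

__all__ = [
    "RangeTable",
    "DEFAULT_CLOOP_RANGES",
    "TRP_INDOLE_ATOMS",
    "SeriesSummary",
    "ca_ca_distance",
    "classify_cloop",
    "hbond_distance",
    "cation_pi_distance",
    "per_residue_rmsd",
    "region_rmsd",
    "sliding_average",
    "series_summary",
]

#: The nine heavy atoms of the tryptophan indole bicyclic system.
TRP_INDOLE_ATOMS = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")


@dataclass
class RangeTable:
    """Closed, non-overlapping distance intervals labelled by state."""

    rows: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("range table is empty")
        for label, lo, hi in self.rows:
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"range {label!r}: bounds must be finite")
            if lo > hi:
                raise ValueError(f"range {label!r}: lower bound exceeds upper")
        ordered = sorted(self.rows, key=lambda r: r[1])
        for (la, _, hi_a), (lb, lo_b, _) in zip(ordered, ordered[1:]):
            if hi_a > lo_b:
                raise ValueError(f"ranges {la!r} and {lb!r} overlap")
        self.rows = ordered


#: Cα–Cα C-loop "openness" ranges (Å) calibrated on AChBP crystal
#: structures, per bound-ligand pharmacology.
DEFAULT_CLOOP_RANGES = RangeTable(
    [
        ("agonist", 7.72, 8.19),
        ("partial agonist", 9.75, 12.30),
        ("antagonist/unbound", 12.88, 16.05),
        ("peptidic antagonist", 17.50, 19.24),
    ]
)


def _require_atom(frame: StructureModel, key: ResidueKey, atom_name: str) -> Atom:
    residue = frame.get_residue(key)
    atom = residue.atom(atom_name)
    if atom is None:
        raise LookupError(f"residue {key} has no atom {atom_name!r}")
    return atom


def ca_ca_distance(frame: StructureModel, key_a: ResidueKey, key_b: ResidueKey) -> float:
    """Euclidean distance (Å) between the designated Cα atoms."""
    ca_a = _require_atom(frame, key_a, "CA")
    ca_b = _require_atom(frame, key_b, "CA")
    return float(np.linalg.norm(ca_a.coords - ca_b.coords))


def classify_cloop(distance: float, range_table: RangeTable = DEFAULT_CLOOP_RANGES) -> str:
    """Pharmacological state for a C-loop closure distance.

    Returns the label of the unique closed interval containing the
    distance.  Distances between intervals return
    ``indeterminate(lower_state, upper_state)``; below the lowest or
    above the highest interval, ``indeterminate(state)`` with the single
    flanking state.  The ranges do not tile the line, and values in the
    gaps are reported as such rather than snapped to a nearest state.
    """
    if distance < 0:
        raise ValueError("distance must be non-negative")
    rows = range_table.rows
    for label, lo, hi in rows:
        if lo <= distance <= hi:
            return label
    if distance < rows[0][1]:
        return f"indeterminate({rows[0][0]})"
    if distance > rows[-1][2]:
        return f"indeterminate({rows[-1][0]})"
    for (la, _, hi_a), (lb, lo_b, _) in zip(rows, rows[1:]):
        if hi_a < distance < lo_b:
            return f"indeterminate({la}, {lb})"
    raise RuntimeError("unreachable: range table not contiguous")  # pragma: no cover


def _cation_coords(ligand_cation_N) -> np.ndarray:
    if isinstance(ligand_cation_N, Atom):
        return ligand_cation_N.coords
    arr = np.asarray(ligand_cation_N, dtype=float)
    if arr.shape != (3,):
        raise ValueError("ligand cation position must be an Atom or 3-vector")
    return arr


def hbond_distance(frame: StructureModel, ligand_cation_N, residue_key: ResidueKey) -> float:
    """Distance (Å) from the ligand's charged N to a backbone carbonyl O."""
    o_atom = _require_atom(frame, residue_key, "O")
    return float(np.linalg.norm(_cation_coords(ligand_cation_N) - o_atom.coords))


def cation_pi_distance(
    frame: StructureModel,
    ligand_cation_N,
    ring_atom_names: Sequence[str],
    residue_key: ResidueKey,
) -> float:
    """Distance (Å) from the ligand's charged N to an aromatic ring's
    mass-weighted centre (centre of mass of the named heavy atoms)."""
    residue = frame.get_residue(residue_key)
    coords, masses = [], []
    for name in ring_atom_names:
        atom = residue.atom(name)
        if atom is None:
            raise LookupError(f"residue {residue_key} lacks ring atom {name!r}")
        coords.append(atom.coords)
        masses.append(atom.mass)
    coords = np.array(coords)
    masses = np.array(masses)
    center = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    return float(np.linalg.norm(_cation_coords(ligand_cation_N) - center))


# ---------------------------------------------------------------------------
# RMSD analyses


def _superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[Rotation, np.ndarray, np.ndarray]:
    """Kabsch fit of ``mobile`` onto ``reference`` (both N×3).

    Returns the rotation plus the two centroids; apply as
    ``rot.apply(x - mob_centroid) + ref_centroid``.
    """
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c)
    return rot, mob_c, ref_c


def _collect(frame: StructureModel, keys: Iterable[ResidueKey],
             atom_filter=None) -> np.ndarray:
    coords = []
    for key in keys:
        for atom in frame.get_residue(key).atoms:
            if atom_filter is None or atom_filter(atom):
                coords.append(atom.coords)
    return np.array(coords) if coords else np.empty((0, 3))


_BACKBONE_NAMES = ("N", "CA", "C", "O")


def per_residue_rmsd(
    trajectory: Trajectory,
    reference_frame: StructureModel,
    selection: Sequence[ResidueKey] | None = None,
    superpose: bool = True,
) -> pd.Series:
    """Frame-averaged all-atom RMSD per residue versus a reference.

    Each frame is first globally superposed onto the reference using the
    backbone atoms of the selection (set ``superpose=False`` to compare
    raw coordinates); the per-residue all-atom RMSD against the
    reference is then averaged over frames.  Returns a Series indexed by
    residue key string.
    """
    keys = list(selection) if selection is not None else [r.key for r in reference_frame.residues()]
    if not keys:
        raise ValueError("empty residue selection")
    is_backbone = lambda a: a.name in _BACKBONE_NAMES
    ref_bb = _collect(reference_frame, keys, is_backbone)
    ref_res = {k: _collect(reference_frame, [k]) for k in keys}
    sums = {k: 0.0 for k in keys}
    for frame in trajectory.frames:
        if superpose:
            mob_bb = _collect(frame, keys, is_backbone)
            if len(mob_bb) == 0 or len(mob_bb) != len(ref_bb):
                raise ValueError("backbone selection mismatch between frame and reference")
            rot, mob_c, ref_c = _superpose(mob_bb, ref_bb)
        for key in keys:
            xyz = _collect(frame, [key])
            if superpose:
                xyz = rot.apply(xyz - mob_c) + ref_c
            diff = xyz - ref_res[key]
            sums[key] += float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    n = len(trajectory.frames)
    return pd.Series({str(k): sums[k] / n for k in keys}, name="rmsd")


def region_rmsd(
    trajectory: Trajectory,
    reference_frame: StructureModel,
    exclude: Sequence[ResidueKey] = (),
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame all-atom RMSD over all residues outside ``exclude``.

    Superposition (when enabled) is fit on the included selection, so a
    flexible excluded region — e.g. an unstable Cys loop — influences
    neither the fit nor the reported deviation.
    """
    excluded = set(exclude)
    keys = [r.key for r in reference_frame.residues() if r.key not in excluded]
    if not keys:
        raise ValueError("exclusion covers every residue")
    ref = _collect(reference_frame, keys)
    out = np.empty(len(trajectory.frames))
    for i, frame in enumerate(trajectory.frames):
        xyz = _collect(frame, keys)
        if xyz.shape != ref.shape:
            raise ValueError(f"frame {i}: selection atom count differs from reference")
        if superpose:
            rot, mob_c, ref_c = _superpose(xyz, ref)
            xyz = rot.apply(xyz - mob_c) + ref_c
        out[i] = np.sqrt(np.mean(np.sum((xyz - ref) ** 2, axis=1)))
    return out


# ---------------------------------------------------------------------------
# Series statistics


def sliding_average(series, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Moving mean over trailing windows, plus the per-window SD.

    Output length is ``len(series) − window + 1``; the i-th entry covers
    ``series[i : i + window]``.
    """
    values = np.asarray(series, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("series must be non-empty and 1-D")
    if not 1 <= window <= len(values):
        raise ValueError(f"window must lie in [1, {len(values)}], got {window}")
    windows = np.lib.stride_tricks.sliding_window_view(values, window)
    return windows.mean(axis=1), windows.std(axis=1)


@dataclass
class SeriesSummary:
    """Mean with population SD, formatted like the study's tables."""

    mean: float
    sd: float
    minimum: float | None = None

    def __str__(self) -> str:
        base = f"{self.mean:.2f} ({self.sd:.2f})"
        if self.minimum is not None:
            base += f" min {self.minimum:.2f}"
        return base


def series_summary(series, with_min: bool = False) -> SeriesSummary:
    """Arithmetic mean and population SD of a series, 2-decimal formatting.

    ``with_min=True`` also records the series minimum, mirroring tables
    that report a minimum approach distance alongside the average.
    """
    values = np.asarray(series, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise ValueError("series must be non-empty and 1-D")
    return SeriesSummary(
        mean=float(values.mean()),
        sd=float(values.std()),
        minimum=float(values.min()) if with_min else None,
    )
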