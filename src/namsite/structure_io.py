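"""Structural containers and PDB/PDBQT input-output.

The pipeline works on light-weight containers (chains → residues → atoms
with coordinates in Å) rather than a full crystallographic data model:
residue identity is ``(chain_id, residue_number, insertion_code)`` so that
point mutants keep comparable contact fingerprints, and multi-model PDB
files map to :class:`Trajectory` objects whose frames share topology
exactly.  Reading of standard PDB goes through Bio.PDB in strict mode;
writing and the minimal PDBQT dialect (atom records plus a docking-energy
remark) are handled directly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "Atom",
    "ResidueKey",
    "Residue",
    "Chain",
    "StructureModel",
    "Trajectory",
    "Pose",
    "PoseSet",
    "NumberingMap",
    "read_structure",
    "write_structure",
    "read_pose_set",
    "write_pose_set",
    "load_numbering_map",
    "resolve_label",
]

#: Standard atomic masses (u) for the elements that occur in these models.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "F": 18.998,
    "CL": 35.45,
    "BR": 79.904,
}


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of a residue: chain, number and insertion code.

    The residue *name* is deliberately not part of the identity, so a
    T58K mutant and the wild type produce comparable contact
    fingerprints at the same position.
    """

    chain_id: str
    residue_number: int
    insertion_code: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.residue_number}{self.insertion_code}"


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"atom {self.name!r}: coordinates must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: non-finite coordinates")
        if not self.element:
            self.element = _guess_element(self.name)
        self.element = self.element.upper()
        if self.element in ("H", "D"):
            self.is_hydrogen = True

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element, 12.011)


@dataclass
class Residue:
    key: ResidueKey
    name: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    @property
    def backbone_o(self) -> Atom | None:
        return self.atom("O")

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class StructureModel:
    """One frame: ordered chains of ordered residues of ordered atoms."""

    chains: list[Chain] = field(default_factory=list)
    frame_index: int | None = None

    def __post_init__(self) -> None:
        self._index: dict[ResidueKey, Residue] | None = None

    def residues(self):
        for chain in self.chains:
            yield from chain.residues

    def atoms(self):
        for res in self.residues():
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.atoms())

    def get_residue(self, key: ResidueKey) -> Residue:
        if self._index is None:
            self._index = {r.key: r for r in self.residues()}
        try:
            return self._index[key]
        except KeyError:
            raise LookupError(f"residue {key} not found in model") from None

    def topology_signature(self) -> tuple:
        return tuple(
            (r.key, r.name, tuple(a.name for a in r.atoms)) for r in self.residues()
        )

    def coordinate_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms()], dtype=float)

    def set_coordinates(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        atoms = list(self.atoms())
        if coords.shape != (len(atoms), 3):
            raise ValueError("coordinate array shape does not match topology")
        for atom, xyz in zip(atoms, coords):
            atom.coords = xyz.copy()

    def heavy_atom_table(self) -> tuple[np.ndarray, list[ResidueKey]]:
        """Coordinates of all heavy atoms plus the owning residue per row."""
        coords, owners = [], []
        for res in self.residues():
            for a in res.heavy_atoms:
                coords.append(a.coords)
                owners.append(res.key)
        if not coords:
            return np.empty((0, 3)), []
        return np.array(coords, dtype=float), owners

    def copy(self) -> "StructureModel":
        chains = [
            Chain(
                c.chain_id,
                [
                    Residue(
                        r.key,
                        r.name,
                        [Atom(a.name, a.element, a.coords.copy(), a.is_hydrogen) for a in r.atoms],
                    )
                    for r in c.residues
                ],
            )
            for c in self.chains
        ]
        return StructureModel(chains, frame_index=self.frame_index)


@dataclass
class Trajectory:
    """Ordered frames sharing topology; optional frame spacing in ps."""

    frames: list[StructureModel]
    frame_interval_ps: float | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        sig0 = self.frames[0].topology_signature()
        for i, frame in enumerate(self.frames[1:], start=1):
            if frame.topology_signature() != sig0:
                raise ValueError(f"frame {i} topology differs from frame 0")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> StructureModel:
        return self.frames[i]


@dataclass
class Pose:
    """One docked ligand conformation with an optional docking energy."""

    atoms: list[Atom]
    docking_energy: float | None = None
    pose_id: str = ""
    conformation_id: str = ""
    site_label: str | None = None  # synthetic provenance; None for real data

    def __post_init__(self) -> None:
        if not any(not a.is_hydrogen for a in self.atoms):
            raise ValueError(f"pose {self.pose_id!r}: needs at least one heavy atom")

    @property
    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if not a.is_hydrogen])

    @property
    def all_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])


@dataclass
class PoseSet:
    poses: list[Pose]
    conformation_id: str = ""

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)


# ---------------------------------------------------------------------------
# PDB reading / writing


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR"):
        return stripped[:2].upper()
    return (stripped[:1] or "C").upper()


def _from_biopdb_model(model, frame_index: int) -> StructureModel:
    chains = []
    for bchain in model:
        chain = Chain(bchain.id)
        for bres in bchain:
            het, resnum, icode = bres.id
            key = ResidueKey(bchain.id, resnum, icode.strip())
            res = Residue(key, bres.get_resname().strip())
            for batom in bres:  # disordered atoms yield highest-occupancy altloc
                res.atoms.append(
                    Atom(
                        batom.get_name(),
                        (batom.element or "").strip(),
                        np.asarray(batom.get_coord(), dtype=float),
                    )
                )
            chain.residues.append(res)
        chains.append(chain)
    return StructureModel(chains, frame_index=frame_index)


def read_structure(path, fmt: str = "pdb") -> Trajectory:
    """Read a single- or multi-model PDB file into a :class:`Trajectory`.

    One frame per MODEL record (a single frame if the file has none);
    HETATM ligands are retained as their own residues and hydrogens are
    flagged by element.  Raises :class:`ValueError` naming the offending
    line for unparseable records, and for topology that changes between
    MODEL blocks.
    """
    if fmt != "pdb":
        raise ValueError(f"unsupported structure format: {fmt!r}")
    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        structure = parser.get_structure("s", str(path))
    except PDBConstructionException as exc:
        raise ValueError(f"unparseable PDB record in {path}: {exc}") from exc
    frames = [_from_biopdb_model(m, i) for i, m in enumerate(structure)]
    if not frames:
        raise ValueError(f"{path}: no models found")
    try:
        return Trajectory(frames)
    except ValueError as exc:
        raise ValueError(f"{path}: inconsistent topology across MODELs ({exc})") from exc


def _format_atom_line(
    record: str, serial: int, atom: Atom, resname: str, key: ResidueKey
) -> str:
    name = atom.name
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    x, y, z = atom.coords
    return (
        f"{record:<6s}{serial:>5d} {name:<4s} {resname:>3s} {key.chain_id[:1]:1s}"
        f"{key.residue_number:>4d}{(key.insertion_code or ' '):1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          "
        f"{atom.element:>2s}"
    )


def _write_model(handle, model: StructureModel, hetero: bool = False) -> None:
    serial = 1
    for chain in model.chains:
        for res in chain.residues:
            record = "HETATM" if hetero else "ATOM"
            for atom in res.atoms:
                handle.write(_format_atom_line(record, serial, atom, res.name, res.key) + "\n")
                serial += 1
        handle.write("TER\n")


def write_structure(path, obj: StructureModel | Trajectory) -> None:
    """Write a model or trajectory as (multi-model) PDB, 3-decimal Å."""
    frames = obj.frames if isinstance(obj, Trajectory) else [obj]
    with open(path, "w") as fh:
        if len(frames) == 1:
            _write_model(fh, frames[0])
        else:
            for i, frame in enumerate(frames, start=1):
                fh.write(f"MODEL     {i:>4d}\n")
                _write_model(fh, frame)
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Pose-set reading / writing

_ENERGY_PATTERNS = (
    re.compile(r"REMARK\s+VINA\s+RESULT:\s+(-?\d+\.?\d*)"),
    re.compile(r"REMARK\s+ENERGY\s+(-?\d+\.?\d*)"),
    re.compile(r"USER\s+Estimated Free Energy of Binding\s*=\s*(-?\d+\.?\d*)"),
)

# PDBQT atom-type → element, for the types that matter here
_PDBQT_TYPES = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N", "OA": "O", "OS": "O",
    "SA": "S", "S": "S", "H": "H", "HD": "H", "HS": "H", "F": "F", "CL": "CL",
    "BR": "BR", "P": "P",
}


def _parse_pose_atom(line: str, lineno: int, pdbqt: bool) -> Atom:
    try:
        name = line[12:16].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError):
        raise ValueError(f"unparseable atom record at line {lineno}") from None
    if pdbqt:
        # charge + AutoDock atom type trail the B-factor; take the last token
        tail = line[66:].split()
        atype = tail[-1].upper() if tail else ""
        element = _PDBQT_TYPES.get(atype, _guess_element(name))
    else:
        element = line[76:78].strip() or _guess_element(name)
    return Atom(name, element, np.array([x, y, z]))


def read_pose_set(path, fmt: str = "pdb_multimodel", conformation_id: str = "") -> PoseSet:
    """Read docked poses from multi-model PDB or PDBQT.

    One :class:`Pose` per MODEL/ENDMDL block (a single pose if the file
    has none); the docking energy is taken from the dialect's energy
    remark line when present and left absent otherwise.  PDBQT support
    is minimal and read-only: torsion-tree records are ignored.
    """
    if fmt not in ("pdb_multimodel", "pdbqt"):
        raise ValueError(f"unsupported pose format: {fmt!r}")
    pdbqt = fmt == "pdbqt"
    poses: list[Pose] = []
    atoms: list[Atom] = []
    energy: float | None = None
    in_block = False

    def flush(model_no: int) -> None:
        nonlocal atoms, energy
        if atoms:
            poses.append(
                Pose(
                    atoms,
                    docking_energy=energy,
                    pose_id=f"{conformation_id or 'pose'}_{model_no:03d}",
                    conformation_id=conformation_id,
                )
            )
        atoms, energy = [], None

    model_no = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                in_block = True
                continue
            if rec == "ENDMDL":
                flush(model_no)
                model_no += 1
                in_block = False
                continue
            if rec in ("ATOM", "HETATM"):
                atoms.append(_parse_pose_atom(line, lineno, pdbqt))
                continue
            if energy is None:
                for pat in _ENERGY_PATTERNS:
                    m = pat.match(line)
                    if m:
                        energy = float(m.group(1))
                        break
    flush(model_no)
    if not poses:
        raise ValueError(f"{path}: no ligand atoms found")
    return PoseSet(poses, conformation_id=conformation_id)


def write_pose_set(path, pose_set: PoseSet) -> None:
    """Write poses as multi-model PDB with a ``REMARK ENERGY`` per model."""
    with open(path, "w") as fh:
        for i, pose in enumerate(pose_set.poses, start=1):
            fh.write(f"MODEL     {i:>4d}\n")
            if pose.docking_energy is not None:
                fh.write(f"REMARK ENERGY {pose.docking_energy:.3f}\n")
            key = ResidueKey("L", 1)
            for serial, atom in enumerate(pose.atoms, start=1):
                fh.write(_format_atom_line("HETATM", serial, atom, "LIG", key) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Numbering map


@dataclass
class NumberingMap:
    """Canonical residue labels (e.g. ``alpha:C191``) → per-chain residues.

    Keys are ``(canonical_label, chain_id)`` pairs so the same canonical
    position resolves independently on each chain it occurs on.
    """

    entries: dict[tuple[str, str], ResidueKey] = field(default_factory=dict)

    def add(self, label: str, key: ResidueKey) -> None:
        self.entries[(label, key.chain_id)] = key


def load_numbering_map(path) -> NumberingMap:
    """Load a plain-text numbering map.

    Each non-comment line: ``canonical_label  chain_id  residue_number
    [insertion_code]``, whitespace-separated.
    """
    nmap = NumberingMap()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (3, 4):
                raise ValueError(f"{path}:{lineno}: expected 'label chain resnum [icode]'")
            label, chain_id, resnum = parts[0], parts[1], parts[2]
            icode = parts[3] if len(parts) == 4 else ""
            try:
                num = int(resnum)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: residue number {resnum!r} not an integer") from None
            nmap.add(label, ResidueKey(chain_id, num, icode))
    return nmap


def resolve_label(nmap: NumberingMap, canonical_label: str, chain_id: str) -> ResidueKey:
    """Resolve a canonical label on one chain; fails rather than guessing."""
    try:
        return nmap.entries[(canonical_label, chain_id)]
    except KeyError:
        raise LookupError(
            f"label {canonical_label!r} on chain {chain_id!r} not in numbering map"
        ) from None
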