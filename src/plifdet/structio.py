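"""Molecular structure I/O and docking-box geometry.

Reads the file formats produced by a typical AutoDock Vina virtual-screening
campaign — PDB receptors, Mol2 co-crystal ligands, multi-MODEL PDBQT pose
ensembles — into light-weight atom/structure containers, and computes the
docking box and the ordered binding-site residue list that defines the
fingerprint bit layout downstream.

Parsers are deliberately column-oriented and tolerant: screening-era PDB
files frequently lack the element column, so the element is inferred from
the atom name when absent.  Coordinates are in Angstrom throughout.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Structure",
    "PoseSet",
    "DockingBox",
    "VinaConfig",
    "ResidueRef",
    "ParseError",
    "read_pdb",
    "write_pdb",
    "read_pdbqt_poses",
    "write_pdbqt_poses",
    "read_mol2",
    "compute_box",
    "list_box_residues",
    "write_vina_config",
    "read_vina_config",
]


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed; names the offending line."""


#: Backbone heavy-atom names of standard amino acids (plus the terminal OXT).
BACKBONE_HEAVY = {"N", "CA", "C", "O", "OXT"}
#: Hydrogen names attached to the backbone (amide H, alpha H, terminal H's).
BACKBONE_H = {"H", "HN", "HA", "H1", "H2", "H3", "HA2", "HA3", "HXT"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_TWO_LETTER_ELEMENTS = {"CL", "BR", "FE", "ZN", "MG", "MN", "NA", "CA", "SI", "SE"}


def infer_element(atom_name: str, residue_name: str = "") -> str:
    """Guess the element from a PDB atom name when the element column is blank.

    Digits and primes are stripped; two-letter elements (Cl, Br, Zn, ...) are
    recognised, except inside standard residues where 'CA' is an alpha carbon.
    """
    stripped = re.sub(r"[0-9'\"]", "", atom_name).strip().upper()
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    if residue_name.upper() not in STANDARD_AA and stripped[:2] in _TWO_LETTER_ELEMENTS:
        return stripped[0] + stripped[1].lower()
    return stripped[0]


class ResidueRef(NamedTuple):
    """Stable identifier of a residue: chain, sequence number, 3-letter name."""

    chain_id: str
    residue_number: int
    residue_name: str

    def __str__(self) -> str:  # e.g. "A:ASP113"
        return f"{self.chain_id}:{self.residue_name}{self.residue_number}"


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    residue_number: int
    residue_name: str
    chain_id: str
    is_backbone: bool = False
    partial_charge: float | None = None
    is_hetatm: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.serial}: element must be non-empty")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


def _backbone_flag(atom: Atom) -> bool:
    if atom.is_hetatm or atom.residue_name.upper() not in STANDARD_AA:
        return False
    name = atom.name.upper()
    return name in BACKBONE_HEAVY or name in BACKBONE_H


@dataclass
class Structure:
    """An ordered list of atoms with a derived residue grouping."""

    atoms: list[Atom] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.vstack([a.coords for a in self.atoms])

    def residues(self) -> list[tuple[ResidueRef, list[Atom]]]:
        """Group atoms by (chain, residue number) preserving file order."""
        groups: dict[tuple[str, int], tuple[ResidueRef, list[Atom]]] = {}
        for atom in self.atoms:
            key = (atom.chain_id, atom.residue_number)
            if key not in groups:
                ref = ResidueRef(atom.chain_id, atom.residue_number, atom.residue_name)
                groups[key] = (ref, [])
            groups[key][1].append(atom)
        return list(groups.values())

    def residue_atoms(self, ref: ResidueRef) -> list[Atom]:
        return [
            a for a in self.atoms
            if a.chain_id == ref.chain_id and a.residue_number == ref.residue_number
        ]

    def protein(self) -> "Structure":
        """ATOM records of standard residues (drops HETATM ligand/water)."""
        return Structure([a for a in self.atoms
                          if not a.is_hetatm and a.residue_name.upper() in STANDARD_AA])

    def het(self) -> "Structure":
        return Structure([a for a in self.atoms if a.is_hetatm])

    def heavy(self) -> "Structure":
        return Structure([a for a in self.atoms if a.is_heavy])


@dataclass
class PoseSet:
    """A docked pose ensemble for one compound, best affinity first."""

    compound_name: str
    poses: list[Structure] = field(default_factory=list)
    affinities: list[float] = field(default_factory=list)  # kcal/mol
    no_poses: bool = False

    def __post_init__(self) -> None:
        if len(self.poses) != len(self.affinities):
            raise ValueError("one affinity is required per pose")
        if not self.poses:
            self.no_poses = True

    def __len__(self) -> int:
        return len(self.poses)

    @property
    def best_affinity(self) -> float:
        if self.no_poses:
            raise ValueError(f"{self.compound_name}: no poses")
        return self.affinities[0]


@dataclass
class DockingBox:
    """Axis-aligned search box around the co-crystal ligand."""

    center: np.ndarray
    size: np.ndarray
    margin: float = 5.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.size = np.asarray(self.size, dtype=float)
        if np.any(self.size <= 0):
            raise ValueError("box size components must be positive")

    def contains(self, point: np.ndarray) -> bool:
        """Closed-interval membership test."""
        d = np.abs(np.asarray(point, dtype=float) - self.center)
        return bool(np.all(d <= self.size / 2.0 + 1e-9))


@dataclass
class VinaConfig:
    """Configuration file contents for an AutoDock Vina run."""

    receptor_path: str
    ligand_path: str
    center_x: float
    center_y: float
    center_z: float
    size_x: float
    size_y: float
    size_z: float
    num_modes: int = 10
    energy_range: float = 5.0
    cpu: int = 8
    log: str = "out.log"

    def __post_init__(self) -> None:
        if not self.receptor_path or not self.ligand_path:
            raise ValueError("receptor and ligand paths are required")
        if self.num_modes < 1:
            raise ValueError("num_modes must be >= 1")
        if self.energy_range < 0:
            raise ValueError("energy_range must be >= 0")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _parse_pdb_atom(line: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21].strip() or " "
        residue_number = int(line[22:26])
        coords = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = infer_element(name, residue_name)
    element = element[0].upper() + element[1:].lower()
    atom = Atom(
        serial=serial, name=name, element=element, coords=np.array(coords),
        residue_number=residue_number, residue_name=residue_name,
        chain_id=chain_id, is_hetatm=line.startswith("HETATM"),
    )
    atom.is_backbone = _backbone_flag(atom)
    return atom


def read_pdb(path, chain_filter: str | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    ATOM and HETATM records are both kept (distinguished by ``is_hetatm``);
    ``chain_filter`` keeps only atoms of the matching chain.  An empty
    selection is returned as an empty structure with a logged warning.
    """
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                atom = _parse_pdb_atom(line, lineno)
                if chain_filter is not None and atom.chain_id != chain_filter:
                    continue
                atoms.append(atom)
    if chain_filter is not None and not atoms:
        logger.warning("chain filter %r matched no atoms in %s", chain_filter, path)
    return Structure(atoms)


def write_pdb(structure: Structure, path) -> None:
    with open(path, "w") as fh:
        for atom in structure.atoms:
            fh.write(_format_pdb_line(atom))
        fh.write("END\n")


def _format_pdb_line(atom: Atom, record: str | None = None) -> str:
    record = record or ("HETATM" if atom.is_hetatm else "ATOM  ")
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    x, y, z = atom.coords
    return (
        f"{record}{atom.serial:>5d} {name:<4s}{'':1s}{atom.residue_name:>3s} "
        f"{atom.chain_id:1s}{atom.residue_number:>4d}{'':4s}"
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}{'':10s}{atom.element:>2s}\n"
    )


# ---------------------------------------------------------------------------
# PDBQT (AutoDock Vina pose ensembles)
# ---------------------------------------------------------------------------

#: AutoDock atom type -> chemical element.
_AUTODOCK_TYPES = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N", "OA": "O", "OS": "O",
    "O": "O", "S": "S", "SA": "S", "H": "H", "HD": "H", "HS": "H", "P": "P",
    "F": "F", "CL": "Cl", "BR": "Br", "I": "I", "SI": "Si", "FE": "Fe",
    "ZN": "Zn", "MG": "Mg", "MN": "Mn",
}

_VINA_REMARK = re.compile(r"REMARK VINA RESULT:\s+(-?\d+(?:\.\d+)?)")


def read_pdbqt_poses(path, compound_name: str | None = None) -> PoseSet:
    """Read a multi-MODEL PDBQT file written by AutoDock Vina.

    One pose per MODEL block, with the binding affinity (kcal/mol) taken from
    the ``REMARK VINA RESULT`` line of each block.  A file without MODEL
    blocks yields an empty pose set flagged ``no_poses`` — the route taken by
    compounds for which docking produced no output.
    """
    name = compound_name or str(path)
    poses: list[Structure] = []
    affinities: list[float] = []
    current: list[Atom] | None = None
    current_affinity: float | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("MODEL"):
                current, current_affinity = [], None
            elif line.startswith("ENDMDL"):
                if current is None:
                    raise ParseError(f"line {lineno}: ENDMDL without MODEL")
                if current_affinity is None:
                    raise ParseError(
                        f"line {lineno}: pose without REMARK VINA RESULT affinity")
                poses.append(Structure(current))
                affinities.append(current_affinity)
                current = None
            elif line.startswith("REMARK") and current is not None:
                m = _VINA_REMARK.search(line)
                if m:
                    current_affinity = float(m.group(1))
            elif line.startswith(("ATOM  ", "HETATM")) and current is not None:
                current.append(_parse_pdbqt_atom(line, lineno))
    return PoseSet(compound_name=name, poses=poses, affinities=affinities)


def _parse_pdbqt_atom(line: str, lineno: int) -> Atom:
    atom = _parse_pdb_atom(line[:54].ljust(54) + line[54:76].ljust(22), lineno)
    # PDBQT trailing columns: partial charge then AutoDock atom type.
    try:
        atom.partial_charge = float(line[70:76])
    except (ValueError, IndexError):
        atom.partial_charge = None
    ad_type = line[77:79].strip().upper() if len(line) > 77 else ""
    if ad_type in _AUTODOCK_TYPES:
        atom.element = _AUTODOCK_TYPES[ad_type]
    return atom


def write_pdbqt_poses(pose_set: PoseSet, path) -> None:
    """Write a pose ensemble in Vina's multi-MODEL PDBQT layout."""
    inverse = {"C": "C", "N": "N", "O": "OA", "S": "SA", "H": "HD", "P": "P",
               "F": "F", "Cl": "Cl", "Br": "Br", "I": "I", "Si": "Si"}
    with open(path, "w") as fh:
        for i, (pose, dg) in enumerate(zip(pose_set.poses, pose_set.affinities), start=1):
            fh.write(f"MODEL {i}\n")
            fh.write(f"REMARK VINA RESULT:    {dg:8.1f}      0.000      0.000\n")
            for atom in pose.atoms:
                base = _format_pdb_line(atom, record="ATOM  ").rstrip("\n")
                charge = atom.partial_charge if atom.partial_charge is not None else 0.0
                ad = inverse.get(atom.element, atom.element.upper())
                fh.write(f"{base[:66]}    {charge:6.3f} {ad:<2s}\n")
            fh.write("ENDMDL\n")


# ---------------------------------------------------------------------------
# Mol2 (co-crystal ligands, compound libraries)
# ---------------------------------------------------------------------------

def read_mol2(path) -> list[Structure]:
    """Read a (possibly multi-molecule) Mol2 file; one Structure per molecule.

    Only the ATOM section is interpreted: serial, name, coordinates, SYBYL
    atom type (element = part before the dot) and, when present, the partial
    charge.  This mirrors splitting a library with Open Babel's "separate".
    """
    molecules: list[Structure] = []
    atoms: list[Atom] | None = None
    section = ""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("@<TRIPOS>"):
                section = stripped[9:].upper()
                if section == "MOLECULE":
                    if atoms is not None:
                        molecules.append(Structure(atoms))
                    atoms = []
                continue
            if section == "ATOM" and stripped and atoms is not None:
                parts = stripped.split()
                if len(parts) < 6:
                    raise ParseError(f"line {lineno}: malformed Mol2 ATOM record")
                try:
                    serial = int(parts[0])
                    coords = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: malformed Mol2 ATOM record: {exc}") from exc
                element = parts[5].split(".")[0]
                charge = float(parts[8]) if len(parts) > 8 else None
                atoms.append(Atom(
                    serial=serial, name=parts[1], element=element, coords=coords,
                    residue_number=int(parts[6]) if len(parts) > 6 else 1,
                    residue_name=(parts[7][:3] if len(parts) > 7 else "LIG"),
                    chain_id=" ", partial_charge=charge, is_hetatm=True,
                ))
    if atoms is not None:
        molecules.append(Structure(atoms))
    return molecules


# ---------------------------------------------------------------------------
# Docking box and binding-site residues
# ---------------------------------------------------------------------------

def compute_box(cocrystal: Structure, margin: float = 5.0) -> DockingBox:
    """Docking box centred on the co-crystal ligand.

    The centre is the midpoint of the heavy-atom axis-aligned bounding box and
    each edge extends the heavy-atom extent by ``margin`` (default 5 A) on
    both sides.  Hydrogens are excluded: their placement depends on the
    preparation protocol, the heavy-atom envelope does not.
    """
    heavy = cocrystal.heavy()
    if not heavy.atoms:
        raise ValueError("co-crystal ligand has no heavy atoms")
    xyz = heavy.coords
    lo, hi = xyz.min(axis=0), xyz.max(axis=0)
    return DockingBox(center=(lo + hi) / 2.0, size=(hi - lo) + 2.0 * margin,
                      margin=margin)


def list_box_residues(
    receptor: Structure,
    box: DockingBox,
    criterion: str = "any_heavy",
) -> list[ResidueRef]:
    """Ordered binding-site residue list; this ordering defines the
    fingerprint bit layout downstream.

    A residue is included when any of its heavy atoms lies inside the closed
    box (``criterion='any_heavy'``, the default) or when its alpha carbon
    does (``criterion='ca'``).  Output is sorted by (chain, residue number).
    """
    if criterion not in ("any_heavy", "ca"):
        raise ValueError(f"unknown criterion {criterion!r}")
    selected: dict[ResidueRef, bool] = {}
    for ref, atoms in receptor.protein().residues():
        if criterion == "any_heavy":
            hit = any(a.is_heavy and box.contains(a.coords) for a in atoms)
        else:
            hit = any(a.name.upper() == "CA" and box.contains(a.coords) for a in atoms)
        if hit:
            selected[ref] = True
    return sorted(selected, key=lambda r: (r.chain_id, r.residue_number))


# ---------------------------------------------------------------------------
# Vina configuration files
# ---------------------------------------------------------------------------

_CONFIG_FIELDS = [
    ("receptor", "receptor_path", str), ("ligand", "ligand_path", str),
    ("center_x", "center_x", float), ("center_y", "center_y", float),
    ("center_z", "center_z", float), ("size_x", "size_x", float),
    ("size_y", "size_y", float), ("size_z", "size_z", float),
    ("num_modes", "num_modes", int), ("energy_range", "energy_range", float),
    ("cpu", "cpu", int), ("log", "log", str),
]


def write_vina_config(cfg: VinaConfig, path) -> None:
    """Emit ``key = value`` lines in Vina's configuration grammar."""
    with open(path, "w") as fh:
        for key, attr, _ in _CONFIG_FIELDS:
            value = getattr(cfg, attr)
            if isinstance(value, float):
                value = f"{value:g}"
            fh.write(f"{key} = {value}\n")


def read_vina_config(path) -> VinaConfig:
    values: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if "=" in line:
                key, _, raw = line.partition("=")
                values[key.strip()] = raw.strip()
    kwargs = {}
    for key, attr, conv in _CONFIG_FIELDS:
        if key in values:
            kwargs[attr] = conv(values[key])
    return VinaConfig(**kwargs)


def write_residue_list(residues: Sequence[ResidueRef], path) -> None:
    """One residue per line: ``chain residue_number residue_name``."""
    with open(path, "w") as fh:
        for ref in residues:
            fh.write(f"{ref.chain_id} {ref.residue_number} {ref.residue_name}\n")


def read_residue_list(path) -> list[ResidueRef]:
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                out.append(ResidueRef(parts[0], int(parts[1]), parts[2]))
    return out


def vina_config_from_box(
    box: DockingBox, receptor_path: str, ligand_path: str, **overrides
) -> VinaConfig:
    """Convenience: a VinaConfig whose box fields come from a DockingBox."""
    cx, cy, cz = box.center
    sx, sy, sz = box.size
    return VinaConfig(
        receptor_path=receptor_path, ligand_path=ligand_path,
        center_x=cx, center_y=cy, center_z=cz,
        size_x=sx, size_y=sy, size_z=sz, **overrides,
    )
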