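"""Protein-ligand interaction fingerprints (PLIF).

Seven interaction types are detected per binding-site residue, in a fixed
order that defines the bit positions of the fingerprint:

    1  hydrophobic contact
    2  aromatic face-to-face
    3  aromatic edge-to-face
    4  hydrogen bond, protein as donor
    5  hydrogen bond, protein as acceptor
    6  ionic, protein as cation
    7  ionic, protein as anion

The concatenation over an ordered binding-site residue list gives a
bitstring of length 7 x n_residues; descriptor index k (1-based) therefore
maps to residue rank ((k-1) // 7) + 1 and type code ((k-1) mod 7) + 1.
This is the layout implied by published ensPLIF descriptor listings (e.g.
ensPLIF-63 = 9th residue, ionic with the protein as the anion).

Protein atoms are typed from a per-residue template table; ligand poses are
typed from elements plus distance-based bond perception.  The ``nobb``
option removes backbone atoms from every protein category before detection,
emulating side-chain-only (mutagenesis-like) interactions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .structio import Atom, ResidueRef, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionType",
    "GeomThresholds",
    "AromaticRing",
    "Donor",
    "AtomTyping",
    "Fingerprint",
    "type_protein_residue",
    "type_ligand_pose",
    "detect_bits",
    "fingerprint_pose",
    "fingerprint_poses",
    "bit_to_descriptor",
    "N_INTERACTION_TYPES",
]

N_INTERACTION_TYPES = 7


class InteractionType(IntEnum):
    """The seven interaction types, in bit order (order is immutable)."""

    HYDROPHOBIC = 1
    AROMATIC_FACE_TO_FACE = 2
    AROMATIC_EDGE_TO_FACE = 3
    HBOND_PROTEIN_DONOR = 4
    HBOND_PROTEIN_ACCEPTOR = 5
    IONIC_PROTEIN_CATION = 6
    IONIC_PROTEIN_ANION = 7

    @property
    def label(self) -> str:
        return _TYPE_LABELS[self]


_TYPE_LABELS = {
    InteractionType.HYDROPHOBIC: "hydrophobic",
    InteractionType.AROMATIC_FACE_TO_FACE: "aromatic face-to-face",
    InteractionType.AROMATIC_EDGE_TO_FACE: "aromatic edge-to-face",
    InteractionType.HBOND_PROTEIN_DONOR: "h-bond (protein as donor)",
    InteractionType.HBOND_PROTEIN_ACCEPTOR: "h-bond (protein as acceptor)",
    InteractionType.IONIC_PROTEIN_CATION: "ionic (protein as cation)",
    InteractionType.IONIC_PROTEIN_ANION: "ionic (protein as anion)",
}

LABEL_TO_TYPE = {v: k for k, v in _TYPE_LABELS.items()}


@dataclass(frozen=True)
class GeomThresholds:
    """Geometric cutoffs for interaction detection.

    The values follow the classic interaction-fingerprint lineage; all are
    configurable.  Distances in Angstrom, angles in degrees.  An interplanar
    angle of exactly ``f2f_angle_max`` classifies as face-to-face (closed
    upper bound).
    """

    hydrophobic_dmax: float = 4.5
    hbond_dmax: float = 3.5          # donor-acceptor heavy-atom distance
    hbond_angle_min: float = 135.0   # D-H...A angle, explicit hydrogens
    pseudo_angle_min: float = 120.0  # D-H...A angle with a pseudo-H (no explicit H)
    ionic_dmax: float = 5.6          # charged-group centre distance
    aromatic_dmax: float = 4.5      # ring centroid-centroid distance
    f2f_angle_max: float = 30.0      # interplanar angle, face-to-face
    e2f_angle_max: float = 90.0      # edge-to-face upper bound

    def __post_init__(self) -> None:
        for name in ("hydrophobic_dmax", "hbond_dmax", "ionic_dmax", "aromatic_dmax"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.f2f_angle_max < 90:
            raise ValueError("f2f_angle_max must lie in (0, 90)")


@dataclass
class AromaticRing:
    atoms: list[Atom]
    centroid: np.ndarray
    normal: np.ndarray  # unit vector


@dataclass
class Donor:
    heavy: Atom
    hydrogens: list[Atom]          # may be empty (implicit-H fallback)
    neighbor_centroid: np.ndarray | None = None  # for pseudo-H placement


@dataclass
class AtomTyping:
    """Pharmacophoric typing of one residue or one ligand pose."""

    hydrophobic_atoms: list[Atom] = field(default_factory=list)
    aromatic_rings: list[AromaticRing] = field(default_factory=list)
    donors: list[Donor] = field(default_factory=list)
    acceptors: list[Atom] = field(default_factory=list)
    cations: list[np.ndarray] = field(default_factory=list)
    anions: list[np.ndarray] = field(default_factory=list)


def ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of the best-fit plane through ring atoms."""
    centroid = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - centroid)
    normal = vt[2]
    return centroid, normal / np.linalg.norm(normal)


# ---------------------------------------------------------------------------
# Protein residue templates
# ---------------------------------------------------------------------------

# Side-chain atoms per category.  Hydrophobic = C/S atoms not bonded to N/O;
# rings, donors, acceptors and charged groups follow standard residue
# chemistry.  Backbone contributions (N donor, O acceptor, CA contacts are
# excluded as polar-adjacent) are added separately unless nobb is set.

_HYDROPHOBIC = {
    "ALA": ["CB"], "VAL": ["CB", "CG1", "CG2"], "LEU": ["CB", "CG", "CD1", "CD2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"], "MET": ["CB", "CG", "SD", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2"],
    "PRO": ["CB", "CG"], "LYS": ["CB", "CG", "CD"], "ARG": ["CB", "CG"],
    "GLU": ["CB", "CG"], "ASP": ["CB"], "GLN": ["CB", "CG"], "ASN": ["CB"],
    "HIS": ["CB"], "CYS": ["CB", "SG"], "THR": ["CG2"],
    "SER": [], "GLY": [],
}

_RINGS = {
    "PHE": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TYR": [["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]],
    "HIS": [["CG", "ND1", "CD2", "CE1", "NE2"]],
}

# donor heavy atom -> bonded heavy neighbour (anchor for pseudo-H placement)
_DONORS = {
    "SER": {"OG": "CB"}, "THR": {"OG1": "CB"}, "TYR": {"OH": "CZ"},
    "TRP": {"NE1": "CD1"}, "ASN": {"ND2": "CG"}, "GLN": {"NE2": "CD"},
    "LYS": {"NZ": "CE"}, "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "HIS": {"ND1": "CG", "NE2": "CD2"}, "CYS": {"SG": "CB"},
}

_ACCEPTORS = {
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"], "ASN": ["OD1"], "GLN": ["OE1"],
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "HIS": ["ND1", "NE2"],
}

# charged-group centre = midpoint of the equivalent terminal atoms
_CATIONS = {"LYS": [["NZ"]], "ARG": [["NH1", "NH2"]]}
_ANIONS = {"ASP": [["OD1", "OD2"]], "GLU": [["OE1", "OE2"]]}


def type_protein_residue(
    residue_atoms: list[Atom],
    nobb: bool = True,
    his_cationic: bool = False,
) -> AtomTyping:
    """Type one protein residue from the fixed per-residue template table.

    With ``nobb=True`` (the default, matching side-chain-only analysis)
    backbone atoms are removed from every category before detection; with
    ``nobb=False`` the backbone amide N contributes a donor and the carbonyl
    O an acceptor.  His rings are aromatic by default and additionally
    cationic only when ``his_cationic`` is set.  Unknown residue names are
    typed as hydrophobic-only (their carbons and sulfurs) with a warning.
    """
    if not residue_atoms:
        return AtomTyping()
    resname = residue_atoms[0].residue_name.upper()
    atoms = [a for a in residue_atoms if not (nobb and a.is_backbone)]
    by_name = {a.name.upper(): a for a in atoms}
    typing = AtomTyping()

    if resname not in _HYDROPHOBIC:
        logger.warning("unknown residue %s: typed as hydrophobic-only", resname)
        typing.hydrophobic_atoms = [a for a in atoms
                                    if a.element.upper() in ("C", "S")]
        return typing

    typing.hydrophobic_atoms = [by_name[n] for n in _HYDROPHOBIC[resname] if n in by_name]

    for ring_names in _RINGS.get(resname, []):
        members = [by_name[n] for n in ring_names if n in by_name]
        if len(members) == len(ring_names):
            centroid, normal = ring_plane(np.vstack([a.coords for a in members]))
            typing.aromatic_rings.append(AromaticRing(members, centroid, normal))

    for donor_name, anchor_name in _DONORS.get(resname, {}).items():
        if donor_name not in by_name:
            continue
        heavy = by_name[donor_name]
        hydrogens = [a for a in atoms if not a.is_heavy
                     and np.linalg.norm(a.coords - heavy.coords) < 1.3]
        anchor = by_name.get(anchor_name)
        typing.donors.append(Donor(
            heavy, hydrogens,
            neighbor_centroid=None if anchor is None else anchor.coords.copy()))

    typing.acceptors = [by_name[n] for n in _ACCEPTORS.get(resname, []) if n in by_name]

    for group in _CATIONS.get(resname, []):
        pts = [by_name[n].coords for n in group if n in by_name]
        if len(pts) == len(group):
            typing.cations.append(np.mean(pts, axis=0))
    if his_cationic and resname == "HIS" and {"ND1", "NE2"} <= by_name.keys():
        typing.cations.append(np.mean(
            [by_name["ND1"].coords, by_name["NE2"].coords], axis=0))
    for group in _ANIONS.get(resname, []):
        pts = [by_name[n].coords for n in group if n in by_name]
        if len(pts) == len(group):
            typing.anions.append(np.mean(pts, axis=0))

    if not nobb:
        n = by_name.get("N")
        if n is not None:
            hydrogens = [a for a in residue_atoms if not a.is_heavy
                         and np.linalg.norm(a.coords - n.coords) < 1.3]
            ca = by_name.get("CA")
            typing.donors.append(Donor(
                n, hydrogens,
                neighbor_centroid=None if ca is None else ca.coords.copy()))
        if "O" in by_name:
            typing.acceptors.append(by_name["O"])
    return typing


# ---------------------------------------------------------------------------
# Ligand perception
# ---------------------------------------------------------------------------

_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39, "Si": 1.11, "B": 0.84,
}


def _perceive_bonds(atoms: list[Atom]) -> dict[int, set[int]]:
    """Distance-based bond perception: bonded when within 1.25x the sum of
    covalent radii.  Returns an adjacency map over atom indices."""
    adjacency: dict[int, set[int]] = {i: set() for i in range(len(atoms))}
    for i, j in itertools.combinations(range(len(atoms)), 2):
        ri = _COVALENT_RADII.get(atoms[i].element, 0.77)
        rj = _COVALENT_RADII.get(atoms[j].element, 0.77)
        if np.linalg.norm(atoms[i].coords - atoms[j].coords) <= 1.25 * (ri + rj):
            adjacency[i].add(j)
            adjacency[j].add(i)
    return adjacency


def _find_rings(adjacency: dict[int, set[int]], max_size: int = 6) -> list[list[int]]:
    """Simple cycles of length 3..max_size via DFS, deduplicated."""
    rings: set[frozenset[int]] = set()
    ordered: list[list[int]] = []

    def dfs(start: int, current: int, path: list[int]) -> None:
        for nxt in adjacency[current]:
            if nxt == start and len(path) >= 3:
                key = frozenset(path)
                if key not in rings and len(path) <= max_size:
                    rings.add(key)
                    ordered.append(list(path))
            elif nxt not in path and len(path) < max_size and nxt > start:
                dfs(start, nxt, path + [nxt])

    for start in adjacency:
        dfs(start, start, [start])
    # keep minimal rings only (no ring that is a union of smaller ones)
    minimal = []
    for ring in ordered:
        key = set(ring)
        if not any(set(other) < key for other in ordered):
            minimal.append(ring)
    return minimal


def type_ligand_pose(pose: Structure, planarity_tol: float = 0.15) -> AtomTyping:
    """Pharmacophoric typing of a ligand pose from elements and geometry.

    Bonds are perceived by distance; then: hydrophobic = C/S not bonded to
    N/O; aromatic = planar 5/6-rings of C/N/O/S; donors = N/O with attached
    hydrogens (or, when the pose carries no hydrogens at all, N/O with free
    valence, the implicit-H mode); acceptors = O plus H-free N of heavy
    degree <= 2; cations = N with >= 4 bonds and guanidinium groups; anions
    = carboxylate/sulfonate/phosphate terminal-oxygen midpoints.
    """
    for atom in pose.atoms:
        if not atom.element:
            raise ValueError(f"atom {atom.serial}: missing element")
    atoms = pose.atoms
    adjacency = _perceive_bonds(atoms)
    typing = AtomTyping()
    has_explicit_h = any(not a.is_heavy for a in atoms)

    def neighbors(i: int) -> list[Atom]:
        return [atoms[j] for j in adjacency[i]]

    def h_neighbors(i: int) -> list[Atom]:
        return [a for a in neighbors(i) if not a.is_heavy]

    def heavy_neighbors(i: int) -> list[Atom]:
        return [a for a in neighbors(i) if a.is_heavy]

    # hydrophobic
    for i, atom in enumerate(atoms):
        if atom.element.upper() in ("C", "S"):
            if not any(n.element.upper() in ("N", "O") for n in neighbors(i)):
                typing.hydrophobic_atoms.append(atom)

    # aromatic rings: planar 5/6-membered rings of C/N/O/S heavy atoms
    heavy_idx = [i for i, a in enumerate(atoms) if a.is_heavy]
    heavy_adj = {i: {j for j in adjacency[i] if atoms[j].is_heavy} for i in heavy_idx}
    for ring in _find_rings(heavy_adj):
        members = [atoms[i] for i in ring]
        if len(ring) not in (5, 6):
            continue
        if not all(a.element.upper() in ("C", "N", "O", "S") for a in members):
            continue
        coords = np.vstack([a.coords for a in members])
        centroid, normal = ring_plane(coords)
        if np.max(np.abs((coords - centroid) @ normal)) <= planarity_tol:
            typing.aromatic_rings.append(AromaticRing(members, centroid, normal))

    # donors / acceptors
    for i, atom in enumerate(atoms):
        el = atom.element.upper()
        if el not in ("N", "O"):
            continue
        hs = h_neighbors(i)
        heavy_deg = len(heavy_neighbors(i))
        anchor = (np.mean([a.coords for a in heavy_neighbors(i)], axis=0)
                  if heavy_deg else None)
        if hs:
            typing.donors.append(Donor(atom, hs, neighbor_centroid=anchor))
        elif not has_explicit_h:
            free_valence = (el == "N" and heavy_deg < 3) or (el == "O" and heavy_deg < 2)
            if free_valence:
                typing.donors.append(Donor(atom, [], neighbor_centroid=anchor))
        if el == "O":
            typing.acceptors.append(atom)
        elif el == "N" and not hs and heavy_deg <= 2:
            typing.acceptors.append(atom)

    # cations
    for i, atom in enumerate(atoms):
        el = atom.element.upper()
        if el == "N" and len(adjacency[i]) >= 4:
            typing.cations.append(atom.coords.copy())
        elif el == "C":
            n_nbrs = [j for j in adjacency[i] if atoms[j].element.upper() == "N"]
            if len(n_nbrs) == 3:  # guanidinium-like
                typing.cations.append(
                    np.mean([atoms[j].coords for j in n_nbrs], axis=0))

    # anions: C/S/P with >= 2 terminal oxygens -> midpoint of those oxygens
    for i, atom in enumerate(atoms):
        if atom.element.upper() not in ("C", "S", "P"):
            continue
        terminal_o = [a for j in adjacency[i]
                      if (a := atoms[j]).element.upper() == "O"
                      and len([k for k in adjacency[j] if atoms[k].is_heavy]) == 1
                      and not h_neighbors(j)]
        if len(terminal_o) >= 2:
            typing.anions.append(np.mean([a.coords for a in terminal_o], axis=0))

    return typing


# ---------------------------------------------------------------------------
# Geometric detection
# ---------------------------------------------------------------------------

def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at vertex b of a-b-c, in degrees."""
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _interplanar_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    """Angle between ring planes, folded into [0, 90] degrees."""
    cosang = abs(float(np.dot(n1, n2)))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def _hbond_geometry_ok(donor: Donor, acceptor: Atom, thr: GeomThresholds) -> bool:
    d_a = float(np.linalg.norm(donor.heavy.coords - acceptor.coords))
    if d_a > thr.hbond_dmax:
        return False
    if donor.hydrogens:
        return any(
            _angle_deg(donor.heavy.coords, h.coords, acceptor.coords)
            >= thr.hbond_angle_min
            for h in donor.hydrogens
        )
    # No explicit hydrogen: place a pseudo-H 1.0 A from the donor, anti to the
    # centroid of its bonded heavy neighbours, and apply a relaxed angle cut.
    if donor.neighbor_centroid is None:
        return True  # bare donor: distance criterion only
    direction = donor.heavy.coords - donor.neighbor_centroid
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        return True
    pseudo_h = donor.heavy.coords + direction / norm
    return _angle_deg(donor.heavy.coords, pseudo_h, acceptor.coords) >= thr.pseudo_angle_min


def detect_bits(
    res_typing: AtomTyping,
    lig_typing: AtomTyping,
    thr: GeomThresholds | None = None,
) -> np.ndarray:
    """The 7-bit interaction vector between one residue and one ligand pose.

    Empty typings simply yield zero bits.
    """
    thr = thr or GeomThresholds()
    bits = np.zeros(N_INTERACTION_TYPES, dtype=np.uint8)

    for pa in res_typing.hydrophobic_atoms:
        for la in lig_typing.hydrophobic_atoms:
            if np.linalg.norm(pa.coords - la.coords) <= thr.hydrophobic_dmax:
                bits[0] = 1
                break
        if bits[0]:
            break

    for pr in res_typing.aromatic_rings:
        for lr in lig_typing.aromatic_rings:
            if np.linalg.norm(pr.centroid - lr.centroid) > thr.aromatic_dmax:
                continue
            angle = _interplanar_angle(pr.normal, lr.normal)
            if angle <= thr.f2f_angle_max:
                bits[1] = 1
            elif angle <= thr.e2f_angle_max:
                bits[2] = 1

    for donor in res_typing.donors:
        for acceptor in lig_typing.acceptors:
            if _hbond_geometry_ok(donor, acceptor, thr):
                bits[3] = 1
                break
        if bits[3]:
            break

    for donor in lig_typing.donors:
        for acceptor in res_typing.acceptors:
            if _hbond_geometry_ok(donor, acceptor, thr):
                bits[4] = 1
                break
        if bits[4]:
            break

    for cation in res_typing.cations:
        for anion in lig_typing.anions:
            if np.linalg.norm(cation - anion) <= thr.ionic_dmax:
                bits[5] = 1
                break
        if bits[5]:
            break

    for anion in res_typing.anions:
        for cation in lig_typing.cations:
            if np.linalg.norm(anion - cation) <= thr.ionic_dmax:
                bits[6] = 1
                break
        if bits[6]:
            break

    return bits


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------

@dataclass
class Fingerprint:
    """Concatenated per-residue 7-bit vectors over an ordered residue list."""

    residue_list: list[ResidueRef]
    bits: np.ndarray  # uint8, length 7 * n_residues

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.size != N_INTERACTION_TYPES * len(self.residue_list):
            raise ValueError("bit vector length must be 7 x n_residues")

    def __len__(self) -> int:
        return int(self.bits.size)

    def to_text(self) -> str:
        """Bit-text with one 7-bit block per residue, e.g. '0000001|0100000'."""
        blocks = self.bits.reshape(-1, N_INTERACTION_TYPES)
        return "|".join("".join(str(b) for b in block) for block in blocks)

    def set_indices(self) -> list[int]:
        """1-based descriptor indices of the set bits."""
        return [int(i) + 1 for i in np.flatnonzero(self.bits)]


def fingerprint_pose(
    receptor: Structure,
    residue_list: list[ResidueRef],
    pose: Structure,
    thr: GeomThresholds | None = None,
    nobb: bool = True,
    his_cationic: bool = False,
    lig_typing: AtomTyping | None = None,
) -> Fingerprint:
    """Fingerprint one ligand pose against the ordered binding-site residues.

    Deterministic: bits are the concatenation of :func:`detect_bits` over
    ``residue_list`` in order.  A residue listed but absent from the receptor
    is an error.  A pre-computed ligand typing can be passed to avoid
    re-perceiving the same pose.
    """
    thr = thr or GeomThresholds()
    if lig_typing is None:
        lig_typing = type_ligand_pose(pose)
    chunks = []
    for ref in residue_list:
        residue_atoms = receptor.residue_atoms(ref)
        if not residue_atoms:
            raise ValueError(f"residue {ref} not found in receptor")
        res_typing = type_protein_residue(residue_atoms, nobb=nobb,
                                          his_cationic=his_cationic)
        chunks.append(detect_bits(res_typing, lig_typing, thr))
    bits = np.concatenate(chunks) if chunks else np.zeros(0, dtype=np.uint8)
    return Fingerprint(residue_list=list(residue_list), bits=bits)


def fingerprint_poses(
    receptor: Structure,
    residue_list: list[ResidueRef],
    poses: list[Structure],
    thr: GeomThresholds | None = None,
    nobb: bool = True,
    his_cationic: bool = False,
) -> list[Fingerprint]:
    """Fingerprint every pose of an ensemble (ligand typing per pose)."""
    return [
        fingerprint_pose(receptor, residue_list, pose, thr=thr, nobb=nobb,
                         his_cationic=his_cationic)
        for pose in poses
    ]


def bit_to_descriptor(
    k: int, residue_list: list[ResidueRef]
) -> tuple[ResidueRef, InteractionType]:
    """Map 1-based descriptor index k to its (residue, interaction type).

    Inverse of the fingerprint layout: residue rank ((k-1) // 7) + 1, type
    code ((k-1) mod 7) + 1.
    """
    n = N_INTERACTION_TYPES * len(residue_list)
    if not 1 <= k <= n:
        raise ValueError(f"descriptor index {k} out of range 1..{n}")
    rank = (k - 1) // N_INTERACTION_TYPES  # 0-based
    code = (k - 1) % N_INTERACTION_TYPES + 1
    return residue_list[rank], InteractionType(code)


def descriptor_type_code(k: int) -> int:
    """Interaction-type code of descriptor index k, independent of layout size."""
    if k < 1:
        raise ValueError("descriptor index must be >= 1")
    return (k - 1) % N_INTERACTION_TYPES + 1


def descriptor_residue_rank(k: int) -> int:
    """1-based residue rank of descriptor index k."""
    if k < 1:
        raise ValueError("descriptor index must be >= 1")
    return (k - 1) // N_INTERACTION_TYPES + 1
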