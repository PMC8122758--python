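"""Synthetic inputs with known ground truth, plus the bundled reference data.

Three generators cover the pipeline's stages:

* :func:`make_toy_complex` builds a toy receptor and a docked-pose ensemble
  with interactions planted at chosen geometries, so that fingerprinting
  recovers exactly the planted bits at the default thresholds.  Residue
  sites are spaced 25 A apart — far beyond every detection cutoff — so a
  planted contact can only register on its own residue.  Ligand fragments
  are chosen so no unplanned pharmacophore is within reach of the residue
  (e.g. the aromatic probe is an N-alternating six-ring carrying no
  hydrophobic atoms, so ring stacking does not drag a hydrophobic bit in).

* :func:`make_synthetic_table` draws ensPLIF analysis tables that emulate
  the actives/decoys structure of screening benchmarks (DUD-E-like, ~50
  property-matched decoys per active): informative bits are concentrated
  near a high frequency in actives and a low frequency in decoys, the rest
  is low-frequency background.  Planted bits may be restricted to subgroups
  of the actives, emulating ligand-dependent determinants (distinct tree
  branches).

* :func:`load_table1_fixture` loads the bundled reference listing of 23
  molecular determinants reported for four GPCR screening campaigns (AA2AR,
  ADRB2, CXCR4, DRD3) together with the per-receptor descriptor indices and
  screening metrics, including the places where the source material
  contradicts itself (both variants are stored, with a canonical choice and
  a discrepancy flag, so analyses never silently pick a side).  The
  accompanying mutation table is a synthetic stand-in for curated
  site-directed-mutagenesis records.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensplif import EnsPlifRow, EnsPlifTable
from .ifp import (
    InteractionType,
    LABEL_TO_TYPE,
    N_INTERACTION_TYPES,
)
from .structio import Atom, PoseSet, ResidueRef, Structure

__all__ = [
    "PlantedInteractionSpec",
    "PlantedBit",
    "SyntheticTableSpec",
    "ToyComplex",
    "Table1Fixture",
    "make_residue",
    "make_toy_complex",
    "random_specs",
    "make_synthetic_table",
    "load_table1_fixture",
    "mutation_fixture_path",
]


# ---------------------------------------------------------------------------
# Idealised residue templates (local frame: backbone below y=0, side chain +y)
# ---------------------------------------------------------------------------

def _hexagon(center: np.ndarray, radius: float = 1.39) -> list[np.ndarray]:
    """Vertices of a planar hexagon in the z=0 plane, first vertex at -y."""
    out = []
    for k in range(6):
        theta = math.radians(60 * k)
        out.append(center + radius * np.array([math.sin(theta), -math.cos(theta), 0.0]))
    return out


def _pentagon(center: np.ndarray, radius: float = 1.17) -> list[np.ndarray]:
    out = []
    for k in range(5):
        theta = math.radians(72 * k)
        out.append(center + radius * np.array([math.sin(theta), -math.cos(theta), 0.0]))
    return out


def _build_templates() -> dict[str, dict[str, np.ndarray]]:
    bb = {
        "N": np.array([-1.46, -0.60, 0.0]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([1.35, -0.70, 0.0]),
        "O": np.array([1.45, -1.93, 0.0]),
    }
    CB = np.array([0.0, 1.53, 0.0])
    t: dict[str, dict[str, np.ndarray]] = {}

    t["GLY"] = {}
    t["ALA"] = {"CB": CB}
    t["LEU"] = {"CB": CB, "CG": np.array([0.0, 2.90, 0.0]),
                "CD1": np.array([-1.10, 3.75, 0.0]), "CD2": np.array([1.10, 3.75, 0.0])}
    t["VAL"] = {"CB": CB, "CG1": np.array([-1.10, 2.30, 0.0]),
                "CG2": np.array([1.10, 2.30, 0.0])}
    t["ILE"] = {"CB": CB, "CG1": np.array([0.90, 2.40, 0.0]),
                "CG2": np.array([-1.20, 2.20, 0.0]), "CD1": np.array([0.90, 3.90, 0.0])}
    t["ASP"] = {"CB": CB, "CG": np.array([0.0, 3.00, 0.0]),
                "OD1": np.array([-1.09, 3.63, 0.0]), "OD2": np.array([1.09, 3.63, 0.0])}
    t["GLU"] = {"CB": CB, "CG": np.array([0.0, 2.90, 0.0]),
                "CD": np.array([0.0, 4.30, 0.0]),
                "OE1": np.array([-1.09, 4.93, 0.0]), "OE2": np.array([1.09, 4.93, 0.0])}
    t["SER"] = {"CB": CB, "OG": np.array([0.0, 2.95, 0.0])}
    t["THR"] = {"CB": CB, "OG1": np.array([-1.10, 2.45, 0.0]),
                "CG2": np.array([1.20, 2.40, 0.0])}
    t["ASN"] = {"CB": CB, "CG": np.array([0.0, 3.00, 0.0]),
                "OD1": np.array([-1.09, 3.63, 0.0]), "ND2": np.array([1.09, 3.63, 0.0])}
    t["GLN"] = {"CB": CB, "CG": np.array([0.0, 2.90, 0.0]),
                "CD": np.array([0.0, 4.30, 0.0]),
                "OE1": np.array([-1.09, 4.93, 0.0]), "NE2": np.array([1.09, 4.93, 0.0])}
    t["LYS"] = {"CB": CB, "CG": np.array([0.0, 2.83, 0.0]),
                "CD": np.array([0.0, 4.13, 0.0]), "CE": np.array([0.0, 5.43, 0.0]),
                "NZ": np.array([0.0, 6.73, 0.0])}
    t["ARG"] = {"CB": CB, "CG": np.array([0.0, 2.83, 0.0]),
                "CD": np.array([0.0, 4.13, 0.0]), "NE": np.array([0.0, 5.43, 0.0]),
                "CZ": np.array([0.0, 6.73, 0.0]),
                "NH1": np.array([-1.09, 7.36, 0.0]), "NH2": np.array([1.09, 7.36, 0.0])}

    hexa = _hexagon(np.array([0.0, 4.39, 0.0]))
    t["PHE"] = {"CB": CB, "CG": hexa[0], "CD1": hexa[1], "CE1": hexa[2],
                "CZ": hexa[3], "CE2": hexa[4], "CD2": hexa[5]}
    t["TYR"] = dict(t["PHE"], OH=np.array([0.0, 7.15, 0.0]))

    penta = _pentagon(np.array([0.0, 4.17, 0.0]))
    t["HIS"] = {"CB": CB, "CG": penta[0], "ND1": penta[1], "CE1": penta[2],
                "NE2": penta[3], "CD2": penta[4]}

    # TRP: pyrrole pentagon fused to a benzene hexagon across the CD2-CE2 edge
    trp = {"CB": CB, "CG": penta[0], "CD1": penta[1], "NE1": penta[2],
           "CE2": penta[3], "CD2": penta[4]}
    p_center = np.array([0.0, 4.17, 0.0])
    edge_mid = (trp["CE2"] + trp["CD2"]) / 2.0
    u = (edge_mid - p_center) / np.linalg.norm(edge_mid - p_center)
    side = float(np.linalg.norm(trp["CE2"] - trp["CD2"]))
    hex_center = edge_mid + u * (side * math.cos(math.radians(30)))

    def rot60(v: np.ndarray, sign: int) -> np.ndarray:
        c, s = math.cos(math.radians(60 * sign)), math.sin(math.radians(60 * sign))
        return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], 0.0])

    start = trp["CE2"] - hex_center
    sign = 1
    if np.linalg.norm(rot60(start, 1) + hex_center - trp["CD2"]) < 0.2:
        sign = -1  # rotate away from CD2 so it comes out last
    names = ["CZ2", "CH2", "CZ3", "CE3"]
    v = start
    for name in names:
        v = rot60(v, sign)
        trp[name] = hex_center + v
    t["TRP"] = trp

    for res in t.values():
        res.update({k: v.copy() for k, v in bb.items()})
    return t


RESIDUE_TEMPLATES = _build_templates()
#: Benzene-ring centre of the TRP template (anchor for aromatic planting).
_TRP_HEX_CENTER_NAMES = ("CE2", "CD2", "CZ2", "CH2", "CZ3", "CE3")


def make_residue(
    resname: str,
    residue_number: int,
    origin=(0.0, 0.0, 0.0),
    chain_id: str = "A",
    serial_start: int = 1,
) -> list[Atom]:
    """Instantiate a residue template at ``origin`` (heavy atoms only)."""
    template = RESIDUE_TEMPLATES[resname.upper()]
    origin = np.asarray(origin, dtype=float)
    atoms = []
    order = ["N", "CA", "C", "O"] + [n for n in template if n not in ("N", "CA", "C", "O")]
    for i, name in enumerate(order):
        atom = Atom(
            serial=serial_start + i, name=name, element=name[0],
            coords=template[name] + origin, residue_number=residue_number,
            residue_name=resname.upper(), chain_id=chain_id,
        )
        atom.is_backbone = name in ("N", "CA", "C", "O")
        atoms.append(atom)
    return atoms


# ---------------------------------------------------------------------------
# Planted protein-ligand complexes
# ---------------------------------------------------------------------------

#: Default residue and target geometry per interaction type.  Distances are
#: the planted contact distance (between the atoms/centres the detector
#: measures) and sit comfortably inside the default thresholds.
_PLANT_DEFAULTS = {
    InteractionType.HYDROPHOBIC: ("LEU", 3.8),
    InteractionType.AROMATIC_FACE_TO_FACE: ("PHE", 3.5),
    InteractionType.AROMATIC_EDGE_TO_FACE: ("TRP", 4.3),
    InteractionType.HBOND_PROTEIN_DONOR: ("SER", 2.9),
    InteractionType.HBOND_PROTEIN_ACCEPTOR: ("ASN", 2.9),
    InteractionType.IONIC_PROTEIN_CATION: ("LYS", 5.0),
    InteractionType.IONIC_PROTEIN_ANION: ("ASP", 4.5),
}

#: Safe planting ranges per type: jittered geometry stays within the default
#: thresholds and outside every unplanned detector's reach.
_PLANT_RANGES = {
    InteractionType.HYDROPHOBIC: (3.2, 4.2),
    InteractionType.AROMATIC_FACE_TO_FACE: (3.2, 3.8),
    InteractionType.AROMATIC_EDGE_TO_FACE: (3.9, 4.3),
    InteractionType.HBOND_PROTEIN_DONOR: (2.7, 3.3),
    InteractionType.HBOND_PROTEIN_ACCEPTOR: (2.7, 3.3),
    InteractionType.IONIC_PROTEIN_CATION: (4.2, 5.3),
    InteractionType.IONIC_PROTEIN_ANION: (3.9, 5.2),
}


@dataclass
class PlantedInteractionSpec:
    interaction: InteractionType
    residue: str | None = None      # template name; None -> type default
    distance: float | None = None   # target contact distance, A
    jitter: float = 0.05            # per-coordinate Gaussian sigma, A

    def __post_init__(self) -> None:
        self.interaction = InteractionType(self.interaction)
        default_res, default_d = _PLANT_DEFAULTS[self.interaction]
        if self.residue is None:
            self.residue = default_res
        if self.distance is None:
            self.distance = default_d
        lo, hi = _PLANT_RANGES[self.interaction]
        if not lo - 1e-9 <= self.distance <= hi + 1e-9:
            raise ValueError(
                f"{self.interaction.label}: planted distance {self.distance} "
                f"outside the safe range [{lo}, {hi}]")


@dataclass
class ToyComplex:
    receptor: Structure
    pose_set: PoseSet
    residue_list: list[ResidueRef]
    expected_bits: np.ndarray  # uint8, 7 * n_residues


def _aromatic_probe(center: np.ndarray, axis1: np.ndarray, axis2: np.ndarray,
                    serial: int) -> list[Atom]:
    """Alternating C/N six-ring (triazine-like): aromatic but carrying no
    hydrophobic atoms, donors or charges, so stacking plants a single bit."""
    atoms = []
    for k in range(6):
        theta = math.radians(60 * k)
        pos = center + 1.34 * (math.cos(theta) * axis1 + math.sin(theta) * axis2)
        element = "C" if k % 2 == 0 else "N"
        atoms.append(Atom(serial=serial + k, name=f"{element}{k + 1}",
                          element=element, coords=pos, residue_number=1,
                          residue_name="LIG", chain_id=" ", is_hetatm=True))
    return atoms


def _lig_atom(serial: int, element: str, coords: np.ndarray, name: str = "") -> Atom:
    return Atom(serial=serial, name=name or f"{element}{serial}", element=element,
                coords=np.asarray(coords, dtype=float), residue_number=1,
                residue_name="LIG", chain_id=" ", is_hetatm=True)


def _fragment_for(spec: PlantedInteractionSpec, origin: np.ndarray,
                  serial: int) -> list[Atom]:
    """Ligand fragment realising one planted interaction, in ideal geometry."""
    template = RESIDUE_TEMPLATES[spec.residue]
    at = lambda name: template[name] + origin  # noqa: E731
    d = spec.distance
    t = spec.interaction
    X, Y, Z = np.eye(3)

    if t is InteractionType.HYDROPHOBIC:
        anchor = at("CD1") if "CD1" in template else at("CB")
        return [_lig_atom(serial, "C", anchor + d * Y)]
    if t in (InteractionType.AROMATIC_FACE_TO_FACE,
             InteractionType.AROMATIC_EDGE_TO_FACE):
        if spec.residue == "TRP":
            ring_center = np.mean([at(n) for n in _TRP_HEX_CENTER_NAMES], axis=0)
        else:
            names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"] if "CZ" in template \
                else ["CG", "ND1", "CE1", "NE2", "CD2"]
            ring_center = np.mean([at(n) for n in names], axis=0)
        center = ring_center + d * Z  # templates keep ring planes in z=0
        if t is InteractionType.AROMATIC_FACE_TO_FACE:
            return _aromatic_probe(center, X, Y, serial)      # parallel: angle 0
        return _aromatic_probe(center, X, Z, serial)          # perpendicular: 90
    if t is InteractionType.HBOND_PROTEIN_DONOR:
        og = at("OG") if "OG" in template else at("OG1")
        o = og + d * Y  # anti to the CB anchor -> ideal pseudo-H geometry
        return [
            _lig_atom(serial, "O", o),
            _lig_atom(serial + 1, "C", o + np.array([-1.17, 0.79, 0.0])),
            _lig_atom(serial + 2, "C", o + np.array([1.17, 0.79, 0.0])),
        ]
    if t is InteractionType.HBOND_PROTEIN_ACCEPTOR:
        od1 = at("OD1")
        n = od1 - d * X  # away from the ND2 donor of the same amide
        return [
            _lig_atom(serial, "N", n),
            _lig_atom(serial + 1, "H", n + X * 1.0),          # points at OD1
            _lig_atom(serial + 2, "H", n + np.array([-0.47, 0.82, 0.0])),
            _lig_atom(serial + 3, "C", n + np.array([-0.75, -1.29, 0.0])),
        ]
    if t is InteractionType.IONIC_PROTEIN_CATION:
        nz = at("NZ")
        a = nz + d * Y  # carboxylate midpoint
        c2 = a + np.array([0.0, 0.77, 0.0])
        return [
            _lig_atom(serial, "O", a + np.array([-1.09, 0.0, 0.0])),
            _lig_atom(serial + 1, "O", a + np.array([1.09, 0.0, 0.0])),
            _lig_atom(serial + 2, "C", c2),
            _lig_atom(serial + 3, "C", c2 + np.array([0.0, 1.52, 0.0])),
        ]
    if t is InteractionType.IONIC_PROTEIN_ANION:
        mid = (at("OD1") + at("OD2")) / 2.0 if "OD1" in template \
            else (at("OE1") + at("OE2")) / 2.0
        n = mid + d * Y
        return [
            _lig_atom(serial, "N", n),
            _lig_atom(serial + 1, "H", n + np.array([0.94, 0.33, 0.0])),
            _lig_atom(serial + 2, "H", n + np.array([-0.47, 0.33, 0.82])),
            _lig_atom(serial + 3, "H", n + np.array([-0.47, 0.33, -0.82])),
            _lig_atom(serial + 4, "C", n + np.array([0.0, 1.49, 0.0])),
        ]
    raise ValueError(f"unhandled interaction type {t}")


def make_toy_complex(
    specs: list[PlantedInteractionSpec],
    seed: int = 0,
    n_poses: int = 1,
    site_spacing: float = 25.0,
    compound_name: str = "planted",
) -> ToyComplex:
    """Toy receptor + pose ensemble realising exactly the given interactions.

    Residue i sits at ``(site_spacing * i, 0, 0)`` with its planted ligand
    fragment nearby; the expected fingerprint has bit
    ``i*7 + interaction_code`` set for each spec and nothing else.  Each
    pose gets independent Gaussian jitter on the ligand atoms.
    """
    rng = np.random.default_rng(seed)
    receptor_atoms: list[Atom] = []
    fragments: list[list[Atom]] = []
    serial = 1
    lig_serial = 1
    for i, spec in enumerate(specs):
        origin = np.array([site_spacing * i, 0.0, 0.0])
        res_atoms = make_residue(spec.residue, i + 1, origin, serial_start=serial)
        serial += len(res_atoms)
        receptor_atoms.extend(res_atoms)
        frag = _fragment_for(spec, origin, lig_serial)
        lig_serial += len(frag)
        fragments.append(frag)

    receptor = Structure(receptor_atoms)
    poses, affinities = [], []
    for p in range(n_poses):
        pose_atoms = []
        for frag, spec in zip(fragments, specs):
            for atom in frag:
                jittered = Atom(
                    serial=atom.serial, name=atom.name, element=atom.element,
                    coords=atom.coords + rng.normal(0.0, spec.jitter, size=3),
                    residue_number=1, residue_name="LIG", chain_id=" ",
                    is_hetatm=True,
                )
                pose_atoms.append(jittered)
        poses.append(Structure(pose_atoms))
        affinities.append(round(-9.0 + 0.1 * p, 1))
    pose_set = PoseSet(compound_name=compound_name, poses=poses,
                       affinities=affinities)

    residue_list = [ResidueRef("A", i + 1, spec.residue)
                    for i, spec in enumerate(specs)]
    expected = np.zeros(N_INTERACTION_TYPES * len(specs), dtype=np.uint8)
    for i, spec in enumerate(specs):
        expected[i * N_INTERACTION_TYPES + int(spec.interaction) - 1] = 1
    return ToyComplex(receptor=receptor, pose_set=pose_set,
                      residue_list=residue_list, expected_bits=expected)


def random_specs(n: int, seed: int = 0, jitter: float = 0.05
                 ) -> list[PlantedInteractionSpec]:
    """Random planted-interaction specs with geometries in the safe ranges."""
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n):
        t = InteractionType(int(rng.integers(1, N_INTERACTION_TYPES + 1)))
        lo, hi = _PLANT_RANGES[t]
        specs.append(PlantedInteractionSpec(
            interaction=t, distance=float(rng.uniform(lo, hi)), jitter=jitter))
    return specs


# ---------------------------------------------------------------------------
# Synthetic ensPLIF tables
# ---------------------------------------------------------------------------

@dataclass
class PlantedBit:
    """An informative descriptor: frequency p_active in (a subgroup of) the
    actives, p_decoy in decoys and the remaining actives."""

    index: int               # 1-based descriptor index
    p_active: float = 0.9
    p_decoy: float = 0.05
    group: int | None = None  # restrict the high frequency to one active subgroup

    def __post_init__(self) -> None:
        if not 0 <= self.p_decoy < self.p_active <= 1:
            raise ValueError("planted bit requires 0 <= p_decoy < p_active <= 1")


@dataclass
class SyntheticTableSpec:
    """Study conditions for a synthetic screening table: ~1 active per 50
    decoys, low background bit frequency, strongly informative planted bits."""

    n_actives: int = 20
    n_decoys: int = 1000
    n_residues: int = 6
    planted: list[PlantedBit] = field(default_factory=lambda: [PlantedBit(10)])
    background: float = 0.05
    concentration: float = 30.0   # Beta concentration around the target frequency
    seed: int = 0

    def __post_init__(self) -> None:
        n_vars = N_INTERACTION_TYPES * self.n_residues
        for bit in self.planted:
            if not 1 <= bit.index <= n_vars:
                raise ValueError(f"planted index {bit.index} outside 1..{n_vars}")

    @property
    def n_groups(self) -> int:
        groups = {b.group for b in self.planted if b.group is not None}
        return max(groups) + 1 if groups else 1


def _beta_around(rng: np.random.Generator, p: float, c: float, size) -> np.ndarray:
    a = max(p * c, 1e-3)
    b = max((1.0 - p) * c, 1e-3)
    return np.clip(rng.beta(a, b, size=size), 0.0, 1.0)


def make_synthetic_table(spec: SyntheticTableSpec) -> EnsPlifTable:
    """Draw an ensPLIF table with known informative bits.

    Every value is Beta-distributed around its target frequency (background
    for uninformative bits, p_active/p_decoy for planted ones) and the
    best-affinity column separates the classes weakly, as docking scores do.
    Deterministic under the spec's seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_vars = N_INTERACTION_TYPES * spec.n_residues
    n = spec.n_actives + spec.n_decoys
    V = _beta_around(rng, spec.background, spec.concentration, (n, n_vars))
    y = np.array([1] * spec.n_actives + [0] * spec.n_decoys)
    groups = np.arange(spec.n_actives) % spec.n_groups
    for bit in spec.planted:
        col = bit.index - 1
        V[spec.n_actives:, col] = _beta_around(
            rng, bit.p_decoy, spec.concentration, spec.n_decoys)
        in_group = np.ones(spec.n_actives, dtype=bool) if bit.group is None \
            else groups == bit.group
        V[:spec.n_actives, col][in_group] = _beta_around(
            rng, bit.p_active, spec.concentration, int(in_group.sum()))
        V[:spec.n_actives, col][~in_group] = _beta_around(
            rng, bit.p_decoy, spec.concentration, int((~in_group).sum()))
    dg = np.where(y == 1, rng.normal(-9.0, 0.7, n), rng.normal(-7.5, 0.7, n))
    rows = [
        EnsPlifRow(
            y=int(y[i]),
            name=(f"ACT{i + 1:04d}" if y[i] == 1 else f"DEC{i - spec.n_actives + 1:04d}"),
            dg=float(dg[i]), V=V[i],
        )
        for i in range(n)
    ]
    return EnsPlifTable(rows=rows)


# ---------------------------------------------------------------------------
# Bundled reference listing (four GPCR screening campaigns)
# ---------------------------------------------------------------------------

@dataclass
class Table1Fixture:
    records: list  # DeterminantRecord
    descriptor_lists: dict[str, list[int]]
    metrics: dict[str, dict]
    discrepancies: list[dict]
    #: interaction-type frequency claim from the accompanying prose; sums to
    #: 24, not 23, so it cannot all be right — kept verbatim with a flag.
    claimed_type_frequencies: dict[str, int] = field(default_factory=dict)


def _data_path(name: str):
    return importlib.resources.files("plifdet").joinpath("data", name)


def mutation_fixture_path():
    """Path to the synthetic mutation-verification table (GPCRdb stand-in)."""
    return _data_path("gpcrdb_mutations_synthetic.csv")


def load_table1_fixture() -> Table1Fixture:
    """The bundled 23-determinant reference listing with metrics and flags."""
    from .determinants import DeterminantRecord  # deferred: avoids cycle

    det = pd.read_csv(_data_path("reference_determinants.csv"))
    records = []
    descriptor_lists: dict[str, list[int]] = {}
    discrepancies: list[dict] = []
    for row in det.itertuples(index=False):
        ref = ResidueRef("A", int(row.residue_number), str(row.residue_name))
        records.append(DeterminantRecord(
            receptor=str(row.receptor),
            descriptor_index=int(row.descriptor_index),
            residue=ref,
            interaction=LABEL_TO_TYPE[str(row.interaction_type)],
            favorable=bool(row.favorable),
            verified=str(row.verification),
            note="" if pd.isna(row.note) else str(row.note),
        ))
        descriptor_lists.setdefault(str(row.receptor), []).append(
            int(row.descriptor_index))
        if isinstance(row.alt_residue, str) and row.alt_residue:
            discrepancies.append({
                "kind": "residue_identity",
                "receptor": str(row.receptor),
                "descriptor_index": int(row.descriptor_index),
                "canonical": f"{row.residue_name}{row.residue_number}",
                "variant": str(row.alt_residue),
            })

    met = pd.read_csv(_data_path("reference_metrics.csv"))
    metrics: dict[str, dict] = {}
    for row in met.itertuples(index=False):
        try:
            ef = float(row.ef)
        except ValueError:  # the zero-FPR sentinel "n.d."
            ef = str(row.ef)
        metrics[str(row.receptor)] = {"ef": ef, "f_measure": float(row.f_measure)}
        if not pd.isna(row.f_measure_alt):
            discrepancies.append({
                "kind": "f_measure",
                "receptor": str(row.receptor),
                "canonical": float(row.f_measure),
                "variant": float(row.f_measure_alt),
            })

    claimed = {
        "aromatic edge-to-face": 9,
        "hydrophobic": 8,
        "ionic (protein as anion)": 3,
        "aromatic face-to-face": 2,
        "h-bond (protein as donor)": 2,
    }
    discrepancies.append({
        "kind": "type_frequencies",
        "canonical": "derived from the record list (sums to 23)",
        "variant": claimed,
        "note": "claimed frequencies sum to 24 for 23 records",
    })
    return Table1Fixture(records=records, descriptor_lists=descriptor_lists,
                         metrics=metrics, discrepancies=discrepancies,
                         claimed_type_frequencies=claimed)
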