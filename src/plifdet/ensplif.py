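"""Ensemble-PLIF (ensPLIF) descriptors.

A compound's ensPLIF vector summarises its whole docking-pose ensemble: the
k-th value is the fraction of (optionally score-filtered) poses whose
fingerprint has bit k set, so each V_k lies in [0, 1] and a single pose
reproduces its bitstring exactly.  The per-receptor analysis table has the
layout

    y, name, dg, V1, ..., Vn

with y in {0, 1} (1 = active, 0 = decoy), name the compound id and dg the
best docking affinity (kcal/mol).  Compounds whose docking produced no
poses are routed to an exclusion list (keeping their label so screening
metrics can count them — an excluded active is a false negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ifp import Fingerprint, GeomThresholds, fingerprint_pose, type_ligand_pose
from .structio import PoseSet, ResidueRef, Structure

__all__ = [
    "EnsPlifRow",
    "EnsPlifTable",
    "compute_ensplif",
    "assemble_table",
    "write_table_csv",
    "read_table_csv",
]


@dataclass
class EnsPlifRow:
    y: int
    name: str
    dg: float
    V: np.ndarray  # reals in [0, 1], length 7 * n_residues

    def __post_init__(self) -> None:
        if self.y not in (0, 1):
            raise ValueError(f"{self.name}: y must be 0 or 1, got {self.y}")
        self.V = np.asarray(self.V, dtype=float)
        if np.any(self.V < 0) or np.any(self.V > 1):
            raise ValueError(f"{self.name}: ensPLIF values must lie in [0, 1]")


@dataclass
class EnsPlifTable:
    rows: list[EnsPlifRow] = field(default_factory=list)
    residue_list: list[ResidueRef] | None = None
    excluded: list[tuple[str, int, str]] = field(default_factory=list)  # (name, y, reason)

    def __post_init__(self) -> None:
        lengths = {row.V.size for row in self.rows}
        if len(lengths) > 1:
            raise ValueError("all rows must have the same ensPLIF vector length")
        names = [row.name for row in self.rows]
        if len(set(names)) != len(names):
            raise ValueError("compound names must be unique")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_variables(self) -> int:
        return int(self.rows[0].V.size) if self.rows else 0

    @property
    def y(self) -> np.ndarray:
        return np.array([row.y for row in self.rows], dtype=int)

    @property
    def X(self) -> np.ndarray:
        """Row-major matrix of the ensPLIF variables V1..Vn."""
        return (np.vstack([row.V for row in self.rows])
                if self.rows else np.zeros((0, 0)))

    def to_frame(self) -> pd.DataFrame:
        n = self.n_variables
        data = {
            "y": [row.y for row in self.rows],
            "name": [row.name for row in self.rows],
            "dg": [row.dg for row in self.rows],
        }
        X = self.X
        for k in range(n):
            data[f"V{k + 1}"] = X[:, k]
        return pd.DataFrame(data)


def compute_ensplif(
    pose_fps: list[Fingerprint],
    affinities: list[float] | None = None,
    score_cutoff: float | None = None,
) -> np.ndarray:
    """Per-bit frequency over the retained poses of one compound.

    With a ``score_cutoff`` only poses with affinity <= cutoff (kcal/mol,
    more negative is better) are retained; by default every pose counts.
    """
    if score_cutoff is not None:
        if affinities is None or len(affinities) != len(pose_fps):
            raise ValueError("score filtering requires one affinity per fingerprint")
        pose_fps = [fp for fp, dg in zip(pose_fps, affinities) if dg <= score_cutoff]
    if not pose_fps:
        raise ValueError(
            "no poses retained; route this compound to the exclusion list")
    matrix = np.vstack([fp.bits for fp in pose_fps]).astype(float)
    return matrix.mean(axis=0)


def assemble_table(
    compounds: list[tuple[str, int, PoseSet]],
    receptor: Structure,
    residue_list: list[ResidueRef],
    thr: GeomThresholds | None = None,
    nobb: bool = True,
    score_cutoff: float | None = None,
) -> EnsPlifTable:
    """Build the per-receptor analysis table from labelled pose ensembles.

    Each compound is fingerprinted pose by pose and aggregated with
    :func:`compute_ensplif`; ``dg`` is the best (first) Vina affinity.
    Compounds without docking output land in ``excluded`` with reason
    ``"no docking output"`` rather than in the rows.
    """
    names = [name for name, _, _ in compounds]
    if len(set(names)) != len(names):
        raise ValueError("compound names must be unique")
    rows: list[EnsPlifRow] = []
    excluded: list[tuple[str, int, str]] = []
    for name, y, pose_set in compounds:
        if pose_set.no_poses:
            excluded.append((name, y, "no docking output"))
            continue
        fps = [
            fingerprint_pose(receptor, residue_list, pose, thr=thr, nobb=nobb,
                             lig_typing=type_ligand_pose(pose))
            for pose in pose_set.poses
        ]
        try:
            V = compute_ensplif(fps, affinities=pose_set.affinities,
                                score_cutoff=score_cutoff)
        except ValueError:
            excluded.append((name, y, "no poses pass the score cutoff"))
            continue
        rows.append(EnsPlifRow(y=y, name=name, dg=pose_set.best_affinity, V=V))
    return EnsPlifTable(rows=rows, residue_list=list(residue_list), excluded=excluded)


def write_table_csv(table: EnsPlifTable, path) -> None:
    """CSV with header exactly ``y,name,dg,V1,...,Vn``."""
    table.to_frame().to_csv(path, index=False, float_format="%.6g")


def read_table_csv(path) -> EnsPlifTable:
    frame = pd.read_csv(path)
    expected_prefix = ["y", "name", "dg"]
    if list(frame.columns[:3]) != expected_prefix:
        raise ValueError(f"table must start with columns {expected_prefix}")
    v_cols = [c for c in frame.columns[3:]]
    if v_cols != [f"V{k + 1}" for k in range(len(v_cols))]:
        raise ValueError("ensPLIF columns must be V1..Vn in order")
    bad = set(frame["y"].unique()) - {0, 1}
    if bad:
        raise ValueError(f"y values must be 0 or 1, found {sorted(bad)}")
    rows = [
        EnsPlifRow(y=int(rec.y), name=str(rec.name), dg=float(rec.dg),
                   V=np.array([getattr(rec, c) for c in v_cols], dtype=float))
        for rec in frame.itertuples(index=False)
    ]
    return EnsPlifTable(rows=rows)
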