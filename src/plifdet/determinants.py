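"""Molecular determinants, screening metrics and mutation-data verification.

A molecular determinant is a (residue, interaction type) pair whose
fingerprint frequency drives the classification of a compound as a ligand.
Determinants are read off a fitted decision tree: every split on a
root-to-ligand-leaf path contributes one, favorable when the path leaves
the split on the ">= threshold" side (presence of the interaction favours
ligand calls) and unfavorable on the "< threshold" side.  The same
descriptor may appear both ways on different branches — a ligand-dependent
determinant — and then yields two records.

Screening quality is summarised by the enrichment factor EF = TPR / FPR
(reported as the sentinel "n.d." when no false positives occur) and the
F-measure 2PR/(P+R).  Actives excluded before docking output count as
false negatives; excluded decoys as true negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .cart import DecisionTree, LIGAND, Node
from .ifp import InteractionType, bit_to_descriptor
from .structio import ResidueRef

logger = logging.getLogger(__name__)

__all__ = [
    "DeterminantRecord",
    "ScreenMetrics",
    "ND",
    "extract_determinants",
    "score_screen",
    "verify_determinants",
    "summarize",
    "records_to_frame",
]

#: Sentinel for an enrichment factor that cannot be determined (FPR = 0).
ND = "n.d."


@dataclass
class DeterminantRecord:
    receptor: str
    descriptor_index: int
    residue: ResidueRef
    interaction: InteractionType
    favorable: bool
    verified: str = "n.a."  # "verified" | "n.a."
    note: str = ""

    def __post_init__(self) -> None:
        _, expected = bit_to_descriptor(
            self.descriptor_index,
            [self.residue] * (((self.descriptor_index - 1) // 7) + 1),
        )
        if expected != self.interaction:
            raise ValueError(
                f"descriptor {self.descriptor_index} implies interaction type "
                f"{expected.label}, not {self.interaction.label}")


@dataclass
class ScreenMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else 0.0

    @property
    def recall(self) -> float:
        return self.tpr

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def ef(self) -> float | str:
        """Enrichment factor TPR/FPR; "n.d." when the FPR is zero."""
        if self.fpr == 0.0:
            return ND
        return self.tpr / self.fpr

    @property
    def f_measure(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def extract_determinants(
    tree: DecisionTree,
    residue_list: list[ResidueRef],
    receptor: str = "",
) -> list[DeterminantRecord]:
    """Determinant records from every root-to-ligand-leaf path of a tree.

    Each (variable, direction) pair on such a path becomes a record,
    deduplicated by (descriptor index, favorable); a tree without a ligand
    leaf yields an empty list with a warning.  Records are ordered by
    descriptor index, favorable first.
    """
    found: dict[tuple[int, bool], None] = {}

    def walk(node: Node, path: list[tuple[int, bool]]) -> None:
        if node.is_leaf:
            if node.klass == LIGAND:
                for key in path:
                    found.setdefault(key, None)
            return
        walk(node.left, path + [(node.variable, False)])   # < threshold
        walk(node.right, path + [(node.variable, True)])   # >= threshold

    walk(tree.root, [])
    if not found:
        logger.warning("tree has no ligand leaf: no determinants extracted")
        return []
    records = []
    for k, favorable in sorted(found, key=lambda kv: (kv[0], not kv[1])):
        residue, interaction = bit_to_descriptor(k, residue_list)
        records.append(DeterminantRecord(
            receptor=receptor, descriptor_index=k, residue=residue,
            interaction=interaction, favorable=favorable))
    return records


def score_screen(
    predictions,
    labels,
    n_excluded_actives: int = 0,
    n_excluded_decoys: int = 0,
) -> ScreenMetrics:
    """Confusion matrix and EF/F-measure for a virtual-screening run.

    ``predictions`` may be class labels ("ligand"/"decoy") or 0/1;
    ``labels`` are the observed 0/1 activities.  Compounds excluded before
    prediction (no docking output) enter as false negatives when active and
    true negatives when decoys.
    """
    pred = np.asarray(predictions)
    if pred.dtype.kind in "US":
        pred1 = pred == LIGAND
    else:
        pred1 = pred.astype(int) == 1
    y = np.asarray(labels, dtype=int)
    if pred1.size != y.size:
        raise ValueError("predictions and labels differ in length")
    tp = int(np.sum(pred1 & (y == 1)))
    fp = int(np.sum(pred1 & (y == 0)))
    fn = int(np.sum(~pred1 & (y == 1))) + n_excluded_actives
    tn = int(np.sum(~pred1 & (y == 0))) + n_excluded_decoys
    return ScreenMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def verify_determinants(
    records: list[DeterminantRecord],
    mutation_table: pd.DataFrame | str,
) -> list[DeterminantRecord]:
    """Mark records as "verified" when site-directed-mutagenesis data exist.

    The mutation table (a DataFrame or CSV path with columns
    ``receptor,residue_number,residue_name,note``) is keyed by
    (receptor, residue number); matching records get ``verified="verified"``
    and carry the table's note, the rest stay "n.a.".  Records are modified
    in place and returned.
    """
    if isinstance(mutation_table, (str, bytes)) or hasattr(mutation_table, "__fspath__"):
        mutation_table = pd.read_csv(mutation_table)
    keyed = {}
    for rec in mutation_table.itertuples(index=False):
        note = getattr(rec, "note", "")
        keyed[(str(rec.receptor), int(rec.residue_number))] = (
            "" if pd.isna(note) else str(note))
    for record in records:
        key = (record.receptor, record.residue.residue_number)
        if key in keyed:
            record.verified = "verified"
            if keyed[key]:
                record.note = keyed[key]
        else:
            record.verified = "n.a."
    return records


def _round_half_up(value: float, places: int = 2) -> float:
    quant = Decimal(1).scaleb(-places)
    return float(Decimal(repr(value)).quantize(quant, rounding=ROUND_HALF_UP))


def summarize(records: list[DeterminantRecord]) -> dict:
    """Bookkeeping over a determinant list.

    Returns the total count, per-receptor and per-interaction-type counts,
    the verified count and the verified percentage (two decimals, half-up).
    An empty list yields zeros throughout.
    """
    per_receptor: dict[str, int] = {}
    per_type: dict[str, int] = {}
    verified = 0
    for rec in records:
        per_receptor[rec.receptor] = per_receptor.get(rec.receptor, 0) + 1
        per_type[rec.interaction.label] = per_type.get(rec.interaction.label, 0) + 1
        if rec.verified == "verified":
            verified += 1
    total = len(records)
    return {
        "total": total,
        "verified": verified,
        "verified_percent": _round_half_up(100.0 * verified / total) if total else 0.0,
        "per_receptor": per_receptor,
        "per_interaction_type": per_type,
    }


def records_to_frame(records: list[DeterminantRecord]) -> pd.DataFrame:
    """Determinant report mirroring the residue / interaction / verification
    table layout."""
    return pd.DataFrame({
        "receptor": [r.receptor for r in records],
        "descriptor": [f"ensPLIF-{r.descriptor_index}" for r in records],
        "residue": [f"{r.residue.residue_name.capitalize()}{r.residue.residue_number}"
                    for r in records],
        "interaction_type": [r.interaction.label for r in records],
        "favorable": [r.favorable for r in records],
        "verification": [r.verified for r in records],
        "note": [r.note for r in records],
    })
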