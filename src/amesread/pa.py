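"""Pyrrolizidine-alkaloid structural grouping and prediction summaries.

Pyrrolizidine alkaloids (PAs) are plant ester alkaloids built from a
necine base (two fused five-membered rings sharing a nitrogen — or, in the
otonecine series, the ring-opened N-methyl azacyclooctanone) and one or
two necic-acid ester arms.  Each compound is classified along three
independent axes with an explicit SMARTS rule bank:

* necine base — retronecine-type (1,2-unsaturated), otonecine-type,
  platynecine-type (saturated), or unassigned;
* modification — N-oxide, dehydropyrrolizidine (pyrrolic core), or
  tertiary (neither);
* necic acid — monoester, open-ring diester, macrocyclic diester, or
  unassigned (no ester on the core).

The rule bank is a package design decision: the distinguishing features
(1,2-unsaturation, N-methylated eight-membered ring ketone, ester counting
on the C7/C9 arms, ring membership of both ester oxygens for macrocycle
detection) follow the accepted structural definitions of the PA subtypes
and are unit-tested on named alkaloids with hand-verified structures.
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from rdkit import Chem

from . import MUTAGENIC

# --- SMARTS rule bank ------------------------------------------------------
# Generic pyrrolizidine core: two fused 5-rings sharing N, any bond orders
# (covers saturated, 1,2-unsaturated and aromatic/pyrrolic variants).
_CORE_ANY = Chem.MolFromSmarts("[#6]~1~[#6]~[#6]~[#7]~2~[#6]~[#6]~[#6]~[#6]~1~2")
# 1,2-unsaturated pyrrolizidine (retronecine/heliotridine series).
_CORE_UNSAT = Chem.MolFromSmarts("C1=CCN2CCCC12")
# Fully saturated pyrrolizidine (platynecine series).
_CORE_SAT = Chem.MolFromSmarts("C1CCN2CCCC12")
# Otonecine: N-methyl azacyclooctanone with the 1,2 double bond retained.
_CORE_OTONECINE = Chem.MolFromSmarts("C1=CCN(C)CCCC1=O")
# Dehydropyrrolizidine (DHP): pyrrolic (aromatic) ring fused to the
# saturated ring.
_CORE_DHP = Chem.MolFromSmarts("C1CCn2cccc21")
# N-oxide on a ring nitrogen.
_N_OXIDE = Chem.MolFromSmarts("[N+;R]-[O-]")
# Ester: carbonyl carbon, ester oxygen, alkoxy carbon (in that match order).
_ESTER = Chem.MolFromSmarts("[CX3](=O)[OX2][#6]")

NECINE_BASES = ("retronecine", "otonecine", "platynecine", "unassigned")
MODIFICATIONS = ("n_oxide", "dehydropyrrolizidine", "tertiary")
NECIC_ACIDS = ("monoester", "open_diester", "macrocyclic_diester", "unassigned")


@dataclass
class PAGroupAssignment:
    key: str
    necine_base: str
    modification: str
    necic_acid: str
    reason: str | None = None  # set when no PA core was found


def _core_atoms(mol: Chem.Mol) -> set[int]:
    atoms: set[int] = set()
    for pattern in (_CORE_ANY, _CORE_OTONECINE):
        for match in mol.GetSubstructMatches(pattern):
            atoms.update(match)
    return atoms


def _classify_necic_acid(mol: Chem.Mol, core: set[int]) -> str:
    """Count ester arms anchored on the necine core.

    An ester belongs to the core when its alkoxy carbon is a core atom or
    directly bonded to one (the C9 arm is exocyclic).  Two or more core
    esters whose ester oxygens both sit in a large ring (>= 10 atoms) make
    a macrocyclic diester; otherwise an open-ring diester.
    """
    core_esters = []
    for match in mol.GetSubstructMatches(_ESTER):
        carbonyl_c, _carbonyl_o, ester_o, alkoxy_c = match
        neighbors = {a.GetIdx() for a in mol.GetAtomWithIdx(alkoxy_c).GetNeighbors()}
        if alkoxy_c in core or neighbors & core:
            core_esters.append((carbonyl_c, ester_o))
    if not core_esters:
        return "unassigned"
    if len(core_esters) == 1:
        return "monoester"
    ring_info = mol.GetRingInfo()
    big_rings = [set(r) for r in ring_info.AtomRings() if len(r) >= 10]
    ester_oxygens = [o for _, o in core_esters]
    for ring in big_rings:
        if sum(1 for o in ester_oxygens if o in ring) >= 2:
            return "macrocyclic_diester"
    return "open_diester"


def assign_groups(smiles: str, key: str | None = None) -> PAGroupAssignment:
    """Classify one structure along the three PA feature axes.

    Structures without a recognizable necine core come back all-unassigned
    (modification defaults to tertiary) with a reason, so totals always
    reconcile.  Unparseable SMILES raise ``ValueError``.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    key = key if key is not None else smiles

    has_core = mol.HasSubstructMatch(_CORE_ANY) or mol.HasSubstructMatch(_CORE_OTONECINE)
    if not has_core:
        return PAGroupAssignment(
            key, "unassigned", "tertiary", "unassigned", reason="no pyrrolizidine core"
        )

    if mol.HasSubstructMatch(_CORE_OTONECINE):
        base = "otonecine"
    elif mol.HasSubstructMatch(_CORE_UNSAT):
        base = "retronecine"
    elif mol.HasSubstructMatch(_CORE_DHP):
        base = "unassigned"  # pyrrolic core: 1,2-saturation no longer defined
    elif mol.HasSubstructMatch(_CORE_SAT):
        base = "platynecine"
    else:
        base = "unassigned"

    if mol.HasSubstructMatch(_N_OXIDE):
        modification = "n_oxide"
    elif mol.HasSubstructMatch(_CORE_DHP):
        modification = "dehydropyrrolizidine"
    else:
        modification = "tertiary"

    necic_acid = _classify_necic_acid(mol, _core_atoms(mol))
    return PAGroupAssignment(key, base, modification, necic_acid)


def assign_groups_batch(smiles_by_key: Mapping[str, str]) -> list[PAGroupAssignment]:
    return [assign_groups(s, key=k) for k, s in smiles_by_key.items()]


@dataclass
class GroupSummary:
    model: str
    axis: str  # "necine_base" | "modification" | "necic_acid"
    group: str
    n_predicted: int
    n_positive: int

    @property
    def fraction_positive(self) -> float | None:
        if self.n_predicted == 0:
            return None
        return self.n_positive / self.n_predicted


def summarize_predictions(
    assignments: Sequence[PAGroupAssignment],
    predictions: Mapping[str, Mapping[str, str | None]],
) -> tuple[list[GroupSummary], dict[str, list[str]]]:
    """Group-wise positive-prediction fractions and per-axis rank orders.

    ``predictions`` maps model name -> {key -> predicted class or None};
    abstentions (None) are excluded from denominators.  Rank orders pool
    all models per axis and sort groups by ascending positive fraction
    (groups without predictions are omitted from the ranking).
    """
    axes = {
        "necine_base": lambda a: a.necine_base,
        "modification": lambda a: a.modification,
        "necic_acid": lambda a: a.necic_acid,
    }
    summaries: list[GroupSummary] = []
    pooled: dict[tuple[str, str], list[int]] = defaultdict(lambda: [0, 0])
    for model, preds in predictions.items():
        for axis, getter in axes.items():
            counts: dict[str, list[int]] = defaultdict(lambda: [0, 0])
            for a in assignments:
                predicted = preds.get(a.key)
                if predicted is None:
                    continue
                group = getter(a)
                counts[group][0] += 1
                pooled[(axis, group)][0] += 1
                if predicted == MUTAGENIC:
                    counts[group][1] += 1
                    pooled[(axis, group)][1] += 1
            for group in sorted(counts):
                n_pred, n_pos = counts[group]
                summaries.append(GroupSummary(model, axis, group, n_pred, n_pos))
    rank_orders = {}
    for axis in axes:
        groups = [
            (n_pos / n_pred, group)
            for (ax, group), (n_pred, n_pos) in pooled.items()
            if ax == axis and n_pred > 0
        ]
        rank_orders[axis] = [g for _, g in sorted(groups)]
    return summaries, rank_orders


def write_assignments_csv(
    assignments: Sequence[PAGroupAssignment], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["key", "necine_base", "modification", "necic_acid", "reason"])
        for a in assignments:
            writer.writerow([a.key, a.necine_base, a.modification, a.necic_acid, a.reason or ""])


def read_assignments_csv(path: str | Path) -> list[PAGroupAssignment]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                PAGroupAssignment(
                    row["key"],
                    row["necine_base"],
                    row["modification"],
                    row["necic_acid"],
                    row["reason"] or None,
                )
            )
    return out


def write_summaries_csv(summaries: Sequence[GroupSummary], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["model", "axis", "group", "n_predicted", "n_positive", "fraction_positive"])
        for s in summaries:
            frac = "" if s.fraction_positive is None else f"{s.fraction_positive:.4f}"
            writer.writerow([s.model, s.axis, s.group, s.n_predicted, s.n_positive, frac])


#: Named pyrrolizidine alkaloids and necine bases with hand-verified
#: structures, used for rule-bank unit tests and worked examples.  The
#: 7,9-diacetate is a synthetic test structure (a minimal open diester of
#: retronecine), not a natural product.
NAMED_PA_SMILES: dict[str, str] = {
    "retronecine": "OCC1=CCN2CCC(O)C12",
    "platynecine": "OCC1CCN2CCC(O)C12",
    "otonecine": "OCC1=CCN(C)CCC(O)C1=O",
    "supinidine": "OCC1=CCN2CCCC12",
    "trachelanthamidine": "OCC1CCN2CCCC12",
    "dehydroretronecine": "OCc1ccn2CCC(O)c12",
    "lycopsamine": "CC(O)C(C)(O)C(=O)OCC1=CCN2CCC(O)C12",
    "retronecine-7,9-diacetate": "CC(=O)OCC1=CCN2CCC(OC(C)=O)C12",
    "senecionine": "CC=C1CC(C)C(C)(O)C(=O)OCC2=CCN3CCC(OC1=O)C23",
    "senecionine-N-oxide": "CC=C1CC(C)C(C)(O)C(=O)OCC2=CC[N+]3([O-])CCC(OC1=O)C23",
}
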