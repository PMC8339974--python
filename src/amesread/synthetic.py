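"""Deterministic synthetic congeneric series with toxicophore-driven labels.

The generator emulates the structure of a curated mutagenicity training
database: families of congeners (a shared scaffold with varying
substituents) whose binary outcome is driven by the presence of a
toxicophore substructure — by default the aromatic nitro group, a
classical bacterial-mutagenicity alert.  Optional label noise flips
outcomes at a configurable rate.  A companion numeric descriptor matrix
(simple computed properties plus engineered constant, duplicated and noise
columns) exercises the descriptor-preprocessing filters.

Everything is reproducible from the seed, and all outputs use the same CSV
dialects as the real pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from . import MUTAGENIC, NON_MUTAGENIC
from .dataset import (
    CompoundRecord,
    Measurement,
    MutagenicityDataset,
    SourceRecord,
    merge,
)

#: Drug-like scaffolds with aromatic substitution slots ({0}, {1}, ...).
SCAFFOLDS: tuple[str, ...] = (
    "c1cc({0})cc({1})c1{2}",
    "c1ccc({0})c({1})c1{2}",
    "c1cc({0})ccc1-c1ccc({1})cc1{2}",
    "c1cc({0})ccc1Oc1ccc({1})cc1{2}",
    "c1cc({0})c2cc({1})ccc2c1{2}",
    "c1cc({0})ncc1{1}",
    "c1cc({0})cnc1{1}",
    "c1cc({0})sc1{1}",
    "c1cc({0})oc1{1}",
    "c1cc({0})ccc1Cc1ccc({1})cc1{2}",
    "c1cc({0})ccc1N(C)c1ccc({1})cc1{2}",
    "c1cc({0})ccc1C(=O)Nc1ccc({1})cc1{2}",
    "c1cc({0})ccc1S(=O)(=O)c1ccc({1})cc1{2}",
    "c1cc({0})ccc1OCCOc1ccc({1})cc1{2}",
    "c1cc({0})ccc1C(=O)c1ccc({1})cc1{2}",
    "c1cc({0})ccc1CCc1ccc({1})cc1{2}",
    "c1cc({0})ccc1OC(=O)c1ccc({1})cc1{2}",
    "c1cc({0})ccc1C(C)(C)c1ccc({1})cc1{2}",
    "c1cc({0})ccc1/C=C/c1ccc({1})cc1{2}",
    "c1cc({0})ccc1n1cc({1})cn1",
    "c1cc({0})ccc1-c1nc({1})cs1",
    "c1cc({0})ccc1NC(=O)Cc1ccc({1})cc1{2}",
)

#: Substituent grammar: 11 benign fragments + the toxicophore fragment.
#: Benign fragments are kept to <= 2 heavy atoms so the three-atom nitro
#: toxicophore always dominates the atom-environment difference between a
#: class-mate and a cross-class congener; none of them is a structural
#: mimic of the toxicophore under element+aromaticity atom typing.
TOXICOPHORE_FRAGMENT = "[N+](=O)[O-]"
BENIGN_FRAGMENTS: tuple[str, ...] = (
    "C", "CC", "O", "OC", "CO", "SC", "F", "Cl", "Br", "I", "C#N",
)
#: SMARTS that defines the positive class (aromatic nitro).
DEFAULT_TOXICOPHORE_SMARTS = "[a][N+](=O)[O-]"


@dataclass
class FixtureSpec:
    """Study conditions of the synthetic series."""

    n_scaffolds: int = 20
    variants_per_scaffold: int = 10
    toxicophore: str = DEFAULT_TOXICOPHORE_SMARTS
    label_noise: float = 0.0
    positive_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.n_scaffolds > len(SCAFFOLDS):
            raise ValueError(f"at most {len(SCAFFOLDS)} scaffolds available")


def _descriptor_row(mol: Chem.Mol) -> dict[str, float]:
    n_heavy = mol.GetNumAtoms()
    n_hetero = sum(1 for a in mol.GetAtoms() if a.GetSymbol() not in ("C", "H"))
    nitro = Chem.MolFromSmarts(DEFAULT_TOXICOPHORE_SMARTS)
    return {
        "heavy_atoms": float(n_heavy),
        "rings": float(rdMolDescriptors.CalcNumRings(mol)),
        "aromatic_atoms": float(sum(a.GetIsAromatic() for a in mol.GetAtoms())),
        "hetero_fraction": n_hetero / n_heavy,
        "mol_wt": Descriptors.MolWt(mol),
        "logp": Crippen.MolLogP(mol),
        "tpsa": rdMolDescriptors.CalcTPSA(mol),
        "hbd": float(rdMolDescriptors.CalcNumHBD(mol)),
        "hba": float(rdMolDescriptors.CalcNumHBA(mol)),
        "nitro_groups": float(len(mol.GetSubstructMatches(nitro))),
    }


def generate(spec: FixtureSpec) -> tuple[MutagenicityDataset, pd.DataFrame]:
    """Generate the congeneric series and its descriptor matrix.

    Each scaffold yields one congeneric series: the first substitution
    slot carries the toxicophore in positives (and a methyl in negatives),
    while one peripheral slot takes a benign decoration.  Decorations are
    drawn *without replacement* within a series, so no two congeners share
    the same substituent pattern and — crucially — a compound never has a
    cross-class twin differing only in the toxicophore's absence at equal
    decoration.  The outcome is toxicophore presence, XOR a noise flip
    drawn at ``label_noise``.  Structures are guaranteed unique by
    canonical-SMILES recount.  The descriptor matrix carries computed
    properties plus, by design, 2 constant columns, 3 duplicated columns
    and 3 Gaussian noise columns so the preprocessing filters always have
    work to do.
    """
    rng = np.random.default_rng(spec.seed)
    toxicophore = Chem.MolFromSmarts(spec.toxicophore)
    if toxicophore is None:
        raise ValueError(f"invalid toxicophore SMARTS: {spec.toxicophore!r}")

    records: list[SourceRecord] = []
    rows: dict[str, dict[str, float]] = {}
    seen: set[str] = set()
    for scaffold in SCAFFOLDS[: spec.n_scaffolds]:
        n_slots = scaffold.count("{")
        # Distinct (peripheral slot, fragment) decorations for this series.
        combos = [
            (v, frag)
            for v in range(max(1, n_slots - 1))
            for frag in BENIGN_FRAGMENTS
        ]
        if spec.variants_per_scaffold > len(combos):
            raise ValueError(
                f"scaffold {scaffold!r} supports at most {len(combos)} variants"
            )
        order = rng.permutation(len(combos))
        n_positive = round(spec.positive_fraction * spec.variants_per_scaffold)
        built = 0
        for idx in order:
            if built >= spec.variants_per_scaffold:
                break
            v, frag = combos[idx]
            want_positive = built < n_positive
            frags = ["C"] * n_slots
            if n_slots > 1:
                frags[1 + v] = frag
            if want_positive:
                frags[0] = TOXICOPHORE_FRAGMENT
            mol = Chem.MolFromSmiles(scaffold.format(*frags))
            if mol is None:
                continue
            key = Chem.MolToSmiles(mol)
            if key in seen:
                continue
            if mol.HasSubstructMatch(toxicophore) != want_positive:
                continue
            seen.add(key)
            built += 1
            label = want_positive
            if spec.label_noise > 0 and rng.random() < spec.label_noise:
                label = not label
            records.append(
                SourceRecord("synthetic", key, MUTAGENIC if label else NON_MUTAGENIC)
            )
            rows[key] = _descriptor_row(mol)
        if built < spec.variants_per_scaffold:
            raise RuntimeError(f"cannot build enough unique variants of {scaffold!r}")

    dataset = merge(records)
    descriptors = pd.DataFrame.from_dict(rows, orient="index").loc[dataset.keys()]
    n = len(descriptors)
    descriptors["const_zero"] = 0.0
    descriptors["const_one"] = 1.0
    descriptors["dup_heavy_atoms"] = descriptors["heavy_atoms"]
    descriptors["dup_mol_wt"] = descriptors["mol_wt"]
    descriptors["dup_logp"] = descriptors["logp"]
    for i in range(3):
        descriptors[f"noise_{i}"] = rng.normal(size=n)
    return dataset, descriptors


def inject_duplicates_and_conflicts(
    dataset: MutagenicityDataset, n_dup: int = 0, n_conflict: int = 0, seed: int = 0
) -> MutagenicityDataset:
    """Add same-outcome replicates and opposite-outcome measurements.

    Same-outcome duplicates collapse under the merge rule, leaving all
    counts unchanged; each conflict adds one measurement and flags its
    compound contradictory.  Targets are drawn without replacement from
    currently non-contradictory compounds.
    """
    eligible = [k for k in dataset.keys() if not dataset[k].contradictory]
    if n_dup + n_conflict > len(eligible):
        raise ValueError("not enough non-contradictory compounds to modify")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_dup + n_conflict, replace=False)
    conflict_keys = {eligible[i] for i in chosen[:n_conflict]}
    dup_keys = {eligible[i] for i in chosen[n_conflict:]}

    out = MutagenicityDataset(provenance=sorted(set(dataset.provenance) | {"injected"}))
    for key, rec in dataset.records.items():
        measurements = list(rec.measurements)
        if key in conflict_keys:
            opposite = (
                NON_MUTAGENIC if measurements[0].outcome == MUTAGENIC else MUTAGENIC
            )
            measurements.append(Measurement(opposite, ("injected",)))
            measurements.sort(key=lambda m: m.outcome)
        elif key in dup_keys:
            # same outcome from a second source: collapses into the
            # existing measurement's source list
            m = measurements[0]
            measurements[0] = Measurement(
                m.outcome, tuple(sorted(set(m.source_ids) | {"injected"}))
            )
        out.records[key] = CompoundRecord(key, measurements)
    return out


def as_source_records(dataset: MutagenicityDataset) -> list[SourceRecord]:
    """Flatten a dataset back to one source record per (measurement,
    source) pair — the inverse view used to exercise merge()."""
    records = []
    for key in dataset.keys():
        for m in dataset[key].measurements:
            for source_id in m.source_ids:
                records.append(SourceRecord(source_id, key, m.outcome))
    return records
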