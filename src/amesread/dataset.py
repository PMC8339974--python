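"""Compilation of a unified mutagenicity training database.

Heterogeneous source tables (SMILES + binary Ames outcome, or strain-wise
result lists) are normalized to :class:`SourceRecord`, canonicalized, and
merged into one :class:`CompoundRecord` per unique structure.  Replicate
results with the same outcome collapse to a single measurement; conflicting
outcomes are retained as two measurements and the compound is flagged
contradictory.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from rdkit import Chem
from rdkit import RDLogger

from . import MUTAGENIC, NON_MUTAGENIC, OUTCOMES

RDLogger.DisableLog("rdApp.error")

#: Salmonella typhimurium tester strains whose results drive the binary call.
SALMONELLA_STRAINS = frozenset(
    {"TA97", "TA98", "TA100", "TA102", "TA1535", "TA1537", "TA1538"}
)


class SmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


def canonicalize(smiles: str) -> str:
    """Return the canonical SMILES key for a structure.

    Idempotent: any SMILES of the same molecular graph (after aromaticity
    perception) maps to the same key.  Raises :class:`SmilesError` on parse
    failure; batch callers collect those into a rejects report instead of
    aborting.
    """
    if not smiles or not smiles.strip():
        raise SmilesError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class SourceRecord:
    """One experimental result from one source table."""

    source_id: str
    smiles: str
    outcome: str
    strain: str | None = None
    s9: bool | None = None

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}, got {self.outcome!r}")
        if not self.smiles:
            raise ValueError("smiles must be non-empty")


@dataclass(frozen=True)
class Measurement:
    """One retained measurement: an outcome plus the sources reporting it."""

    outcome: str
    source_ids: tuple[str, ...]


@dataclass
class CompoundRecord:
    """All retained measurements for one unique structure."""

    canonical_smiles: str
    measurements: list[Measurement]

    @property
    def contradictory(self) -> bool:
        return len({m.outcome for m in self.measurements}) > 1

    @property
    def outcomes(self) -> list[str]:
        return [m.outcome for m in self.measurements]


@dataclass
class RejectedRecord:
    source_id: str
    smiles: str
    reason: str


@dataclass
class MutagenicityDataset:
    """Keyed collection of compound records plus provenance bookkeeping."""

    records: dict[str, CompoundRecord] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)
    rejects: list[RejectedRecord] = field(default_factory=list)

    @property
    def n_structures(self) -> int:
        return len(self.records)

    @property
    def n_measurements(self) -> int:
        return sum(len(r.measurements) for r in self.records.values())

    @property
    def n_contradictory(self) -> int:
        return sum(1 for r in self.records.values() if r.contradictory)

    def keys(self) -> list[str]:
        return list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, key: str) -> bool:
        return key in self.records

    def __getitem__(self, key: str) -> CompoundRecord:
        return self.records[key]

    def summary(self) -> dict:
        return {
            "structures": self.n_structures,
            "measurements": self.n_measurements,
            "contradictory": self.n_contradictory,
            "rejected": len(self.rejects),
            "sources": sorted(self.provenance),
        }

    def measurement_rows(self) -> Iterator[tuple[str, str]]:
        """Yield ``(canonical_smiles, outcome)`` — one row per measurement."""
        for key in self.records:
            for m in self.records[key].measurements:
                yield key, m.outcome


def normalize_strain(strain: str) -> str:
    return strain.replace(" ", "").replace("-", "").upper()


def classify_strainwise(
    results: Sequence[tuple[str, bool | None, str]],
) -> tuple[str | None, str | None]:
    """Binary outcome from strain-wise Ames calls, or exclusion.

    ``results`` holds ``(strain, s9, call)`` triples with call in
    {"positive", "negative"}.  A compound is mutagenic if at least one
    positive result exists in the seven Salmonella tester strains (with or
    without S9), non-mutagenic if listed-strain results exist and none is
    positive, and excluded (outcome ``None`` with a reason) when only
    non-listed strains — e.g. E. coli WP2 — were tested.

    Returns ``(outcome, reason)`` where ``reason`` is set only on exclusion.
    """
    if not results:
        return None, "no results"
    relevant = [
        (strain, s9, call)
        for strain, s9, call in results
        if normalize_strain(strain) in SALMONELLA_STRAINS
    ]
    if not relevant:
        return None, "no results in listed Salmonella strains"
    for _, _, call in relevant:
        if call not in ("positive", "negative"):
            raise ValueError(f"call must be positive/negative, got {call!r}")
    if any(call == "positive" for _, _, call in relevant):
        return MUTAGENIC, None
    return NON_MUTAGENIC, None


def merge(sources: Iterable[SourceRecord]) -> MutagenicityDataset:
    """Merge outcome-classified source records into one record per structure.

    Same-structure, same-outcome replicates collapse to a single
    measurement (their source ids are pooled); opposite outcomes are kept
    as separate measurements and flag the compound contradictory.  The
    result is independent of input order.
    """
    by_key: dict[str, dict[str, set[str]]] = {}
    rejects: list[RejectedRecord] = []
    source_ids: set[str] = set()
    for rec in sources:
        source_ids.add(rec.source_id)
        try:
            key = canonicalize(rec.smiles)
        except SmilesError as exc:
            rejects.append(RejectedRecord(rec.source_id, rec.smiles, str(exc)))
            continue
        by_key.setdefault(key, {}).setdefault(rec.outcome, set()).add(rec.source_id)

    dataset = MutagenicityDataset(provenance=sorted(source_ids), rejects=rejects)
    for key in sorted(by_key):
        measurements = [
            Measurement(outcome, tuple(sorted(by_key[key][outcome])))
            for outcome in OUTCOMES
            if outcome in by_key[key]
        ]
        dataset.records[key] = CompoundRecord(key, measurements)
    return dataset


def drop_for_descriptor_path(
    dataset: MutagenicityDataset, available_keys: Iterable[str]
) -> tuple[MutagenicityDataset, dict]:
    """Restrict to compounds usable on the numeric-descriptor path.

    Contradictory compounds and compounds without a descriptor row (failed
    descriptor calculations) are removed.  Returns the filtered dataset and
    a removal-count log.
    """
    available = set(available_keys)
    out = MutagenicityDataset(provenance=list(dataset.provenance))
    n_contradictory = 0
    n_missing = 0
    for key, rec in dataset.records.items():
        if rec.contradictory:
            n_contradictory += 1
            continue
        if key not in available:
            n_missing += 1
            continue
        out.records[key] = CompoundRecord(key, list(rec.measurements))
    log = {
        "removed_contradictory": n_contradictory,
        "removed_no_descriptors": n_missing,
        "kept": out.n_structures,
    }
    return out, log


# ---------------------------------------------------------------------------
# Source-file adapters.  Each source ships its own column dialect; every
# adapter yields SourceRecord so merge() needs a single schema.

def read_generic_csv(
    path: str | Path,
    source_id: str,
    smiles_column: str = "smiles",
    outcome_column: str = "outcome",
    outcome_map: Mapping[str, str] | None = None,
) -> list[SourceRecord]:
    """Read ``smiles,outcome`` style tables (the combined-dataset dialect)."""
    outcome_map = dict(outcome_map or {})
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames and smiles_column not in reader.fieldnames:
            # combined-dataset dialect names the structure column after the
            # canonical key
            if "canonical_smiles" in reader.fieldnames:
                smiles_column = "canonical_smiles"
        for row in reader:
            raw = row[outcome_column].strip()
            outcome = outcome_map.get(raw, raw)
            records.append(SourceRecord(source_id, row[smiles_column].strip(), outcome))
    return records


def read_kazius_csv(path: str | Path) -> list[SourceRecord]:
    """Kazius/Bursi dialect: columns ``smiles`` and ``mutagen`` with
    values ``mutagen``/``nonmutagen``."""
    return read_generic_csv(
        path,
        "kazius",
        smiles_column="smiles",
        outcome_column="mutagen",
        outcome_map={"mutagen": MUTAGENIC, "nonmutagen": NON_MUTAGENIC},
    )


def read_hansen_csv(path: str | Path) -> list[SourceRecord]:
    """Hansen benchmark dialect: columns ``SMILES`` and binary ``label``
    (1 = mutagenic)."""
    return read_generic_csv(
        path,
        "hansen",
        smiles_column="SMILES",
        outcome_column="label",
        outcome_map={"1": MUTAGENIC, "0": NON_MUTAGENIC},
    )


def read_efsa_strainwise_csv(path: str | Path) -> list[SourceRecord]:
    """EFSA-style strain-wise table: ``substance,smiles,strain,s9,call``
    with one row per individual strain result.

    Rows are grouped per substance and reduced with
    :func:`classify_strainwise`; substances tested only in non-listed
    strains are excluded.
    """
    groups: dict[str, list[tuple[str, bool | None, str]]] = {}
    smiles_of: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            substance = row["substance"].strip()
            smiles_of[substance] = row["smiles"].strip()
            s9_raw = row.get("s9", "").strip().lower()
            s9 = None if s9_raw == "" else s9_raw in ("1", "true", "yes", "+", "+s9")
            groups.setdefault(substance, []).append(
                (row["strain"].strip(), s9, row["call"].strip().lower())
            )
    records = []
    for substance, results in groups.items():
        outcome, _reason = classify_strainwise(results)
        if outcome is None:
            continue
        records.append(SourceRecord("efsa", smiles_of[substance], outcome))
    return records


def write_measurements_csv(dataset: MutagenicityDataset, path: str | Path) -> None:
    """Write the combined dataset: ``canonical_smiles,outcome``, one row per
    measurement (contradictory compounds contribute two rows)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["canonical_smiles", "outcome"])
        for key, outcome in dataset.measurement_rows():
            writer.writerow([key, outcome])


def read_measurements_csv(path: str | Path) -> MutagenicityDataset:
    """Read a ``canonical_smiles,outcome`` measurement table back into a
    dataset (re-merging rows per structure)."""
    records = read_generic_csv(path, Path(path).stem, smiles_column="canonical_smiles")
    return merge(records)


def write_rejects(dataset: MutagenicityDataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source_id", "smiles", "reason"])
        for rej in dataset.rejects:
            writer.writerow([rej.source_id, rej.smiles, rej.reason])


def write_summary_json(dataset: MutagenicityDataset, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataset.summary(), indent=2))
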