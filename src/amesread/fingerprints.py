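"""Atom-environment fingerprints (MolPrint2D-style).

Each heavy atom contributes one feature string describing its own atom type
and the counted atom types at topological distances 1 and 2.  A molecule's
fingerprint is the *set* of these strings, so similarity reduces to set
operations (Tanimoto/Jaccard).  Feature strings are canonical — types
within a layer are sorted — which makes them graph-invariant and diffable.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from rdkit import Chem

FingerprintSet = set[str]


def atom_type(atom: Chem.Atom) -> str:
    """Default atom typing: element symbol plus an aromaticity flag.

    Pluggable — any callable ``Atom -> str`` may replace it in
    :func:`atom_environments`.
    """
    return atom.GetSymbol() + (".ar" if atom.GetIsAromatic() else "")


def _serialize(root: str, layers: list[Counter]) -> str:
    parts = [root]
    for d, layer in enumerate(layers, start=1):
        body = ",".join(f"{t}x{layer[t]}" for t in sorted(layer))
        parts.append(f"d{d}:{body}")
    return ";".join(parts)


def atom_environments(
    molecule: Chem.Mol | str, depth: int = 2, typer=atom_type
) -> FingerprintSet:
    """Compute the atom-environment feature set of a molecule.

    One environment per heavy atom (hydrogens excluded), deduplicated into
    a set.  ``depth`` is the number of topological-distance layers (2 for
    the published definition).  Accepts a parsed molecule or a SMILES
    string.  Raises ``ValueError`` for molecules without heavy atoms or
    unparseable SMILES.
    """
    if isinstance(molecule, str):
        mol = Chem.MolFromSmiles(molecule)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {molecule!r}")
    else:
        mol = molecule
    if depth < 0:
        raise ValueError("depth must be >= 0")
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    if not heavy:
        raise ValueError("molecule has no heavy atoms")
    types = {i: typer(mol.GetAtomWithIdx(i)) for i in heavy}
    dist = Chem.GetDistanceMatrix(mol)
    features: FingerprintSet = set()
    for i in heavy:
        layers = []
        for d in range(1, depth + 1):
            layer = Counter(types[j] for j in heavy if dist[i, j] == d)
            layers.append(layer)
        features.add(_serialize(types[i], layers))
    return features


def fingerprints_for(
    smiles_by_key: Mapping[str, str], depth: int = 2
) -> dict[str, FingerprintSet]:
    """Fingerprint a keyed SMILES collection (key -> SMILES)."""
    return {k: atom_environments(s, depth=depth) for k, s in smiles_by_key.items()}


# ---------------------------------------------------------------------------
# Sparse on-disk representation: one line per compound,
# ``key<TAB>feature<TAB>feature...``.

def write_sparse(fps: Mapping[str, FingerprintSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, features in fps.items():
            fh.write("\t".join([key, *sorted(features)]) + "\n")


def read_sparse(path: str | Path) -> dict[str, FingerprintSet]:
    """Inverse of :func:`write_sparse`.  Duplicate keys or empty lines are
    format violations and raise with the offending line number."""
    fps: dict[str, FingerprintSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0]:
                raise ValueError(f"malformed sparse line {lineno}: {line!r}")
            key = fields[0]
            if key in fps:
                raise ValueError(f"duplicate key {key!r} at line {lineno}")
            fps[key] = set(fields[1:])
    return fps


def expand_to_matrix(
    fps: Mapping[str, FingerprintSet], vocabulary: list[str] | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Expand set fingerprints to a binary presence matrix.

    When ``vocabulary`` is None it is built from the input (sorted union of
    features — deterministic).  Features outside a given vocabulary are
    dropped (intersection semantics: a prediction set is projected onto the
    training vocabulary).  Returns ``(matrix, vocabulary)`` with rows keyed
    by compound and int8 cells.
    """
    if vocabulary is None:
        vocabulary = sorted(set().union(*fps.values())) if fps else []
    else:
        if len(set(vocabulary)) != len(vocabulary):
            raise ValueError("vocabulary contains duplicates")
    index = list(fps)
    col_of = {f: j for j, f in enumerate(vocabulary)}
    data = np.zeros((len(index), len(vocabulary)), dtype=np.int8)
    for i, key in enumerate(index):
        for feature in fps[key]:
            j = col_of.get(feature)
            if j is not None:
                data[i, j] = 1
    return pd.DataFrame(data, index=index, columns=vocabulary), vocabulary
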