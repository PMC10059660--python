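"""Readers and writers for the plain-text formats the pipeline exchanges.

All CSV output is UTF-8 with a mandatory header row and deterministic row
order (molecule_id, then atom_index), so identical inputs give byte-identical
files.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence, Union

from rdkit import Chem

from .chem import (
    MappedReaction,
    SomLabelSet,
    StandardMolecule,
    parse_mapped_reaction,
    standardize_mol,
    standardize_molecule,
)
from .errors import InputError
from .sites import NON_SOM, SOM, UNKNOWN, CandidateSite

__all__ = [
    "read_smiles_file",
    "read_sdf",
    "read_reaction_file",
    "write_labeled_sites_csv",
    "read_labeled_sites_csv",
]

PathLike = Union[str, Path]


def read_smiles_file(path: PathLike) -> list[StandardMolecule]:
    """One molecule per line: ``SMILES`` or ``SMILES<TAB>id``."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            source_id = parts[1].strip() if len(parts) > 1 else f"mol-{lineno}"
            out.append(standardize_molecule(smiles, source_id=source_id))
    if not out:
        raise InputError(f"{path}: no molecules parsed")
    return out


def read_sdf(path: PathLike) -> list[StandardMolecule]:
    """V2000 SDF reader; molecule names become source ids."""
    out = []
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol-{i + 1}"
        out.append(standardize_mol(mol, source_id=name))
    if not out:
        raise InputError(f"{path}: no molecules parsed")
    return out


def read_reaction_file(path: PathLike) -> list[MappedReaction]:
    """One ``reactants>>products`` reaction SMILES per line."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(parse_mapped_reaction(line))
    if not out:
        raise InputError(f"{path}: no reactions parsed")
    return out


_LABEL_TO_INT = {SOM: 1, NON_SOM: 0}


def write_labeled_sites_csv(sites: Sequence[CandidateSite], path: PathLike) -> None:
    """Labeled-site table: molecule_id, canonical_smiles, atom_index,
    site_type, label. Sites still labeled 'unknown' are refused."""
    rows = []
    for s in sites:
        if s.label == UNKNOWN:
            raise InputError(
                f"site {s.molecule.source_id}:{s.atom_index} is unlabeled; "
                "attach labels before writing"
            )
        rows.append(
            (
                s.molecule.source_id or s.molecule.canonical_smiles,
                s.molecule.canonical_smiles,
                s.atom_index,
                "".join(sorted(s.site_types)),
                _LABEL_TO_INT[s.label],
            )
        )
    rows.sort(key=lambda r: (r[0], r[2]))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["molecule_id", "canonical_smiles", "atom_index", "site_type", "label"])
        writer.writerows(rows)


def read_labeled_sites_csv(path: PathLike) -> list[CandidateSite]:
    """Inverse of `write_labeled_sites_csv`; molecules sharing an id share one
    StandardMolecule instance."""
    cache: dict[str, StandardMolecule] = {}
    out = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"molecule_id", "canonical_smiles", "atom_index", "site_type", "label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise InputError(
                f"{path}: expected columns {sorted(required)}, found {reader.fieldnames}"
            )
        for row in reader:
            key = row["molecule_id"]
            if key not in cache:
                cache[key] = standardize_molecule(row["canonical_smiles"], source_id=key)
            label = SOM if int(row["label"]) == 1 else NON_SOM
            out.append(
                CandidateSite(
                    cache[key],
                    int(row["atom_index"]),
                    frozenset(row["site_type"]),
                    label=label,
                )
            )
    if not out:
        raise InputError(f"{path}: no sites parsed")
    return out


def sites_to_label_sets(
    sites: Sequence[CandidateSite],
) -> list[tuple[StandardMolecule, SomLabelSet]]:
    """Group a labeled-site table into per-molecule SOM label sets."""
    by_mol: dict[str, tuple[StandardMolecule, set[int]]] = {}
    order: list[str] = []
    for s in sites:
        key = s.molecule.source_id or s.molecule.canonical_smiles
        if key not in by_mol:
            by_mol[key] = (s.molecule, set())
            order.append(key)
        if s.label == SOM:
            by_mol[key][1].add(s.atom_index)
    return [
        (by_mol[k][0], SomLabelSet(by_mol[k][0], frozenset(by_mol[k][1])))
        for k in order
    ]
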