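"""Enumeration of candidate sites of metabolism on azaheteroaromatic rings.

hAOX oxidizes electron-poor ring carbons of N-containing heteroaromatics.
Two mechanistic site types cover the reported chemistry:

* type A — an aromatic CH directly bonded to a two-connected aromatic ring
  nitrogen (the alpha carbon of a pyridine-like ring);
* type B — a ring CH with two heavy neighbors lying three conjugated bonds
  from a two-connected ring nitrogen (the gamma carbon).

Each type exists in two interchangeable implementations: a SMARTS pattern
(fast path, user-extensible via a YAML definition file) and a brute-force
atom-iteration reference (`type_a_atoms_reference`, `type_b_atoms_reference`)
that is the normative definition — the printed SMARTS in the source
literature for these rules are not syntactically well-formed, so the
reference routines pin the semantics and the shipped SMARTS are tested to
agree with them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml
from rdkit import Chem

from .chem import SomLabelSet, StandardMolecule
from .errors import ConfigError, MoleculeStateError, ReferenceMismatchError

__all__ = [
    "SiteTypeDefinition",
    "CandidateSite",
    "load_site_definitions",
    "default_site_definitions",
    "enumerate_candidate_sites",
    "attach_labels",
    "type_a_atoms_reference",
    "type_b_atoms_reference",
]

SOM = "SOM"
NON_SOM = "non-SOM"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class SiteTypeDefinition:
    """One candidate-site type: a code, a one-atom SMARTS query, prose."""

    type_code: str
    smarts: str
    description: str = ""
    enabled: bool = True

    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:
            raise ConfigError(f"site type {self.type_code}: invalid SMARTS {self.smarts!r}")
        return q


@dataclass(frozen=True)
class CandidateSite:
    """One potential SOM atom; an atom matching several types yields one site."""

    molecule: StandardMolecule
    atom_index: int
    site_types: frozenset[str]
    label: str = UNKNOWN


def load_site_definitions(path: Union[str, Path]) -> list[SiteTypeDefinition]:
    """Load site-type definitions from a user YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "site_types" not in doc:
        raise ConfigError(f"{path}: expected a mapping with a 'site_types' list")
    defs = []
    for entry in doc["site_types"]:
        try:
            d = SiteTypeDefinition(
                type_code=str(entry["type_code"]),
                smarts=str(entry["smarts"]),
                description=str(entry.get("description", "")),
                enabled=bool(entry.get("enabled", True)),
            )
        except KeyError as exc:
            raise ConfigError(f"{path}: site-type entry missing field {exc}") from exc
        d.query()  # validate eagerly
        defs.append(d)
    return defs


def default_site_definitions() -> list[SiteTypeDefinition]:
    """The two shipped site types (A: alpha to ring N, B: gamma to ring N)."""
    ref = resources.files("aoxsom.data").joinpath("site_types.yaml")
    with resources.as_file(ref) as path:
        return load_site_definitions(path)


# --- brute-force reference definitions --------------------------------------


def _is_path_bond(bond: Chem.Bond) -> bool:
    # conjugated path step: aromatic or double bond
    return bond.GetIsAromatic() or bond.GetBondType() in (
        Chem.BondType.AROMATIC,
        Chem.BondType.DOUBLE,
    )


def type_a_atoms_reference(mol: Chem.Mol) -> set[int]:
    """Aromatic CH (one hydrogen, in ring) aromatic-bonded to an in-ring
    aromatic nitrogen with two total connections. Direct atom iteration."""
    hits: set[int] = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or not atom.GetIsAromatic():
            continue
        if atom.GetTotalNumHs() != 1 or not atom.IsInRing():
            continue
        for nbr in atom.GetNeighbors():
            bond = mol.GetBondBetweenAtoms(atom.GetIdx(), nbr.GetIdx())
            if (
                nbr.GetAtomicNum() == 7
                and nbr.GetIsAromatic()
                and nbr.IsInRing()
                and nbr.GetTotalDegree() == 2
                and bond.GetIsAromatic()
            ):
                hits.add(atom.GetIdx())
                break
    return hits


def type_b_atoms_reference(mol: Chem.Mol) -> set[int]:
    """Ring CH with two heavy neighbors and a simple 3-bond path of
    aromatic/double bonds ending at a two-connected ring nitrogen."""
    hits: set[int] = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or not atom.IsInRing():
            continue
        if atom.GetTotalNumHs() != 1 or atom.GetTotalDegree() != 3:
            continue
        a = atom.GetIdx()
        found = False
        for n1 in atom.GetNeighbors():
            if not _is_path_bond(mol.GetBondBetweenAtoms(a, n1.GetIdx())):
                continue
            for n2 in n1.GetNeighbors():
                if n2.GetIdx() == a:
                    continue
                if not _is_path_bond(mol.GetBondBetweenAtoms(n1.GetIdx(), n2.GetIdx())):
                    continue
                for n3 in n2.GetNeighbors():
                    if n3.GetIdx() in (a, n1.GetIdx()):
                        continue
                    if not _is_path_bond(mol.GetBondBetweenAtoms(n2.GetIdx(), n3.GetIdx())):
                        continue
                    if (
                        n3.GetAtomicNum() == 7
                        and n3.GetTotalDegree() == 2
                        and n3.IsInRing()
                    ):
                        found = True
                        break
                if found:
                    break
            if found:
                break
        if found:
            hits.add(a)
    return hits


_REFERENCE_BY_CODE = {"A": type_a_atoms_reference, "B": type_b_atoms_reference}


# --- enumeration ------------------------------------------------------------


def _check_standardized(mol: StandardMolecule) -> None:
    if not isinstance(mol, StandardMolecule):
        raise MoleculeStateError(
            "enumerate_candidate_sites requires a StandardMolecule; "
            "run standardize_molecule first so aromaticity is perceived"
        )


def enumerate_candidate_sites(
    mol: StandardMolecule,
    definitions: Optional[Sequence[SiteTypeDefinition]] = None,
    use_smarts: bool = True,
) -> list[CandidateSite]:
    """All candidate SOM atoms of a standardized molecule, sorted by index.

    An atom matching several site types yields a single site with merged
    ``site_types`` (so site tallies never double-count). Molecules with no
    candidate at all are simply returned as an empty list; downstream they are
    reported as predicted non-substrates, not as errors.

    ``use_smarts=False`` switches to the brute-force reference routines for
    the two shipped type codes.
    """
    _check_standardized(mol)
    if definitions is None:
        definitions = default_site_definitions()

    types_by_atom: dict[int, set[str]] = {}
    for d in definitions:
        if not d.enabled:
            continue
        if use_smarts:
            matched = {m[0] for m in mol.mol.GetSubstructMatches(d.query())}
        else:
            try:
                matched = _REFERENCE_BY_CODE[d.type_code](mol.mol)
            except KeyError as exc:
                raise ConfigError(
                    f"no reference implementation for site type {d.type_code!r}"
                ) from exc
        for idx in matched:
            types_by_atom.setdefault(idx, set()).add(d.type_code)

    return [
        CandidateSite(mol, idx, frozenset(codes))
        for idx, codes in sorted(types_by_atom.items())
    ]


def attach_labels(
    sites: Sequence[CandidateSite], labels: SomLabelSet
) -> tuple[list[CandidateSite], int]:
    """Mark each site SOM/non-SOM; return (labeled sites, uncovered-SOM count).

    The second value counts experimental SOMs that no candidate site proposes
    — the per-molecule contribution to the coverage ceiling of top-k accuracy.
    """
    for s in sites:
        if not s.molecule.same_molecule_as(labels.substrate_ref):
            raise ReferenceMismatchError(
                "sites and labels refer to different molecules: "
                f"{s.molecule.canonical_smiles!r} vs {labels.substrate_ref.canonical_smiles!r}"
            )
    labeled = [
        replace(s, label=SOM if s.atom_index in labels.som_atom_indices else NON_SOM)
        for s in sites
    ]
    uncovered = len(labels.som_atom_indices - {s.atom_index for s in sites})
    return labeled, uncovered
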