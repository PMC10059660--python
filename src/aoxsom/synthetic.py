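"""Deterministic synthetic substrates, labels, and mapped reactions.

Real hAOX substrate collections are literature-curated N-heteroaromatics
with experimentally assigned oxidation sites. This module emulates that
shape offline: azaheteroaromatic scaffolds (pyridine, pyrimidine, quinoline,
quinazoline, cinnoline, purine cores) are decorated with small substituents
at non-candidate ring positions, and SOM labels are assigned by a
deterministic rule over the candidate-site types — so the labels are, by
construction, learnable from atom-environment fingerprints and every stage
of the pipeline can be exercised and scored against the generating rule
without any downloaded data.

Label rules:

* ``A-only`` — every type-A candidate (alpha to a ring N) is a SOM;
* ``bis-N-flanked`` — the candidate CH with two aromatic ring-N neighbors is
  the SOM (scaffolds lacking such a carbon are resampled away);
* ``distance-weighted`` — one SOM drawn per molecule with probability
  proportional to 1/d^2, d the bond distance to the nearest two-connected
  ring N (a stochastic, harder task).

`generate_mapped_reactions` writes the corresponding C–H -> C–OH oxidation
as fully atom-mapped reaction SMILES, the exact inverse of the label
extraction in `aoxsom.chem`, with the ring-retentive hydroxyl tautomer by
default and the 2-pyridinone-style lactam as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import (
    MappedReaction,
    SomLabelSet,
    StandardMolecule,
    deduplicate,
    parse_mapped_reaction,
    standardize_mol,
    standardize_molecule,
)
from .errors import ConfigError, FixtureGenerationError, SchemaError
from .sites import CandidateSite, enumerate_candidate_sites

__all__ = [
    "DEFAULT_SCAFFOLDS",
    "DEFAULT_SUBSTITUENTS",
    "LABEL_RULES",
    "FixtureSpec",
    "generate_substrates",
    "generate_mapped_reactions",
    "load_deposited_dataset",
]

DEFAULT_SCAFFOLDS = (
    "c1ccncc1",          # pyridine
    "c1cncnc1",          # pyrimidine
    "c1ccc2ncccc2c1",    # quinoline
    "c1ccc2ncncc2c1",    # quinazoline
    "c1ccc2nnccc2c1",    # cinnoline
    "c1ncc2[nH]cnc2n1",  # purine
)

# Small, chemistry-safe decorations: none adds a new two-connected ring
# nitrogen, so the candidate-site semantics of the scaffold are preserved.
DEFAULT_SUBSTITUENTS = ("C", "CC", "F", "Cl", "Br", "O", "OC", "N", "C(F)(F)F")

LABEL_RULES = ("A-only", "bis-N-flanked", "distance-weighted")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one deterministic batch of labeled substrates."""

    seed: int
    n_molecules: int
    scaffold_pool: tuple[str, ...] = DEFAULT_SCAFFOLDS
    substituent_pool: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    label_rule: str = "bis-N-flanked"
    max_substituents: int = 2
    retry_cap: int = 100

    def __post_init__(self) -> None:
        if not self.scaffold_pool or not self.substituent_pool:
            raise ConfigError("scaffold and substituent pools must be non-empty")
        if self.label_rule not in LABEL_RULES:
            raise ConfigError(f"label_rule must be one of {LABEL_RULES}")


def _bis_n_flanked(site: CandidateSite) -> bool:
    atom = site.molecule.mol.GetAtomWithIdx(site.atom_index)
    n_nbrs = sum(
        1
        for n in atom.GetNeighbors()
        if n.GetAtomicNum() == 7 and n.GetIsAromatic() and n.IsInRing()
    )
    return n_nbrs >= 2


def _distance_to_ring_n(mol: Chem.Mol, idx: int) -> Optional[int]:
    dmat = Chem.GetDistanceMatrix(mol)
    targets = [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 7 and a.IsInRing() and a.GetTotalDegree() == 2
    ]
    if not targets:
        return None
    return int(min(dmat[idx, t] for t in targets))


def _assign_soms(
    std: StandardMolecule,
    sites: Sequence[CandidateSite],
    rule: str,
    rng: np.random.Generator,
) -> frozenset[int]:
    if rule == "A-only":
        return frozenset(s.atom_index for s in sites if "A" in s.site_types)
    if rule == "bis-N-flanked":
        return frozenset(s.atom_index for s in sites if _bis_n_flanked(s))
    # distance-weighted
    dists = [_distance_to_ring_n(std.mol, s.atom_index) for s in sites]
    weights = np.array([0.0 if d is None or d == 0 else 1.0 / d**2 for d in dists])
    if weights.sum() == 0:
        return frozenset()
    pick = rng.choice(len(sites), p=weights / weights.sum())
    return frozenset({sites[pick].atom_index})


def _decorate(
    scaffold: str,
    substituents: Sequence[str],
    max_substituents: int,
    rng: np.random.Generator,
) -> str:
    """Attach 0..max substituents at non-candidate aromatic CH positions."""
    std = standardize_molecule(scaffold)
    candidate_idx = {s.atom_index for s in enumerate_candidate_sites(std)}
    eligible = [
        a.GetIdx()
        for a in std.mol.GetAtoms()
        if a.GetIsAromatic()
        and a.GetAtomicNum() == 6
        and a.GetTotalNumHs() == 1
        and a.GetIdx() not in candidate_idx
    ]
    n_sub = int(rng.integers(0, max_substituents + 1))
    n_sub = min(n_sub, len(eligible))
    ed = Chem.RWMol(std.mol)
    if n_sub:
        positions = rng.choice(len(eligible), size=n_sub, replace=False)
        for pos in sorted(positions):
            ring_atom = eligible[int(pos)]
            frag = Chem.MolFromSmiles(substituents[int(rng.integers(0, len(substituents)))])
            offset = ed.GetNumAtoms()
            ed.InsertMol(frag)
            ed.AddBond(ring_atom, offset, Chem.BondType.SINGLE)
    mol = ed.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def generate_substrates(
    spec: FixtureSpec,
) -> list[tuple[StandardMolecule, SomLabelSet]]:
    """Deterministic batch of (substrate, SOM labels) pairs.

    Each molecule is guaranteed >= 1 candidate site and >= 1 SOM under the
    requested rule (non-conforming draws are resampled, up to a retry cap),
    so the coverage ceiling of a generated batch is exactly 1.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[tuple[StandardMolecule, SomLabelSet]] = []
    for mol_no in range(spec.n_molecules):
        for _attempt in range(spec.retry_cap):
            scaffold = spec.scaffold_pool[int(rng.integers(0, len(spec.scaffold_pool)))]
            try:
                smiles = _decorate(scaffold, spec.substituent_pool, spec.max_substituents, rng)
                std = standardize_molecule(smiles, source_id=f"synthetic-{mol_no:04d}")
            except Exception:
                continue  # chemically invalid decoration; redraw
            sites = enumerate_candidate_sites(std)
            if not sites:
                continue
            soms = _assign_soms(std, sites, spec.label_rule, rng)
            if not soms:
                continue
            out.append((std, SomLabelSet(std, soms)))
            break
        else:
            raise FixtureGenerationError(
                f"rule {spec.label_rule!r} yielded no SOM in {spec.retry_cap} draws "
                f"for molecule {mol_no}"
            )
    return out


def _oxidation_product(
    substrate: Chem.Mol, som_idx: int, tautomer: str
) -> Chem.Mol:
    """C–H -> C–OH (or lactam C=O / N–H) product at one ring carbon."""
    ed = Chem.RWMol(substrate)
    o_idx = ed.AddAtom(Chem.Atom(8))
    ed.GetAtomWithIdx(o_idx).SetAtomMapNum(substrate.GetNumAtoms() + 1)
    ed.AddBond(som_idx, o_idx, Chem.BondType.SINGLE)
    if tautomer == "lactam":
        som = ed.GetAtomWithIdx(som_idx)
        ring_n = [
            n
            for n in som.GetNeighbors()
            if n.GetAtomicNum() == 7 and n.IsInRing() and n.GetTotalDegree() == 2
        ]
        if not ring_n:
            raise FixtureGenerationError(
                f"no adjacent ring nitrogen for a lactam tautomer at atom {som_idx}"
            )
        n_atom = min(ring_n, key=lambda a: a.GetIdx())
        ed.GetBondBetweenAtoms(som_idx, o_idx).SetBondType(Chem.BondType.DOUBLE)
        n_atom.SetNumExplicitHs(1)
    product = ed.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception as exc:
        raise FixtureGenerationError(
            f"oxidation product at atom {som_idx} is chemically invalid: {exc}"
        ) from exc
    return product


def generate_mapped_reactions(
    substrates_with_labels: Sequence[tuple[StandardMolecule, SomLabelSet]],
    tautomer: str = "hydroxyl",
) -> list[MappedReaction]:
    """One fully atom-mapped oxidation reaction per SOM of each substrate.

    Reactant atom i carries map number i+1; the incoming oxygen carries the
    next number. `aoxsom.chem.extract_som_labels` inverts the construction
    exactly (round-trip identity is the module's contract).
    """
    if tautomer not in ("hydroxyl", "lactam"):
        raise ConfigError(f"tautomer must be 'hydroxyl' or 'lactam', got {tautomer!r}")
    reactions = []
    for std, labels in substrates_with_labels:
        if not labels.som_atom_indices:
            raise FixtureGenerationError(
                f"substrate {std.source_id or std.canonical_smiles} has no SOM label"
            )
        reactant = Chem.Mol(std.mol)
        for atom in reactant.GetAtoms():
            atom.SetAtomMapNum(atom.GetIdx() + 1)
        for som_idx in sorted(labels.som_atom_indices):
            product = _oxidation_product(reactant, som_idx, tautomer)
            rxn_smiles = f"{Chem.MolToSmiles(reactant)}>>{Chem.MolToSmiles(product)}"
            reactions.append(parse_mapped_reaction(rxn_smiles))
    return reactions


# --- deposited-dataset loader ----------------------------------------------

_EXPECTED_CARDINALITY = {"train": 198, "test": 53}


def _parse_som_field(value) -> frozenset[int]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return frozenset()
    return frozenset(int(tok) for tok in str(value).split(";") if tok.strip() != "")


def _load_csv(path: Path) -> list[tuple[StandardMolecule, SomLabelSet]]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise SchemaError(f"{path}: unreadable CSV ({exc})") from exc
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    cols = {c.lower(): c for c in df.columns}
    smiles_col = next((cols[c] for c in cols if "smiles" in c), None)
    som_col = next((cols[c] for c in cols if "som" in c), None)
    if smiles_col is None or som_col is None:
        raise SchemaError(
            f"{path}: need a SMILES column and a SOM-index column; found {list(df.columns)}"
        )
    id_col = next((cols[c] for c in cols if c in ("id", "molecule_id", "name")), None)
    out = []
    for i, row in df.iterrows():
        source_id = str(row[id_col]) if id_col else f"{path.stem}-{i}"
        std = standardize_molecule(str(row[smiles_col]), source_id=source_id)
        raw = _parse_som_field(row[som_col])
        assert std.index_map is not None
        remapped = frozenset(
            std.index_map[j] for j in raw if std.index_map.get(j) is not None
        )
        out.append((std, SomLabelSet(std, remapped)))
    return out


def _load_sdf(path: Path) -> list[tuple[StandardMolecule, SomLabelSet]]:
    supplier = Chem.SDMolSupplier(str(path))
    out = []
    for i, mol in enumerate(supplier):
        if mol is None:
            continue
        props = {p.lower(): p for p in mol.GetPropNames()}
        som_prop = next((props[p] for p in props if "som" in p), None)
        if som_prop is None:
            raise SchemaError(f"{path}: molecule {i} lacks a SOM atom-index property")
        source_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"{path.stem}-{i}"
        std = standardize_mol(mol, source_id=source_id)
        raw = _parse_som_field(mol.GetProp(som_prop))
        assert std.index_map is not None
        remapped = frozenset(
            std.index_map[j] for j in raw if std.index_map.get(j) is not None
        )
        out.append((std, SomLabelSet(std, remapped)))
    if not out:
        raise SchemaError(f"{path}: no parseable molecules")
    return out


def _load_one(path: Path) -> list[tuple[StandardMolecule, SomLabelSet]]:
    if path.suffix.lower() == ".sdf":
        records = _load_sdf(path)
    else:
        records = _load_csv(path)
    mols = deduplicate([std for std, _ in records])
    kept = {m.canonical_smiles for m in mols}
    seen: set[str] = set()
    deduped = []
    for std, labels in records:
        if std.canonical_smiles in kept and std.canonical_smiles not in seen:
            seen.add(std.canonical_smiles)
            deduped.append((std, labels))
    return deduped


def load_deposited_dataset(
    path: Union[str, Path],
) -> tuple[
    list[tuple[StandardMolecule, SomLabelSet]],
    list[tuple[StandardMolecule, SomLabelSet]],
]:
    """Load a locally supplied copy of the curated substrate collection.

    ``path`` is a directory holding a training file and a test file (names
    containing "train" / "test"; CSV with smiles + semicolon-separated SOM
    indices, or SDF with a SOM property). Molecules are standardized and
    deduplicated; the expected cardinalities (198 training / 53 test
    substrates) are checked with a warning, not an error, since deposited
    schemas drift. Never downloads anything.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: no such file or directory")
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".csv", ".sdf"))
        train_file = next((p for p in files if "train" in p.name.lower()), None)
        test_file = next((p for p in files if "test" in p.name.lower()), None)
        if train_file is None or test_file is None:
            raise SchemaError(
                f"{path}: expected files with 'train' and 'test' in their names; "
                f"found {[p.name for p in files]}"
            )
    else:
        raise SchemaError(f"{path}: pass the dataset directory, not a single file")
    train = _load_one(train_file)
    test = _load_one(test_file)
    for name, data in (("train", train), ("test", test)):
        expected = _EXPECTED_CARDINALITY[name]
        if len(data) != expected:
            warnings.warn(
                f"{name} set has {len(data)} substrates, expected {expected}; "
                "proceeding with what was loaded"
            )
    return train, test
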