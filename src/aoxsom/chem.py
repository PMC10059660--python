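"""Molecule standardization, atom-mapped reactions, SOM labels, SMILES tokens.

Substrates of human aldehyde oxidase (hAOX) are handled as canonicalized,
standardized molecules with a stable 0-based atom indexing; every downstream
object (candidate sites, fingerprints, labels, rankings) refers to atoms of
that canonical form. Atom-map numbers in reaction SMILES are a separate,
1-based namespace and are translated to canonical indices at the boundary,
never used internally.

Experimental sites of metabolism are recovered from atom-mapped reaction
SMILES (``reactants>>products``) by diffing each mapped reactant atom's
environment against its product counterpart: an atom whose hydrogen count or
heavy-neighbor multiset changes — typically the ring carbon that gains the
incoming oxygen — is a SOM. Bond-order-only changes (aromatic bond
rearrangement in an otherwise intact ring) are deliberately ignored, since
hAOX chemistry is an oxygen addition at a ring carbon.
"""

from __future__ import annotations

import ast
import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import (
    AtomMapIntegrityError,
    EmptyInputError,
    LabelExtractionError,
    ReactionFormatError,
    SmilesParseError,
    TokenizationError,
)

__all__ = [
    "AtomInfo",
    "StandardMolecule",
    "MappedReaction",
    "SomLabelSet",
    "TokenSequence",
    "standardize_molecule",
    "standardize_mol",
    "deduplicate",
    "parse_mapped_reaction",
    "extract_som_labels",
    "tokenize_smiles",
    "TOKEN_PATTERN",
]


@dataclass(frozen=True)
class AtomInfo:
    """Summary of one heavy atom of a standardized molecule."""

    symbol: str
    is_aromatic: bool
    in_ring: bool
    n_hydrogens: int
    degree: int


@dataclass
class StandardMolecule:
    """A canonicalized, standardized molecule with stable atom indexing.

    ``mol`` holds the RDKit molecule re-parsed from ``canonical_smiles``, so
    its atom order *is* the canonical order; ``index_map`` translates atom
    indices of the caller's original input into this canonical order (``None``
    for atoms dropped with a salt/solvent fragment, or for the whole map when
    tautomer canonicalization destroyed the correspondence).
    """

    source_id: str
    canonical_smiles: str
    mol: Chem.Mol = field(repr=False)
    atoms: tuple[AtomInfo, ...] = field(repr=False)
    index_map: Optional[dict[int, Optional[int]]] = field(default=None, repr=False)

    @property
    def atom_count(self) -> int:
        return len(self.atoms)

    def same_molecule_as(self, other: "StandardMolecule") -> bool:
        return self.canonical_smiles == other.canonical_smiles


def _atom_info(atom: Chem.Atom) -> AtomInfo:
    return AtomInfo(
        symbol=atom.GetSymbol(),
        is_aromatic=atom.GetIsAromatic(),
        in_ring=atom.IsInRing(),
        n_hydrogens=atom.GetTotalNumHs(),
        degree=atom.GetDegree(),
    )


_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def standardize_mol(
    mol: Chem.Mol,
    source_id: str = "",
    canonical_tautomer: bool = False,
) -> StandardMolecule:
    """Standardize an already-parsed RDKit molecule.

    Keeps the largest organic fragment, neutralizes charges where chemically
    safe, perceives aromaticity, and reorders atoms into RDKit's canonical
    output order. Atom-map numbers, if present, are cleared first (they are
    reaction bookkeeping, not structure).
    """
    work = Chem.Mol(mol)
    for atom in work.GetAtoms():
        atom.SetAtomMapNum(0)

    # Largest fragment, by heavy-atom count, ties broken by first occurrence;
    # done by hand (not LargestFragmentChooser) so the index correspondence
    # original -> kept fragment stays explicit.
    frags = Chem.GetMolFrags(work)
    best = max(range(len(frags)), key=lambda i: (len(frags[i]), -i))
    kept = list(frags[best])
    if len(frags) > 1:
        ed = Chem.RWMol(work)
        for idx in sorted(set(range(work.GetNumAtoms())) - set(kept), reverse=True):
            ed.RemoveAtom(idx)
        work = ed.GetMol()
    # original index -> index within the kept fragment (pre-canonical)
    frag_map: dict[int, Optional[int]] = {i: None for i in range(mol.GetNumAtoms())}
    for new, old in enumerate(sorted(kept)):
        frag_map[old] = new

    work = _UNCHARGER.uncharge(work)  # preserves heavy-atom order
    Chem.SanitizeMol(work)

    tainted = False
    if canonical_tautomer:
        work = rdMolStandardize.TautomerEnumerator().Canonicalize(work)
        tainted = True  # atom correspondence no longer guaranteed

    smiles = Chem.MolToSmiles(work)
    # position i of the output order is the pre-canonical index written i-th
    output_order = ast.literal_eval(work.GetProp("_smilesAtomOutputOrder"))
    canonical_of: dict[int, int] = {old: pos for pos, old in enumerate(output_order)}

    canon = Chem.MolFromSmiles(smiles)
    if canon is None:  # pragma: no cover - canonical SMILES always re-parses
        raise SmilesParseError(smiles, "canonical SMILES failed to re-parse")

    index_map: Optional[dict[int, Optional[int]]]
    if tainted:
        index_map = None
    else:
        index_map = {
            orig: (canonical_of[frag] if frag is not None else None)
            for orig, frag in frag_map.items()
        }

    return StandardMolecule(
        source_id=source_id,
        canonical_smiles=smiles,
        mol=canon,
        atoms=tuple(_atom_info(a) for a in canon.GetAtoms()),
        index_map=index_map,
    )


def standardize_molecule(
    smiles: str,
    source_id: str = "",
    canonical_tautomer: bool = False,
) -> StandardMolecule:
    """Parse and standardize a SMILES string.

    Idempotent: applied to its own ``canonical_smiles`` it returns the same
    canonical form with the identity index map.
    """
    if smiles is None or not smiles.strip():
        raise EmptyInputError("empty SMILES input")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return standardize_mol(mol, source_id=source_id, canonical_tautomer=canonical_tautomer)


def deduplicate(molecules: Sequence[StandardMolecule]) -> list[StandardMolecule]:
    """Keep the first occurrence of each canonical SMILES, preserving order."""
    seen: set[str] = set()
    out = []
    for m in molecules:
        if m.canonical_smiles not in seen:
            seen.add(m.canonical_smiles)
            out.append(m)
    return out


# --- atom-mapped reactions --------------------------------------------------


@dataclass
class MappedReaction:
    """An atom-mapped ``reactants>>products`` reaction.

    Map tables go map-number -> atom index on the respective side. The product
    side may be multi-fragment (a substrate with two metabolites) and may
    contain atoms absent from the reactant (the incoming oxygen); reactant map
    numbers are therefore not required to exhaust the product's.
    """

    reaction_smiles: str
    reactant: Chem.Mol = field(repr=False)
    product: Chem.Mol = field(repr=False)
    atom_maps_reactant: dict[int, int] = field(default_factory=dict)
    atom_maps_product: dict[int, int] = field(default_factory=dict)

    @property
    def is_mapped(self) -> bool:
        return bool(self.atom_maps_reactant) and bool(self.atom_maps_product)


def _map_table(mol: Chem.Mol, side: str) -> dict[int, int]:
    table: dict[int, int] = {}
    for atom in mol.GetAtoms():
        num = atom.GetAtomMapNum()
        if num > 0:
            if num in table:
                raise AtomMapIntegrityError(
                    f"atom-map number {num} occurs twice on the {side} side"
                )
            table[num] = atom.GetIdx()
    return table


def parse_mapped_reaction(reaction_smiles: str) -> MappedReaction:
    """Parse a (possibly atom-mapped) reaction SMILES.

    Whitespace is stripped first: printed tables often typeset spaces around
    ``=`` and inside ``>>``, which are not part of SMILES.
    """
    if reaction_smiles is None or not reaction_smiles.strip():
        raise EmptyInputError("empty reaction SMILES")
    text = re.sub(r"\s+", "", reaction_smiles)
    parts = text.split(">>")
    if len(parts) != 2:
        raise ReactionFormatError(
            f"expected exactly one '>>' separator, got {len(parts) - 1}: {reaction_smiles!r}"
        )
    sides = []
    for label, part in zip(("reactant", "product"), parts):
        if not part:
            raise ReactionFormatError(f"empty {label} side in {reaction_smiles!r}")
        mol = Chem.MolFromSmiles(part)
        if mol is None:
            raise SmilesParseError(part, f"{label} side of reaction")
        sides.append(mol)
    reactant, product = sides
    return MappedReaction(
        reaction_smiles=text,
        reactant=reactant,
        product=product,
        atom_maps_reactant=_map_table(reactant, "reactant"),
        atom_maps_product=_map_table(product, "product"),
    )


@dataclass
class SomLabelSet:
    """Experimentally observed SOM atoms of one substrate.

    Indices are 0-based positions in ``substrate_ref``'s canonical atom order.
    ``som_map_numbers`` carries the originating atom-map numbers when the
    labels came from a mapped reaction (empty otherwise).
    """

    substrate_ref: StandardMolecule
    som_atom_indices: frozenset[int]
    som_map_numbers: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        bad = [i for i in self.som_atom_indices if not 0 <= i < self.substrate_ref.atom_count]
        if bad:
            raise LabelExtractionError(
                f"SOM indices {sorted(bad)} out of range for a "
                f"{self.substrate_ref.atom_count}-atom substrate"
            )


def _neighbor_profile(atom: Chem.Atom, reactant_maps: set[int]) -> tuple:
    """Hashable environment summary: H count + heavy-neighbor multiset.

    Mapped neighbors are keyed by map number when the map exists on the
    reactant side; anything else (unmapped, or product-only maps like the
    incoming oxygen) is keyed by element symbol. Bond orders are excluded on
    purpose.
    """
    keys = []
    for nbr in atom.GetNeighbors():
        num = nbr.GetAtomMapNum()
        if num > 0 and num in reactant_maps:
            keys.append(("map", num))
        else:
            keys.append(("new", nbr.GetSymbol()))
    return atom.GetTotalNumHs(), tuple(sorted(keys))


def extract_som_labels(reaction: MappedReaction) -> SomLabelSet:
    """Diff a mapped reaction and return the changed reactant atoms as SOMs.

    A reactant atom is a SOM iff its hydrogen count or heavy-neighbor multiset
    differs between the two sides (a neighbor present on only one side, e.g. a
    newly attached oxygen, counts as a difference; so does disappearing from
    the product altogether). The result is expressed on the standardized
    reactant via canonical atom indices.
    """
    if not reaction.is_mapped:
        raise LabelExtractionError("reaction not atom-mapped")

    rmaps = set(reaction.atom_maps_reactant)
    changed_maps: set[int] = set()
    for num, ridx in reaction.atom_maps_reactant.items():
        pidx = reaction.atom_maps_product.get(num)
        if pidx is None:
            continue  # atom left with a fragment; its neighbors register the change
        r_prof = _neighbor_profile(reaction.reactant.GetAtomWithIdx(ridx), rmaps)
        p_prof = _neighbor_profile(reaction.product.GetAtomWithIdx(pidx), rmaps)
        if r_prof != p_prof:
            changed_maps.add(num)

    # Renumber the reactant into map-number order first: canonical-SMILES
    # output order breaks symmetry ties by current atom order, so this makes
    # the extracted indices a pure function of (molecular graph, atom maps),
    # invariant to how the reaction string happened to be written.
    n_atoms = reaction.reactant.GetNumAtoms()
    map_order = sorted(reaction.atom_maps_reactant)
    new_order = [reaction.atom_maps_reactant[m] for m in map_order]
    new_order += [i for i in range(n_atoms) if i not in set(new_order)]
    work = Chem.RenumberAtoms(reaction.reactant, new_order)
    work_index_of_map = {m: pos for pos, m in enumerate(map_order)}

    substrate = standardize_mol(work)
    if not changed_maps:
        warnings.warn("no atom changed between reactant and product; empty SOM label set")
        return SomLabelSet(substrate, frozenset(), frozenset())

    assert substrate.index_map is not None
    indices = set()
    for num in changed_maps:
        canon = substrate.index_map.get(work_index_of_map[num])
        if canon is None:  # pragma: no cover - SOM atom lost to fragment stripping
            raise LabelExtractionError(f"SOM atom (map {num}) was removed by standardization")
        indices.add(canon)
    return SomLabelSet(substrate, frozenset(indices), frozenset(changed_maps))


def merge_som_labels(label_sets: Sequence[SomLabelSet]) -> list[SomLabelSet]:
    """Union label sets per substrate (by canonical SMILES), keeping first-seen
    order. A substrate with several reported metabolites contributes one
    record whose SOM set is the union over its reactions."""
    merged: dict[str, tuple[StandardMolecule, set[int], set[int]]] = {}
    order: list[str] = []
    for ls in label_sets:
        key = ls.substrate_ref.canonical_smiles
        if key not in merged:
            merged[key] = (ls.substrate_ref, set(), set())
            order.append(key)
        merged[key][1].update(ls.som_atom_indices)
        merged[key][2].update(ls.som_map_numbers)
    return [
        SomLabelSet(merged[k][0], frozenset(merged[k][1]), frozenset(merged[k][2]))
        for k in order
    ]


# --- SMILES tokenizer -------------------------------------------------------

# The published reaction-SMILES tokenization pattern: bracket atoms, two-letter
# halogens (with bare B/C falling out of the optional 'r'/'l'), the aromatic
# and aliphatic organic subset, punctuation/bond symbols, %NN ring closures,
# and single digits.
TOKEN_PATTERN = (
    r"(\[[^\]]+\]|Br?|Cl?|N|O|S|P|F|I|b|c|n|o|s|p|\(|\)|\.|=|#|-|\+|\\|\/|:|~|@"
    r"|\?|>|\*|\$|%[0-9]{2}|[0-9])"
)
_TOKEN_RE = re.compile(TOKEN_PATTERN)


@dataclass(frozen=True)
class TokenSequence:
    """Lossless tokenization of a SMILES string."""

    tokens: tuple[str, ...]
    source: str

    def __post_init__(self) -> None:
        assert "".join(self.tokens) == self.source
        assert all(self.tokens)

    def __str__(self) -> str:
        return " ".join(self.tokens)


def tokenize_smiles(smiles: str) -> TokenSequence:
    """Greedy left-to-right tokenization with the published pattern.

    Every character must be consumed by some alternative; an unmatched
    character raises with its position.
    """
    if smiles is None or smiles == "":
        raise EmptyInputError("empty SMILES input")
    tokens: list[str] = []
    pos = 0
    while pos < len(smiles):
        m = _TOKEN_RE.match(smiles, pos)
        if m is None:
            raise TokenizationError(smiles, pos)
        tokens.append(m.group(0))
        pos = m.end()
    return TokenSequence(tuple(tokens), smiles)
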