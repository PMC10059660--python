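"""Standardization, mapped-reaction parsing, SOM extraction, tokenizer."""

import numpy as np
import pytest
from rdkit import Chem

import aoxsom as ax
from aoxsom.errors import (
    AtomMapIntegrityError,
    EmptyInputError,
    LabelExtractionError,
    ReactionFormatError,
    SmilesParseError,
    TokenizationError,
)

from conftest import FIXTURE_SMILES, TABLE2_MAPPED_REACTION, TABLE2_REACTANT_SMILES


class TestStandardize:
    def test_pyridine(self, pyridine):
        assert pyridine.atom_count == 6
        aromatic_n = [a for a in pyridine.atoms if a.symbol == "N" and a.is_aromatic]
        assert len(aromatic_n) == 1

    def test_printed_substrate_heavy_atom_count(self):
        std = ax.standardize_molecule(TABLE2_REACTANT_SMILES.replace(" ", ""))
        assert std.atom_count == 11

    def test_salt_stripping_keeps_largest_fragment(self):
        std = ax.standardize_molecule("C1CC1.[Na+].[Cl-]")
        assert std.atom_count == 3
        assert std.canonical_smiles == "C1CC1"
        # dropped atoms map to None, kept ones to valid indices
        assert sorted(v for v in std.index_map.values() if v is not None) == [0, 1, 2]
        assert list(std.index_map.values()).count(None) == 2

    def test_charge_neutralization(self):
        std = ax.standardize_molecule("CC(=O)[O-]")
        assert "-" not in std.canonical_smiles

    @pytest.mark.parametrize("smiles", FIXTURE_SMILES)
    def test_idempotent_canonicalization(self, smiles):
        once = ax.standardize_molecule(smiles)
        twice = ax.standardize_molecule(once.canonical_smiles)
        assert once.canonical_smiles == twice.canonical_smiles
        assert once.atom_count == twice.atom_count
        # re-standardizing the canonical form permutes atoms only within
        # symmetry orbits (graph-equivalent atoms are interchangeable)
        perm = [twice.index_map[i] for i in range(twice.atom_count)]
        assert sorted(perm) == list(range(twice.atom_count))
        orbits = list(Chem.CanonicalRankAtoms(twice.mol, breakTies=False))
        assert all(orbits[i] == orbits[perm[i]] for i in range(twice.atom_count))

    def test_unparseable_smiles_names_input(self):
        with pytest.raises(SmilesParseError, match="not-a-molecule"):
            ax.standardize_molecule("not-a-molecule")

    def test_empty_input(self):
        with pytest.raises(EmptyInputError):
            ax.standardize_molecule("   ")


class TestDeduplicate:
    def test_same_molecule_two_writings(self):
        mols = [ax.standardize_molecule(s) for s in ("c1ccncc1", "n1ccccc1")]
        assert len(ax.deduplicate(mols)) == 1

    def test_distinct_molecules_kept_in_order(self):
        mols = [ax.standardize_molecule(s) for s in ("c1ccncc1", "c1ccccc1")]
        out = ax.deduplicate(mols)
        assert [m.canonical_smiles for m in out] == [m.canonical_smiles for m in mols]

    def test_many_copies_collapse(self):
        mols = [ax.standardize_molecule("c1ccncc1") for _ in range(10)]
        assert len(ax.deduplicate(mols)) == 1


class TestParseMappedReaction:
    def test_printed_mapped_string(self, table2_reaction):
        assert set(table2_reaction.atom_maps_reactant) == set(range(1, 12))
        assert set(table2_reaction.atom_maps_product) == set(range(1, 13))

    def test_unmapped_reaction_has_empty_tables(self):
        rxn = ax.parse_mapped_reaction("C>>C")
        assert rxn.atom_maps_reactant == {} and rxn.atom_maps_product == {}
        assert not rxn.is_mapped

    def test_product_side_unmapped_atom_count(self):
        rxn = ax.parse_mapped_reaction("[CH4:1]>>[CH3:1]O")
        unmapped = [
            a.GetIdx() for a in rxn.product.GetAtoms() if a.GetAtomMapNum() == 0
        ]
        assert len(unmapped) == 1
        assert rxn.product.GetAtomWithIdx(unmapped[0]).GetSymbol() == "O"

    def test_missing_separator_is_format_error(self):
        with pytest.raises(ReactionFormatError):
            ax.parse_mapped_reaction("CCO")
        with pytest.raises(ReactionFormatError):
            ax.parse_mapped_reaction("C>>C>>C")

    def test_duplicate_map_number_is_integrity_error(self):
        with pytest.raises(AtomMapIntegrityError):
            ax.parse_mapped_reaction("[CH3:1][CH3:1]>>CC")


class TestExtractSomLabels:
    def test_printed_reaction_som_is_map_two(self, table2_reaction):
        labels = ax.extract_som_labels(table2_reaction)
        assert labels.som_map_numbers == frozenset({2})
        assert len(labels.som_atom_indices) == 1
        # the labeled atom is an aromatic CH next to a ring nitrogen
        (idx,) = labels.som_atom_indices
        atom = labels.substrate_ref.mol.GetAtomWithIdx(idx)
        assert atom.GetSymbol() == "C" and atom.GetIsAromatic()
        assert any(n.GetSymbol() == "N" for n in atom.GetNeighbors())

    def test_identity_reaction_gives_empty_labels(self):
        rxn = ax.parse_mapped_reaction("[cH:1]1[cH:2][cH:3][n:4][cH:5][cH:6]1>>[cH:1]1[cH:2][cH:3][n:4][cH:5][cH:6]1")
        with pytest.warns(UserWarning, match="no atom changed"):
            labels = ax.extract_som_labels(rxn)
        assert labels.som_atom_indices == frozenset()

    def test_pyridine_to_pyridinone_labels_ortho_carbon(self):
        rxn = ax.parse_mapped_reaction(
            "[cH:1]1[cH:2][cH:3][cH:4][n:5][cH:6]1>>[cH:1]1[cH:2][cH:3][c:4](O)[n:5][cH:6]1"
        )
        labels = ax.extract_som_labels(rxn)
        assert labels.som_map_numbers == frozenset({4})
        (idx,) = labels.som_atom_indices
        atom = labels.substrate_ref.mol.GetAtomWithIdx(idx)
        assert any(n.GetSymbol() == "N" for n in atom.GetNeighbors())

    def test_unmapped_reaction_refused(self):
        rxn = ax.parse_mapped_reaction("C>>C")
        with pytest.raises(LabelExtractionError, match="not atom-mapped"):
            ax.extract_som_labels(rxn)

    def test_label_permutation_invariance(self, synthetic_batch, rng):
        """Atom renumbering of the written SMILES never moves the labels."""
        pairs = synthetic_batch[:5]
        reactions = ax.generate_mapped_reactions(pairs)
        expected = [
            (std, frozenset({som}))
            for std, labels in pairs
            for som in sorted(labels.som_atom_indices)
        ]
        assert len(expected) == len(reactions)
        for rxn, (std, som_set) in zip(reactions, expected):
            for _ in range(20):
                perm = list(rng.permutation(rxn.reactant.GetNumAtoms()))
                perm = [int(p) for p in perm]
                shuffled_r = Chem.MolToSmiles(
                    Chem.RenumberAtoms(rxn.reactant, perm), canonical=False
                )
                relabeled = ax.extract_som_labels(
                    ax.parse_mapped_reaction(f"{shuffled_r}>>{Chem.MolToSmiles(rxn.product)}")
                )
                assert relabeled.substrate_ref.canonical_smiles == std.canonical_smiles
                assert relabeled.som_atom_indices == som_set

    def test_single_site_oxidation_diff_soundness(self, fixture_molecules):
        """For every constructed single-atom oxidation, the diff recovers
        exactly the oxidized atom (oracle: the construction itself)."""
        for std in fixture_molecules:
            orbits = list(Chem.CanonicalRankAtoms(std.mol, breakTies=False))
            ring_ch = [
                a.GetIdx()
                for a in std.mol.GetAtoms()
                if a.GetSymbol() == "C" and a.GetIsAromatic() and a.GetTotalNumHs() == 1
            ]
            for idx in ring_ch:
                pairs = [(std, ax.SomLabelSet(std, frozenset({idx})))]
                (rxn,) = ax.generate_mapped_reactions(pairs)
                labels = ax.extract_som_labels(rxn)
                # exact recovery, up to graph automorphism (e.g. benzene's
                # six equivalent carbons are chemically one site)
                (got,) = labels.som_atom_indices
                assert orbits[got] == orbits[idx]
                if orbits.count(orbits[idx]) == 1:
                    assert got == idx


class TestTokenizer:
    def test_two_letter_halogen_is_single_token(self):
        assert ax.tokenize_smiles("Cl").tokens == ("Cl",)
        assert ax.tokenize_smiles("CCl").tokens == ("C", "Cl")

    def test_percent_ring_closures(self):
        assert ax.tokenize_smiles("C%12CC%12").tokens == ("C", "%12", "C", "C", "%12")

    def test_bracket_atom_single_token(self):
        assert ax.tokenize_smiles("[nH]1cccc1").tokens == ("[nH]", "1", "c", "c", "c", "c", "1")

    @pytest.mark.parametrize("smiles", FIXTURE_SMILES + [TABLE2_MAPPED_REACTION.replace(" ", "")])
    def test_losslessness(self, smiles):
        seq = ax.tokenize_smiles(smiles)
        assert "".join(seq.tokens) == smiles
        assert all(seq.tokens)

    def test_unmatched_character_reports_position(self):
        with pytest.raises(TokenizationError) as err:
            ax.tokenize_smiles("CC{O")
        assert err.value.position == 2
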