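"""Cofactor pruning and mono-substrate decomposition."""

import pytest
from rdkit import Chem

from templex.decomposer import (
    EMPTY_COFACTORS,
    CofactorEntry,
    CofactorList,
    decompose,
    load_cofactor_list,
    prune_cofactors,
)
from templex.errors import DegenerateReactionError
from templex.fixtures import worked_example
from templex.reaction_model import parse_mapped_reaction


def _cof(*smiles_names):
    entries = []
    for name, smi in smiles_names:
        entries.append(
            CofactorEntry(
                name=name,
                smiles=smi,
                canonical=Chem.MolToSmiles(Chem.MolFromSmiles(smi)),
            )
        )
    return CofactorList(entries=entries, scope="biochem")


def test_empty_cofactor_list_is_identity(worked):
    pruned = prune_cofactors(worked, EMPTY_COFACTORS)
    assert pruned is worked
    assert pruned.omitted_cofactors == []


def test_cofactor_removed_from_both_sides_and_disclosed():
    rxn = parse_mapped_reaction(
        "[CH3:1][OH:2].O>>[CH3:1][Cl:3].O", reaction_id="R1"
    )
    pruned = prune_cofactors(rxn, _cof(("water", "O")))
    assert len(pruned.substrates) == 1 and len(pruned.products) == 1
    assert pruned.omitted_cofactors == ["water", "water"]


def test_cofactor_matching_is_whole_molecule_not_substructure():
    rxn = parse_mapped_reaction("[CH3:1][OH:2]>>[CH3:1][Cl:3]")
    pruned = prune_cofactors(rxn, _cof(("water", "O")))
    assert len(pruned.substrates) == 1  # methanol contains O but is kept


def test_pruning_that_empties_a_side_is_degenerate():
    rxn = parse_mapped_reaction("[CH3:1][OH:2].[OH2:4]>>[OH2:2]")
    with pytest.raises(DegenerateReactionError):
        prune_cofactors(rxn, _cof(("water", "O")))


def test_packaged_cofactor_lists_load():
    for scope in ("biochem", "organic"):
        cof = load_cofactor_list(scope)
        assert len(cof.entries) >= 10
        assert len(cof.canonical_set()) > 0


def test_disjoint_products_inherit_separately():
    # A + B -> C + D where C's atoms all map into A and D's into B
    rxn = parse_mapped_reaction(
        "[CH3:1][OH:2].[NH2:3][CH3:4]>>[CH2:1]=[O:2].[NH2:3][CH2:4][OH:5]"
    )
    comps = decompose(rxn, "forward")
    assert len(comps) == 2
    inherited = {
        c.focal_index: [Chem.MolToSmiles(m) for m in c.inherited_products]
        for c in comps
    }
    assert len(inherited[0]) == 1 and len(inherited[1]) == 1
    assert "O" in inherited[0][0] and "N" in inherited[1][0]


def test_single_substrate_single_product():
    rxn = parse_mapped_reaction("[CH3:1][OH:2]>>[CH2:1]=[O:2]")
    comps = decompose(rxn, "forward")
    assert len(comps) == 1
    assert len(comps[0].inherited_products) == 1


def test_spectator_substrate_is_dropped_not_fatal():
    rxn = parse_mapped_reaction("[CH3:1][OH:2].[CH4:3]>>[CH2:1]=[O:2]")
    comps = decompose(rxn, "forward")
    assert len(comps) == 1
    assert comps[0].focal_index == 0


def test_worked_example_forward_components(worked):
    comps = decompose(worked, "forward")
    assert len(comps) == 2
    # phenylalanine's component inherits both phenylpyruvate (skeleton) and
    # glutamate (via the transferred amine nitrogen)
    phe = [c for c in comps if c.focal_index == 1][0]
    assert len(phe.inherited_products) == 2


def test_foreign_map_indices_relabelled_as_unmapped(worked):
    comps = decompose(worked, "forward")
    phe = [c for c in comps if c.focal_index == 1][0]
    focal_maps = {
        a.GetAtomMapNum()
        for a in phe.focal_substrate.GetAtoms()
        if a.GetAtomMapNum() > 0
    }
    for mol in phe.inherited_products:
        for atom in mol.GetAtoms():
            assert atom.GetAtomMapNum() in focal_maps | {0}


def test_reverse_equals_swapped_forward(corpus):
    reactions, _ = corpus
    for rxn in reactions[::4]:
        rev = decompose(rxn, "reverse")
        fwd_of_swapped = decompose(rxn.swapped(), "forward")
        assert len(rev) == len(fwd_of_swapped)
        for a, b in zip(rev, fwd_of_swapped):
            assert a.signature() == b.signature()
            assert a.inheritance_map.keys() == b.inheritance_map.keys()


def test_inherited_atoms_cover_all_mapped_product_atoms(corpus):
    # coverage holds component-by-component; reactions with stoichiometric
    # duplicate substrates collapse duplicate components, so their atoms are
    # covered by the retained representative only
    reactions, _ = corpus
    for rxn in reactions[::4]:
        duplicated = len(
            {Chem.MolToSmiles(_strip(m)) for m in rxn.substrates}
        ) < len(rxn.substrates)
        if duplicated:
            continue
        comps = decompose(rxn, "forward")
        covered = set()
        for comp in comps:
            covered.update(comp.inheritance_map.keys())
        assert covered == set(rxn.atom_map.keys())


def _strip(mol):
    copy = Chem.Mol(mol)
    for a in copy.GetAtoms():
        a.SetAtomMapNum(0)
    return copy


def test_stoichiometric_duplicate_components_collapse(corpus):
    reactions, _ = corpus
    diesters = [
        r for r in reactions if r.reaction_id.startswith("FIX:DIESTER")
    ]
    assert diesters
    for rxn in diesters:
        comps = decompose(rxn, "forward")
        # diacid + two identical ethanol copies -> acid component plus a
        # single collapsed alcohol component
        assert len(comps) == 2


def test_prune_then_decompose_equals_decompose_with_inert_cofactor():
    # unmapped water on both sides: a spectator substrate and an uninherited
    # product; pruning first must agree with decomposing then discarding
    smiles = "[CH3:1][OH:2].O>>[CH2:1]=[O:2].O"
    rxn = parse_mapped_reaction(smiles)
    pruned = prune_cofactors(rxn, _cof(("water", "O")))
    a = [c.signature() for c in decompose(pruned, "forward")]
    b = [
        c.signature()
        for c in decompose(rxn, "forward")
        if Chem.MolToSmiles(c.focal_substrate) != "O"
    ]
    assert a == b
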