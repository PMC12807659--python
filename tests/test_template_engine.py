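"""Centre detection, radius expansion, encoding and round-trip checks."""

import pytest
from rdkit import Chem

from templex.canonical import canonical_template
from templex.decomposer import decompose
from templex.errors import NoChangeError
from templex.fixtures import (
    L_PHENYLALANINE_SMILES,
    PHENYLPYRUVATE_SMILES,
    WORKED_EXAMPLE_PHE_CENTRE,
)
from templex.pattern import parse_template
from templex.reaction_model import parse_mapped_reaction
from templex.template_engine import (
    apply_template,
    encode_smarts,
    expand_environment,
    expected_products,
    extract_all,
    find_reaction_centre,
    round_trip_check,
)

from conftest import phe_templates


def _component(smiles):
    return decompose(parse_mapped_reaction(smiles), "forward")[0]


def test_deprotonation_centre_change_kinds():
    comp = _component("[CH3:1][OH:2]>>[CH3:1][O-:2]")
    centre = find_reaction_centre(comp)
    assert centre.atom_indices == {2}
    assert centre.change_kinds[2] == frozenset({"h_count", "charge"})


def test_identity_reaction_has_no_centre():
    with pytest.raises(NoChangeError):
        find_reaction_centre(_component("[CH4:1]>>[CH4:1]"))


def test_worked_example_phe_centre(worked):
    phe = [c for c in decompose(worked, "forward") if c.focal_index == 1][0]
    centre = find_reaction_centre(phe)
    # alpha carbon and departing amine nitrogen; the arriving keto oxygen is
    # an appearing atom in this component
    assert centre.atom_indices == WORKED_EXAMPLE_PHE_CENTRE
    assert centre.appearing  # keto O + glutamate skeleton


def test_unmapped_leaving_group_swap_detected():
    comp = _component("[CH3:1][CH2:2][OH:3]>>[CH3:1][CH2:2][Cl:4]")
    centre = find_reaction_centre(comp)
    assert centre.atom_indices == {2}
    assert centre.change_kinds[2] == frozenset({"neighbor_set"})


def test_radius_expansion_matches_bfs_oracle():
    comp = _component("[CH3:1][CH2:2][OH:3]>>[CH3:1][CH2:2][Cl:4]")
    centre = find_reaction_centre(comp)
    mol = comp.focal_substrate
    dist = Chem.GetDistanceMatrix(mol)
    seeds = [
        a.GetIdx() for a in mol.GetAtoms() if a.GetAtomMapNum() in {2, 0}
    ]
    for radius in range(4):
        env = expand_environment(comp, centre, radius)
        oracle = {
            i
            for i in range(mol.GetNumAtoms())
            if min(dist[i][s] for s in seeds) <= radius
        }
        assert env.sub_atoms == oracle


def test_radius_saturates_on_full_substrate(worked):
    phe = [c for c in decompose(worked, "forward") if c.focal_index == 1][0]
    centre = find_reaction_centre(phe)
    n = phe.focal_substrate.GetNumAtoms()
    sizes = [
        len(expand_environment(phe, centre, r).sub_atoms) for r in range(11)
    ]
    assert sizes == sorted(sizes)
    assert sizes[-1] == n
    smarts_hi = encode_smarts(phe, expand_environment(phe, centre, 10))
    smarts_lo = encode_smarts(phe, expand_environment(phe, centre, 8))
    assert smarts_hi == smarts_lo  # eccentricity < 8 from the centre


def test_centre_matches_brute_force_oracle(corpus):
    """Independent per-atom environment-diff oracle over every component."""
    reactions, _ = corpus
    for rxn in reactions:
        for direction in ("forward", "reverse"):
            for comp in decompose(rxn, direction):
                oracle = _oracle_centre(comp)
                try:
                    got = find_reaction_centre(comp).atom_indices
                except NoChangeError:
                    got = None
                assert got == oracle, (rxn.reaction_id, direction)


def _oracle_centre(comp):
    """Brute-force: compare literal environment serializations per atom."""

    def env_string(atom):
        incident = []
        for b in atom.GetBonds():
            o = b.GetOtherAtom(atom)
            key = (
                o.GetAtomMapNum()
                if o.GetAtomMapNum() > 0
                else f"?{o.GetSymbol()}"
            )
            incident.append(f"{key}|{b.GetBondTypeAsDouble()}")
        return (
            f"H{atom.GetTotalNumHs()}"
            f"q{atom.GetFormalCharge()}"
            f"[{','.join(sorted(map(str, incident)))}]"
        )

    sub = {
        a.GetAtomMapNum(): env_string(a)
        for a in comp.focal_substrate.GetAtoms()
        if a.GetAtomMapNum() > 0
    }
    prod = {}
    unmapped = any(
        a.GetAtomMapNum() == 0 for a in comp.focal_substrate.GetAtoms()
    )
    for m in comp.inherited_products:
        for a in m.GetAtoms():
            if a.GetAtomMapNum() > 0:
                prod[a.GetAtomMapNum()] = env_string(a)
            else:
                unmapped = True
    centre = {i for i in sub if i in prod and sub[i] != prod[i]}
    if not centre and not unmapped:
        return None
    return centre


def test_encoding_is_invariant_to_map_relabelling(worked):
    import random
    import re

    base_templates, _ = extract_all(worked)
    base = sorted(t.smarts for t in base_templates)
    smiles = worked.to_smiles()
    for trial in range(2):
        rng = random.Random(trial)
        perm = list(range(1, 23))
        rng.shuffle(perm)
        relabel = {i + 1: perm[i] for i in range(22)}
        shuffled = re.sub(
            r":(\d+)\]", lambda m: f":{relabel[int(m.group(1))]}]", smiles
        )
        rxn = parse_mapped_reaction(shuffled, "X", "rhea")
        got = sorted(t.smarts for t in extract_all(rxn)[0])
        assert got == base


def test_encode_decode_encode_is_identity(corpus_extraction):
    templates, _ = corpus_extraction
    for t in templates[::17]:
        sub, prod = parse_template(t.smarts)
        assert canonical_template(sub, prod) == t.smarts


def test_charge_primitive_only_on_charged_pairs(corpus_extraction):
    templates, _ = corpus_extraction
    charged = [t for t in templates if "-1" in t.smarts]
    assert charged  # the substitution family provides hydroxide/chloride
    t = charged[0]
    sub, prod = parse_template(t.smarts)
    for side in (sub, prod):
        for atom in side.atoms:
            if atom.emit_charge and atom.charge == 0:
                # a "+0" primitive appears only on atoms whose partner is
                # charged on the other side
                partners = [
                    a
                    for g in (sub, prod)
                    for a in g.atoms
                    if a.map_num == atom.map_num and atom.map_num
                ]
                assert any(p.charge != 0 for p in partners)


def test_neutral_template_has_no_charge_primitives(worked_templates):
    templates, _ = worked_templates
    for t in templates:
        assert "+0" not in t.smarts and "-1" not in t.smarts


def test_round_trip_worked_example_regenerates_phenylpyruvate(worked_templates):
    by_radius = phe_templates(worked_templates)
    target = Chem.MolFromSmiles(L_PHENYLALANINE_SMILES)
    expected = Chem.MolToSmiles(Chem.MolFromSmiles(PHENYLPYRUVATE_SMILES))
    for radius in (0, 1):
        outcomes = apply_template(by_radius[radius].smarts, target)
        assert any(expected in prods for prods in outcomes)


def test_template_does_not_match_foreign_molecule(worked_templates):
    by_radius = phe_templates(worked_templates)
    cyclohexane = Chem.MolFromSmiles("C1CCCCC1")
    assert apply_template(by_radius[0].smarts, cyclohexane) == []
    ok, reason = round_trip_check(
        by_radius[0].smarts,
        _component("[CH3:1][OH:2]>>[CH2:1]=[O:2]"),
    )
    assert not ok


def test_relaxed_hydrogen_matching_is_a_superset(worked_templates):
    by_radius = phe_templates(worked_templates)
    # N-methyl phenylalanine: exact H counts reject it, relaxed mode matches
    target = Chem.MolFromSmiles("CNC(Cc1ccccc1)C(O)=O")
    strict = apply_template(by_radius[0].smarts, target)
    relaxed = apply_template(by_radius[0].smarts, target, relax_h=True)
    assert strict == []
    assert relaxed


def test_extract_all_counts_and_determinism(worked):
    templates, diagnostics = extract_all(worked)
    # 2 substrates x 2 directions x 11 radii, all passing round trip
    assert len(templates) == 44
    assert not diagnostics
    order = [(t.direction, t.component.focal_index, t.radius) for t in templates]
    assert order == sorted(
        order, key=lambda x: (x[0] != "forward", x[1], x[2])
    )
    again, _ = extract_all(worked)
    assert [t.smarts for t in again] == [t.smarts for t in templates]


def test_identity_reaction_yields_zero_templates_one_diagnostic():
    rxn = parse_mapped_reaction("[CH4:1]>>[CH4:1]", "ID", "user")
    templates, diagnostics = extract_all(rxn)
    assert templates == []
    assert len(diagnostics) == 2  # one per direction
    assert {d.category for d in diagnostics} == {"no-change"}


def test_all_emitted_templates_regenerate_their_products(corpus_extraction):
    templates, _ = corpus_extraction
    for t in templates[::13]:
        ok, reason = round_trip_check(t.smarts, t.component)
        assert ok, reason


def test_expected_products_match_ground_truth(corpus):
    reactions, ground_truth = corpus
    for rxn in reactions[::3]:
        gt = ground_truth[rxn.reaction_id]
        for comp in decompose(rxn, "forward"):
            assert (
                expected_products(comp)
                == gt["forward_products"][str(comp.focal_index)]
            )
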