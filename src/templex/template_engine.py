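"""Reaction-centre detection, radius expansion, SMARTS encoding, round-trip.

The reaction centre of a mono-substrate component is the set of atoms whose
local environment changes between the two sides under the atom map: incident
bond orders, mapped-neighbor sets, implicit hydrogen counts, formal charges,
or appearance/disappearance across sides.  Environments are expanded by
topological bond distance (shortest path) from the nearest centre atom;
radius 0 keeps the centre atoms only.  Unmapped (disappearing) substrate
atoms and unmapped (appearing) product atoms are included at every radius
with full primitives -- this is what lets mass-imbalanced reactions with a
coherent centre yield templates whose round-trip application still
regenerates the expected products.

Every emitted template must pass the round-trip check: applied back to its
source substrate, one generated outcome must equal the inherited products.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import AllChem, rdChemReactions

from .canonical import canonical_template
from .decomposer import (
    FORWARD,
    REVERSE,
    CofactorList,
    EMPTY_COFACTORS,
    MonoComponent,
    decompose,
    prune_cofactors,
)
from .errors import NoChangeError, TemplexError
from .pattern import AROMATIC, DOUBLE, SINGLE, TRIPLE, PatternAtom, SideGraph
from .reaction_model import MappedReaction

logger = logging.getLogger(__name__)

MAX_RADIUS = 10

_BOND_CODE = {
    Chem.BondType.SINGLE: SINGLE,
    Chem.BondType.DOUBLE: DOUBLE,
    Chem.BondType.TRIPLE: TRIPLE,
    Chem.BondType.AROMATIC: AROMATIC,
}


@dataclass
class ReactionCentre:
    """Atoms whose environment changes, plus appearing/disappearing atoms."""

    atom_indices: set[int]  # map indices of changed mapped atoms
    change_kinds: dict[int, frozenset[str]]
    disappearing: list[int] = field(default_factory=list)  # focal atom idxs
    appearing: list[tuple[int, int]] = field(default_factory=list)  # (mol, atom)

    def is_empty(self) -> bool:
        return not (self.atom_indices or self.disappearing or self.appearing)


@dataclass
class EnvironmentPair:
    """Substrate/product subgraph selection at a given radius."""

    sub_atoms: set[int]  # focal atom indices
    prod_atoms: dict[int, set[int]]  # product mol index -> atom indices
    radius: int


@dataclass
class Template:
    smarts: str
    radius: int
    direction: str
    component: MonoComponent
    valid: bool = True


@dataclass
class Diagnostic:
    reaction_id: str
    direction: str
    focal_index: int | None
    radius: int | None
    category: str
    message: str

    def as_row(self) -> list[str]:
        return [
            self.reaction_id,
            self.direction,
            "" if self.focal_index is None else str(self.focal_index),
            "" if self.radius is None else str(self.radius),
            self.category,
            self.message,
        ]


DIAGNOSTIC_COLUMNS = [
    "reaction_id",
    "direction",
    "focal_index",
    "radius",
    "category",
    "message",
]


def _mapped_atoms(mol: Chem.Mol) -> dict[int, Chem.Atom]:
    return {
        a.GetAtomMapNum(): a for a in mol.GetAtoms() if a.GetAtomMapNum() > 0
    }


def find_reaction_centre(comp: MonoComponent) -> ReactionCentre:
    """Per-atom environment diff under the map; deterministic.

    Raises :class:`NoChangeError` for an identity transformation.
    """
    focal = _mapped_atoms(comp.focal_substrate)
    prod: dict[int, Chem.Atom] = {}
    for mol in comp.inherited_products:
        prod.update(_mapped_atoms(mol))

    def nbr_profile(atom: Chem.Atom):
        mapped = set()
        unmapped = []  # (element, bond order) profile of unmapped neighbors
        orders = {}
        for bond in atom.GetBonds():
            other = bond.GetOtherAtom(atom)
            idx = other.GetAtomMapNum()
            if idx > 0:
                mapped.add(idx)
                orders[idx] = bond.GetBondType()
            else:
                unmapped.append((other.GetAtomicNum(), str(bond.GetBondType())))
        return mapped, sorted(unmapped), orders

    change_kinds: dict[int, set[str]] = {}
    for idx, a in focal.items():
        b = prod.get(idx)
        if b is None:
            continue  # cannot happen after decomposition, defensive
        kinds: set[str] = set()
        if a.GetTotalNumHs() != b.GetTotalNumHs():
            kinds.add("h_count")
        if a.GetFormalCharge() != b.GetFormalCharge():
            kinds.add("charge")
        a_mapped, a_unmapped, a_orders = nbr_profile(a)
        b_mapped, b_unmapped, b_orders = nbr_profile(b)
        if a_mapped != b_mapped or a_unmapped != b_unmapped:
            kinds.add("neighbor_set")
        for shared in a_mapped & b_mapped:
            if a_orders[shared] != b_orders[shared]:
                kinds.add("bond_order")
        if kinds:
            change_kinds[idx] = kinds

    disappearing = [
        a.GetIdx()
        for a in comp.focal_substrate.GetAtoms()
        if a.GetAtomMapNum() == 0
    ]
    appearing = [
        (mi, a.GetIdx())
        for mi, mol in enumerate(comp.inherited_products)
        for a in mol.GetAtoms()
        if a.GetAtomMapNum() == 0
    ]
    centre = ReactionCentre(
        atom_indices=set(change_kinds),
        change_kinds={k: frozenset(v) for k, v in change_kinds.items()},
        disappearing=disappearing,
        appearing=appearing,
    )
    if centre.is_empty():
        raise NoChangeError(
            f"{comp.parent_reaction_id!r}: identity transformation "
            f"(empty reaction centre)"
        )
    return centre


def expand_environment(
    comp: MonoComponent, centre: ReactionCentre, radius: int
) -> EnvironmentPair:
    """Atoms within ``radius`` bonds of any centre atom (plus all unmapped
    atoms, which are centre members by definition)."""
    if not (0 <= radius <= MAX_RADIUS):
        raise ValueError(f"radius must be in [0, {MAX_RADIUS}], got {radius}")
    focal = comp.focal_substrate
    focal_by_map = _mapped_atoms(focal)
    seeds = {focal_by_map[i].GetIdx() for i in centre.atom_indices}
    seeds.update(centre.disappearing)

    selected = set(seeds)
    frontier = set(seeds)
    for _ in range(radius):
        nxt = set()
        for i in frontier:
            for nbr in focal.GetAtomWithIdx(i).GetNeighbors():
                j = nbr.GetIdx()
                if j not in selected:
                    nxt.add(j)
        selected |= nxt
        frontier = nxt
        if not frontier:
            break

    selected_maps = {
        focal.GetAtomWithIdx(i).GetAtomMapNum()
        for i in selected
        if focal.GetAtomWithIdx(i).GetAtomMapNum() > 0
    }
    prod_atoms: dict[int, set[int]] = {}
    for mi, mol in enumerate(comp.inherited_products):
        chosen = {
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetAtomMapNum() in selected_maps or a.GetAtomMapNum() == 0
        }
        if chosen:
            prod_atoms[mi] = chosen
    return EnvironmentPair(sub_atoms=selected, prod_atoms=prod_atoms, radius=radius)


def _charged_pairs(comp: MonoComponent) -> set[int]:
    """Map indices charged on either side (these emit a charge primitive)."""
    focal = _mapped_atoms(comp.focal_substrate)
    out = set()
    for mol in comp.inherited_products:
        for atom in mol.GetAtoms():
            idx = atom.GetAtomMapNum()
            if idx > 0 and (
                atom.GetFormalCharge() != 0
                or focal[idx].GetFormalCharge() != 0
            ):
                out.add(idx)
    return out


def _side_graph(
    mol: Chem.Mol, atoms: set[int], charged_maps: set[int]
) -> tuple[SideGraph, dict[int, int]]:
    """Build a SideGraph for one molecule's selected atoms.

    Returns the graph and the molecule-atom-index -> pattern-index lookup.
    """
    graph = SideGraph()
    lookup: dict[int, int] = {}
    for i in sorted(atoms):
        atom = mol.GetAtomWithIdx(i)
        mapped = atom.GetAtomMapNum()
        emit_charge = (
            mapped in charged_maps
            if mapped > 0
            else atom.GetFormalCharge() != 0
        )
        lookup[i] = len(graph.atoms)
        graph.atoms.append(
            PatternAtom(
                atomic_num=atom.GetAtomicNum(),
                aromatic=atom.GetIsAromatic(),
                h_count=atom.GetTotalNumHs(),
                charge=atom.GetFormalCharge(),
                map_num=mapped,
                emit_charge=emit_charge,
                source=i,
            )
        )
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in atoms and j in atoms:
            code = _BOND_CODE.get(bond.GetBondType())
            if code is None:
                raise TemplexError(
                    f"unsupported bond order {bond.GetBondType()} in template"
                )
            graph.add_bond(lookup[i], lookup[j], code)
    return graph, lookup


def encode_smarts(comp: MonoComponent, env: EnvironmentPair) -> str:
    """Encode an environment pair as a canonical minimal-primitive SMARTS."""
    charged = _charged_pairs(comp)
    sub_graph, _ = _side_graph(comp.focal_substrate, env.sub_atoms, charged)
    sub_graph.groups = [set(range(len(sub_graph.atoms)))]

    prod_graph = SideGraph()
    for mi in sorted(env.prod_atoms):
        part, lookup = _side_graph(
            comp.inherited_products[mi], env.prod_atoms[mi], charged
        )
        offset = len(prod_graph.atoms)
        prod_graph.atoms.extend(part.atoms)
        for (a, b), order in part.bonds.items():
            prod_graph.bonds[(a + offset, b + offset)] = order
        prod_graph.groups.append({k + offset for k in lookup.values()})
    return canonical_template(sub_graph, prod_graph)


def _clear_maps(mol: Chem.Mol) -> Chem.Mol:
    copy = Chem.Mol(mol)
    for atom in copy.GetAtoms():
        atom.SetAtomMapNum(0)
    return copy


def expected_products(comp: MonoComponent) -> list[str]:
    """Sorted map-free canonical SMILES of the inherited products."""
    return sorted(Chem.MolToSmiles(_clear_maps(m)) for m in comp.inherited_products)


def round_trip_check(
    smarts: str, comp: MonoComponent
) -> tuple[bool, str]:
    """Apply a template back to its source substrate.

    True iff one generated outcome's canonical product structures equal the
    canonical structures of the component's inherited products.
    """
    try:
        rxn = AllChem.ReactionFromSmarts(smarts)
    except Exception as exc:  # noqa: BLE001 - RDKit raises bare exceptions
        return False, f"template does not parse as a reaction: {exc}"
    if rxn is None:
        return False, "template does not parse as a reaction"
    source = _clear_maps(comp.focal_substrate)
    expected = expected_products(comp)
    try:
        outcomes = rxn.RunReactants((source,))
    except Exception as exc:  # noqa: BLE001
        return False, f"application failed: {exc}"
    if not outcomes:
        return False, "substrate pattern does not match the source substrate"
    for prods in outcomes:
        smis = []
        ok = True
        for p in prods:
            try:
                Chem.SanitizeMol(p)
            except Exception:  # noqa: BLE001
                ok = False
                break
            smis.append(Chem.MolToSmiles(p))
        if ok and sorted(smis) == expected:
            return True, ""
    return False, "no outcome regenerates the expected products"


def apply_template(
    smarts: str, target: Chem.Mol, relax_h: bool = False
) -> list[list[str]]:
    """One-step application of a template to a target structure.

    Returns one list of canonical product SMILES per distinct outcome.  With
    ``relax_h`` the hydrogen-count primitives of the substrate pattern are
    dropped before matching (lower-bound-free matching), a deliberately
    non-default mode.
    """
    if relax_h:
        import re

        sub, prod = smarts.split(">>")
        sub = re.sub(r";H\d+", "", sub)
        # mapped product atoms inherit hydrogens from the matched substrate;
        # unmapped (appearing) atoms keep their stated counts
        prod = re.sub(r";H\d+(?=(?:;[+-]\d+)?:\d+\])", "", prod)
        smarts = sub + ">>" + prod
    rxn = rdChemReactions.ReactionFromSmarts(smarts)
    seen = set()
    out = []
    for prods in rxn.RunReactants((target,)):
        smis = []
        ok = True
        for p in prods:
            try:
                Chem.SanitizeMol(p)
            except Exception:  # noqa: BLE001
                ok = False
                break
            smis.append(Chem.MolToSmiles(p))
        if ok:
            key = tuple(sorted(smis))
            if key not in seen:
                seen.add(key)
                out.append(sorted(smis))
    return out


def extract_component(
    comp: MonoComponent, radii: range
) -> tuple[list[Template], list[Diagnostic]]:
    templates: list[Template] = []
    diagnostics: list[Diagnostic] = []
    try:
        centre = find_reaction_centre(comp)
    except NoChangeError as exc:
        diagnostics.append(
            Diagnostic(
                comp.parent_reaction_id,
                comp.direction,
                comp.focal_index,
                None,
                "no-change",
                str(exc),
            )
        )
        return templates, diagnostics
    for radius in radii:
        env = expand_environment(comp, centre, radius)
        smarts = encode_smarts(comp, env)
        ok, reason = round_trip_check(smarts, comp)
        if ok:
            templates.append(
                Template(
                    smarts=smarts,
                    radius=radius,
                    direction=comp.direction,
                    component=comp,
                )
            )
        else:
            diagnostics.append(
                Diagnostic(
                    comp.parent_reaction_id,
                    comp.direction,
                    comp.focal_index,
                    radius,
                    "round-trip",
                    reason,
                )
            )
    return templates, diagnostics


def extract_all(
    rxn: MappedReaction,
    cof: CofactorList = EMPTY_COFACTORS,
    radii: range = range(0, MAX_RADIUS + 1),
    directions: tuple[str, ...] = (FORWARD, REVERSE),
) -> tuple[list[Template], list[Diagnostic]]:
    """Full per-reaction chain: prune, decompose both ways, extract, check.

    Output order is deterministic: (direction, component index, radius).
    Per-component failures become diagnostics; they never abort the batch.
    """
    templates: list[Template] = []
    diagnostics: list[Diagnostic] = []
    try:
        pruned = prune_cofactors(rxn, cof)
    except TemplexError as exc:
        diagnostics.append(
            Diagnostic(rxn.reaction_id, "", None, None, exc.category, str(exc))
        )
        return templates, diagnostics
    for direction in directions:
        try:
            components = decompose(pruned, direction)
        except TemplexError as exc:
            diagnostics.append(
                Diagnostic(
                    rxn.reaction_id, direction, None, None, exc.category, str(exc)
                )
            )
            continue
        for comp in components:
            t, d = extract_component(comp, radii)
            templates.extend(t)
            diagnostics.extend(d)
    return templates, diagnostics
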