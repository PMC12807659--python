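"""Cofactor pruning and mono-substrate decomposition.

A multi-substrate reaction is split into mono-substrate components: each
component pairs one focal substrate with the products that inherit at least
one of its mapped atoms.  Product atoms mapped to *other* substrates are
re-labelled as unmapped context, so every emitted component -- and therefore
every template -- is strictly mono-substrate.  Cofactors are removed before
decomposition by whole-molecule canonical-structure equality against a
curated list; removed names are recorded so catalog records can disclose
them.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from rdkit import Chem

from .errors import DecompositionEmptyError, DegenerateReactionError, ParseError
from .reaction_model import MappedReaction

logger = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"


@dataclass
class CofactorEntry:
    name: str
    smiles: str
    canonical: str  # map-free canonical SMILES, the membership key


@dataclass
class CofactorList:
    entries: list[CofactorEntry]
    scope: str  # "biochem" or "organic"

    def canonical_set(self) -> dict[str, str]:
        return {e.canonical: e.name for e in self.entries}


EMPTY_COFACTORS = CofactorList(entries=[], scope="biochem")


def _canonical_structure(mol: Chem.Mol) -> str:
    """Map-free canonical SMILES: the identity used for cofactor matching."""
    copy = Chem.Mol(mol)
    for atom in copy.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(copy)


def load_cofactor_list(source: str | Path) -> CofactorList:
    """Load a cofactor TSV (columns name, smiles, scope).

    ``source`` is either the name of a packaged list (``"biochem"`` or
    ``"organic"``) or a path to a user-supplied file in the same format.
    """
    if source in ("biochem", "organic"):
        ref = resources.files("templex.data") / f"cofactors_{source}.tsv"
        text = ref.read_text(encoding="utf-8")
        rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    else:
        with open(source, encoding="utf-8", newline="") as handle:
            rows = list(csv.DictReader(handle, delimiter="\t"))
    entries = []
    scope = "biochem"
    for row in rows:
        mol = Chem.MolFromSmiles(row["smiles"])
        if mol is None:
            raise ParseError(f"cofactor {row['name']!r}: unparsable SMILES")
        entries.append(
            CofactorEntry(
                name=row["name"],
                smiles=row["smiles"],
                canonical=_canonical_structure(mol),
            )
        )
        scope = row.get("scope", scope) or scope
    return CofactorList(entries=entries, scope=scope)


def prune_cofactors(rxn: MappedReaction, cof: CofactorList) -> MappedReaction:
    """Remove whole molecules matching the cofactor list, on both sides.

    Matching is exact canonical-structure equality, never substructure.
    Raises :class:`DegenerateReactionError` if a side is emptied.
    """
    lookup = cof.canonical_set()
    omitted: list[str] = []

    def keep(mols: list[Chem.Mol]) -> list[Chem.Mol]:
        kept = []
        for mol in mols:
            name = lookup.get(_canonical_structure(mol))
            if name is None:
                kept.append(mol)
            else:
                omitted.append(name)
        return kept

    substrates = keep(rxn.substrates)
    products = keep(rxn.products)
    if not omitted:
        return rxn
    if not substrates or not products:
        raise DegenerateReactionError(
            f"{rxn.reaction_id!r}: cofactor pruning emptied one side "
            f"(omitted: {omitted})"
        )
    out = MappedReaction(
        reaction_id=rxn.reaction_id,
        dataset=rxn.dataset,
        substrates=substrates,
        products=products,
        ec_numbers=list(rxn.ec_numbers),
        spontaneous=rxn.spontaneous,
        sequence_cluster_count=rxn.sequence_cluster_count,
        omitted_cofactors=list(rxn.omitted_cofactors) + omitted,
    )
    return out


@dataclass
class MonoComponent:
    """One focal substrate plus the products inheriting its atoms."""

    focal_substrate: Chem.Mol
    inherited_products: list[Chem.Mol]
    direction: str
    parent: MappedReaction
    focal_index: int
    omitted_cofactors: list[str] = field(default_factory=list)

    @property
    def parent_reaction_id(self) -> str:
        return self.parent.reaction_id

    @property
    def inheritance_map(self) -> dict[int, tuple[int, tuple[int, int]]]:
        """map index -> (focal atom idx, (product mol idx, atom idx))."""
        focal = {
            a.GetAtomMapNum(): a.GetIdx()
            for a in self.focal_substrate.GetAtoms()
            if a.GetAtomMapNum() > 0
        }
        out = {}
        for pi, mol in enumerate(self.inherited_products):
            for atom in mol.GetAtoms():
                idx = atom.GetAtomMapNum()
                if idx in focal:
                    out[idx] = (focal[idx], (pi, atom.GetIdx()))
        return out

    def signature(self) -> tuple:
        """Map-free structural key used to collapse exact duplicates."""
        return (
            _canonical_structure(self.focal_substrate),
            tuple(
                sorted(
                    _canonical_structure(m) for m in self.inherited_products
                )
            ),
        )


def decompose(rxn: MappedReaction, direction: str = FORWARD) -> list[MonoComponent]:
    """Split a pruned reaction into mono-substrate components.

    A product is inherited by a focal substrate iff it contains at least one
    mapped atom whose partner lies in that substrate; products with no mapped
    atoms are never inherited; focal substrates contributing no mapped atom
    to any product are dropped as spectators (with a logged notice).
    """
    if direction == REVERSE:
        rxn = rxn.swapped()
    elif direction != FORWARD:
        raise ValueError(f"direction must be forward or reverse, got {direction!r}")
    if not rxn.substrates or not rxn.products:
        raise DecompositionEmptyError(
            f"{rxn.reaction_id!r}: cannot decompose with an empty side"
        )

    atom_map = rxn.atom_map
    components: list[MonoComponent] = []
    seen_signatures: set[tuple] = set()
    for si, focal in enumerate(rxn.substrates):
        focal_indices = {
            a.GetAtomMapNum()
            for a in focal.GetAtoms()
            if a.GetAtomMapNum() in atom_map
        }
        inherited: list[Chem.Mol] = []
        for prod in rxn.products:
            prod_indices = {
                a.GetAtomMapNum()
                for a in prod.GetAtoms()
                if a.GetAtomMapNum() in atom_map
            }
            if prod_indices & focal_indices:
                # re-label atoms mapped to non-focal substrates (or one-sided
                # indices) as unmapped context
                copy = Chem.Mol(prod)
                for atom in copy.GetAtoms():
                    if atom.GetAtomMapNum() not in focal_indices:
                        atom.SetAtomMapNum(0)
                inherited.append(copy)
        if not inherited:
            logger.info(
                "%s: substrate %d is a spectator (no atoms inherited), dropped",
                rxn.reaction_id,
                si,
            )
            continue
        focal_copy = Chem.Mol(focal)
        for atom in focal_copy.GetAtoms():
            if atom.GetAtomMapNum() not in focal_indices:
                atom.SetAtomMapNum(0)
        comp = MonoComponent(
            focal_substrate=focal_copy,
            inherited_products=inherited,
            direction=direction,
            parent=rxn,
            focal_index=si,
            omitted_cofactors=list(rxn.omitted_cofactors),
        )
        sig = comp.signature()
        if sig in seen_signatures:
            logger.info(
                "%s: collapsing duplicate component for substrate %d",
                rxn.reaction_id,
                si,
            )
            continue
        seen_signatures.add(sig)
        components.append(comp)
    if not components:
        raise DecompositionEmptyError(
            f"{rxn.reaction_id!r}: no mono-substrate component survives"
        )
    return components
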