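"""Parsing, normalization and validation of atom-mapped reaction SMILES.

A reaction record arrives as ``substrates>>products`` SMILES with atom-map
indices.  Parsing produces a :class:`MappedReaction`: heavy-atom molecular
graphs (explicit hydrogens are folded into per-atom counts), stripped of all
stereochemistry, with aromaticity perceived once by the default RDKit model
and frozen thereafter.  The same model is used when templates are applied, so
patterns and probe molecules always agree on aromaticity.

Map index 0 and an absent map attribute both mean "unmapped".  Indices that
occur on only one side are retained on the atoms but excluded from the
substrate/product bijection; such atoms count as unmapped, which is how
mass-imbalanced records (missing water, lumped cofactors...) flow through the
pipeline without artificial rebalancing.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from rdkit import Chem

from .errors import InvalidAnnotationError, MappingError, ParseError

logger = logging.getLogger(__name__)

DATASETS = ("mnx", "rhea", "uspto", "user")

#: datasets that count as biochemical for catalog domain tagging
BIOCHEMICAL_DATASETS = frozenset({"mnx", "rhea"})

AtomRef = tuple[int, int]  # (molecule index within its side, atom index)


@dataclass
class MappingReport:
    """Pure report on mapping completeness of a reaction."""

    n_substrate_atoms_unmapped: int
    n_product_atoms_unmapped: int
    is_balanced: bool
    duplicate_indices: list[int] = field(default_factory=list)


@dataclass
class MappedReaction:
    """A normalized, atom-mapped reaction."""

    reaction_id: str
    dataset: str
    substrates: list[Chem.Mol]
    products: list[Chem.Mol]
    ec_numbers: list[str] = field(default_factory=list)
    spontaneous: bool = False
    sequence_cluster_count: int | None = None
    omitted_cofactors: list[str] = field(default_factory=list)

    @property
    def atom_map(self) -> dict[int, tuple[AtomRef, AtomRef]]:
        """Bijection map-index -> (substrate atom, product atom).

        Only indices present on both sides participate; one-sided indices
        are treated as unmapped.
        """
        subs = _index_side(self.substrates)
        prods = _index_side(self.products)
        return {
            idx: (subs[idx], prods[idx]) for idx in subs.keys() & prods.keys()
        }

    def to_smiles(self) -> str:
        return (
            ".".join(Chem.MolToSmiles(m) for m in self.substrates)
            + ">>"
            + ".".join(Chem.MolToSmiles(m) for m in self.products)
        )

    def swapped(self) -> "MappedReaction":
        """The same reaction written in the opposite direction."""
        return replace(
            self, substrates=list(self.products), products=list(self.substrates)
        )


def _index_side(mols: list[Chem.Mol]) -> dict[int, AtomRef]:
    out: dict[int, AtomRef] = {}
    for mi, mol in enumerate(mols):
        for atom in mol.GetAtoms():
            idx = atom.GetAtomMapNum()
            if idx > 0:
                out[idx] = (mi, atom.GetIdx())
    return out


def _side_duplicates(mols: list[Chem.Mol]) -> list[int]:
    seen: set[int] = set()
    dups: set[int] = set()
    for mol in mols:
        for atom in mol.GetAtoms():
            idx = atom.GetAtomMapNum()
            if idx > 0:
                if idx in seen:
                    dups.add(idx)
                seen.add(idx)
    return sorted(dups)


def normalize_molecule(mol: Chem.Mol) -> Chem.Mol:
    """Strip stereochemistry and fold explicit hydrogens into counts.

    Removes tetrahedral tags, double-bond geometry and enhanced stereo
    groups; nothing else about the graph is altered.  Idempotent.
    """
    mol = Chem.Mol(mol)
    # clears tetrahedral tags, double-bond geometry and enhanced stereo groups
    Chem.RemoveStereochemistry(mol)
    for bond in mol.GetBonds():
        bond.SetBondDir(Chem.BondDir.NONE)
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            atom.SetAtomMapNum(0)
    mol = Chem.RemoveHs(mol)
    return mol


def _parse_side(text: str) -> list[Chem.Mol]:
    text = text.strip()
    if not text:
        return []
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        # find the offending fragment for the error message
        for frag in text.split("."):
            if frag and Chem.MolFromSmiles(frag) is None:
                raise ParseError(f"unparsable SMILES fragment: {frag!r}")
        raise ParseError(f"unparsable SMILES: {text!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    return [normalize_molecule(f) for f in frags]


def parse_mapped_reaction(
    smiles: str,
    reaction_id: str = "",
    dataset: str = "user",
    ec_numbers: list[str] | None = None,
    spontaneous: bool = False,
    sequence_cluster_count: int | None = None,
) -> MappedReaction:
    """Parse and normalize one mapped reaction SMILES record."""
    if smiles.count(">>") != 1:
        raise ParseError(
            f"{reaction_id or smiles!r}: expected exactly one '>>' separator"
        )
    if dataset not in DATASETS:
        raise InvalidAnnotationError(f"unknown dataset label {dataset!r}")
    if sequence_cluster_count is not None and sequence_cluster_count < 1:
        raise InvalidAnnotationError(
            "sequence_cluster_count must be a positive integer"
        )
    left, right = smiles.split(">>")
    substrates = _parse_side(left)
    products = _parse_side(right)

    for side_name, mols in (("substrate", substrates), ("product", products)):
        dups = _side_duplicates(mols)
        if dups:
            raise MappingError(
                f"{reaction_id or smiles!r}: duplicate map indices on "
                f"{side_name} side: {dups}"
            )
    subs = _index_side(substrates)
    prods = _index_side(products)
    mismatched = []
    for idx in subs.keys() & prods.keys():
        si, ai = subs[idx]
        pi, aj = prods[idx]
        if (
            substrates[si].GetAtomWithIdx(ai).GetAtomicNum()
            != products[pi].GetAtomWithIdx(aj).GetAtomicNum()
        ):
            mismatched.append(idx)
    if mismatched:
        raise MappingError(
            f"{reaction_id or smiles!r}: element mismatch across sides for "
            f"map indices {sorted(mismatched)}"
        )
    return MappedReaction(
        reaction_id=reaction_id,
        dataset=dataset,
        substrates=substrates,
        products=products,
        ec_numbers=list(ec_numbers or []),
        spontaneous=spontaneous,
        sequence_cluster_count=sequence_cluster_count,
    )


def validate_mapping(rxn: MappedReaction) -> MappingReport:
    """Count unmapped heavy atoms per side; a balanced reaction has none.

    An atom is unmapped when it carries no (positive) map index or when its
    index has no partner on the other side.
    """
    subs = _index_side(rxn.substrates)
    prods = _index_side(rxn.products)
    shared = subs.keys() & prods.keys()

    def count_unmapped(mols: list[Chem.Mol]) -> int:
        n = 0
        for mol in mols:
            for atom in mol.GetAtoms():
                if atom.GetAtomMapNum() not in shared:
                    n += 1
        return n

    n_sub = count_unmapped(rxn.substrates)
    n_prod = count_unmapped(rxn.products)
    return MappingReport(
        n_substrate_atoms_unmapped=n_sub,
        n_product_atoms_unmapped=n_prod,
        is_balanced=(n_sub == 0 and n_prod == 0 and bool(shared)),
    )


def parse_with_mapper(
    smiles: str,
    mapper,
    **annotations,
) -> MappedReaction:
    """Map an unmapped reaction SMILES with a pluggable mapper, then parse.

    ``mapper`` is any callable taking an unmapped reaction SMILES and
    returning a mapped one; the engine never depends on a specific mapper.
    """
    return parse_mapped_reaction(mapper(smiles), **annotations)


# ---------------------------------------------------------------------------
# batch I/O

BATCH_COLUMNS = [
    "reaction_id",
    "dataset",
    "mapped_rxn_smiles",
    "ec_numbers",
    "spontaneous",
    "sequence_cluster_count",
]


def read_batch(path: str | Path | io.TextIOBase) -> list[MappedReaction]:
    """Read the batch TSV format (header required, UTF-8)."""
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path, encoding="utf-8", newline="")
        close = True
    else:
        handle = path
    try:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(BATCH_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ParseError(f"batch TSV missing columns: {sorted(missing)}")
        out = []
        for row in reader:
            ec = [e for e in (row["ec_numbers"] or "").split(";") if e]
            count = row["sequence_cluster_count"].strip()
            out.append(
                parse_mapped_reaction(
                    row["mapped_rxn_smiles"],
                    reaction_id=row["reaction_id"],
                    dataset=row["dataset"],
                    ec_numbers=ec,
                    spontaneous=row["spontaneous"].strip() == "1",
                    sequence_cluster_count=int(count) if count else None,
                )
            )
        return out
    finally:
        if close:
            handle.close()


def write_batch(records: list[dict], path: str | Path) -> None:
    """Write raw batch rows (dicts keyed by BATCH_COLUMNS) as TSV."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.DictWriter(
            handle, fieldnames=BATCH_COLUMNS, delimiter="\t", lineterminator="\n"
        )
        writer.writeheader()
        for rec in records:
            writer.writerow(rec)
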