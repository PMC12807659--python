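"""In-memory representation of one side of a SMARTS template.

Templates are written in a deliberately minimal SMARTS dialect: every atom is
a bracket atom carrying exactly the primitives element symbol (lower-case when
aromatic), atomic number, total hydrogen count, and -- only when the atom is
charged on either side of the transformation -- a formal charge; bonds are
always written explicitly (``-``, ``=``, ``#``, ``:``).  Because the grammar
is closed, the dialect can be parsed back without a full SMARTS engine, which
is what :func:`parse_side` does.

Connected fragments that belong to the same molecule are kept together in a
*group* (rendered with SMARTS component parentheses ``(frag.frag)``) so that
reaction application produces one product molecule per source molecule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ParseError

#: bond order codes used throughout (aromatic gets its own code)
SINGLE, DOUBLE, TRIPLE, AROMATIC = 1, 2, 3, 4

BOND_TOKEN = {SINGLE: "-", DOUBLE: "=", TRIPLE: "#", AROMATIC: ":"}
TOKEN_BOND = {v: k for k, v in BOND_TOKEN.items()}

_ATOM_RE = re.compile(
    r"\[([A-Za-z][a-z]?|\*)"  # element symbol (case carries aromaticity)
    r";#(\d+)"                # atomic number
    r";H(\d+)"                # total hydrogen count
    r"(?:;([+-]\d+))?"        # optional formal charge
    r"(?::(\d+))?\]"          # optional atom map
)


@dataclass
class PatternAtom:
    """One query atom of a template side."""

    atomic_num: int
    aromatic: bool
    h_count: int
    charge: int
    map_num: int = 0
    emit_charge: bool = False
    #: membership of the reaction centre; feeds canonical ranking only
    is_centre: bool = False
    #: opaque link back to the source graph atom (set by the extractor)
    source: object = None

    @property
    def symbol(self) -> str:
        from rdkit.Chem import GetPeriodicTable

        sym = GetPeriodicTable().GetElementSymbol(self.atomic_num)
        return sym.lower() if self.aromatic else sym

    def token(self, with_map: bool = True) -> str:
        parts = [self.symbol, f"#{self.atomic_num}", f"H{self.h_count}"]
        if self.emit_charge:
            parts.append(f"{self.charge:+d}")
        body = ";".join(parts)
        if with_map and self.map_num:
            body += f":{self.map_num}"
        return f"[{body}]"


@dataclass
class SideGraph:
    """One side of a template: atoms, explicit bonds, molecule grouping."""

    atoms: list[PatternAtom] = field(default_factory=list)
    #: (i, j) -> bond order code, i < j
    bonds: dict[tuple[int, int], int] = field(default_factory=dict)
    #: atom-index sets, one per source molecule
    groups: list[set[int]] = field(default_factory=list)

    def add_bond(self, i: int, j: int, order: int) -> None:
        if i == j:
            raise ValueError("self-bond")
        self.bonds[(min(i, j), max(i, j))] = order

    def neighbors(self, i: int) -> list[tuple[int, int]]:
        out = []
        for (a, b), order in self.bonds.items():
            if a == i:
                out.append((b, order))
            elif b == i:
                out.append((a, order))
        return out


def _split_top_level(text: str, sep: str = ".") -> list[str]:
    """Split on `sep` outside parentheses and bracket atoms."""
    parts, depth, brack, start = [], 0, False, 0
    for pos, ch in enumerate(text):
        if brack:
            brack = ch != "]"
        elif ch == "[":
            brack = True
        elif ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        elif ch == sep and depth == 0:
            parts.append(text[start:pos])
            start = pos + 1
    parts.append(text[start:])
    return [p for p in parts if p]


def _parse_chain(chain: str, side: SideGraph, group: set[int]) -> None:
    pos = 0
    prev: int | None = None
    pending: int | None = None
    branch_stack: list[int] = []
    ring_open: dict[str, tuple[int, int | None]] = {}
    n = len(chain)
    while pos < n:
        ch = chain[pos]
        if ch == "[":
            m = _ATOM_RE.match(chain, pos)
            if not m:
                raise ParseError(f"bad atom token at ...{chain[pos:pos + 30]!r}")
            sym, num, hc, charge, mapn = m.groups()
            atom = PatternAtom(
                atomic_num=int(num),
                aromatic=sym.islower(),
                h_count=int(hc),
                charge=int(charge) if charge is not None else 0,
                emit_charge=charge is not None,
                map_num=int(mapn) if mapn else 0,
            )
            idx = len(side.atoms)
            side.atoms.append(atom)
            group.add(idx)
            if prev is not None:
                side.add_bond(prev, idx, pending if pending is not None else SINGLE)
            prev = idx
            pending = None
            pos = m.end()
        elif ch in TOKEN_BOND:
            pending = TOKEN_BOND[ch]
            pos += 1
        elif ch == "(":
            branch_stack.append(prev)
            pos += 1
        elif ch == ")":
            if not branch_stack:
                raise ParseError(f"unbalanced ')' in {chain!r}")
            prev = branch_stack.pop()
            pos += 1
        elif ch.isdigit() or ch == "%":
            if ch == "%":
                label, pos = chain[pos + 1:pos + 3], pos + 3
            else:
                label, pos = ch, pos + 1
            if label in ring_open:
                o_atom, o_bond = ring_open.pop(label)
                order = pending if pending is not None else o_bond
                if order is None:
                    order = SINGLE
                side.add_bond(o_atom, prev, order)
            else:
                ring_open[label] = (prev, pending)
            pending = None
        else:
            raise ParseError(f"unexpected character {ch!r} in {chain!r}")
    if branch_stack:
        raise ParseError(f"unbalanced '(' in {chain!r}")
    if ring_open:
        raise ParseError(f"unclosed ring bond(s) in {chain!r}")


def parse_side(text: str) -> SideGraph:
    """Parse one side of a template written in the package's dialect."""
    side = SideGraph()
    for group_text in _split_top_level(text):
        if group_text.startswith("(") and group_text.endswith(")"):
            inner = group_text[1:-1]
        else:
            inner = group_text
        group: set[int] = set()
        for chain in _split_top_level(inner):
            _parse_chain(chain, side, group)
        side.groups.append(group)
    return side


def parse_template(smarts: str) -> tuple[SideGraph, SideGraph]:
    """Parse ``substrate>>product`` template text into two side graphs."""
    if smarts.count(">>") != 1:
        raise ParseError("template must contain exactly one '>>'")
    sub, prod = smarts.split(">>")
    return parse_side(sub), parse_side(prod)
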