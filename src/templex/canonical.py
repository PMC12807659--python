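"""Canonical ordering and serialization of template side graphs.

Canonicalization uses Morgan-style iterative refinement of atom ranks over
the invariants (atomic number, aromaticity, hydrogen count, formal charge,
product-partner signature), with remaining ties broken by exhaustively
choosing the order that yields the lexicographically smallest serialized
string.  Atom maps are excluded from substrate-side ranking and then
renumbered 1..k in the canonical output order, so any two isomorphic inputs
-- whatever their original map indices or atom order -- serialize to
byte-identical template strings.

The serialization itself is a SMILES-like depth-first writer restricted to
the package's minimal-primitive dialect (see :mod:`templex.pattern`).
"""

from __future__ import annotations

import itertools
from collections.abc import Callable

from .pattern import BOND_TOKEN, PatternAtom, SideGraph

# caps on the tie-break search; generous for the molecule sizes templates see
_MAX_ORDERS_PER_FRAGMENT = 8
_MAX_LEAVES = 2048
_MAX_COMBINATIONS = 64


def _connected_components(side: SideGraph, atoms: set[int]) -> list[list[int]]:
    seen: set[int] = set()
    comps = []
    for start in sorted(atoms):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            i = stack.pop()
            comp.append(i)
            for j, _ in side.neighbors(i):
                if j in atoms and j not in seen:
                    seen.add(j)
                    stack.append(j)
        comps.append(sorted(comp))
    return comps


def _refine(
    side: SideGraph, atoms: list[int], init: dict[int, tuple]
) -> dict[int, int]:
    """Iterative neighborhood refinement to dense ranks."""
    inv = dict(init)
    ranks = _dense_ranks(inv, atoms)
    while True:
        nxt = {
            i: (
                ranks[i],
                tuple(
                    sorted(
                        (order, ranks[j])
                        for j, order in side.neighbors(i)
                        if j in ranks
                    )
                ),
            )
            for i in atoms
        }
        new_ranks = _dense_ranks(nxt, atoms)
        if len(set(new_ranks.values())) == len(set(ranks.values())):
            return new_ranks
        ranks = new_ranks


def _dense_ranks(inv: dict[int, tuple], atoms: list[int]) -> dict[int, int]:
    classes = sorted({inv[i] for i in atoms})
    lookup = {c: r for r, c in enumerate(classes)}
    return {i: lookup[inv[i]] for i in atoms}


def _write_fragment(
    side: SideGraph,
    order: dict[int, int],
    atoms: list[int],
    label: Callable[[PatternAtom], str],
) -> str:
    """Serialize one connected fragment following a total atom order."""
    adj = {
        i: sorted(
            ((j, o) for j, o in side.neighbors(i) if j in order),
            key=lambda t: order[t[0]],
        )
        for i in atoms
    }
    root = min(atoms, key=lambda i: order[i])

    # pass 1: depth-first spanning tree + ring-closure bonds
    children: dict[int, list[int]] = {i: [] for i in atoms}
    ring_bonds: list[tuple[int, int]] = []
    visited = {root}
    stack = [(root, iter(adj[root]))]
    parent = {root: None}
    while stack:
        i, it = stack[-1]
        advanced = False
        for j, _ in it:
            if j not in visited:
                visited.add(j)
                parent[j] = i
                children[i].append(j)
                stack.append((j, iter(adj[j])))
                advanced = True
                break
            elif j != parent[i]:
                key = (min(i, j), max(i, j))
                if key not in ring_bonds:
                    ring_bonds.append(key)
        if not advanced:
            stack.pop()

    ring_label: dict[tuple[int, int], str] = {}
    counter = itertools.count(1)

    def closure_token(i: int, key: tuple[int, int]) -> str:
        if key not in ring_label:
            n = next(counter)
            ring_label[key] = str(n) if n < 10 else f"%{n:02d}"
        return BOND_TOKEN[side.bonds[key]] + ring_label[key]

    out: list[str] = []

    def emit(i: int) -> None:
        out.append(label(side.atoms[i]))
        for key in ring_bonds:
            if i in key:
                out.append(closure_token(i, key))
        kids = children[i]
        for pos, j in enumerate(kids):
            bond = BOND_TOKEN[side.bonds[(min(i, j), max(i, j))]]
            if pos < len(kids) - 1:
                out.append("(")
                out.append(bond)
                emit(j)
                out.append(")")
            else:
                out.append(bond)
                emit(j)

    emit(root)
    return "".join(out)


def _fragment_orders(
    side: SideGraph,
    atoms: list[int],
    init_inv: dict[int, tuple],
    label: Callable[[PatternAtom], str],
    max_orders: int = _MAX_ORDERS_PER_FRAGMENT,
) -> tuple[str, list[dict[int, int]]]:
    """All atom orders (capped) realizing the minimal fragment string.

    Ties left by refinement are resolved by branching on every member of the
    first tied orbit and keeping the branch(es) with the smallest string.
    """
    best: list[tuple[str, dict[int, int]]] = []
    leaves = 0

    def descend(ranks: dict[int, int]) -> None:
        nonlocal leaves
        if leaves >= _MAX_LEAVES:
            return
        orbits: dict[int, list[int]] = {}
        for i in atoms:
            orbits.setdefault(ranks[i], []).append(i)
        tied = [v for _, v in sorted(orbits.items()) if len(v) > 1]
        if not tied:
            leaves += 1
            s = _write_fragment(side, ranks, atoms, label)
            best.append((s, dict(ranks)))
            return
        orbit = tied[0]
        for a in sorted(orbit):
            promoted = {i: (ranks[i], 0 if i == a else 1) for i in atoms}
            descend(_refine(side, atoms, promoted))

    descend(_refine(side, atoms, init_inv))
    min_s = min(s for s, _ in best)
    orders = [r for s, r in best if s == min_s]
    # drop duplicates (identical rank dicts reached via different branches)
    unique: list[dict[int, int]] = []
    for r in orders:
        if r not in unique:
            unique.append(r)
        if len(unique) >= max_orders:
            break
    return min_s, unique


def _partner_signature(prod: SideGraph, orig_map: int) -> tuple:
    """1-neighborhood fingerprint of a substrate atom's product partner."""
    for idx, atom in enumerate(prod.atoms):
        if atom.map_num == orig_map:
            nbrs = tuple(
                sorted(
                    (order, prod.atoms[j].atomic_num, prod.atoms[j].aromatic)
                    for j, order in prod.neighbors(idx)
                )
            )
            return (atom.atomic_num, atom.aromatic, atom.h_count, atom.charge, nbrs)
    return ("absent",)


def _base_inv(a: PatternAtom) -> tuple:
    return (a.atomic_num, a.aromatic, a.h_count, a.charge, a.emit_charge)


def canonical_template(sub: SideGraph, prod: SideGraph) -> str:
    """Render a canonical ``substrate>>product`` template string.

    ``sub`` and ``prod`` carry the original map indices (0 = unmapped); the
    output carries fresh map numbers 1..k assigned in canonical substrate
    order.
    """
    sub_atoms = set(range(len(sub.atoms)))
    fragments = _connected_components(sub, sub_atoms)

    frag_results = []
    for frag in fragments:
        init = {
            i: _base_inv(sub.atoms[i])
            + (
                _partner_signature(prod, sub.atoms[i].map_num)
                if sub.atoms[i].map_num
                else ("unmapped",)
            )
            for i in frag
        }
        s, orders = _fragment_orders(
            sub, frag, init, lambda a: a.token(with_map=False)
        )
        frag_results.append((s, frag, orders))

    frag_results.sort(key=lambda t: t[0])

    # fragment arrangements: permute only within runs of equal mapless strings
    runs: list[list[int]] = []
    for idx, (s, _, _) in enumerate(frag_results):
        if runs and frag_results[runs[-1][0]][0] == s:
            runs[-1].append(idx)
        else:
            runs.append([idx])
    arrangement_pools = [
        list(itertools.permutations(run))[:_MAX_COMBINATIONS] for run in runs
    ]

    candidates: list[str] = []
    n_combos = 0
    for arrangement in itertools.product(*arrangement_pools):
        frag_seq = [frag_results[i] for grp in arrangement for i in grp]
        order_pools = [orders for _, _, orders in frag_seq]
        for choice in itertools.product(*order_pools):
            n_combos += 1
            if n_combos > _MAX_COMBINATIONS:
                break
            candidates.append(_render(sub, prod, frag_seq, choice))
        if n_combos > _MAX_COMBINATIONS:
            break
    return min(candidates)


def _render(
    sub: SideGraph,
    prod: SideGraph,
    frag_seq: list[tuple[str, list[int], list[dict[int, int]]]],
    choice: tuple[dict[int, int], ...],
) -> str:
    # assign fresh map numbers in substrate output order
    newmap: dict[int, int] = {}  # original map index -> fresh number
    counter = itertools.count(1)
    for (_, frag, _), ranks in zip(frag_seq, choice):
        for i in sorted(frag, key=lambda x: ranks[x]):
            orig = sub.atoms[i].map_num
            if orig:
                newmap[orig] = next(counter)

    def sub_label(ranks):
        def label(a: PatternAtom) -> str:
            tok = a.token(with_map=False)
            if a.map_num:
                tok = tok[:-1] + f":{newmap[a.map_num]}]"
            return tok

        return label

    sub_frag_strings = [
        _write_fragment(sub, ranks, frag, sub_label(ranks))
        for (_, frag, _), ranks in zip(frag_seq, choice)
    ]
    sub_str = ".".join(sub_frag_strings)
    if len(sub_frag_strings) > 1:
        sub_str = f"({sub_str})"

    def prod_label(a: PatternAtom) -> str:
        tok = a.token(with_map=False)
        if a.map_num:
            tok = tok[:-1] + f":{newmap[a.map_num]}]"
        return tok

    group_strings = []
    for group in prod.groups:
        frag_strs = []
        for frag in _connected_components(prod, set(group)):
            init = {
                i: _base_inv(prod.atoms[i])
                + (newmap.get(prod.atoms[i].map_num, 0),)
                for i in frag
            }
            _, orders = _fragment_orders(prod, frag, init, prod_label, max_orders=1)
            frag_strs.append(_write_fragment(prod, orders[0], frag, prod_label))
        frag_strs.sort()
        gs = ".".join(frag_strs)
        if len(frag_strs) > 1:
            gs = f"({gs})"
        group_strings.append(gs)
    group_strings.sort()
    return sub_str + ">>" + ".".join(group_strings)


def topology_string(side: SideGraph) -> str:
    """Canonical heavy-atom connectivity serialization of one side.

    Atoms are reduced to bare atomic numbers (``[#6]``); hydrogen counts,
    charges, aromatic case and atom maps are all excluded.  Used for the A/B
    identifier segments.
    """

    def label(a: PatternAtom) -> str:
        return f"[#{a.atomic_num}]"

    frag_strings = []
    for frag in _connected_components(side, set(range(len(side.atoms)))):
        init = {
            i: (side.atoms[i].atomic_num, len(side.neighbors(i))) for i in frag
        }
        s, _ = _fragment_orders(side, frag, init, label)
        frag_strings.append(s)
    return ".".join(sorted(frag_strings))
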