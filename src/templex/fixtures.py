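"""Synthetic mapped-reaction corpus and the transaminase worked example.

Every fixture mapping is *constructed*, not computed, so tests never depend
on an external atom-atom mapper.  Each corpus record carries its ground
truth: the mapped reaction-centre atom set per focal substrate (as map
indices) and the expected inherited product structures (map-free canonical
SMILES), both derived from how the record was built -- they serve as
independent oracles for centre detection and round-trip tests.

Families cover balanced and mass-imbalanced records, 1-3 substrates,
aliphatic and aromatic centres, charged species, spontaneous flags and
synthetic sequence-cluster annotations:

``transamination``
    keto acid + amino acid <-> new amino acid + new keto acid (the shape of
    the RHEA:25152 example), aliphatic or benzylic side chains.
``esterification`` / ``imbalanced_variant``
    acid + alcohol -> ester (+ water); the imbalanced variant omits water so
    the leaving acid oxygen is mapped on one side only.
``diesterification``
    diacid + two alcohol copies -> diester + 2 water (stoichiometric
    duplicate substrates).
``substitution``
    hydroxide + alkyl/aryl chloride -> alcohol/phenol + chloride (charged
    species; the aryl variant puts the centre on an aromatic carbon).
``oxidation``
    secondary alcohol -> ketone (heavy atoms balanced, hydrogens not).
``ring_opening``
    epoxide + water -> vicinal diol, flagged spontaneous.
"""

from __future__ import annotations

import itertools
import json
import random
from dataclasses import dataclass
from pathlib import Path

from rdkit import Chem

from .errors import ConfigurationError
from .reaction_model import BATCH_COLUMNS, MappedReaction, parse_mapped_reaction

FAMILIES = (
    "transamination",
    "esterification",
    "imbalanced_variant",
    "diesterification",
    "substitution",
    "oxidation",
    "ring_opening",
)


@dataclass(frozen=True)
class FixtureSpec:
    family: str
    size_params: tuple
    seed: int


def _canon(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return Chem.MolToSmiles(mol)


def _ch2(ids: list[int]) -> str:
    return "".join(f"[CH2:{i}]" for i in ids)


class _Ids:
    def __init__(self) -> None:
        self._counter = itertools.count(1)

    def __call__(self, n: int | None = None):
        if n is None:
            return next(self._counter)
        return [next(self._counter) for _ in range(n)]


def _amino_side_chain(ids: _Ids, q: int, aromatic: bool) -> str:
    if aromatic:
        cb = ids()
        ar = ids(6)
        ring = "".join(f"[cH:{i}]" for i in ar[1:])
        return f"[CH2:{cb}][c:{ar[0]}]1{ring}1"
    chain = ids(q)
    if q == 1:
        return f"[CH3:{chain[0]}]"
    return _ch2(chain[:-1]) + f"[CH3:{chain[-1]}]"


def _build_transamination(p: int, q: int, aromatic: bool) -> dict:
    ids = _Ids()
    oc1, c1, oh1 = ids(), ids(), ids()
    chain = ids(p)
    ck, ok, c2, oc2, oh2 = ids(), ids(), ids(), ids(), ids()
    keto = (
        f"[O:{oc1}]=[C:{c1}]([OH:{oh1}])"
        + _ch2(chain)
        + f"[C:{ck}](=[O:{ok}])[C:{c2}](=[O:{oc2}])[OH:{oh2}]"
    )
    n, ca = ids(), ids()
    side = _amino_side_chain(ids, q, aromatic)
    cc, occ, och = ids(), ids(), ids()
    amino = f"[NH2:{n}][CH:{ca}]({side})[C:{cc}](=[O:{occ}])[OH:{och}]"
    new_keto = f"[O:{ok}]=[C:{ca}]({side})[C:{cc}](=[O:{occ}])[OH:{och}]"
    new_amino = (
        f"[O:{oc1}]=[C:{c1}]([OH:{oh1}])"
        + _ch2(chain)
        + f"[CH:{ck}]([NH2:{n}])[C:{c2}](=[O:{oc2}])[OH:{oh2}]"
    )
    both = sorted([_canon(new_keto), _canon(new_amino)])
    return {
        "smiles": f"{keto}.{amino}>>{new_keto}.{new_amino}",
        "centres": {0: sorted([ck, ok]), 1: sorted([n, ca])},
        "products": {0: both, 1: both},
    }


def _build_esterification(p: int, q: int, balanced: bool) -> dict:
    ids = _Ids()
    cm = ids()
    chain = ids(p) if p else []
    cc, oc, oh = ids(), ids(), ids()
    acid = f"[CH3:{cm}]" + _ch2(chain) + f"[C:{cc}](=[O:{oc}])[OH:{oh}]"
    om = ids()
    achain = ids(q)
    cm2 = ids()
    alcohol = f"[OH:{om}]" + _ch2(achain) + f"[CH3:{cm2}]"
    ester = (
        f"[CH3:{cm}]"
        + _ch2(chain)
        + f"[C:{cc}](=[O:{oc}])[O:{om}]"
        + _ch2(achain)
        + f"[CH3:{cm2}]"
    )
    water = f"[OH2:{oh}]"
    products = f"{ester}.{water}" if balanced else ester
    return {
        "smiles": f"{acid}.{alcohol}>>{products}",
        # without water the leaving acid O is one-sided-mapped (a
        # disappearing atom) and the carbonyl C keeps an identical mapped
        # neighborhood, so the acid-focal mapped centre is empty
        "centres": {
            0: sorted([cc, oh]) if balanced else [],
            1: [om],
        },
        "products": {
            0: sorted([_canon(ester), _canon(water)])
            if balanced
            else [_canon(ester)],
            1: [_canon(ester)],
        },
    }


def _build_diesterification(p: int) -> dict:
    ids = _Ids()
    oA, cA, ohA = ids(), ids(), ids()
    chain = ids(p)
    cB, oB, ohB = ids(), ids(), ids()
    acid = (
        f"[O:{oA}]=[C:{cA}]([OH:{ohA}])"
        + _ch2(chain)
        + f"[C:{cB}](=[O:{oB}])[OH:{ohB}]"
    )
    omA, e1A, e2A = ids(), ids(), ids()
    omB, e1B, e2B = ids(), ids(), ids()
    ethA = f"[OH:{omA}][CH2:{e1A}][CH3:{e2A}]"
    ethB = f"[OH:{omB}][CH2:{e1B}][CH3:{e2B}]"
    diester = (
        f"[O:{oA}]=[C:{cA}]([O:{omA}][CH2:{e1A}][CH3:{e2A}])"
        + _ch2(chain)
        + f"[C:{cB}](=[O:{oB}])[O:{omB}][CH2:{e1B}][CH3:{e2B}]"
    )
    wA, wB = f"[OH2:{ohA}]", f"[OH2:{ohB}]"
    return {
        "smiles": f"{acid}.{ethA}.{ethB}>>{diester}.{wA}.{wB}",
        "centres": {
            0: sorted([cA, ohA, cB, ohB]),
            1: [omA],
            2: [omB],
        },
        "products": {
            0: sorted([_canon(diester), _canon(wA), _canon(wB)]),
            1: [_canon(diester)],
            2: [_canon(diester)],
        },
    }


def _build_substitution(p: int, aryl: bool) -> dict:
    ids = _Ids()
    o, cl = ids(), ids()
    if aryl:
        ar = ids(6)
        ring = "".join(f"[cH:{i}]" for i in ar[1:])
        body = f"[c:{ar[0]}]1{ring}1"
        halide = f"[Cl:{cl}]{body}"
        product = f"[OH:{o}]{body}"
        carbon = ar[0]
    else:
        c3 = ids()
        chain = ids(p - 1) if p > 1 else []
        tail = _ch2(chain[:-1]) + f"[CH3:{chain[-1]}]" if chain else ""
        if not chain:
            halide = f"[Cl:{cl}][CH3:{c3}]"
            product = f"[OH:{o}][CH3:{c3}]"
        else:
            halide = f"[Cl:{cl}][CH2:{c3}]{tail}"
            product = f"[OH:{o}][CH2:{c3}]{tail}"
        carbon = c3
    return {
        "smiles": f"[OH-:{o}].{halide}>>{product}.[Cl-:{cl}]",
        "centres": {0: [o], 1: sorted([cl, carbon])},
        "products": {
            0: [_canon(product)],
            1: sorted([_canon(product), _canon(f"[Cl-:{cl}]")]),
        },
    }


def _build_oxidation(a: int, b: int) -> dict:
    ids = _Ids()
    cm1 = ids()
    chainA = ids(a) if a else []
    coh, o = ids(), ids()
    chainB = ids(b) if b else []
    cm2 = ids()
    sub = (
        f"[CH3:{cm1}]"
        + _ch2(chainA)
        + f"[CH:{coh}]([OH:{o}])"
        + _ch2(chainB)
        + f"[CH3:{cm2}]"
    )
    prod = (
        f"[CH3:{cm1}]"
        + _ch2(chainA)
        + f"[C:{coh}](=[O:{o}])"
        + _ch2(chainB)
        + f"[CH3:{cm2}]"
    )
    return {
        "smiles": f"{sub}>>{prod}",
        "centres": {0: sorted([coh, o])},
        "products": {0: [_canon(prod)]},
    }


def _build_ring_opening(q: int) -> dict:
    ids = _Ids()
    c1, o2, c3 = ids(), ids(), ids()
    chain = ids(q) if q else []
    cm = ids()
    w = ids()
    tail = _ch2(chain) + f"[CH3:{cm}]"
    epoxide = f"[CH2:{c1}]1[O:{o2}][CH:{c3}]1{tail}"
    diol = f"[OH:{o2}][CH2:{c1}][CH:{c3}]([OH:{w}]){tail}"
    return {
        "smiles": f"{epoxide}.[OH2:{w}]>>{diol}",
        "centres": {0: sorted([o2, c3]), 1: [w]},
        "products": {0: [_canon(diol)], 1: [_canon(diol)]},
    }


_BUILDERS = {
    "transamination": _build_transamination,
    "esterification": lambda p, q: _build_esterification(p, q, True),
    "imbalanced_variant": lambda p, q: _build_esterification(p, q, False),
    "diesterification": _build_diesterification,
    "substitution": _build_substitution,
    "oxidation": _build_oxidation,
    "ring_opening": _build_ring_opening,
}

_DATASET_POOL = {
    "transamination": ("rhea", "mnx"),
    "esterification": ("mnx", "rhea"),
    "imbalanced_variant": ("mnx",),
    "diesterification": ("uspto",),
    "substitution": ("uspto",),
    "oxidation": ("mnx",),
    "ring_opening": ("rhea",),
}

_EC_PREFIX = {
    "transamination": "2.6.1",
    "esterification": "3.1.1",
    "imbalanced_variant": "3.1.1",
    "oxidation": "1.1.1",
    "ring_opening": "3.3.2",
}


def build_record(spec: FixtureSpec, index: int = 0) -> tuple[dict, dict]:
    """One batch-TSV row plus its ground truth, purely from the spec."""
    if spec.family not in FAMILIES:
        raise ConfigurationError(f"unknown fixture family {spec.family!r}")
    built = _BUILDERS[spec.family](*spec.size_params)
    rng = random.Random(spec.seed)
    dataset = rng.choice(_DATASET_POOL[spec.family])
    spontaneous = spec.family == "ring_opening"
    if dataset == "uspto" or spontaneous:
        count: int | None = None
    else:
        count = rng.randint(1, 40) if rng.random() > 0.2 else None
    prefix = _EC_PREFIX.get(spec.family)
    ec = f"{prefix}.{rng.randint(1, 99)}" if prefix and dataset != "uspto" else ""
    params = "_".join(str(x) for x in spec.size_params)
    reaction_id = f"FIX:{spec.family.upper()}:{params}:{index:03d}"
    row = {
        "reaction_id": reaction_id,
        "dataset": dataset,
        "mapped_rxn_smiles": built["smiles"],
        "ec_numbers": ec,
        "spontaneous": "1" if spontaneous else "0",
        "sequence_cluster_count": "" if count is None else str(count),
    }
    ground_truth = {
        "family": spec.family,
        "forward_centres": {str(k): v for k, v in built["centres"].items()},
        "forward_products": {str(k): v for k, v in built["products"].items()},
    }
    return row, ground_truth


def default_specs(base_seed: int = 1) -> list[FixtureSpec]:
    """The standard >=50-reaction corpus specification."""
    specs: list[FixtureSpec] = []

    def add(family: str, params: tuple) -> None:
        specs.append(FixtureSpec(family, params, base_seed * 1009 + len(specs)))

    for p in (1, 2, 3):
        for q, aromatic in ((1, False), (2, False), (3, False), (2, True)):
            add("transamination", (p, q, aromatic))
    for p in (0, 1, 2):
        for q in (1, 2, 3):
            add("esterification", (p, q))
            add("imbalanced_variant", (p, q))
    for p in (1, 2, 3, 4, 5, 6):
        add("substitution", (p, False))
    add("substitution", (1, True))
    for a, b in ((0, 0), (1, 0), (1, 1), (2, 1), (2, 2), (3, 2)):
        add("oxidation", (a, b))
    for q in (0, 1, 2, 3, 4):
        add("ring_opening", (q,))
    for p in (1, 2, 3):
        add("diesterification", (p,))
    return specs


def generate_corpus(
    specs: list[FixtureSpec],
) -> tuple[list[dict], dict[str, dict]]:
    """Deterministically build batch rows and the ground-truth sidecar."""
    rows = []
    ground_truth = {}
    for index, spec in enumerate(specs):
        row, gt = build_record(spec, index)
        rows.append(row)
        ground_truth[row["reaction_id"]] = gt
    return rows, ground_truth


def corpus_tsv(rows: list[dict]) -> str:
    lines = ["\t".join(BATCH_COLUMNS)]
    for row in rows:
        lines.append("\t".join(row[c] for c in BATCH_COLUMNS))
    return "\n".join(lines) + "\n"


def write_corpus(
    directory: str | Path, specs: list[FixtureSpec] | None = None
) -> tuple[Path, Path]:
    """Write corpus.tsv and its ground_truth.json sidecar; returns paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows, ground_truth = generate_corpus(specs or default_specs())
    tsv_path = directory / "corpus.tsv"
    gt_path = directory / "ground_truth.json"
    tsv_path.write_text(corpus_tsv(rows), encoding="utf-8")
    gt_path.write_text(
        json.dumps(ground_truth, indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    return tsv_path, gt_path


WORKED_EXAMPLE_ID = "RHEA:25152"

_OXOGLUTARATE = (
    "[O:1]=[C:2]([OH:3])[CH2:4][CH2:5][C:6](=[O:7])[C:8](=[O:9])[OH:10]"
)
_PHENYLALANINE = (
    "[NH2:11][CH:12]([CH2:13][c:14]1[cH:15][cH:16][cH:17][cH:18][cH:19]1)"
    "[C:20](=[O:21])[OH:22]"
)
_PHENYLPYRUVATE = (
    "[O:7]=[C:12]([CH2:13][c:14]1[cH:15][cH:16][cH:17][cH:18][cH:19]1)"
    "[C:20](=[O:21])[OH:22]"
)
_GLUTAMATE = (
    "[O:1]=[C:2]([OH:3])[CH2:4][CH2:5][CH:6]([NH2:11])[C:8](=[O:9])[OH:10]"
)

#: map indices of the phenylalanine-focal forward centre: the alpha carbon,
#: the departing amine nitrogen (the arriving keto oxygen is an appearing
#: atom in that component, carrying no two-sided map index there)
WORKED_EXAMPLE_PHE_CENTRE = {11, 12}
#: 2-oxoglutarate-focal forward centre: the keto carbon and keto oxygen
WORKED_EXAMPLE_KETO_CENTRE = {6, 7}

L_PHENYLALANINE_SMILES = "NC(Cc1ccccc1)C(O)=O"
PHENYLPYRUVATE_SMILES = "O=C(C(=O)O)Cc1ccccc1"


def worked_example() -> MappedReaction:
    """The transaminase example: 2-oxoglutarate + L-phenylalanine ->
    3-phenylpyruvate + L-glutamate (RHEA:25152, EC 2.6.1.5 / 2.6.1.57).

    The mapping transfers the amine nitrogen of phenylalanine to glutamate
    and the keto oxygen of 2-oxoglutarate to 3-phenylpyruvate.
    """
    smiles = (
        f"{_OXOGLUTARATE}.{_PHENYLALANINE}>>{_PHENYLPYRUVATE}.{_GLUTAMATE}"
    )
    return parse_mapped_reaction(
        smiles,
        reaction_id=WORKED_EXAMPLE_ID,
        dataset="rhea",
        ec_numbers=["2.6.1.5", "2.6.1.57"],
    )
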