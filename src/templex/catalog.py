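"""Deduplicated, provenance-aware template catalog: merge, filter, export.

One record per distinct canonical SMARTS.  Merging unions provenance across
reactions and datasets, derives chemistry domains from dataset labels
(mnx/rhea are biochemical, uspto is organic chemistry), and recomputes the
sequence-support score from the union of supporting evidence: the maximum
cluster count across supporting reactions (the most conservative ambiguity
estimate), with spontaneous support from any source forcing a score of 1.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import ParseError, QueryError
from .identity import (
    DEFAULT_R,
    HASH_SCHEME,
    format_score,
    make_identifier,
    sequence_score,
)
from .reaction_model import BIOCHEMICAL_DATASETS
from .template_engine import Template

logger = logging.getLogger(__name__)

EXPORT_COLUMNS = [
    "identifier",
    "smarts",
    "radii",
    "directions",
    "datasets",
    "domains",
    "ec_numbers",
    "sequence_score",
    "source_reaction_count",
    "omitted_cofactors",
    "reaction_ids",
]

_EC_FILTER_RE = re.compile(r"^\d+(\.\d+){0,3}$")


@dataclass
class CatalogRecord:
    identifier: str
    smarts: str
    radii: frozenset[int]
    directions: frozenset[str]
    datasets: dict[str, tuple[str, ...]]  # label -> sorted reaction ids
    domains: frozenset[str]
    ec_numbers: frozenset[str]
    sequence_score: float | None
    omitted_cofactors: frozenset[str]

    @property
    def source_reaction_count(self) -> int:
        return sum(len(v) for v in self.datasets.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, CatalogRecord):
            return NotImplemented
        return (
            self.identifier == other.identifier
            and self.smarts == other.smarts
            and self.radii == other.radii
            and self.directions == other.directions
            and self.datasets == other.datasets
            and self.domains == other.domains
            and self.ec_numbers == other.ec_numbers
            and self.sequence_score == other.sequence_score
            and self.omitted_cofactors == other.omitted_cofactors
        )


@dataclass
class Catalog:
    records: list[CatalogRecord] = field(default_factory=list)
    r: float = DEFAULT_R

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Catalog):
            return NotImplemented
        return self.records == other.records

    def by_smarts(self) -> dict[str, CatalogRecord]:
        return {r.smarts: r for r in self.records}

    def by_identifier(self) -> dict[str, CatalogRecord]:
        return {r.identifier: r for r in self.records}


def _domain(dataset: str) -> str:
    return "biochemical" if dataset in BIOCHEMICAL_DATASETS else "organic chemistry"


def merge(templates: list[Template], r: float = DEFAULT_R) -> Catalog:
    """Merge valid templates into a deduplicated catalog.

    Deterministic output order (identifier ascending, SMARTS as tiebreak);
    input order never affects the result.  Conflicting annotations for the
    same (dataset, reaction_id) pair are resolved first-writer-wins with a
    logged warning.
    """
    buckets: dict[str, dict] = {}
    seen_annotations: dict[tuple[str, str], tuple] = {}
    for t in templates:
        if not t.valid:
            continue
        parent = t.component.parent
        key = (parent.dataset, parent.reaction_id)
        annot = (
            tuple(sorted(parent.ec_numbers)),
            parent.spontaneous,
            parent.sequence_cluster_count,
        )
        if key in seen_annotations:
            if seen_annotations[key] != annot:
                logger.warning(
                    "conflicting annotations for %s; first writer wins", key
                )
                annot = seen_annotations[key]
        else:
            seen_annotations[key] = annot
        ec, spontaneous, n = annot
        b = buckets.setdefault(
            t.smarts,
            {
                "radii": set(),
                "directions": set(),
                "datasets": {},
                "ec": set(),
                "omitted": set(),
                "spontaneous": False,
                "max_n": None,
            },
        )
        b["radii"].add(t.radius)
        b["directions"].add(t.direction)
        b["datasets"].setdefault(parent.dataset, set()).add(parent.reaction_id)
        b["ec"].update(ec)
        b["omitted"].update(t.component.omitted_cofactors)
        b["spontaneous"] = b["spontaneous"] or spontaneous
        if n is not None:
            b["max_n"] = n if b["max_n"] is None else max(b["max_n"], n)

    records = []
    for smarts, b in buckets.items():
        score = sequence_score(b["max_n"], r=r, spontaneous=b["spontaneous"])
        # store at the serialized precision so export/import round-trips
        value = float(format_score(score)) if score is not None else None
        records.append(
            CatalogRecord(
                identifier=make_identifier(smarts).render(),
                smarts=smarts,
                radii=frozenset(b["radii"]),
                directions=frozenset(b["directions"]),
                datasets={
                    ds: tuple(sorted(rids))
                    for ds, rids in sorted(b["datasets"].items())
                },
                domains=frozenset(_domain(ds) for ds in b["datasets"]),
                ec_numbers=frozenset(b["ec"]),
                sequence_score=value,
                omitted_cofactors=frozenset(b["omitted"]),
            )
        )
    records.sort(key=lambda rec: (rec.identifier, rec.smarts))
    return Catalog(records=records, r=r)


def filter_catalog(
    cat: Catalog,
    dataset: str | None = None,
    radius: int | None = None,
    ec: str | None = None,
    reaction_id: str | None = None,
    template_id: str | None = None,
) -> Catalog:
    """Conjunctive faceted filtering; returns a new catalog.

    EC matching is string-prefix on dot boundaries: ``"2.7.1"`` matches any
    ``2.7.1.x`` and ``2.7.1`` itself.
    """
    if ec is not None and not _EC_FILTER_RE.match(ec):
        raise QueryError(f"malformed EC filter {ec!r}")

    def ec_matches(rec: CatalogRecord) -> bool:
        return any(e == ec or e.startswith(ec + ".") for e in rec.ec_numbers)

    kept = []
    for rec in cat.records:
        if dataset is not None and dataset not in rec.datasets:
            continue
        if radius is not None and radius not in rec.radii:
            continue
        if ec is not None and not ec_matches(rec):
            continue
        if reaction_id is not None and not any(
            reaction_id in rids for rids in rec.datasets.values()
        ):
            continue
        if template_id is not None and rec.identifier != template_id:
            continue
        kept.append(rec)
    return Catalog(records=kept, r=cat.r)


# ---------------------------------------------------------------------------
# export / import

def _record_row(rec: CatalogRecord) -> dict[str, str]:
    pairs = sorted(
        f"{ds}={rid}" for ds, rids in rec.datasets.items() for rid in rids
    )
    return {
        "identifier": rec.identifier,
        "smarts": rec.smarts,
        "radii": ";".join(str(x) for x in sorted(rec.radii)),
        "directions": ";".join(sorted(rec.directions)),
        "datasets": ";".join(sorted(rec.datasets)),
        "domains": ";".join(sorted(rec.domains)),
        "ec_numbers": ";".join(sorted(rec.ec_numbers)),
        "sequence_score": (
            "" if rec.sequence_score is None else f"{rec.sequence_score:.6g}"
        ),
        "source_reaction_count": str(rec.source_reaction_count),
        "omitted_cofactors": ";".join(sorted(rec.omitted_cofactors)),
        "reaction_ids": ";".join(pairs),
    }


def _row_record(row: dict[str, str]) -> CatalogRecord:
    datasets: dict[str, set[str]] = {}
    for pair in filter(None, row["reaction_ids"].split(";")):
        ds, _, rid = pair.partition("=")
        datasets.setdefault(ds, set()).add(rid)
    score = row["sequence_score"].strip()
    return CatalogRecord(
        identifier=row["identifier"],
        smarts=row["smarts"],
        radii=frozenset(int(x) for x in filter(None, row["radii"].split(";"))),
        directions=frozenset(filter(None, row["directions"].split(";"))),
        datasets={
            ds: tuple(sorted(rids)) for ds, rids in sorted(datasets.items())
        },
        domains=frozenset(filter(None, row["domains"].split(";"))),
        ec_numbers=frozenset(filter(None, row["ec_numbers"].split(";"))),
        sequence_score=float(score) if score else None,
        omitted_cofactors=frozenset(
            filter(None, row["omitted_cofactors"].split(";"))
        ),
    )


def _record_json(rec: CatalogRecord) -> dict:
    return {
        "identifier": rec.identifier,
        "smarts": rec.smarts,
        "radii": sorted(rec.radii),
        "directions": sorted(rec.directions),
        "datasets": {ds: list(rids) for ds, rids in sorted(rec.datasets.items())},
        "domains": sorted(rec.domains),
        "ec_numbers": sorted(rec.ec_numbers),
        "sequence_score": rec.sequence_score,
        "source_reaction_count": rec.source_reaction_count,
        "omitted_cofactors": sorted(rec.omitted_cofactors),
    }


def export(cat: Catalog, path: str | Path, fmt: str = "tsv") -> None:
    """Write the catalog as TSV, CSV or JSON (lossless round trip)."""
    path = Path(path)
    if fmt in ("tsv", "csv"):
        delim = "\t" if fmt == "tsv" else ","
        with open(path, "w", encoding="utf-8", newline="") as handle:
            writer = csv.DictWriter(
                handle,
                fieldnames=EXPORT_COLUMNS,
                delimiter=delim,
                lineterminator="\n",
            )
            writer.writeheader()
            for rec in cat.records:
                writer.writerow(_record_row(rec))
    elif fmt == "json":
        doc = {
            "format": "templex-catalog",
            "version": 1,
            "hash_scheme": HASH_SCHEME,
            "r": cat.r,
            "records": [_record_json(rec) for rec in cat.records],
        }
        path.write_text(
            json.dumps(doc, indent=1, sort_keys=False) + "\n", encoding="utf-8"
        )
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_catalog(path: str | Path, fmt: str | None = None) -> Catalog:
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "tsv"
    if fmt in ("tsv", "csv"):
        delim = "\t" if fmt == "tsv" else ","
        with open(path, encoding="utf-8", newline="") as handle:
            reader = csv.DictReader(handle, delimiter=delim)
            missing = set(EXPORT_COLUMNS) - set(reader.fieldnames or [])
            if missing:
                raise ParseError(f"catalog missing columns: {sorted(missing)}")
            records = [_row_record(row) for row in reader]
        return Catalog(records=records)
    if fmt == "json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        validate_catalog_json(doc)
        records = []
        for rj in doc["records"]:
            records.append(
                CatalogRecord(
                    identifier=rj["identifier"],
                    smarts=rj["smarts"],
                    radii=frozenset(rj["radii"]),
                    directions=frozenset(rj["directions"]),
                    datasets={
                        ds: tuple(sorted(rids))
                        for ds, rids in sorted(rj["datasets"].items())
                    },
                    domains=frozenset(rj["domains"]),
                    ec_numbers=frozenset(rj["ec_numbers"]),
                    sequence_score=rj["sequence_score"],
                    omitted_cofactors=frozenset(rj["omitted_cofactors"]),
                )
            )
        return Catalog(records=records, r=doc.get("r", DEFAULT_R))
    raise ValueError(f"unknown import format {fmt!r}")


# ---------------------------------------------------------------------------
# JSON schema validation (structural subset: type/required/properties/items/
# enum/pattern/minimum, which is all the shipped schema uses)

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "null": type(None),
}


def load_schema() -> dict:
    ref = resources.files("templex.data") / "catalog.schema.json"
    return json.loads(ref.read_text(encoding="utf-8"))


def _check(instance, schema: dict, where: str, errors: list[str]) -> None:
    typ = schema.get("type")
    if typ is not None:
        allowed = typ if isinstance(typ, list) else [typ]
        ok = False
        for t in allowed:
            if t == "number":
                ok = ok or (
                    isinstance(instance, (int, float))
                    and not isinstance(instance, bool)
                )
            elif t == "integer":
                ok = ok or (
                    isinstance(instance, int) and not isinstance(instance, bool)
                )
            else:
                ok = ok or isinstance(instance, _TYPES[t])
        if not ok:
            errors.append(f"{where}: expected type {typ}, got {type(instance).__name__}")
            return
    if "enum" in schema and instance not in schema["enum"]:
        errors.append(f"{where}: {instance!r} not in enum")
    if "pattern" in schema and isinstance(instance, str):
        if not re.search(schema["pattern"], instance):
            errors.append(f"{where}: {instance!r} does not match pattern")
    if "minimum" in schema and isinstance(instance, (int, float)):
        if instance < schema["minimum"]:
            errors.append(f"{where}: {instance} below minimum")
    if isinstance(instance, dict):
        for req in schema.get("required", []):
            if req not in instance:
                errors.append(f"{where}: missing required key {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                _check(instance[key], sub, f"{where}.{key}", errors)
        extra = schema.get("additionalProperties")
        if isinstance(extra, dict):
            for key, value in instance.items():
                if key not in schema.get("properties", {}):
                    _check(value, extra, f"{where}.{key}", errors)
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            _check(item, schema["items"], f"{where}[{i}]", errors)


def validate_catalog_json(doc: dict, schema: dict | None = None) -> None:
    """Raise ParseError if ``doc`` does not conform to the catalog schema."""
    errors: list[str] = []
    _check(doc, schema or load_schema(), "$", errors)
    if errors:
        raise ParseError("catalog JSON invalid: " + "; ".join(errors[:5]))
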