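"""Catalog merging, filtering and export/import."""

import json
import random

import pytest

from templex.catalog import (
    EXPORT_COLUMNS,
    export,
    filter_catalog,
    import_catalog,
    merge,
    validate_catalog_json,
)
from templex.errors import ParseError, QueryError
from templex.reaction_model import parse_mapped_reaction
from templex.template_engine import extract_all


def _templates(smiles, reaction_id, dataset, **annot):
    rxn = parse_mapped_reaction(smiles, reaction_id, dataset, **annot)
    templates, _ = extract_all(rxn, radii=range(0, 3))
    return templates


OXIDATION = "[CH3:1][CH:2]([OH:3])[CH3:4]>>[CH3:1][C:2](=[O:3])[CH3:4]"


def test_cross_dataset_merge_unions_provenance():
    t = _templates(OXIDATION, "MNXR1", "mnx", sequence_cluster_count=4)
    t += _templates(OXIDATION, "RHEA:9", "rhea", sequence_cluster_count=16)
    cat = merge(t)
    for rec in cat.records:
        assert set(rec.datasets) == {"mnx", "rhea"}
        assert rec.domains == frozenset({"biochemical"})
        assert rec.source_reaction_count == 2
        # max-n convention: 16 clusters at r=2 -> 0.25
        assert rec.sequence_score == pytest.approx(0.25)


def test_spontaneous_support_forces_score_one():
    t = _templates(OXIDATION, "R1", "mnx", sequence_cluster_count=25)
    t += _templates(OXIDATION, "R2", "rhea", spontaneous=True)
    cat = merge(t)
    assert all(rec.sequence_score == 1.0 for rec in cat.records)


def test_unannotated_records_have_null_score():
    cat = merge(_templates(OXIDATION, "US1", "uspto"))
    assert all(rec.sequence_score is None for rec in cat.records)
    assert all(
        rec.domains == frozenset({"organic chemistry"}) for rec in cat.records
    )


def test_singleton_catalog():
    t = _templates(OXIDATION, "R1", "user")[:1]
    cat = merge(t)
    assert len(cat) == 1
    rec = cat.records[0]
    assert rec.source_reaction_count == 1
    assert rec.radii == frozenset({0})


def test_merge_idempotent_and_order_independent(corpus_extraction):
    templates, _ = corpus_extraction
    base = merge(templates)
    doubled = merge(templates + templates)
    shuffled = list(templates)
    random.Random(3).shuffle(shuffled)
    assert merge(shuffled) == base
    assert doubled == base


def test_dedup_key_soundness(fixture_catalog):
    smarts = [r.smarts for r in fixture_catalog.records]
    ids = [r.identifier for r in fixture_catalog.records]
    assert len(set(smarts)) == len(smarts)
    assert len(set(ids)) == len(ids)


def test_filter_identity_and_conjunction(fixture_catalog):
    cat = fixture_catalog
    assert filter_catalog(cat) == cat
    a = filter_catalog(filter_catalog(cat, dataset="rhea"), radius=1)
    b = filter_catalog(filter_catalog(cat, radius=1), dataset="rhea")
    c = filter_catalog(cat, dataset="rhea", radius=1)
    assert a == b == c
    assert 0 < len(a) < len(cat)


def test_ec_prefix_matching(fixture_catalog):
    full = filter_catalog(fixture_catalog, ec="2.6.1")
    assert len(full) > 0
    for rec in full.records:
        assert any(e.startswith("2.6.1") for e in rec.ec_numbers)
    # an exact fourth-level filter matches itself only
    some_ec = sorted(full.records[0].ec_numbers)[0]
    exact = filter_catalog(fixture_catalog, ec=some_ec)
    assert all(some_ec in rec.ec_numbers for rec in exact.records)


def test_malformed_ec_filter_raises():
    cat = merge(_templates(OXIDATION, "R1", "user"))
    with pytest.raises(QueryError):
        filter_catalog(cat, ec="2.6.x")
    with pytest.raises(QueryError):
        filter_catalog(cat, ec="2.6.1.5.9")


def test_mismatched_dataset_filter_is_empty_not_error(fixture_catalog):
    biochem_only = filter_catalog(fixture_catalog, dataset="rhea")
    assert len(filter_catalog(biochem_only, dataset="uspto")) == 0


def test_template_id_and_reaction_id_filters(fixture_catalog):
    rec = fixture_catalog.records[5]
    hit = filter_catalog(fixture_catalog, template_id=rec.identifier)
    assert [r.identifier for r in hit.records] == [rec.identifier]
    ds = sorted(rec.datasets)[0]
    rid = rec.datasets[ds][0]
    assert rec in filter_catalog(fixture_catalog, reaction_id=rid).records


@pytest.mark.parametrize("fmt", ["tsv", "csv", "json"])
def test_export_import_round_trip(fixture_catalog, tmp_path, fmt):
    p1 = tmp_path / f"cat.{fmt}"
    p2 = tmp_path / f"cat2.{fmt}"
    export(fixture_catalog, p1, fmt)
    back = import_catalog(p1)
    assert back == fixture_catalog
    export(back, p2, fmt)
    assert p1.read_bytes() == p2.read_bytes()


def test_tsv_column_order_is_frozen(fixture_catalog, tmp_path):
    p = tmp_path / "cat.tsv"
    export(fixture_catalog, p, "tsv")
    header = p.read_text().splitlines()[0].split("\t")
    assert header == EXPORT_COLUMNS
    assert EXPORT_COLUMNS == [
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


def test_json_export_validates_against_schema(fixture_catalog, tmp_path):
    p = tmp_path / "cat.json"
    export(fixture_catalog, p, "json")
    doc = json.loads(p.read_text())
    validate_catalog_json(doc)  # must not raise
    doc["records"][0]["identifier"] = "bogus"
    with pytest.raises(ParseError, match="pattern"):
        validate_catalog_json(doc)
    with pytest.raises(ParseError, match="required"):
        validate_catalog_json({"format": "templex-catalog"})
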