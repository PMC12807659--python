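import io

import pytest
from hypothesis import settings
from rdkit import Chem, RDLogger

from templex.catalog import merge
from templex.fixtures import (
    corpus_tsv,
    default_specs,
    generate_corpus,
    worked_example,
)
from templex.reaction_model import read_batch
from templex.template_engine import extract_all

RDLogger.DisableLog("rdApp.*")

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def corpus():
    """The standard >=50-reaction synthetic corpus plus its ground truth."""
    rows, ground_truth = generate_corpus(default_specs())
    reactions = read_batch(io.StringIO(corpus_tsv(rows)))
    return reactions, ground_truth


@pytest.fixture(scope="session")
def corpus_extraction(corpus):
    """All templates and diagnostics from the corpus, both directions,
    radii 0-10."""
    reactions, _ = corpus
    templates, diagnostics = [], []
    for rxn in reactions:
        t, d = extract_all(rxn)
        templates.extend(t)
        diagnostics.extend(d)
    return templates, diagnostics


@pytest.fixture(scope="session")
def fixture_catalog(corpus_extraction):
    return merge(corpus_extraction[0])


@pytest.fixture(scope="session")
def worked():
    return worked_example()


@pytest.fixture(scope="session")
def worked_templates(worked):
    templates, diagnostics = extract_all(worked)
    return templates, diagnostics


def phe_templates(worked_templates):
    """Worked-example forward templates whose focal substrate is
    phenylalanine, keyed by radius."""
    templates, _ = worked_templates
    out = {}
    for t in templates:
        if t.direction != "forward":
            continue
        focal = Chem.MolToSmiles(Chem.Mol(t.component.focal_substrate))
        if "N" in focal:  # phenylalanine is the only N-bearing substrate
            out[t.radius] = t
    return out
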