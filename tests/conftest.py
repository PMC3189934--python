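"""Shared fixtures: hand-built toy ontologies/corpora and a reduced
synthetic bundle (all generated at test time)."""

from __future__ import annotations

import pytest

from gocoherence.fixtures import FixtureSpec, generate_fixture_suite
from gocoherence.ontology_io import AnnotationCorpus, OntologyDAG


def make_dag(parents: dict[str, dict[str, str]], namespace: dict[str, str],
             **kwargs) -> OntologyDAG:
    terms = set(parents) | {p for ps in parents.values() for p in ps}
    return OntologyDAG(
        terms=terms,
        namespace={t: namespace.get(t, "BP") for t in terms},
        parents={t: parents.get(t, {}) for t in terms},
        **kwargs,
    )


@pytest.fixture
def diamond_dag() -> OntologyDAG:
    """a <- b, a <- c, b <- d, c <- d (a is the root), all BP."""
    return make_dag(
        parents={
            "a": {},
            "b": {"a": "is_a"},
            "c": {"a": "is_a"},
            "d": {"b": "is_a", "c": "part_of"},
        },
        namespace={},
    )


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """leaf -> mid -> root, all BP."""
    return make_dag(
        parents={"root": {}, "mid": {"root": "is_a"}, "leaf": {"mid": "is_a"}},
        namespace={},
    )


@pytest.fixture
def toy_corpus() -> AnnotationCorpus:
    """P1{a,b}, P2{a,b}, P3{a}, P4{c} — the worked counting example."""
    return AnnotationCorpus(
        annotations={
            "P1": {("a", "IDA"), ("b", "IDA")},
            "P2": {("a", "IMP"), ("b", "IMP")},
            "P3": {("a", "IDA")},
            "P4": {("c", "IDA")},
        }
    )


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    """Reduced study conditions for unit-level checks (fast to generate)."""
    return FixtureSpec(
        seed=7,
        terms_per_namespace={"BP": 45, "MF": 30, "CC": 15},
        n_proteins=300,
        n_abstracts=400,
        n_planted_pairs=4,
        n_planted_sets=6,
        n_random_sets=6,
        set_size_range=(5, 10),
        n_ppi_pairs=60,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return generate_fixture_suite(small_spec)
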