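"""Single-term and pairwise co-occurrence counting.

Two counting modes feed the association scores:

* ``annotation`` — how many proteins carry a GO term (or an unordered pair
  of terms) in their annotation sets. Raw material for the co-occurrence
  association score (CAS).
* ``abstract`` — how many literature abstracts mention a term or a pair of
  terms. Raw material for the literature association score (PAS). The
  abstract corpus is an offline term-tagged surrogate for Entrez ESearch
  hit counts; :func:`build_esearch_query` constructs the query strings a
  user would need to harvest real counts themselves.

A protein (or abstract) contributes at most 1 to each unordered distinct
term pair regardless of annotation multiplicity, and self pairs (i, i) are
never counted: the scores never compare a term against itself.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

from .ontology_io import AnnotationCorpus, OntologyDAG, propagate

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


class EmptyCorpusError(ValueError):
    """Counting was attempted on an empty corpus."""


def pair_key(a: str, b: str) -> Pair:
    """Canonical (sorted) key for an unordered term pair. a != b required."""
    if a == b:
        raise ValueError(f"self pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class CooccurrenceCounts:
    """Single and pairwise occurrence tallies with corpus totals.

    ``single[i]`` is C(i) (annotation mode) or Pub(i) (abstract mode);
    ``pair[(i, j)]`` with i < j is C(i, j) / Pub(i, j). ``total_single``
    and ``total_pair`` are the corpus-wide sums that normalize the
    association scores.
    """

    single: dict[str, int] = field(default_factory=dict)
    pair: dict[Pair, int] = field(default_factory=dict)
    total_single: int = 0
    total_pair: int = 0
    mode: str = "annotation"

    def get_pair(self, a: str, b: str) -> int:
        if a == b:
            return 0
        return self.pair.get(pair_key(a, b), 0)

    def validate(self) -> None:
        """Check the structural invariants (totals, symmetry bound)."""
        if sum(self.single.values()) != self.total_single:
            raise AssertionError("total_single does not match recomputed sum")
        if sum(self.pair.values()) != self.total_pair:
            raise AssertionError("total_pair does not match recomputed sum")
        for (a, b), c in self.pair.items():
            if a >= b:
                raise AssertionError(f"non-canonical pair key {(a, b)}")
            if c > min(self.single.get(a, 0), self.single.get(b, 0)):
                raise AssertionError(f"pair({a},{b}) exceeds a marginal count")


@dataclass
class AbstractCorpus:
    """Term-tagged abstracts: one record per abstract with the GO terms
    detected in it (deduplicated)."""

    records: list[tuple[str, set[str]]] = field(default_factory=list)


def _tally(term_sets: Iterable[set[str]], mode: str) -> CooccurrenceCounts:
    single: dict[str, int] = {}
    pair: dict[Pair, int] = {}
    n_units = 0
    for terms in term_sets:
        n_units += 1
        for t in terms:
            single[t] = single.get(t, 0) + 1
        for a, b in combinations(sorted(terms), 2):
            pair[(a, b)] = pair.get((a, b), 0) + 1
    if n_units == 0:
        raise EmptyCorpusError(f"cannot count co-occurrence over an empty {mode} corpus")
    return CooccurrenceCounts(
        single=single,
        pair=pair,
        total_single=sum(single.values()),
        total_pair=sum(pair.values()),
        mode=mode,
    )


def count_annotation_cooccurrence(
    corpus: AnnotationCorpus,
    dag: OntologyDAG | None = None,
    propagate_first: bool = True,
) -> CooccurrenceCounts:
    """Tally term and term-pair occurrences over protein annotation sets.

    With ``propagate_first`` (the default, and the convention behind CAS)
    each protein's annotation set is first closed under the true-path rule,
    so parent-level co-occurrence is counted too; ``dag`` is then required.
    """
    if not corpus.annotations:
        raise EmptyCorpusError("annotation corpus is empty")
    if propagate_first:
        if dag is None:
            raise ValueError("propagate_first=True requires a dag")
        corpus = propagate(corpus, dag)
    return _tally(corpus.term_sets().values(), mode="annotation")


def count_abstract_comentions(corpus: AbstractCorpus) -> CooccurrenceCounts:
    """Tally term and term-pair mentions over abstracts.

    Repeated mentions of a term within one abstract count once (record term
    sets are deduplicated by construction).
    """
    if not corpus.records:
        raise EmptyCorpusError("abstract corpus is empty")
    return _tally((set(terms) for _, terms in corpus.records), mode="abstract")


#: Boolean-operator tokens stripped from ESearch query text.
_STOP_TOKENS = {"and", "or", "not"}


def build_esearch_query(
    dag: OntologyDAG,
    term_a: str,
    term_b: str | None = None,
    use_definition: bool = False,
) -> str:
    """Construct an Entrez ESearch ``term=`` query string for one or two
    GO terms.

    The term's name (default) or definition text is lowercased, the
    standalone boolean tokens ``and``/``or``/``not`` are removed, and the
    remaining words are joined with ``+``. For two terms the processed
    texts are concatenated. No network call is made.
    """
    parts = [_query_words(dag, term_a, use_definition)]
    if term_b is not None:
        parts.append(_query_words(dag, term_b, use_definition))
    return "+".join(w for part in parts for w in part)


def _query_words(dag: OntologyDAG, term: str, use_definition: bool) -> list[str]:
    source = dag.definition if use_definition else dag.name
    text = source.get(term)
    if not text:
        kind = "definition" if use_definition else "name"
        raise ValueError(f"term {term!r} has no {kind} text")
    words = text.lower().split()
    return [w for w in words if w not in _STOP_TOKENS]


# ---------------------------------------------------------------------------
# File formats: abstract corpus TSV and count-table import/export.

def read_abstract_corpus(path) -> AbstractCorpus:
    """Read a term-tagged abstract corpus: TSV of
    ``abstract-ID <tab> comma-separated GO IDs``."""
    records: list[tuple[str, set[str]]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            abstract_id, _, terms = line.partition("\t")
            term_set = {t for t in terms.split(",") if t}
            records.append((abstract_id, term_set))
    return AbstractCorpus(records=records)


def write_abstract_corpus(corpus: AbstractCorpus, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for abstract_id, terms in corpus.records:
            fh.write(f"{abstract_id}\t{','.join(sorted(terms))}\n")


def read_counts(single_path, pair_path, mode: str = "abstract") -> CooccurrenceCounts:
    """Import externally harvested count tables: TSV (term, count) and
    (term, term, count). Totals are recomputed from the tables."""
    single: dict[str, int] = {}
    pair: dict[Pair, int] = {}
    with open(single_path, "rt", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            single[row[0]] = int(row[1])
    with open(pair_path, "rt", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            pair[pair_key(row[0], row[1])] = int(row[2])
    counts = CooccurrenceCounts(
        single=single,
        pair=pair,
        total_single=sum(single.values()),
        total_pair=sum(pair.values()),
        mode=mode,
    )
    counts.validate()
    return counts


def write_counts(counts: CooccurrenceCounts, single_path, pair_path) -> None:
    with open(single_path, "wt", encoding="utf-8") as fh:
        for term in sorted(counts.single):
            fh.write(f"{term}\t{counts.single[term]}\n")
    with open(pair_path, "wt", encoding="utf-8") as fh:
        for a, b in sorted(counts.pair):
            fh.write(f"{a}\t{b}\t{counts.pair[(a, b)]}\n")
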