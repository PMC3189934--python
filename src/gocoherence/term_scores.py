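"""Term-pair association and similarity scores.

Three families of term-pair scores live here:

* **CAS** — the co-occurrence association score. For terms *i*, *j* with
  annotation counts C(i), C(j), pair count C(i,j) and corpus totals, ::

      CAS(i,j) = [C(i,j) / Σ C(k,l)] / ([C(i) / Σ C(k)] · [C(j) / Σ C(k)])

  i.e. the observed co-annotation frequency over its expectation under
  independence — the same log-odds-free frequency-ratio normalization used
  for knowledge-based amino-acid contact potentials. CAS ≈ 1 means "as
  expected by chance"; > 1 means enriched association. Cross-namespace
  pairs are first-class citizens.

* **PAS** — the literature association score, the same ratio over abstract
  mention counts Pub(·), except that the corpus-wide scaling factor
  (Σ Pub(k))² / Σ Pub(k,l) is impractical to harvest exhaustively from
  PubMed and is substituted by the corresponding annotation-corpus value
  (:func:`cas_scaling_factor`)::

      PAS(i,j) = Pub(i,j) / (Pub(i)·Pub(j)) · scaling_factor

* **semantic similarity** — a relevance-style information-content score
  over the GO hierarchy, defined only within one namespace::

      sim(c1,c2) = max over common ancestors c of
                   [2·log p(c) / (log p(c1) + log p(c2))] · (1 − p(c))

  where p(c) is the fraction of (namespace-annotated) proteins carrying c
  after propagation. The ancestor set is self-inclusive, so
  sim(c,c) = 1 − p(c); the root (p = 1) contributes 0.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

from .cooccurrence import CooccurrenceCounts, Pair, pair_key
from .ontology_io import NAMESPACES, AnnotationCorpus, OntologyDAG

logger = logging.getLogger(__name__)


class ScoreDomainError(ValueError):
    """Semantic similarity requested for terms in different namespaces."""


@dataclass
class ScoreTable:
    """Sparse symmetric term-pair -> positive score map.

    Absent pairs read as 0 through :meth:`get`; only strictly positive
    scores are stored. ``provenance`` tags the score family
    (``CAS`` / ``PAS`` / ``semantic``).
    """

    scores: dict[Pair, float] = field(default_factory=dict)
    provenance: str = ""

    def get(self, a: str, b: str) -> float:
        # identity lookups only arise for semantic tables, which store the
        # (c, c) diagonal explicitly when positive
        key = (a, b) if a == b else pair_key(a, b)
        return self.scores.get(key, 0.0)

    def set(self, a: str, b: str, value: float) -> None:
        if not math.isfinite(value):
            raise ValueError(f"non-finite score for ({a}, {b}): {value}")
        if value > 0.0:
            key = (a, b) if a == b else pair_key(a, b)
            self.scores[key] = value

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class TermFrequencies:
    """p(c): fraction of proteins annotated with term c after propagation.

    Computed per namespace by default (the denominator is the number of
    proteins with at least one term in c's namespace), so each namespace
    root has p = 1. Terms never annotated are absent and cannot serve as
    ancestors in the semantic score.
    """

    p: dict[str, float] = field(default_factory=dict)
    per_namespace: bool = True

    def get(self, term: str) -> float | None:
        return self.p.get(term)


def cas(counts: CooccurrenceCounts) -> ScoreTable:
    """Co-occurrence association score table from annotation-mode counts.

    Pairs that never co-occur score 0 (implicitly: they are not stored).
    """
    if counts.mode != "annotation":
        raise ValueError(f"cas() needs annotation-mode counts, got {counts.mode!r}")
    if counts.total_pair <= 0:
        raise ValueError("no co-occurring term pairs in the corpus")
    table = ScoreTable(provenance="CAS")
    tp = float(counts.total_pair)
    ts = float(counts.total_single)
    for (a, b), c_ab in counts.pair.items():
        c_a = counts.single.get(a, 0)
        c_b = counts.single.get(b, 0)
        if c_a <= 0 or c_b <= 0:
            raise AssertionError(
                f"pair ({a}, {b}) stored but a marginal count is zero"
            )
        table.scores[(a, b)] = (c_ab / tp) / ((c_a / ts) * (c_b / ts))
    return table


def cas_scaling_factor(counts: CooccurrenceCounts) -> float:
    """(Σ C(k))² / Σ C(k,l) — the annotation-corpus surrogate for the
    PAS scaling factor (Σ Pub(k))² / Σ Pub(k,l)."""
    if counts.total_pair <= 0:
        raise ValueError("scaling factor undefined: no co-occurring pairs")
    return counts.total_single ** 2 / counts.total_pair


def pas(counts: CooccurrenceCounts, scaling_factor: float) -> ScoreTable:
    """Literature association score table from abstract-mode counts.

    ``scaling_factor`` is typically :func:`cas_scaling_factor` of the
    companion annotation corpus.
    """
    if counts.mode != "abstract":
        raise ValueError(f"pas() needs abstract-mode counts, got {counts.mode!r}")
    if not scaling_factor > 0:
        raise ValueError(f"scaling_factor must be positive, got {scaling_factor}")
    table = ScoreTable(provenance="PAS")
    for (a, b), p_ab in counts.pair.items():
        p_a = counts.single.get(a, 0)
        p_b = counts.single.get(b, 0)
        if p_a <= 0 or p_b <= 0:
            raise AssertionError(
                f"pair ({a}, {b}) stored but a marginal count is zero"
            )
        table.scores[(a, b)] = p_ab / (p_a * p_b) * scaling_factor
    return table


def term_frequencies(
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    per_namespace: bool = True,
) -> TermFrequencies:
    """Annotation frequencies p(c) over a *propagated* corpus.

    With ``per_namespace`` (default) the denominator for a term in
    namespace N is the number of proteins with at least one N term, which
    makes each namespace root's frequency exactly 1. With
    ``per_namespace=False`` all annotated proteins form one denominator.
    """
    term_sets = corpus.term_sets()
    counts: dict[str, int] = {}
    ns_denominator: dict[str, int] = dict.fromkeys(NAMESPACES, 0)
    n_proteins = 0
    for terms in term_sets.values():
        if not terms:
            continue
        n_proteins += 1
        seen_ns: set[str] = set()
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
            ns = dag.namespace.get(t)
            if ns:
                seen_ns.add(ns)
        for ns in seen_ns:
            ns_denominator[ns] += 1

    p: dict[str, float] = {}
    for term, c in counts.items():
        if per_namespace:
            ns = dag.namespace.get(term)
            denom = ns_denominator.get(ns, 0) if ns else 0
        else:
            denom = n_proteins
        if denom > 0:
            p[term] = c / denom
    return TermFrequencies(p=p, per_namespace=per_namespace)


def semantic_sim(
    freqs: TermFrequencies,
    dag: OntologyDAG,
    c1: str,
    c2: str,
) -> float:
    """Relevance semantic similarity of two same-namespace terms.

    Maximizes [2·ln p(c) / (ln p(c1) + ln p(c2))]·(1 − p(c)) over the
    self-inclusive common ancestors c of c1 and c2. Ancestors without a
    recorded frequency are skipped (p unknown); if no usable common
    ancestor remains, or the best is a root (p = 1), the score is 0.
    The log base cancels in the ratio, so natural log is used.
    """
    ns1, ns2 = dag.namespace.get(c1), dag.namespace.get(c2)
    if ns1 != ns2 or ns1 is None:
        raise ScoreDomainError(
            f"semantic similarity is defined only within one namespace "
            f"({c1}: {ns1}, {c2}: {ns2})"
        )
    p1, p2 = freqs.get(c1), freqs.get(c2)
    if p1 is None or p2 is None:
        return 0.0
    log_denom = math.log(p1) + math.log(p2)
    common = dag.ancestors(c1) & dag.ancestors(c2)
    best = 0.0
    for c in common:
        pc = freqs.get(c)
        if pc is None:
            continue
        if pc >= 1.0:
            continue  # root-like ancestor: (1 - p) term is 0
        if log_denom == 0.0:
            # both query terms sit at frequency 1; only p(c)=1 ancestors
            # exist above them, already skipped
            continue
        value = (2.0 * math.log(pc) / log_denom) * (1.0 - pc)
        best = max(best, value)
    return best


def semantic_table(
    freqs: TermFrequencies,
    dag: OntologyDAG,
    terms: Iterable[str],
    namespace: str,
) -> ScoreTable:
    """All-pairs (including diagonal) semantic similarities for the given
    terms of one namespace, as a :class:`ScoreTable`."""
    terms = sorted(t for t in terms if dag.namespace.get(t) == namespace)
    table = ScoreTable(provenance="semantic")
    for i, a in enumerate(terms):
        for b in terms[i:]:
            value = semantic_sim(freqs, dag, a, b)
            if value > 0.0:
                table.scores[(a, b)] = value
    return table


def write_score_table(table: ScoreTable, path) -> None:
    """Export as TSV (term, term, score), lexicographic pair order, for
    bit-exact reruns. ``.gz`` paths are gzip-compressed."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt", encoding="utf-8") as fh:
        fh.write(f"#provenance: {table.provenance}\n")
        for a, b in sorted(table.scores):
            fh.write(f"{a}\t{b}\t{table.scores[(a, b)]:.12g}\n")


def read_score_table(path) -> ScoreTable:
    opener = gzip.open if str(path).endswith(".gz") else open
    table = ScoreTable()
    with opener(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#provenance:"):
                table.provenance = line.split(":", 1)[1].strip()
                continue
            if line.startswith("#"):
                continue
            a, b, value = line.split("\t")
            table.set(a, b, float(value))
    return table
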