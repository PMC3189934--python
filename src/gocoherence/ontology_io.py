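"""Gene Ontology and annotation file handling.

Parses the GO hierarchy from OBO flat files into an :class:`OntologyDAG`,
parses GAF association files into an :class:`AnnotationCorpus` with
evidence-code filtering, and implements the annotation preprocessing used
throughout the package: true-path (ancestor-closure) propagation and GO
domain (namespace) restriction.

Only ``is_a`` and ``part_of`` edges participate in the hierarchy; other
relationship types (``regulates`` and friends) do not imply annotation
transfer under the true-path convention and are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: GO namespace codes used throughout the package.
NAMESPACES = ("BP", "MF", "CC")

_NAMESPACE_CODES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}

#: Hierarchy edge types that imply annotation transfer (true-path rule).
DEFAULT_EDGE_TYPES = frozenset({"is_a", "part_of"})


class OntologyError(ValueError):
    """Structural problem in an ontology file (e.g. a cyclic is_a path)."""


class UnknownTermError(KeyError):
    """A term identifier that the ontology does not contain."""


@dataclass
class OntologyDAG:
    """The GO hierarchy: terms, namespaces, and labelled parent edges.

    ``parents`` maps each term to its ``{parent: edge_type}`` dictionary,
    restricted to hierarchy edge types. Obsolete terms are kept in
    ``obsolete`` for reference but excluded from ``terms`` and from all
    traversals. ``alt_ids`` maps secondary identifiers to primary ones.
    """

    terms: set[str]
    namespace: dict[str, str]
    parents: dict[str, dict[str, str]]
    obsolete: set[str] = field(default_factory=set)
    name: dict[str, str] = field(default_factory=dict)
    definition: dict[str, str] = field(default_factory=dict)
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def resolve(self, term: str) -> str | None:
        """Map ``term`` (possibly an alt_id) to its primary id, or None."""
        if term in self.terms:
            return term
        primary = self.alt_ids.get(term)
        if primary in self.terms:
            return primary
        return None

    def roots(self) -> set[str]:
        return {t for t in self.terms if not self.parents.get(t)}

    def children_index(self) -> dict[str, set[str]]:
        """Inverse of ``parents``: term -> set of direct children."""
        idx: dict[str, set[str]] = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for parent in ps:
                idx[parent].add(child)
        return idx

    def ancestors(self, term: str, self_inclusive: bool = True) -> set[str]:
        """Transitive closure of hierarchy edges above ``term``.

        Cached per term; the self-exclusive variant is derived from the
        cached closure.
        """
        if term not in self.terms:
            raise UnknownTermError(f"unknown or obsolete term: {term!r}")
        closure = self._closure(term)
        if self_inclusive:
            return set(closure)
        return set(closure) - {term}

    def _closure(self, term: str) -> frozenset[str]:
        cached = self._ancestor_cache.get(term)
        if cached is not None:
            return cached
        out = {term}
        for parent in self.parents.get(term, ()):
            out |= self._closure(parent)
        result = frozenset(out)
        self._ancestor_cache[term] = result
        return result


@dataclass
class AnnotationCorpus:
    """Protein -> {(GO term, evidence code)} associations for one organism."""

    annotations: dict[str, set[tuple[str, str]]]
    organism: str = ""

    @property
    def proteins(self) -> set[str]:
        return set(self.annotations)

    def term_sets(self) -> dict[str, set[str]]:
        """Per-protein term sets with evidence codes stripped."""
        return {p: {t for t, _ in te} for p, te in self.annotations.items()}

    def n_associations(self) -> int:
        """Number of distinct (protein, term) pairs."""
        return sum(len({t for t, _ in te}) for te in self.annotations.values())


def parse_obo(
    path,
    edge_types: Iterable[str] = DEFAULT_EDGE_TYPES,
) -> OntologyDAG:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyDAG`.

    Retains ``is_a`` and ``part_of`` edges by default; other relationship
    types are dropped. Obsolete terms are recorded but excluded from the
    term set and from traversal. Raises :class:`OntologyError` when the
    retained edges contain a cycle (naming one offending edge).
    """
    edge_types = frozenset(edge_types)
    graph = obonet.read_obo(path, ignore_obsolete=False)

    obsolete = {
        n for n, d in graph.nodes(data=True)
        if str(d.get("is_obsolete", "")).lower() == "true"
    }
    terms: set[str] = set()
    namespace: dict[str, str] = {}
    parents: dict[str, dict[str, str]] = {}
    names: dict[str, str] = {}
    definitions: dict[str, str] = {}
    alt_ids: dict[str, str] = {}

    for node, data in graph.nodes(data=True):
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
        if node in obsolete:
            continue
        terms.add(node)
        ns = _NAMESPACE_CODES.get(data.get("namespace", ""))
        if ns is not None:
            namespace[node] = ns
        names[node] = data.get("name", "")
        if "def" in data:
            definitions[node] = _strip_def(data["def"])
        parents[node] = {}

    hier = nx.DiGraph()
    hier.add_nodes_from(terms)
    for child, parent, rel in graph.edges(keys=True):
        if rel not in edge_types:
            continue
        if child in obsolete or parent in obsolete:
            continue
        if parent not in terms:
            continue
        parents[child][parent] = rel
        hier.add_edge(child, parent, relation=rel)

    if not nx.is_directed_acyclic_graph(hier):
        child, parent, *_ = nx.find_cycle(hier)[0]
        raise OntologyError(
            f"cyclic hierarchy: edge {child} -> {parent} participates in a cycle"
        )

    return OntologyDAG(
        terms=terms,
        namespace=namespace,
        parents=parents,
        obsolete=obsolete,
        name=names,
        definition=definitions,
        alt_ids=alt_ids,
    )


def _strip_def(raw: str) -> str:
    """Strip OBO def quoting and trailing dbxref list: '"text" [refs]' -> text."""
    raw = raw.strip()
    if raw.startswith('"'):
        end = raw.rfind('"')
        if end > 0:
            return raw[1:end]
    return raw


#: GAF rows with these qualifiers deny rather than assert function.
_NEGATIVE_QUALIFIERS = {"NOT"}


def parse_gaf(
    path,
    excluded_evidence: Iterable[str] = ("IEA",),
    dag: OntologyDAG | None = None,
    organism: str = "",
) -> AnnotationCorpus:
    """Parse a GAF 1.0/2.x file into an :class:`AnnotationCorpus`.

    Rows whose evidence code is in ``excluded_evidence`` are dropped, as are
    NOT-qualified rows (they deny function). Duplicate (protein, term)
    entries collapse. When ``dag`` is given, terms are resolved through its
    alt_id map; terms absent from the ontology (version skew) and obsolete
    terms are dropped with a logged warning.
    """
    excluded = set(excluded_evidence)
    annotations: dict[str, set[tuple[str, str]]] = {}
    n_rows = n_skipped = n_unknown = 0

    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("!"):
                continue
            n_rows += 1
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 7:
                n_skipped += 1
                logger.warning("skipping malformed GAF row %d (%d columns)", lineno, len(cols))
                continue
            protein, qualifier, term, evidence = cols[1], cols[3], cols[4], cols[6]
            if not protein or not term:
                n_skipped += 1
                logger.warning("skipping GAF row %d: empty protein or term", lineno)
                continue
            if any(q in _NEGATIVE_QUALIFIERS for q in qualifier.split("|")):
                continue
            if evidence in excluded:
                continue
            if dag is not None:
                resolved = dag.resolve(term)
                if resolved is None:
                    n_unknown += 1
                    continue
                term = resolved
            annotations.setdefault(protein, set()).add((term, evidence))

    if n_unknown:
        logger.warning("dropped %d annotations with terms absent from the ontology", n_unknown)
    if n_rows and not annotations:
        logger.warning("GAF %s: all %d rows filtered out; corpus is empty", path, n_rows)
    logger.info(
        "parsed GAF %s: %d rows, %d malformed, %d proteins kept",
        path, n_rows, n_skipped, len(annotations),
    )
    return AnnotationCorpus(annotations=annotations, organism=organism)


def write_gaf(corpus: AnnotationCorpus, path) -> None:
    """Write a corpus back out as GAF 2.1 (deterministic row order)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.1\n")
        for protein in sorted(corpus.annotations):
            for term, evidence in sorted(corpus.annotations[protein]):
                cols = [""] * 17
                cols[0] = "GC"
                cols[1] = protein
                cols[2] = protein
                cols[4] = term
                cols[6] = evidence
                cols[8] = "P"
                fh.write("\t".join(cols) + "\n")


def ancestors(dag: OntologyDAG, term: str, self_inclusive: bool = True) -> set[str]:
    """Ancestor closure of ``term`` over is_a/part_of edges."""
    return dag.ancestors(term, self_inclusive=self_inclusive)


def propagate(corpus: AnnotationCorpus, dag: OntologyDAG) -> AnnotationCorpus:
    """Apply the true-path rule: replace each protein's terms by their
    self-inclusive ancestor closure.

    Evidence codes carry over from the originating annotation; a term
    reachable from several annotations keeps one entry per distinct
    (term, evidence) pair. Idempotent. Terms not resolvable in ``dag``
    are dropped with a warning.
    """
    out: dict[str, set[tuple[str, str]]] = {}
    n_unknown = 0
    for protein, term_evs in corpus.annotations.items():
        expanded: set[tuple[str, str]] = set()
        for term, evidence in term_evs:
            resolved = dag.resolve(term)
            if resolved is None:
                n_unknown += 1
                continue
            for anc in dag.ancestors(resolved, self_inclusive=True):
                expanded.add((anc, evidence))
        out[protein] = expanded
    if n_unknown:
        logger.warning("propagate: dropped %d annotations with unresolvable terms", n_unknown)
    return AnnotationCorpus(annotations=out, organism=corpus.organism)


def restrict_domains(
    term_set: Iterable[str],
    dag: OntologyDAG,
    keep: Iterable[str],
) -> set[str]:
    """Keep only terms whose namespace is in ``keep`` (subset of BP/MF/CC).

    Terms without a recorded namespace are dropped. Used to build the
    BP⁻ / CC⁻ coherence variants.
    """
    keep = set(keep)
    unknown = keep - set(NAMESPACES)
    if unknown:
        raise ValueError(f"unknown namespaces: {sorted(unknown)}")
    return {t for t in term_set if dag.namespace.get(t) in keep}


def restrict_corpus(
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    keep: Iterable[str],
) -> AnnotationCorpus:
    """Apply :func:`restrict_domains` to every protein's annotation set.

    Proteins may end up with empty term sets; they are retained so that
    downstream set scores remain computable (scoring treats them as 0).
    """
    keep = set(keep)
    out = {
        p: {(t, e) for t, e in te if dag.namespace.get(t) in keep}
        for p, te in corpus.annotations.items()
    }
    return AnnotationCorpus(annotations=out, organism=corpus.organism)


def write_obo(dag: OntologyDAG, path) -> None:
    """Serialize a DAG as a minimal OBO 1.2 file (round-trips via parse_obo)."""
    code_to_ns = {v: k for k, v in _NAMESPACE_CODES.items()}
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: gocoherence-fixture\n")
        for term in sorted(dag.terms | dag.obsolete):
            fh.write("\n[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {dag.name.get(term, term)}\n")
            ns = dag.namespace.get(term)
            if ns:
                fh.write(f"namespace: {code_to_ns[ns]}\n")
            if term in dag.definition:
                fh.write(f'def: "{dag.definition[term]}" [gc:fixture]\n')
            if term in dag.obsolete:
                fh.write("is_obsolete: true\n")
                continue
            for parent, rel in sorted(dag.parents.get(term, {}).items()):
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
        fh.write("\n[Typedef]\nid: part_of\nname: part of\n")
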