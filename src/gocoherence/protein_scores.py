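"""Protein-pair scores built on top of term-pair scores.

The association scores (CAS/PAS) and the semantic similarity are lifted
from term pairs to protein pairs by the best-match average (BMA): every
term of one protein is matched to its best-scoring partner term in the
other protein, the best matches are averaged on each side, and the larger
side is kept. Three published pairwise baselines are implemented alongside:

* **funsim** — per-namespace BMA over semantic similarities, combined as
  the mean of the squared BP/MF/CC scores (so funsim ∈ [0, 1]).
* **Chagoyen** — cosine similarity of information-content-weighted BP
  annotation vectors, w_i = −ln(C(i) / Σ C), over propagated annotations.
* **Pandey** — information content of the set Λ of most specific common
  ancestors of the two proteins' BP∪MF annotation closures:
  −log2(|G_Λ| / |G_r|), where G_Λ is the set of proteins annotated with
  every term of Λ and G_r all proteins in the corpus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .cooccurrence import CooccurrenceCounts
from .ontology_io import NAMESPACES, AnnotationCorpus, OntologyDAG
from .term_scores import ScoreTable

logger = logging.getLogger(__name__)


@dataclass
class ProteinAnnotationProfile:
    """A protein's (propagated) annotations split by namespace, plus an
    optional information-content weight vector (for the Chagoyen score)."""

    protein: str
    terms: dict[str, set[str]] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.terms.values():
            out |= ts
        return out

    def namespace_terms(self, namespace: str) -> set[str]:
        return self.terms.get(namespace, set())


def build_profiles(
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    weights: Mapping[str, float] | None = None,
) -> dict[str, ProteinAnnotationProfile]:
    """Profiles for every protein of a (propagated) corpus.

    Terms lacking a namespace in the DAG are dropped. When ``weights`` is
    given, each profile's BP weight vector is filled from it.
    """
    profiles: dict[str, ProteinAnnotationProfile] = {}
    for protein, terms in corpus.term_sets().items():
        by_ns: dict[str, set[str]] = {ns: set() for ns in NAMESPACES}
        for t in terms:
            ns = dag.namespace.get(t)
            if ns:
                by_ns[ns].add(t)
        profile = ProteinAnnotationProfile(protein=protein, terms=by_ns)
        if weights is not None:
            profile.weights = {
                t: weights[t]
                for t in by_ns["BP"]
                if t in weights and weights[t] > 0.0
            }
        profiles[protein] = profile
    return profiles


def bma_score(
    table: ScoreTable,
    terms_x: Iterable[str],
    terms_y: Iterable[str],
) -> float:
    """Best-match average of ``table`` scores between two term sets.

    side_x = mean over i of max over j of score(x_i, y_j); side_y is
    symmetric; the larger side is returned. An empty side scores 0 (this
    arises legitimately under the BP⁻/CC⁻ domain-exclusion variants).
    """
    xs, ys = list(terms_x), list(terms_y)
    if not xs or not ys:
        logger.debug("bma_score: empty term set, returning 0")
        return 0.0
    side_x = sum(max(table.get(a, b) for b in ys) for a in xs) / len(xs)
    side_y = sum(max(table.get(a, b) for a in xs) for b in ys) / len(ys)
    return max(side_x, side_y)


def go_score(
    semantic_tables: Mapping[str, ScoreTable],
    x: ProteinAnnotationProfile,
    y: ProteinAnnotationProfile,
    namespace: str,
) -> float:
    """Per-namespace BMA over a semantic similarity table (0 when either
    protein has no terms in the namespace)."""
    return bma_score(
        semantic_tables[namespace],
        x.namespace_terms(namespace),
        y.namespace_terms(namespace),
    )


def funsim(
    semantic_tables: Mapping[str, ScoreTable],
    x: ProteinAnnotationProfile,
    y: ProteinAnnotationProfile,
) -> float:
    """Mean of the squared per-namespace semantic BMA scores, in [0, 1]."""
    total = 0.0
    for ns in NAMESPACES:
        total += go_score(semantic_tables, x, y, ns) ** 2
    return total / len(NAMESPACES)


def chagoyen_weights(counts: CooccurrenceCounts) -> dict[str, float]:
    """Information-content weights w_i = −ln(C(i) / Σ C) from BP-only,
    propagated annotation counts.

    The denominator is the total number of protein–term associations in
    the (BP-restricted, propagated) corpus, i.e. ``counts.total_single``.
    A term carrying every association weighs 0; zero-count terms are
    absent.
    """
    if counts.mode != "annotation":
        raise ValueError("chagoyen_weights needs annotation-mode counts")
    total = counts.total_single
    if total <= 0:
        raise ValueError("no associations to weight")
    return {
        term: -math.log(c / total)
        for term, c in counts.single.items()
        if c > 0
    }


def chagoyen_sim(
    x: ProteinAnnotationProfile,
    y: ProteinAnnotationProfile,
) -> float:
    """Cosine of the two proteins' BP weight vectors (terms as axes).

    Either vector empty (no weighted BP terms) scores 0.
    """
    wx, wy = x.weights, y.weights
    if not wx or not wy:
        logger.debug(
            "chagoyen_sim(%s, %s): empty BP weight vector, returning 0",
            x.protein, y.protein,
        )
        return 0.0
    dot = sum(w * wy[t] for t, w in wx.items() if t in wy)
    norm_x = math.sqrt(sum(w * w for w in wx.values()))
    norm_y = math.sqrt(sum(w * w for w in wy.values()))
    if norm_x == 0.0 or norm_y == 0.0:
        return 0.0
    return dot / (norm_x * norm_y)


def _gamma_reduce(terms: set[str], dag: OntologyDAG) -> set[str]:
    """Most specific elements of ``terms``: drop any term that is a strict
    ancestor of another term in the set."""
    redundant: set[str] = set()
    for t in terms:
        redundant |= (dag.ancestors(t, self_inclusive=False) & terms)
    return terms - redundant


def most_informative_common_ancestor(
    dag: OntologyDAG,
    term_index: Mapping[str, set[str]],
    n_proteins: int,
    c_i: str,
    c_j: str,
) -> tuple[str | None, float]:
    """λ(c_i, c_j): the common ancestor with maximal information content
    −log2(|G_c| / |G_r|), where G_c is the set of proteins annotated with c.

    Documented helper for the term-level similarity underlying the Pandey
    score; the protein-pair score itself aggregates over the common
    ancestors of whole annotation sets and does not consume this value.
    """
    common = dag.ancestors(c_i) & dag.ancestors(c_j)
    best: tuple[str | None, float] = (None, 0.0)
    for c in common:
        g_c = len(term_index.get(c, ()))
        if g_c == 0:
            continue
        ic = -math.log2(g_c / n_proteins)
        if ic > best[1]:
            best = (c, ic)
    return best


def pandey_sim(
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    x: str,
    y: str,
    formula_literal: bool = False,
) -> float:
    """Pandey common-ancestor similarity of two proteins.

    ``corpus`` must be propagated and is restricted here to BP and MF
    terms. The common-ancestor set of the two annotation closures is
    γ-reduced to its most specific elements Λ; the score is
    −log2(|G_Λ| / |G_r|) with G_Λ the proteins annotated with all of Λ.
    With ``formula_literal`` the reduction is instead applied to the union
    of the two (non-intersected) annotation sets.

    Convenience wrapper over :class:`PandeyScorer`; build the scorer
    directly when scoring many pairs.
    """
    from ._pairwise import PandeyScorer

    return PandeyScorer(corpus, dag, formula_literal=formula_literal).score(x, y)
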