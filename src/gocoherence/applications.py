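"""Evaluation protocols built on the coherence machinery.

Three study designs are provided: cumulative p-value coverage curves over
collections of protein sets (how many pathways/complexes reach a given
significance level), ROC analysis of interacting vs. non-interacting
protein pairs ranked by empirical pair p-value, and pathway assignment of
query proteins by protein-to-set coherence ranking. Also here: grouping
proteins into co-localization (CC-term) candidate sets, and sparsity
reporting for term-pair score tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._pairwise import as_scorer
from .coherence_stats import CoherenceResult, ProteinSet, protein_to_set
from .ontology_io import AnnotationCorpus, OntologyDAG, propagate, restrict_corpus
from .term_scores import ScoreTable

logger = logging.getLogger(__name__)

#: Namespace-pair labels in reporting order.
NAMESPACE_PAIRS = ("MF-MF", "BP-BP", "CC-CC", "MF-BP", "BP-CC", "CC-MF")
_CROSS_PAIRS = ("MF-BP", "BP-CC", "CC-MF")


def coverage_curve(
    results: Sequence[CoherenceResult | float],
    cutoffs: Iterable[float],
) -> dict[float, float]:
    """Fraction of sets with p ≤ cutoff, per cutoff (cumulative, hence
    non-decreasing in the cutoff)."""
    if len(results) == 0:
        raise ValueError("no results to summarize")
    pvals = np.array(
        [res.p_value if isinstance(res, CoherenceResult) else float(res) for res in results]
    )
    return {c: float((pvals <= c).mean()) for c in cutoffs}


@dataclass
class RocResult:
    """ROC points (FPR, TPR), trapezoidal AUC, and recall of positives at
    the p ≤ 0.05 cutoff."""

    points: list[tuple[float, float]]
    auc: float
    recall_at_p05: float


def ppi_roc(
    positives: Sequence[tuple[str, str]],
    negatives: Sequence[tuple[str, str]],
    pair_score,
    null_scores: Sequence[float],
) -> RocResult:
    """ROC over protein pairs ranked by ascending empirical p-value.

    Each pair's score feeds the add-one empirical p-value against
    ``null_scores``; ties in p (equivalently in score) share a trapezoid
    segment, so the AUC equals the Mann–Whitney statistic of positive vs.
    negative scores. Pairs that cannot be scored (unknown protein, no
    annotations) score 0 and are logged.
    """
    if not positives or not negatives:
        raise ValueError("need non-empty positive and negative pair lists")
    scorer = as_scorer(pair_score)

    def safe_score(x: str, y: str) -> float:
        try:
            return scorer.score(x, y)
        except KeyError:
            logger.warning("pair (%s, %s) not scoreable; scored 0", x, y)
            return 0.0

    pos = np.array([safe_score(x, y) for x, y in positives])
    neg = np.array([safe_score(x, y) for x, y in negatives])

    null = np.sort(np.asarray(null_scores, dtype=float))
    if null.size == 0:
        raise ValueError("empty null distribution")

    def pvalues(scores: np.ndarray) -> np.ndarray:
        # #{null >= v} via binary search on the sorted null
        n_ge = null.size - np.searchsorted(null, scores, side="left")
        return (1 + n_ge) / (null.size + 1)

    recall = float((pvalues(pos) <= 0.05).mean())

    # p is a monotone non-increasing function of the raw score, so the
    # p-ascending / score-descending ranking is the score-descending one
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    points = [(0.0, 0.0)]
    auc = 0.0
    prev_fpr = prev_tpr = 0.0
    for t in thresholds:
        tpr = float((pos >= t).mean())
        fpr = float((neg >= t).mean())
        auc += (fpr - prev_fpr) * (tpr + prev_tpr) / 2.0
        points.append((fpr, tpr))
        prev_fpr, prev_tpr = fpr, tpr
    return RocResult(points=points, auc=auc, recall_at_p05=recall)


@dataclass
class AssignmentResult:
    """Pathway-assignment outcome: the rank (1-based) of each query's true
    set in its coherence-sorted candidate list."""

    ranks: dict[str, tuple[str, int]] = field(default_factory=dict)
    n_candidates: int = 0

    def cumulative_accuracy(self, cutoffs: Iterable[int] | None = None) -> dict[int, float]:
        """Fraction of queries whose true set ranks within each cutoff."""
        if not self.ranks:
            raise ValueError("no assignments recorded")
        ranks = np.array([rank for _, rank in self.ranks.values()])
        if cutoffs is None:
            cutoffs = range(1, self.n_candidates + 1)
        return {c: float((ranks <= c).mean()) for c in cutoffs}


def assign_pathways(
    query: str,
    candidate_sets: Sequence[ProteinSet],
    pair_score,
    exclude_self: bool = True,
) -> list[tuple[str, float, int]]:
    """Rank candidate sets by the query's protein-to-set coherence.

    Returns (set name, coherence, rank) sorted by descending coherence.
    ``exclude_self`` removes the query from sets containing it before
    scoring (leave-one-out). Tied coherences all receive the worst rank of
    the tied group — a conservative convention. A query that scores 0
    against every candidate is flagged with a warning.
    """
    if len(candidate_sets) < 2:
        raise ValueError("need at least 2 candidate sets to rank")
    scorer = as_scorer(pair_score)
    scored = []
    for cand in candidate_sets:
        members = cand.members - {query} if exclude_self else cand.members
        if not members:
            value = 0.0
        else:
            value = protein_to_set(scorer, ProteinSet(cand.name, members), query)
        scored.append((cand.name, value))
    if all(v == 0.0 for _, v in scored):
        logger.warning("query %s has zero coherence to every candidate set", query)
    scored.sort(key=lambda item: -item[1])
    ranked: list[tuple[str, float, int]] = []
    i = 0
    while i < len(scored):
        j = i
        while j < len(scored) and scored[j][1] == scored[i][1]:
            j += 1
        worst = j  # 1-based rank of the last element in the tied group
        ranked.extend((name, value, worst) for name, value in scored[i:j])
        i = j
    return ranked


def evaluate_assignment(
    queries: Sequence[tuple[str, str]],
    candidate_sets: Sequence[ProteinSet],
    pair_score,
    exclude_self: bool = True,
) -> AssignmentResult:
    """Assign every (query protein, true set name) and record the rank at
    which the true set appears."""
    result = AssignmentResult(n_candidates=len(candidate_sets))
    by_name = {s.name for s in candidate_sets}
    for query, true_set in queries:
        if true_set not in by_name:
            raise ValueError(f"true set {true_set!r} not among candidates")
        ranking = assign_pathways(query, candidate_sets, pair_score, exclude_self)
        rank = next(rk for name, _, rk in ranking if name == true_set)
        result.ranks[query] = (true_set, rank)
    return result


def build_gocc_sets(
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
    max_size: int = 100,
    min_size: int = 2,
) -> list[ProteinSet]:
    """Co-localization candidate sets: one set per CC term, containing all
    proteins annotated with it after propagation, size-filtered.

    Very large sets correspond to uninformatively general CC terms and are
    dropped by ``max_size``.
    """
    cc = restrict_corpus(propagate(corpus, dag), dag, keep={"CC"})
    by_term: dict[str, set[str]] = {}
    for protein, terms in cc.term_sets().items():
        for t in terms:
            by_term.setdefault(t, set()).add(protein)
    sets = []
    for term in sorted(by_term):
        members = by_term[term]
        if min_size <= len(members) <= max_size:
            sets.append(ProteinSet(name=term, members=members, source="gocc"))
    return sets


@dataclass
class SparsityReport:
    """How densely a term-pair score table covers the possible pair space.

    ``possible_pairs`` follows the ordered-with-self convention T² by
    default (the convention behind published sparsity percentages);
    ``unordered`` switches to T(T−1)/2.
    """

    n_terms: int
    possible_pairs: int
    nonzero: int
    percent_nonzero: float
    by_namespace_pair: dict[str, int]
    percent_by_namespace_pair: dict[str, float]
    cross_domain: int
    percent_cross_domain: float

    @classmethod
    def from_counts(
        cls,
        n_terms: int,
        by_namespace_pair: Mapping[str, int],
        convention: str = "ordered_with_self",
    ) -> "SparsityReport":
        possible = pair_space(n_terms, convention)
        counts = {k: int(by_namespace_pair.get(k, 0)) for k in NAMESPACE_PAIRS}
        nonzero = sum(counts.values())
        cross = sum(counts[k] for k in _CROSS_PAIRS)
        return cls(
            n_terms=n_terms,
            possible_pairs=possible,
            nonzero=nonzero,
            percent_nonzero=100.0 * nonzero / possible if possible else 0.0,
            by_namespace_pair=counts,
            percent_by_namespace_pair={
                k: (100.0 * v / nonzero if nonzero else 0.0) for k, v in counts.items()
            },
            cross_domain=cross,
            percent_cross_domain=100.0 * cross / nonzero if nonzero else 0.0,
        )


def pair_space(n_terms: int, convention: str = "ordered_with_self") -> int:
    """Number of possible term pairs: T² (ordered with self) or T(T−1)/2."""
    if convention == "ordered_with_self":
        return n_terms * n_terms
    if convention == "unordered":
        return n_terms * (n_terms - 1) // 2
    raise ValueError(f"unknown pair-space convention {convention!r}")


def sparsity_report(
    table: ScoreTable,
    dag: OntologyDAG,
    convention: str = "ordered_with_self",
) -> SparsityReport:
    """Classify a score table's non-zero pairs by namespace pair and
    report coverage of the possible pair space of the DAG's terms."""
    counts = dict.fromkeys(NAMESPACE_PAIRS, 0)
    for a, b in table.scores:
        ns_a = dag.namespace.get(a)
        ns_b = dag.namespace.get(b)
        if ns_a is None or ns_b is None:
            continue
        if f"{ns_a}-{ns_b}" in counts:
            counts[f"{ns_a}-{ns_b}"] += 1
        else:
            counts[f"{ns_b}-{ns_a}"] += 1
    return SparsityReport.from_counts(len(dag.terms), counts, convention)
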