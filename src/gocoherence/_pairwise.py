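"""Pairwise protein scorers with a common interface.

Every scorer exposes ``score(x, y) -> float`` for two protein IDs and
``score_many(xs, ys) -> ndarray`` for a block of pairs. The matrix-backed
scorers precompute, per protein, the vector of best term-level matches
against every term in the universe, which turns the best-match average
into two matrix products; they agree with the naive
:func:`~gocoherence.protein_scores.bma_score` to floating-point identity
and exist purely so that genome-scale reference sets stay tractable.
"""

from __future__ import annotations

import logging
import math
from typing import Callable, Mapping, Sequence

import numpy as np

from .ontology_io import NAMESPACES, AnnotationCorpus, OntologyDAG
from .protein_scores import ProteinAnnotationProfile, _gamma_reduce
from .term_scores import ScoreTable

logger = logging.getLogger(__name__)


class PairScorerBase:
    """Interface shared by all pairwise protein scorers."""

    #: short method tag for result tables (CAS/PAS/funsim/chagoyen/pandey/...)
    tag: str = ""

    def score(self, x: str, y: str) -> float:
        raise NotImplementedError

    def score_many(self, xs: Sequence[str], ys: Sequence[str]) -> np.ndarray:
        """len(xs) × len(ys) block of pair scores (generic slow path)."""
        return np.array([[self.score(x, y) for y in ys] for x in xs])


class FunctionScorer(PairScorerBase):
    """Adapter wrapping a plain ``(x, y) -> float`` callable."""

    def __init__(self, fn: Callable[[str, str], float], tag: str = "custom"):
        self._fn = fn
        self.tag = tag

    def score(self, x: str, y: str) -> float:
        return self._fn(x, y)


def as_scorer(pair_score) -> PairScorerBase:
    """Coerce a callable or scorer into the :class:`PairScorerBase` interface."""
    if isinstance(pair_score, PairScorerBase):
        return pair_score
    if callable(pair_score):
        return FunctionScorer(pair_score)
    raise TypeError(f"not a pair scorer: {pair_score!r}")


class MatrixBMAScorer(PairScorerBase):
    """Best-match-average scorer over a dense term-pair score matrix.

    ``term_sets`` maps each protein to the terms used for its side of the
    comparison (already propagated and, for semantic tables, already
    restricted to one namespace). Proteins with empty term sets score 0
    against everything.
    """

    def __init__(
        self,
        table: ScoreTable,
        term_sets: Mapping[str, set[str]],
        tag: str = "",
    ):
        self.tag = tag or table.provenance
        universe = sorted(set().union(*term_sets.values()) if term_sets else set())
        self._term_index = {t: i for i, t in enumerate(universe)}
        n_terms = len(universe)

        m = np.zeros((n_terms, n_terms))
        for (a, b), value in table.scores.items():
            ia = self._term_index.get(a)
            ib = self._term_index.get(b)
            if ia is None or ib is None:
                continue
            m[ia, ib] = value
            m[ib, ia] = value

        self.proteins = sorted(term_sets)
        self._row = {p: i for i, p in enumerate(self.proteins)}
        n_prot = len(self.proteins)
        # _b[p] : 1/|T_p| on p's term columns; _best[p] : best score from
        # any of p's terms to each term in the universe
        self._b = np.zeros((n_prot, n_terms))
        self._best = np.zeros((n_prot, n_terms))
        for p, i in self._row.items():
            idx = [self._term_index[t] for t in term_sets[p] if t in self._term_index]
            if not idx:
                continue
            self._b[i, idx] = 1.0 / len(idx)
            self._best[i] = m[idx].max(axis=0)

    def score(self, x: str, y: str) -> float:
        ix, iy = self._row[x], self._row[y]
        side_x = float(self._b[ix] @ self._best[iy])
        side_y = float(self._b[iy] @ self._best[ix])
        return max(side_x, side_y)

    def score_many(self, xs: Sequence[str], ys: Sequence[str]) -> np.ndarray:
        rx = [self._row[x] for x in xs]
        ry = [self._row[y] for y in ys]
        side_x = self._b[rx] @ self._best[ry].T
        side_y = (self._b[ry] @ self._best[rx].T).T
        return np.maximum(side_x, side_y)


class FunsimScorer(PairScorerBase):
    """funsim: mean of squared per-namespace semantic BMA scores."""

    tag = "funsim"

    def __init__(
        self,
        semantic_tables: Mapping[str, ScoreTable],
        profiles: Mapping[str, ProteinAnnotationProfile],
        namespaces: Sequence[str] = NAMESPACES,
    ):
        self.namespaces = tuple(namespaces)
        self._per_ns = {
            ns: MatrixBMAScorer(
                semantic_tables[ns],
                {p: prof.namespace_terms(ns) for p, prof in profiles.items()},
                tag=f"GOscore_{ns}",
            )
            for ns in self.namespaces
        }

    def go_scorer(self, namespace: str) -> MatrixBMAScorer:
        """The single-namespace BMA scorer (e.g. the BP-only variant)."""
        return self._per_ns[namespace]

    def score(self, x: str, y: str) -> float:
        total = sum(self._per_ns[ns].score(x, y) ** 2 for ns in self.namespaces)
        return total / len(NAMESPACES)

    def score_many(self, xs: Sequence[str], ys: Sequence[str]) -> np.ndarray:
        total = None
        for ns in self.namespaces:
            block = self._per_ns[ns].score_many(xs, ys) ** 2
            total = block if total is None else total + block
        return total / len(NAMESPACES)


class ChagoyenScorer(PairScorerBase):
    """Cosine similarity of IC-weighted BP annotation vectors."""

    tag = "chagoyen"

    def __init__(self, profiles: Mapping[str, ProteinAnnotationProfile]):
        terms = sorted({t for prof in profiles.values() for t in prof.weights})
        term_index = {t: i for i, t in enumerate(terms)}
        self.proteins = sorted(profiles)
        self._row = {p: i for i, p in enumerate(self.proteins)}
        w = np.zeros((len(self.proteins), len(terms)))
        for p, i in self._row.items():
            for t, weight in profiles[p].weights.items():
                w[i, term_index[t]] = weight
        norms = np.linalg.norm(w, axis=1)
        nonzero = norms > 0
        w[nonzero] /= norms[nonzero, None]
        self._w = w

    def score(self, x: str, y: str) -> float:
        return float(self._w[self._row[x]] @ self._w[self._row[y]])

    def score_many(self, xs: Sequence[str], ys: Sequence[str]) -> np.ndarray:
        rx = [self._row[x] for x in xs]
        ry = [self._row[y] for y in ys]
        return self._w[rx] @ self._w[ry].T


class PandeyScorer(PairScorerBase):
    """Common-ancestor information-content score over BP∪MF closures.

    ``corpus`` must already be propagated; BP/MF restriction happens here.
    """

    tag = "pandey"

    def __init__(
        self,
        corpus: AnnotationCorpus,
        dag: OntologyDAG,
        formula_literal: bool = False,
    ):
        self._dag = dag
        self._literal = formula_literal
        keep = {"BP", "MF"}
        self._terms = {
            p: frozenset(t for t in ts if dag.namespace.get(t) in keep)
            for p, ts in corpus.term_sets().items()
        }
        self.proteins = sorted(self._terms)
        self._n = len(self._terms)
        # term -> set of proteins carrying it (for fast G_Λ intersection)
        self._carriers: dict[str, set[str]] = {}
        for p, ts in self._terms.items():
            for t in ts:
                self._carriers.setdefault(t, set()).add(p)

    def score(self, x: str, y: str) -> float:
        tx, ty = self._terms[x], self._terms[y]
        if not tx or not ty:
            logger.debug("pandey: %s or %s has no BP/MF terms, returning 0", x, y)
            return 0.0
        if self._literal:
            candidate = set(tx | ty)
        else:
            # term sets are ancestor-closed, so the intersection is exactly
            # the common-ancestor set of the two annotation closures
            candidate = set(tx & ty)
        lam = _gamma_reduce(candidate, self._dag)
        if not lam:
            logger.debug("pandey(%s, %s): empty ancestor set Λ, returning 0", x, y)
            return 0.0
        g_lambda: set[str] | None = None
        for t in sorted(lam, key=lambda t: len(self._carriers.get(t, ()))):
            carriers = self._carriers.get(t, set())
            g_lambda = set(carriers) if g_lambda is None else (g_lambda & carriers)
            if not g_lambda:
                break
        # default reading: both input proteins carry every term of Λ, so
        # G_Λ is never empty; the formula-literal reading can produce an
        # empty G_Λ (no protein carries both closures' leaves), which is
        # capped at 1 to keep the score finite
        size = max(len(g_lambda or ()), 1)
        return -math.log2(size / self._n)
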