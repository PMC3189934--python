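"""Protein-pair scores: BMA lifting, funsim, Chagoyen, Pandey, and the
vectorized scorers against their naive counterparts."""

from __future__ import annotations

import math

import numpy as np
import pytest

from gocoherence._pairwise import (
    ChagoyenScorer,
    FunsimScorer,
    MatrixBMAScorer,
    PandeyScorer,
)
from gocoherence.cooccurrence import count_annotation_cooccurrence
from gocoherence.ontology_io import AnnotationCorpus, propagate, restrict_corpus
from gocoherence.protein_scores import (
    ProteinAnnotationProfile,
    bma_score,
    build_profiles,
    chagoyen_sim,
    chagoyen_weights,
    funsim,
    most_informative_common_ancestor,
    pandey_sim,
)
from gocoherence.term_scores import (
    ScoreTable,
    cas,
    semantic_table,
    term_frequencies,
)

from conftest import make_dag


def table_from(scores: dict[tuple[str, str], float]) -> ScoreTable:
    t = ScoreTable(provenance="CAS")
    for (a, b), v in scores.items():
        t.set(a, b, v)
    return t


class TestBmaScore:
    def test_singletons_reduce_to_single_lookup(self):
        t = table_from({("a", "b"): 4.2})
        assert bma_score(t, {"a"}, {"b"}) == pytest.approx(4.2)

    def test_two_by_two_hand_case(self):
        # matrix [[1, 0], [0, 0.5]]: both sides (1 + 0.5)/2
        t = table_from({("a", "x"): 1.0, ("b", "y"): 0.5})
        assert bma_score(t, {"a", "b"}, {"x", "y"}) == pytest.approx(0.75)

    def test_asymmetric_sizes_take_larger_side(self):
        t = ScoreTable(provenance="semantic")
        t.scores[("a", "a")] = 1.0
        # x={a}: side_x = 1; y={a,b}: side_y = (1+0)/2; max = 1
        assert bma_score(t, {"a"}, {"a", "b"}) == pytest.approx(1.0)

    def test_empty_side_scores_zero(self):
        t = table_from({("a", "b"): 1.0})
        assert bma_score(t, set(), {"a"}) == 0.0

    def test_matches_exhaustive_matrix_oracle(self, small_bundle):
        counts = count_annotation_cooccurrence(
            small_bundle.corpus, small_bundle.dag, propagate_first=True
        )
        t = cas(counts)
        term_sets = list(propagate(small_bundle.corpus, small_bundle.dag)
                         .term_sets().values())[:8]
        for xs in term_sets:
            for ys in term_sets:
                cells = [[t.get(a, b) for b in sorted(ys)] for a in sorted(xs)]
                side_x = np.mean([max(row) for row in cells])
                side_y = np.mean([max(col) for col in zip(*cells)])
                assert bma_score(t, xs, ys) == pytest.approx(
                    max(side_x, side_y), abs=1e-9
                )


class TestFunsim:
    def profile(self, **terms):
        return ProteinAnnotationProfile(
            protein="P", terms={ns: set(ts) for ns, ts in terms.items()}
        )

    def test_perfect_match_scores_one(self):
        tables = {}
        for ns, term in (("BP", "b"), ("MF", "m"), ("CC", "c")):
            t = ScoreTable(provenance="semantic")
            t.scores[(term, term)] = 1.0  # hypothetical perfect similarity
            tables[ns] = t
        x = self.profile(BP={"b"}, MF={"m"}, CC={"c"})
        assert funsim(tables, x, x) == pytest.approx(1.0)

    def test_disjoint_scores_zero(self):
        tables = {ns: ScoreTable(provenance="semantic") for ns in ("BP", "MF", "CC")}
        x = self.profile(BP={"b1"})
        y = self.profile(BP={"b2"})
        assert funsim(tables, x, y) == 0.0

    def test_mixed_goscores_hand_case(self):
        # GOscores (1, 0.5, 0) -> (1 + 0.25 + 0)/3
        tables = {ns: ScoreTable(provenance="semantic") for ns in ("BP", "MF", "CC")}
        tables["BP"].scores[("b", "b")] = 1.0
        tables["MF"].scores[("m", "m")] = 0.5
        x = self.profile(BP={"b"}, MF={"m"}, CC={"c1"})
        y = self.profile(BP={"b"}, MF={"m"}, CC={"c2"})
        assert funsim(tables, x, y) == pytest.approx((1 + 0.25 + 0) / 3)

    def test_bounded_by_one_on_fixture(self, small_bundle):
        dag = small_bundle.dag
        corpus = propagate(small_bundle.corpus, dag)
        freqs = term_frequencies(corpus, dag)
        all_terms = {t for ts in corpus.term_sets().values() for t in ts}
        tables = {ns: semantic_table(freqs, dag, all_terms, ns)
                  for ns in ("BP", "MF", "CC")}
        profiles = build_profiles(corpus, dag)
        some = sorted(profiles)[:10]
        for x in some:
            for y in some:
                value = funsim(tables, profiles[x], profiles[y])
                assert 0.0 <= value <= 1.0


class TestChagoyen:
    def test_ubiquitous_term_weighs_zero(self):
        from gocoherence.cooccurrence import CooccurrenceCounts
        counts = CooccurrenceCounts(
            single={"t": 5}, total_single=5, mode="annotation"
        )
        assert chagoyen_weights(counts)["t"] == pytest.approx(0.0)

    def test_weights_match_tally_oracle(self, small_bundle):
        dag = small_bundle.dag
        bp = restrict_corpus(propagate(small_bundle.corpus, dag), dag, keep={"BP"})
        counts = count_annotation_cooccurrence(bp, propagate_first=False)
        weights = chagoyen_weights(counts)
        term_sets = list(bp.term_sets().values())
        total = sum(len(ts) for ts in term_sets)
        for term, w in weights.items():
            c = sum(1 for ts in term_sets if term in ts)
            assert w == pytest.approx(-math.log(c / total), abs=1e-9)

    def test_identical_profiles_cosine_one(self):
        x = ProteinAnnotationProfile("X", weights={"a": 1.0, "b": 2.0})
        y = ProteinAnnotationProfile("Y", weights={"a": 1.0, "b": 2.0})
        assert chagoyen_sim(x, y) == pytest.approx(1.0)

    def test_disjoint_profiles_cosine_zero(self):
        x = ProteinAnnotationProfile("X", weights={"a": 1.0})
        y = ProteinAnnotationProfile("Y", weights={"b": 1.0})
        assert chagoyen_sim(x, y) == 0.0

    def test_two_term_overlap_matches_hand_cosine(self):
        x = ProteinAnnotationProfile("X", weights={"a": 1.0, "b": 2.0})
        y = ProteinAnnotationProfile("Y", weights={"b": 2.0, "c": 1.0})
        expected = 4.0 / (math.sqrt(5) * math.sqrt(5))
        assert chagoyen_sim(x, y) == pytest.approx(expected, abs=1e-9)

    def test_empty_vector_scores_zero(self):
        x = ProteinAnnotationProfile("X", weights={})
        y = ProteinAnnotationProfile("Y", weights={"a": 1.0})
        assert chagoyen_sim(x, y) == 0.0


@pytest.fixture
def pandey_dag():
    """BP diamond root<-m1, root<-m2, {m1,m2}<-leaf1, m1<-leaf2."""
    return make_dag(
        parents={
            "root": {},
            "m1": {"root": "is_a"},
            "m2": {"root": "is_a"},
            "leaf1": {"m1": "is_a", "m2": "is_a"},
            "leaf2": {"m1": "is_a"},
        },
        namespace={},
    )


@pytest.fixture
def pandey_corpus(pandey_dag):
    corpus = AnnotationCorpus(annotations={
        "A": {("leaf1", "IDA")},
        "B": {("leaf2", "IDA")},
        "C": {("m2", "IDA")},
        "D": {("root", "IDA")},
    })
    return propagate(corpus, pandey_dag)


class TestPandey:
    def test_universal_ancestors_score_zero(self, pandey_dag, pandey_corpus):
        # A and D share only the root, carried by all 4 proteins
        assert pandey_sim(pandey_corpus, pandey_dag, "A", "D") == pytest.approx(0.0)

    def test_quarter_population_scores_two(self, pandey_dag, pandey_corpus):
        # A ∩ B closures = {m1, root}; γ -> {m1}; G_{m1} = {A, B} of 4 -> 1 bit
        assert pandey_sim(pandey_corpus, pandey_dag, "A", "B") == pytest.approx(1.0)
        # A with itself: γ of closure -> {leaf1}; only A carries it -> 2 bits
        assert pandey_sim(pandey_corpus, pandey_dag, "A", "A") == pytest.approx(2.0)

    def test_gamma_matches_enumeration_oracle(self, small_bundle):
        dag = small_bundle.dag
        corpus = restrict_corpus(
            propagate(small_bundle.corpus, dag), dag, keep={"BP", "MF"}
        )
        term_sets = corpus.term_sets()
        scorer = PandeyScorer(corpus, dag)
        proteins = sorted(term_sets)[:8]
        for x in proteins:
            for y in proteins:
                common = term_sets[x] & term_sets[y]
                # brute-force minimal elements: no other member is a descendant
                lam = {
                    c for c in common
                    if not any(
                        c in dag.ancestors(other, self_inclusive=False)
                        for other in common
                    )
                }
                if not lam:
                    assert scorer.score(x, y) == 0.0
                    continue
                g = [p for p, ts in term_sets.items() if lam <= ts]
                expected = -math.log2(len(g) / len(term_sets))
                assert scorer.score(x, y) == pytest.approx(expected, abs=1e-9)

    def test_bounded_by_log_population(self, pandey_corpus, pandey_dag):
        for x in "ABCD":
            for y in "ABCD":
                v = pandey_sim(pandey_corpus, pandey_dag, x, y)
                assert 0.0 <= v <= math.log2(4)

    def test_mica_helper(self, pandey_dag, pandey_corpus):
        term_sets = pandey_corpus.term_sets()
        index = {}
        for p, ts in term_sets.items():
            for t in ts:
                index.setdefault(t, set()).add(p)
        term, ic = most_informative_common_ancestor(
            pandey_dag, index, 4, "leaf1", "leaf2"
        )
        assert term == "m1"  # carried by A and B only
        assert ic == pytest.approx(1.0)


@pytest.fixture(scope="module")
def setup(small_bundle):
    dag = small_bundle.dag
    corpus = propagate(small_bundle.corpus, dag)
    counts = count_annotation_cooccurrence(corpus, propagate_first=False)
    table = cas(counts)
    freqs = term_frequencies(corpus, dag)
    all_terms = {t for ts in corpus.term_sets().values() for t in ts}
    sem = {ns: semantic_table(freqs, dag, all_terms, ns)
           for ns in ("BP", "MF", "CC")}
    bp = restrict_corpus(corpus, dag, keep={"BP"})
    bp_counts = count_annotation_cooccurrence(bp, propagate_first=False)
    profiles = build_profiles(corpus, dag, weights=chagoyen_weights(bp_counts))
    return dag, corpus, table, sem, profiles


class TestVectorizedScorers:
    """The matrix engines must agree with the naive implementations."""

    def test_matrix_bma_equals_naive(self, setup):
        dag, corpus, table, _, _ = setup
        term_sets = corpus.term_sets()
        scorer = MatrixBMAScorer(table, term_sets, tag="CAS")
        proteins = sorted(term_sets)[:15]
        for x in proteins:
            for y in proteins:
                assert scorer.score(x, y) == pytest.approx(
                    bma_score(table, term_sets[x], term_sets[y]), abs=1e-9
                )

    def test_funsim_scorer_equals_naive(self, setup):
        dag, corpus, _, sem, profiles = setup
        scorer = FunsimScorer(sem, profiles)
        proteins = sorted(profiles)[:10]
        for x in proteins:
            for y in proteins:
                assert scorer.score(x, y) == pytest.approx(
                    funsim(sem, profiles[x], profiles[y]), abs=1e-9
                )

    def test_chagoyen_scorer_equals_naive(self, setup):
        *_, profiles = setup
        scorer = ChagoyenScorer(profiles)
        proteins = sorted(profiles)[:12]
        for x in proteins:
            for y in proteins:
                assert scorer.score(x, y) == pytest.approx(
                    chagoyen_sim(profiles[x], profiles[y]), abs=1e-9
                )

    def test_score_many_matches_score(self, setup):
        _, corpus, table, _, _ = setup
        term_sets = corpus.term_sets()
        scorer = MatrixBMAScorer(table, term_sets, tag="CAS")
        proteins = sorted(term_sets)[:12]
        block = scorer.score_many(proteins, proteins)
        for i, x in enumerate(proteins):
            for j, y in enumerate(proteins):
                assert block[i, j] == pytest.approx(scorer.score(x, y), abs=1e-12)

    def test_all_scorers_commutative(self, setup):
        dag, corpus, table, sem, profiles = setup
        scorers = [
            MatrixBMAScorer(table, corpus.term_sets(), tag="CAS"),
            FunsimScorer(sem, profiles),
            ChagoyenScorer(profiles),
            PandeyScorer(corpus, dag),
        ]
        proteins = sorted(profiles)[:8]
        for scorer in scorers:
            for x in proteins:
                for y in proteins:
                    assert scorer.score(x, y) == pytest.approx(
                        scorer.score(y, x), abs=1e-12
                    )
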