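"""Synthetic fixture generators with known planted structure.

Every generator is a pure, deterministic function of a
:class:`FixtureSpec`; independent pseudo-random streams are derived from
the master seed by labelled sub-seeding, so adding a generator never
perturbs existing fixtures. The generated artifacts emulate the inputs of
a real analysis — a three-namespace GO-like DAG, a protein annotation
corpus, a term-tagged abstract corpus, coherent protein sets, and a PPI
pair collection — at desk scale:

* term-pair associations are planted on **leaf** terms with a joint
  probability multiplied by an enrichment factor while marginals are
  preserved exactly; propagation then induces parent-level co-occurrence
  the same way real annotation signal arises;
* coherent sets are planted by giving members a shared budget of leaf
  terms; size-matched uniform random sets serve as controls;
* PPI positives are drawn preferentially within planted sets, negatives
  uniformly among cross-set pairs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .coherence_stats import ProteinSet, ReferenceSet
from .cooccurrence import AbstractCorpus
from .ontology_io import AnnotationCorpus, OntologyDAG

_NS_DEF = {"BP": "biological process", "MF": "molecular function", "CC": "cellular component"}


class FixtureSpecError(ValueError):
    """Impossible fixture shape or enrichment parameters."""


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study conditions.

    Defaults define the standard fixture used by the evaluation suites:
    2,000 proteins annotated over a 300-term ontology (150 BP / 100 MF /
    50 CC), ten term pairs planted at 10× enrichment, 25 planted coherent
    sets with 25 size-matched random controls, 3,000 abstracts, and 300
    positive / 300 negative PPI pairs.
    """

    seed: int = 0
    terms_per_namespace: dict[str, int] = field(
        default_factory=lambda: {"BP": 150, "MF": 100, "CC": 50}
    )
    depth: int = 4
    branching: float = 3.0
    second_parent_prob: float = 0.3
    part_of_prob: float = 0.2

    n_proteins: int = 2000
    mean_terms_per_protein: float = 6.0
    n_planted_pairs: int = 10
    planted_multiplier: float = 10.0

    n_abstracts: int = 3000
    mean_mentions_per_abstract: float = 4.0
    comention_multiplier: float = 10.0

    n_planted_sets: int = 25
    n_random_sets: int = 25
    set_size_range: tuple[int, int] = (8, 20)
    shared_term_budget: int = 3
    shared_term_prob: float = 0.8

    n_ppi_pairs: int = 300
    ppi_within_preference: float = 10.0

    def validate(self) -> None:
        if any(v < 1 for v in self.terms_per_namespace.values()):
            raise FixtureSpecError("term counts must be positive")
        if self.depth < 1 or self.branching <= 0:
            raise FixtureSpecError("depth and branching must be positive")
        for name in ("n_proteins", "n_abstracts"):
            if getattr(self, name) < 1:
                raise FixtureSpecError(f"{name} must be positive")
        if self.planted_multiplier < 1 or self.comention_multiplier < 1:
            raise FixtureSpecError("enrichment multipliers must be ≥ 1")
        if self.ppi_within_preference < 1:
            raise FixtureSpecError("ppi_within_preference must be ≥ 1")
        lo, hi = self.set_size_range
        if lo < 2 or hi < lo:
            raise FixtureSpecError(f"bad set size range {self.set_size_range}")


def sub_rng(seed: int, label: str) -> np.random.Generator:
    """Independent generator for one labelled stream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


def generate_ontology(spec: FixtureSpec) -> OntologyDAG:
    """Three rooted namespace DAGs with the requested depth and branching.

    Level sizes follow the branching ratio; each non-root term gets one
    parent in the level above and, with some probability, a second parent
    (creating diamonds). Edges are ``is_a`` or, occasionally, ``part_of``.
    Acyclic by construction (edges only point to shallower levels).
    """
    spec.validate()
    rng = sub_rng(spec.seed, "ontology")
    terms: set[str] = set()
    namespace: dict[str, str] = {}
    parents: dict[str, dict[str, str]] = {}
    names: dict[str, str] = {}
    definitions: dict[str, str] = {}

    counter = 1
    for ns in sorted(spec.terms_per_namespace):
        total = spec.terms_per_namespace[ns]
        levels = _level_sizes(total, spec.depth, spec.branching)
        level_terms: list[list[str]] = []
        for level, size in enumerate(levels):
            current: list[str] = []
            for _ in range(size):
                term = f"GO:{counter:07d}"
                counter += 1
                terms.add(term)
                namespace[term] = ns
                names[term] = f"{_NS_DEF[ns]} term {term[3:]}"
                definitions[term] = f"Synthetic {_NS_DEF[ns]} term number {term[3:]}."
                parents[term] = {}
                if level > 0:
                    above = level_terms[level - 1]
                    first = above[int(rng.integers(len(above)))]
                    rel = "part_of" if rng.random() < spec.part_of_prob else "is_a"
                    parents[term][first] = rel
                    if len(above) > 1 and rng.random() < spec.second_parent_prob:
                        second = above[int(rng.integers(len(above)))]
                        if second != first:
                            parents[term].setdefault(second, "is_a")
                current.append(term)
            level_terms.append(current)

    return OntologyDAG(
        terms=terms,
        namespace=namespace,
        parents=parents,
        name=names,
        definition=definitions,
    )


def _level_sizes(total: int, depth: int, branching: float) -> list[int]:
    """Split ``total`` terms over ``depth`` levels, one root, remaining
    levels weighted by the branching ratio."""
    if depth == 1 or total == 1:
        return [total] if depth == 1 else [1] + [0] * 0
    weights = np.array([branching ** k for k in range(1, depth)])
    rest = total - 1
    raw = weights / weights.sum() * rest
    sizes = np.maximum(np.floor(raw).astype(int), 1 if rest >= depth - 1 else 0)
    # distribute the rounding remainder to the deepest levels
    deficit = rest - sizes.sum()
    i = len(sizes) - 1
    while deficit != 0 and len(sizes) > 0:
        step = 1 if deficit > 0 else -1
        if sizes[i] + step >= 0:
            sizes[i] += step
            deficit -= step
        i = (i - 1) % len(sizes)
    return [1] + sizes.tolist()


def leaf_terms(dag: OntologyDAG) -> list[str]:
    """Terms with no children, sorted."""
    children = dag.children_index()
    return sorted(t for t in dag.terms if not children[t])


def planted_leaf_pairs(spec: FixtureSpec, dag: OntologyDAG) -> list[tuple[str, str]]:
    """The leaf-term pairs carrying planted association signal.

    A pure function of (spec, dag): both the annotation and the abstract
    generator plant enrichment on the same pairs, and recovery tests query
    them independently. Pairs are disjoint (each leaf is used at most
    once) so the planted joint probabilities stay well-defined.
    """
    rng = sub_rng(spec.seed, "planted-pairs")
    leaves = leaf_terms(dag)
    need = 2 * spec.n_planted_pairs
    if need > len(leaves):
        raise FixtureSpecError(
            f"{spec.n_planted_pairs} planted pairs need {need} leaves, "
            f"ontology has {len(leaves)}"
        )
    chosen = rng.choice(leaves, size=need, replace=False)
    return [
        (str(chosen[2 * k]), str(chosen[2 * k + 1]))
        for k in range(spec.n_planted_pairs)
    ]


#: Evidence codes assigned round-robin to generated annotations (all
#: experimental/curated, i.e. kept by the default IEA exclusion).
_EVIDENCE_CODES = ("EXP", "IDA", "IMP", "ISS")


def _draw_term_incidence(
    rng: np.random.Generator,
    n_units: int,
    leaves: list[str],
    rate: float,
    planted: list[tuple[str, str]],
    multiplier: float,
) -> dict[int, set[str]]:
    """Rows of leaf terms for ``n_units`` proteins or abstracts.

    Independent Bernoulli draws at ``rate``, except for planted pairs
    whose joint probability is ``multiplier · rate²`` with both marginals
    held at ``rate`` exactly.
    """
    p11 = multiplier * rate * rate
    if p11 > min(rate, 1.0) or 2 * rate - p11 > 1.0:
        raise FixtureSpecError(
            f"enrichment {multiplier}× at rate {rate:.4f} yields an invalid "
            f"joint probability {p11:.4f}"
        )
    planted_terms = {t for pair in planted for t in pair}
    free = [t for t in leaves if t not in planted_terms]

    draws = rng.random((n_units, len(free))) < rate
    rows: dict[int, set[str]] = {i: set() for i in range(n_units)}
    free_arr = np.array(free)
    for i in range(n_units):
        rows[i].update(free_arr[draws[i]])
    for a, b in planted:
        u = rng.random(n_units)
        both = u < p11
        only_a = (u >= p11) & (u < rate)
        only_b = (u >= rate) & (u < 2 * rate - p11)
        for i in np.nonzero(both)[0]:
            rows[int(i)].update((a, b))
        for i in np.nonzero(only_a)[0]:
            rows[int(i)].add(a)
        for i in np.nonzero(only_b)[0]:
            rows[int(i)].add(b)
    return rows


def generate_annotations(spec: FixtureSpec, dag: OntologyDAG) -> AnnotationCorpus:
    """Annotation corpus: each protein draws leaf terms independently at
    the baseline rate, with planted pairs enriched; every protein is
    guaranteed at least one term (unannotated proteins do not occur in
    annotation databases)."""
    spec.validate()
    rng = sub_rng(spec.seed, "annotations")
    leaves = leaf_terms(dag)
    rate = spec.mean_terms_per_protein / len(leaves)
    planted = planted_leaf_pairs(spec, dag)
    rows = _draw_term_incidence(
        rng, spec.n_proteins, leaves, rate, planted, spec.planted_multiplier
    )
    annotations: dict[str, set[tuple[str, str]]] = {}
    for i in range(spec.n_proteins):
        terms = rows[i]
        if not terms:
            terms = {str(rng.choice(leaves))}
        protein = f"P{i:05d}"
        annotations[protein] = {
            (t, _EVIDENCE_CODES[k % len(_EVIDENCE_CODES)])
            for k, t in enumerate(sorted(terms))
        }
    return AnnotationCorpus(annotations=annotations, organism="synthetic")


def generate_abstracts(spec: FixtureSpec, dag: OntologyDAG) -> AbstractCorpus:
    """Term-tagged abstract corpus mirroring the annotation mechanics,
    with co-mention enrichment on the same planted pairs."""
    spec.validate()
    rng = sub_rng(spec.seed, "abstracts")
    leaves = leaf_terms(dag)
    rate = spec.mean_mentions_per_abstract / len(leaves)
    planted = planted_leaf_pairs(spec, dag)
    rows = _draw_term_incidence(
        rng, spec.n_abstracts, leaves, rate, planted, spec.comention_multiplier
    )
    records = [
        (f"PM{i:07d}", rows[i]) for i in range(spec.n_abstracts) if rows[i]
    ]
    return AbstractCorpus(records=records)


def generate_coherent_sets(
    spec: FixtureSpec,
    corpus: AnnotationCorpus,
    dag: OntologyDAG,
) -> tuple[list[ProteinSet], list[ProteinSet], AnnotationCorpus]:
    """Planted coherent sets, size-matched random controls, and the
    corpus augmented with the planted shared annotations.

    Each planted set draws its members (disjoint across sets) and a budget
    of shared leaf terms; every member receives each shared term with
    probability ``shared_term_prob``. Controls are uniform samples and get
    no shared terms. A budget of 0 leaves planted sets statistically
    identical to controls.
    """
    spec.validate()
    rng = sub_rng(spec.seed, "coherent-sets")
    proteins = sorted(corpus.annotations)
    leaves = leaf_terms(dag)
    lo, hi = spec.set_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_planted_sets)
    if sizes.sum() > len(proteins):
        raise FixtureSpecError(
            f"planted sets need {int(sizes.sum())} distinct proteins, "
            f"corpus has {len(proteins)}"
        )

    annotations = {p: set(te) for p, te in corpus.annotations.items()}
    pool = list(rng.permutation(proteins))
    planted_sets: list[ProteinSet] = []
    for k, size in enumerate(sizes):
        members = {str(p) for p in pool[: int(size)]}
        del pool[: int(size)]
        shared = rng.choice(leaves, size=spec.shared_term_budget, replace=False)
        for member in members:
            for t in shared:
                if rng.random() < spec.shared_term_prob:
                    annotations[member].add((str(t), "IDA"))
        planted_sets.append(
            ProteinSet(name=f"planted_{k:02d}", members=members, source="pathway")
        )

    control_sizes = rng.integers(lo, hi + 1, size=spec.n_random_sets)
    random_sets = [
        ProteinSet(
            name=f"control_{k:02d}",
            members={str(p) for p in rng.choice(proteins, size=int(size), replace=False)},
            source="random",
        )
        for k, size in enumerate(control_sizes)
    ]
    augmented = AnnotationCorpus(annotations=annotations, organism=corpus.organism)
    return planted_sets, random_sets, augmented


def generate_ppi(
    spec: FixtureSpec,
    sets: list[ProteinSet],
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Positive and negative PPI pair lists.

    A positive is drawn from within a random planted set with probability
    1 − 1/preference (sets weighted by their number of pairs), otherwise
    uniformly from the whole pool; preference 1 therefore means uniform
    sampling and no signal. Negatives are uniform cross-set pairs. The two
    lists are disjoint and contain no duplicates.
    """
    spec.validate()
    rng = sub_rng(spec.seed, "ppi")
    pool = sorted({p for s in sets for p in s.members})
    if len(pool) < 4:
        raise FixtureSpecError("need at least 4 proteins across sets for PPI pairs")
    set_of: dict[str, int] = {}
    for k, s in enumerate(sets):
        for p in s.members:
            set_of[p] = k
    members_by_set = [sorted(s.members) for s in sets]
    weights = np.array([len(m) * (len(m) - 1) / 2 for m in members_by_set], dtype=float)
    if weights.sum() == 0:
        raise FixtureSpecError("sets too small to contain pairs")
    weights /= weights.sum()
    within_prob = 1.0 - 1.0 / spec.ppi_within_preference

    def uniform_pair() -> tuple[str, str]:
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[int(i)], pool[int(j)]
        return (a, b) if a < b else (b, a)

    positives: set[tuple[str, str]] = set()
    guard = 0
    while len(positives) < spec.n_ppi_pairs:
        guard += 1
        if guard > 100 * spec.n_ppi_pairs:
            raise FixtureSpecError("insufficient distinct pairs for PPI positives")
        if rng.random() < within_prob:
            k = int(rng.choice(len(sets), p=weights))
            members = members_by_set[k]
            i, j = rng.choice(len(members), size=2, replace=False)
            a, b = members[int(i)], members[int(j)]
            pair = (a, b) if a < b else (b, a)
        else:
            pair = uniform_pair()
        positives.add(pair)

    negatives: set[tuple[str, str]] = set()
    guard = 0
    while len(negatives) < spec.n_ppi_pairs:
        guard += 1
        if guard > 100 * spec.n_ppi_pairs:
            raise FixtureSpecError("insufficient distinct cross-set pairs for negatives")
        pair = uniform_pair()
        if set_of.get(pair[0]) == set_of.get(pair[1]):
            continue
        if pair in positives:
            continue
        negatives.add(pair)
    return sorted(positives), sorted(negatives)


def random_protein_pairs(
    proteins: list[str],
    n: int,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Uniform random protein pairs (with replacement across pairs) — the
    null population for empirical pair p-values."""
    proteins = sorted(proteins)
    idx = rng.integers(0, len(proteins), size=(n, 2))
    # re-draw the rare self pairs
    for row in range(n):
        while idx[row, 0] == idx[row, 1]:
            idx[row, 1] = rng.integers(0, len(proteins))
    return [(proteins[int(i)], proteins[int(j)]) for i, j in idx]


@dataclass
class FixtureBundle:
    """Everything the evaluation protocols need, generated from one spec."""

    spec: FixtureSpec
    dag: OntologyDAG
    corpus: AnnotationCorpus
    abstracts: AbstractCorpus
    planted_pairs: list[tuple[str, str]]
    planted_sets: list[ProteinSet]
    random_sets: list[ProteinSet]
    ppi_positives: list[tuple[str, str]]
    ppi_negatives: list[tuple[str, str]]

    @property
    def reference(self) -> ReferenceSet:
        return ReferenceSet(members=set(self.corpus.annotations))


def generate_fixture_suite(spec: FixtureSpec) -> FixtureBundle:
    """Run every generator in sequence and bundle the artifacts."""
    dag = generate_ontology(spec)
    base_corpus = generate_annotations(spec, dag)
    abstracts = generate_abstracts(spec, dag)
    planted_sets, random_sets, corpus = generate_coherent_sets(spec, base_corpus, dag)
    positives, negatives = generate_ppi(spec, planted_sets)
    return FixtureBundle(
        spec=spec,
        dag=dag,
        corpus=corpus,
        abstracts=abstracts,
        planted_pairs=planted_leaf_pairs(spec, dag),
        planted_sets=planted_sets,
        random_sets=random_sets,
        ppi_positives=positives,
        ppi_negatives=negatives,
    )
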