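# Methods

## Model

`gocoherence` treats Gene Ontology (GO) terms as vocabulary items whose
*association* is measured empirically in two corpora, rather than inferred
from the GO hierarchy.

**Annotation co-occurrence (CAS).** Let `C(i)` be the number of proteins
whose annotation set contains term *i*, and `C(i,j)` the number containing
both *i* and *j* (i ≠ j). Annotation sets are first closed under the
true-path rule — a term implies all its `is_a`/`part_of` ancestors — so
parent-level associations are counted implicitly; annotations with the IEA
evidence code are excluded beforehand, as are NOT-qualified rows. The score

```
CAS(i,j) = [C(i,j) / Σ_{k<l} C(k,l)] / ([C(i)/Σ_k C(k)] · [C(j)/Σ_k C(k)])
```

is the observed co-annotation frequency over its expectation under
independent term marginals, the same ratio construction as knowledge-based
amino-acid contact potentials. Pairs that never co-occur score 0 and are
not stored.

*Counting conventions.* One protein contributes at most 1 to each unordered
distinct term pair, regardless of evidence multiplicity; self pairs (i,i)
are never counted; `Σ C(k,l)` sums unordered pairs once. Any consistent
convention rescales all scores by one corpus-wide constant, so rankings,
ROC curves and hypergeometric p-values are unaffected. One visible
consequence of the unordered-pair total: for a corpus whose proteins carry
on average t (propagated) terms, the chance level of CAS is ≈ 2t/(t−1)·
(a value slightly below 2 in practice once the conditioning on observed
pairs is included), not exactly 1. The null-calibration check therefore
brackets the observed-pair median in [0.5, 2.0] rather than pinning it at 1.

**Literature co-mention (PAS).** `Pub(i)` and `Pub(i,j)` count abstracts
mentioning a term or a pair of terms. The corpus-wide totals `Σ Pub(k)` and
`Σ Pub(k,l)` cannot realistically be harvested from PubMed, so the score
substitutes the annotation-corpus scaling factor:

```
PAS(i,j) = Pub(i,j) / (Pub(i)·Pub(j)) · (Σ_k C(k))² / Σ_{k<l} C(k,l)
```

Counts come from an offline term-tagged abstract corpus (TSV: abstract ID,
comma-separated GO IDs) or from imported count tables.
`build_esearch_query` constructs Entrez ESearch query strings — term name
(default) or definition text, lowercased, with standalone boolean tokens
`and`/`or`/`not` removed, joined by `+` — for users who want to harvest
counts themselves; the package itself never touches the network.

**Protein pairs.** A term-pair table lifts to protein pairs by the
best-match average: with annotation sets T_x, T_y,

```
side_x = mean_{i∈T_x} max_{j∈T_y} score(i,j);   BMA = max(side_x, side_y)
```

For CAS/PAS tables cross-namespace lookups are legal; for semantic tables
cross-namespace cells are 0. A protein whose (possibly domain-filtered)
annotation set is empty scores 0 against everything — this keeps the
BP⁻/CC⁻ variants and set averages total.

**Sets.** `coherence(S)` is the mean pair score over all unordered member
pairs; `coherence(S, P)` the mean of P against the members. Significance:
count `s` members and `r` reference proteins whose protein-to-set coherence
reaches `coherence(S)`, then take the hypergeometric upper tail
P(X ≥ s) for X ~ Hypergeom(|R|, r, |S|) (`scipy.stats.hypergeom`, which
evaluates the tail in log space — stable at genome-scale |R|).

*Member self-exclusion.* A member's own protein-to-set coherence is
computed against the **other** members by default. Including the self pair
(BMA of a protein with itself) hands every member a bonus that reference
proteins cannot earn; measured on the standard fixture that inflation makes
the majority of uniform random control sets "significant" at p ≤ 0.05,
destroying the planted-versus-random contrast the statistic exists for.
Both this switch (`exclude_self`) and whether members count in the
reference tally (`include_members_in_reference`, default on, with the
population reduced to R∖S when off) are explicit arguments.

**Baselines.**

* *Semantic similarity / funsim.* `sim(c1,c2) = max_c [2·ln p(c) /
  (ln p(c1)+ln p(c2))]·(1−p(c))` over the self-inclusive common ancestors
  c, where p(c) is the fraction of (per-namespace) annotated proteins
  carrying c after propagation. Self-inclusive ancestors make
  `sim(c,c) = 1−p(c)`; the log base cancels in the ratio (only the (1−p)
  factor breaks scale invariance), so natural log is used. p(c) is computed
  per namespace by default (each namespace root has p = 1 exactly); a
  global denominator is available. Ancestors never annotated have no
  defined frequency and cannot serve as the maximizing ancestor. funsim is
  the mean of the squared per-namespace BMA scores, hence in [0, 1].
* *Chagoyen.* BP-only, propagated annotation vectors weighted by
  information content, `w_i = −ln(C(i)/Σ C)` with Σ C the total number of
  protein–BP-term associations; protein similarity is the cosine of the two
  weight vectors.
* *Pandey.* Over BP∪MF propagated closures, the common-ancestor set of two
  proteins is the intersection of their closures; it is reduced by γ to its
  most specific elements Λ (drop any term that is a strict ancestor of
  another member). The score is −log₂(|G_Λ|/|G_r|), G_Λ being the proteins
  annotated with every term of Λ. A formula-literal variant (γ applied to
  the union of the two annotation sets instead of the intersection of
  closures) is available behind a flag; under that reading G_Λ can be
  empty and its size is capped at 1 to keep the score finite. The
  most-informative-common-ancestor of a single term pair is provided as a
  documented helper but does not enter the pairwise score.

**Evaluations.** Pair significance is the add-one empirical tail
`p = (1 + #{null ≥ score})/(N+1)` against a seeded random-pair null (no
zero p-values). ROC curves rank pairs by ascending p-value — a monotone
non-increasing function of the raw score, so ties in p are ties in score —
with tied groups sharing one trapezoid segment; the AUC therefore equals
the Mann–Whitney statistic and is permutation invariant. Pathway assignment
ranks candidate sets by `coherence(S, P)` descending, with leave-one-out
applied when the query belongs to a candidate (switchable) and tied
coherences all assigned the worst rank of the tied group (conservative).
Co-localization candidate sets are built per CC term from propagated CC
annotations, keeping sets of 2–100 members by default (larger sets belong
to uninformatively general terms). Sparsity reports use T² as the size of
the possible-pair space (the convention behind published coverage
percentages such as 29,278² = 857,201,284); unordered-distinct counting is
available as an alternative.

## Implementation notes

The `MatrixBMAScorer` precomputes, per protein, the vector of best
term-level matches against every term (a dense T×T score matrix), turning
BMA into two matrix products; it agrees with the naive double-loop
implementation to 1e-9 (asserted in the test suite, which keeps both
paths). Genome-scale reference sweeps (2,000 proteins × 50 sets) take
fractions of a second this way. Scores are stored sparsely (only positive
values), exported as deterministic lexicographically ordered TSV for
bit-exact reruns.

## Synthetic study conditions

The fixture generators are first-class, tested code; every generator is a
pure function of a `FixtureSpec` and derives one labelled pseudo-random
stream per generator from the master seed (so adding a generator never
perturbs existing fixtures). Defaults define the standard conditions used
by the evaluation suites:

| parameter | default | meaning |
|---|---|---|
| terms per namespace | 150 BP / 100 MF / 50 CC | DAG size, depth 4, branching 3 |
| second-parent probability | 0.3 | creates diamonds |
| part_of edge probability | 0.2 | mixed edge types |
| proteins | 2,000 | annotation corpus size |
| mean leaf terms/protein | 6 | baseline Bernoulli rate over leaves |
| planted term pairs | 10 at 10× | joint probability m·p², marginals exact |
| abstracts | 3,000, mean 4 mentions | literature corpus |
| planted sets | 25 of size 8–20, 3 shared leaf terms at 0.8 | coherent signal |
| random control sets | 25, size-matched | null sets |
| PPI pairs | 300 + 300, within-set preference 10 | positives/negatives |

Planted associations act on **leaf** terms with the joint probability of a
pair multiplied by the enrichment factor while both marginals are held
exact; propagation then induces parent-level co-occurrence the way real
annotation signal arises. Planted coherent sets are disjoint; controls are
uniform samples. PPI positives mix within-set pairs (fraction 1−1/w for
preference w) with uniform pairs; negatives are uniform cross-set pairs,
disjoint from the positives.

What the generator does **not** emulate: the real GO's topology (term
depths, fan-out and annotation frequencies are far more skewed), annotation
bias toward well-studied proteins, evidence-code structure beyond a
round-robin of experimental codes, literature text (abstracts are term
lists, so PAS here has no NLP or MeSH-synonym component), and database
version skew. Passing suites therefore demonstrate correctness of the
computations and the expected qualitative behaviour of the scores
(calibration, recovery, discrimination), not quantitative agreement with
any archived GOA/PubMed snapshot — snapshot-scale figures quoted in
docstrings are reproducible only against those archives.

## Problem sizes and numerical choices

The validation suite runs the standard 2,000-protein conditions: 20
replicate corpora for planted-pair recovery, 25+25 sets for detection
rates, 500 random sets per size 10…100 for size invariance (max deviation
from the grand mean ≈ 0.3%, far under the 20% flatness band), and a
10,000-pair null for PPI p-values. Equation-level checks run exhaustively
on ≤ 50-protein corpora against brute-force oracles at 1e-9; the
hypergeometric tail is checked against full subset enumeration at |R| = 12.
Hypergeometric p-values are clamped to (0, 1]; empirical p-values use
add-one smoothing; BMA ties and ROC ties break as described above. All
randomness flows from explicit seeds; results files record the seed.

## Known limitations

* PAS quality is bounded by the tagging of the abstract corpus; no synonym
  expansion is performed offline (real Entrez queries would get MeSH
  expansion for free).
* CAS/PAS raw values are convention-dependent up to a corpus-wide constant
  (see counting conventions); only comparisons within one corpus are
  meaningful.
* The Pandey score degrades toward 0 whenever the γ-reduced common-ancestor
  set is carried by many proteins; with shallow synthetic DAGs this happens
  often, which mirrors its weak published performance but means fixture
  results exercise it less sharply than the other scores.
* `parse_obo` handles the OBO subset relevant here (is_a, part_of
  relationships, obsolete flags, alt_ids); intersection/cross-product
  constructs and taxon constraints are out of scope.
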