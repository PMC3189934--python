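# gocoherence

Functional **coherence** scoring for protein sets from Gene Ontology term
associations.

Proteins that work together — in one pathway, one complex, one compartment —
are often *not* functionally similar: enzymes of a single KEGG pathway carry
different molecular-function annotations and frequently do not even share a
biological-process term. Hierarchy-based GO similarity measures therefore
miss functional units in omics data. `gocoherence` instead scores how
strongly two GO terms are **associated** in observed biological contexts,
and lifts that to proteins and protein sets:

* **CAS** (co-occurrence association score) — how often two terms co-occur
  in the annotations of single proteins, relative to chance:

  ```
  CAS(i,j) = [C(i,j) / Σ C(k,l)] / ([C(i) / Σ C(k)] · [C(j) / Σ C(k)])
  ```

  where `C(i)` counts proteins annotated with term *i* (after true-path
  propagation, IEA evidence excluded) and `C(i,j)` counts proteins carrying
  both terms. The normalization is the frequency-ratio scheme used for
  knowledge-based amino-acid contact potentials. Terms from *different* GO
  namespaces (MF–BP, BP–CC, CC–MF) are scored exactly like same-namespace
  pairs — associations are not confined to the hierarchy.

* **PAS** (literature association score) — the same ratio over co-mentions
  of term pairs in PubMed abstracts, `Pub(i,j)/(Pub(i)·Pub(j))`, scaled by
  the annotation-corpus factor `(Σ C(k))² / Σ C(k,l)` (the corpus-wide
  literature totals are impractical to harvest). Counts come from an
  offline term-tagged abstract corpus or from externally harvested Entrez
  ESearch counts; the package builds the query strings but never calls the
  network.

Term-pair scores become protein-pair scores by the best-match average
(BMA): each term of one protein is matched with its best-scoring partner in
the other protein, both directions are averaged and the larger side kept.
The coherence of a set *S* of *n* proteins is the mean pair score over all
n(n−1)/2 member pairs, and its significance is a hypergeometric tail
probability: with *s* members and *r* of the |R| reference proteins whose
protein-to-set coherence reaches the set's own mean,

```
p = Σ_{i=s}^{|S|}  C(r,i) · C(|R|−r, |S|−i) / C(|R|, |S|)
```

Three published baselines are implemented for comparison: **funsim**
(per-namespace information-content similarity, mean of squared BMA scores),
the **Chagoyen** score (cosine of IC-weighted BP annotation vectors) and the
**Pandey** score (information content of the most specific common ancestors
of two proteins' BP∪MF annotation closures). Evaluation protocols cover
coherent-set detection (p-value coverage curves, with BP⁻/CC⁻
domain-exclusion variants), discrimination of interacting protein pairs
(empirical pair p-values against a random-pair null, ROC/AUC), and pathway
assignment by coherence ranking.

## Worked example

Everything runs offline on synthetic fixtures with planted structure — a
three-namespace GO-like DAG, an annotation corpus with ten term pairs
enriched 10-fold over independence, 25 planted coherent sets plus 25 random
controls over 2,000 proteins:

```python
from gocoherence import (
    cas, count_annotation_cooccurrence, set_pvalue, MatrixBMAScorer, propagate,
)
from gocoherence.fixtures import FixtureSpec, generate_fixture_suite

bundle = generate_fixture_suite(FixtureSpec(seed=1))
counts = count_annotation_cooccurrence(bundle.corpus, bundle.dag, propagate_first=True)
table = cas(counts)
print(f"non-zero CAS pairs: {len(table)}")
a, b = bundle.planted_pairs[0]
print(f"planted pair CAS({a}, {b}) = {table.get(a, b):.2f}")

scorer = MatrixBMAScorer(table, propagate(bundle.corpus, bundle.dag).term_sets(), tag="CAS")
for protein_set in (bundle.planted_sets[0], bundle.random_sets[0]):
    r = set_pvalue(scorer, protein_set, bundle.reference)
    print(f"set {r.set_name}: coherence = {r.coherence:.2f}, "
          f"s = {r.s}/{r.n}, r = {r.r}/{r.n_reference}, p = {r.p_value:.3g}")
```

prints

```
non-zero CAS pairs: 41531
planted pair CAS(GO:0000128, GO:0000096) = 11.41
set planted_00: coherence = 6.61, s = 11/17, r = 24/2000, p = 5.97e-19
set control_00: coherence = 4.43, s = 6/15, r = 1091/2000, p = 0.919
```

The planted pair scores an order of magnitude above chance; the planted set
has 11 of 17 members above its own mean coherence versus only 24 of 2,000
reference proteins, giving a vanishing p-value, while the random control is
indistinguishable from background (p ≈ 0.92).

The same pipelines are available from the shell — `gocoherence
make-fixtures`, `build-counts`, `score-terms`, `score-pairs`, `coherence`,
`ppi-roc`, `assign`, `report-sparsity` — all deterministic under `--seed`;
see `gocoherence --help`.

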