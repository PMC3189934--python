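"""Set-level coherence scores and their statistical significance.

The coherence of a protein set S is the mean pairwise score over all
unordered member pairs; the coherence of a single protein P to S is the
mean of its pair scores against the members. Significance of a set's
coherence is assessed with a hypergeometric tail: with s members and r
reference proteins whose protein-to-set coherence reaches the set's own
mean, the p-value is the probability of drawing ≥ s such proteins in |S|
draws from a reference population of |R| containing r of them::

    p = Σ_{i=s}^{|S|} C(r, i) · C(|R|−r, |S|−i) / C(|R|, |S|)

Pair-level significance uses an empirical null of random protein pairs
with the add-one estimator p = (1 + #{null ≥ score}) / (N + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom

from ._pairwise import PairScorerBase, as_scorer

logger = logging.getLogger(__name__)


class SetSizeError(ValueError):
    """A protein set too small (or a reference too small) for the requested
    statistic."""


@dataclass
class ProteinSet:
    """A named group of proteins (pathway, complex, co-localization set,
    or a random control)."""

    name: str
    members: set[str]
    source: str = "pathway"

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class ReferenceSet:
    """All annotated proteins of the organism — the population R against
    which set coherence is calibrated."""

    members: set[str]

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class CoherenceResult:
    set_name: str
    method: str
    coherence: float
    n: int
    s: int
    r: int
    n_reference: int
    p_value: float
    variant: str = "none"
    seed: int | None = None


def set_coherence(pair_score, S: ProteinSet) -> float:
    """Mean pair score over all n(n−1)/2 unordered member pairs."""
    if S.n < 2:
        raise SetSizeError(f"set {S.name!r} has {S.n} members; need ≥ 2")
    scorer = as_scorer(pair_score)
    members = sorted(S.members)
    block = scorer.score_many(members, members)
    iu = np.triu_indices(len(members), k=1)
    return float(block[iu].mean())


def protein_to_set(
    pair_score,
    S: ProteinSet,
    protein: str,
    exclude_self: bool = False,
) -> float:
    """Mean pair score of ``protein`` against the members of S.

    With ``exclude_self`` the protein is first removed from S if present.
    """
    scorer = as_scorer(pair_score)
    members = sorted(S.members - {protein} if exclude_self else S.members)
    if not members:
        raise SetSizeError(f"set {S.name!r} empty after excluding {protein!r}")
    return float(scorer.score_many([protein], members).mean())


def set_pvalue(
    pair_score,
    S: ProteinSet,
    R: ReferenceSet,
    exclude_self: bool = True,
    include_members_in_reference: bool = True,
    variant: str = "none",
    seed: int | None = None,
) -> CoherenceResult:
    """Hypergeometric significance of the coherence of S against R.

    The qualification criterion is coherence(P, S) ≥ coherence(S). By
    default a member's own protein-to-set coherence is computed against
    the *other* members (``exclude_self=True``): including the self pair
    score hands every member a large self-match bonus that reference
    proteins cannot have, which makes even uniform random sets look
    significant. Members count in the reference tally
    (``include_members_in_reference=True``). Both choices are switchable.
    """
    if S.n < 2:
        raise SetSizeError(f"set {S.name!r} has {S.n} members; need ≥ 2")
    if len(R) < S.n:
        raise SetSizeError(
            f"reference ({len(R)}) smaller than set {S.name!r} ({S.n})"
        )
    scorer = as_scorer(pair_score)
    members = sorted(S.members)
    reference = sorted(
        R.members if include_members_in_reference else R.members - S.members
    )
    if len(reference) < S.n:
        raise SetSizeError(
            f"reference population ({len(reference)}) smaller than set size {S.n}"
        )

    member_block = scorer.score_many(members, members)
    iu = np.triu_indices(len(members), k=1)
    coherence = float(member_block[iu].mean())

    if exclude_self:
        # member i's coherence to S excludes the diagonal self-score
        member_coh = (member_block.sum(axis=1) - np.diag(member_block)) / (S.n - 1)
    else:
        member_coh = member_block.mean(axis=1)
    s = int((member_coh >= coherence).sum())

    ref_block = scorer.score_many(reference, members)
    if exclude_self:
        member_pos = {p: i for i, p in enumerate(members)}
        ref_coh = np.empty(len(reference))
        for i, p in enumerate(reference):
            j = member_pos.get(p)
            if j is None:
                ref_coh[i] = ref_block[i].mean()
            else:
                ref_coh[i] = (ref_block[i].sum() - ref_block[i, j]) / (S.n - 1)
    else:
        ref_coh = ref_block.mean(axis=1)
    r = int((ref_coh >= coherence).sum())

    # with members excluded, the population is R \ S and r counts only
    # non-members; tail terms with i > r are impossible and contribute 0
    n_ref = len(reference)
    # P(X ≥ s) for X ~ Hypergeom(population n_ref, r successes, |S| draws);
    # scipy evaluates the tail in log space, stable up to genome-scale |R|
    p = float(hypergeom.sf(s - 1, n_ref, r, S.n))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return CoherenceResult(
        set_name=S.name,
        method=scorer.tag,
        coherence=coherence,
        n=S.n,
        s=s,
        r=r,
        n_reference=n_ref,
        p_value=p,
        variant=variant,
        seed=seed,
    )


def pair_pvalue(pair_score, x: str, y: str, null_scores: Sequence[float]) -> float:
    """Empirical p-value of a protein pair's score against a random-pair
    null, with add-one smoothing: p = (1 + #{v ≥ score}) / (N + 1)."""
    scorer = as_scorer(pair_score)
    return score_pvalue(scorer.score(x, y), null_scores)


def score_pvalue(score: float, null_scores: Sequence[float]) -> float:
    """Add-one empirical tail probability of ``score`` under the null."""
    null = np.asarray(null_scores, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    return float((1 + (null >= score).sum()) / (null.size + 1))


def coherence_with_exclusion(
    scorer_family: Callable[[str], PairScorerBase],
    S: ProteinSet,
    R: ReferenceSet,
    excluded_namespace: str = "none",
    **kwargs,
) -> CoherenceResult:
    """Set significance with one GO namespace removed from every protein's
    annotations (the BP⁻ / CC⁻ variants).

    ``scorer_family`` maps an excluded-namespace label ("none", "BP",
    "CC", "MF") to a pair scorer built on the correspondingly filtered
    annotations. The result carries a variant tag such as ``BP-``.
    """
    if excluded_namespace not in {"none", "BP", "CC", "MF"}:
        raise ValueError(f"bad excluded namespace {excluded_namespace!r}")
    scorer = scorer_family(excluded_namespace)
    variant = "none" if excluded_namespace == "none" else f"{excluded_namespace}-"
    return set_pvalue(scorer, S, R, variant=variant, **kwargs)


def sample_random_sets(
    R: ReferenceSet | Iterable[str],
    sizes: Iterable[int],
    rng: np.random.Generator,
    prefix: str = "random",
) -> list[ProteinSet]:
    """Uniform random protein sets (without replacement within a set) from
    the reference, one per requested size — the null for coherence
    calibration."""
    pool = sorted(R.members if isinstance(R, ReferenceSet) else set(R))
    out = []
    for k, size in enumerate(sizes):
        if size > len(pool):
            raise SetSizeError(f"requested size {size} exceeds reference {len(pool)}")
        members = set(rng.choice(pool, size=size, replace=False))
        out.append(ProteinSet(name=f"{prefix}_{k}", members=members, source="random"))
    return out


# ---------------------------------------------------------------------------
# Result and set-file I/O (TSV).

def read_protein_sets(path, source: str = "pathway") -> list[ProteinSet]:
    """Read set membership TSV: one (set name, protein ID) row per
    membership."""
    by_name: dict[str, set[str]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, _, protein = line.partition("\t")
            by_name.setdefault(name, set()).add(protein)
    return [ProteinSet(name=n, members=m, source=source) for n, m in by_name.items()]


def write_protein_sets(sets: Iterable[ProteinSet], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for s in sets:
            for p in sorted(s.members):
                fh.write(f"{s.name}\t{p}\n")


RESULT_COLUMNS = ("set", "method", "variant", "n", "coherence", "s", "r", "p_value", "seed")


def write_results(results: Iterable[CoherenceResult], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for res in results:
            fh.write(
                f"{res.set_name}\t{res.method}\t{res.variant}\t{res.n}\t"
                f"{res.coherence:.6g}\t{res.s}\t{res.r}\t{res.p_value:.6g}\t"
                f"{'' if res.seed is None else res.seed}\n"
            )
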