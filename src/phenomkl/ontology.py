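"""Phenotype-ontology handling: OBO parsing, ancestor propagation, information
content, and set-level semantic similarity (Jaccard, Resnik, Lin).

Variants are annotated with sets of ontology terms. Before any similarity is
computed the raw term set of each variant is *propagated*: every ancestor of
every annotated term, up to the ontology root, is added to the set. Pairwise
similarity between two variants is then a set similarity over the propagated
sets:

* ``jaccard`` — |A ∩ B| / |A ∪ B|.
* ``resnik`` — per term pair, the information content (IC) of the most
  informative common ancestor (MICA); aggregated over the two sets.
* ``lin`` — per term pair, 2·IC(MICA) / (IC(t1) + IC(t2)); aggregated.

IC of a term is −log2(f) where f is the fraction of (propagated) annotation
sets in the corpus that contain the term. The root occurs in every propagated
set, so IC(root) = 0.

Resnik and Lin similarity matrices on multi-parent ontologies are in general
indefinite; see :mod:`phenomkl.kernels` for PSD corrections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet

__all__ = [
    "OntologyGraph",
    "TermSet",
    "ICMap",
    "SimilarityMatrix",
    "parse_obo",
    "propagate",
    "information_content",
    "mica",
    "set_similarity",
    "similarity_matrix",
]

Measure = Literal["jaccard", "resnik", "lin"]


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies or unknown terms."""


@dataclass(frozen=True)
class OntologyGraph:
    """A rooted DAG of terms connected by IS-A (child -> parent) edges.

    ``parents`` maps every term to its (possibly empty) set of parents. The
    root is the unique term with no parents; multiple parents per term are
    permitted.
    """

    parents: Mapping[str, frozenset[str]]
    root: str
    _anc_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.parents)

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive ancestor set: the term itself plus everything on any
        parent path up to the root."""
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        if term not in self.parents:
            raise OntologyError(f"unknown term id: {term!r}")
        out = {term}
        for p in self.parents[term]:
            out |= self.ancestors(p)
        result = frozenset(out)
        self._anc_cache[term] = result
        return result


@dataclass(frozen=True)
class TermSet:
    """A variant's ontology annotation: raw terms and their ancestor closure."""

    variant_id: str
    raw_terms: frozenset[str]
    propagated_terms: frozenset[str]

    def __post_init__(self):
        if not self.raw_terms <= self.propagated_terms:
            raise ValueError(
                f"{self.variant_id}: raw terms must be a subset of propagated terms"
            )

    @classmethod
    def from_raw(cls, variant_id: str, raw: Iterable[str], graph: OntologyGraph) -> "TermSet":
        raw = frozenset(raw)
        return cls(variant_id, raw, propagate(graph, raw))


@dataclass(frozen=True)
class ICMap:
    """Information content per term: ic(t) = -log2(f_t), f_t the fraction of
    corpus sets containing t."""

    ic: Mapping[str, float]
    corpus_size: int

    def __getitem__(self, term: str) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise OntologyError(
                f"term {term!r} absent from the IC corpus; IC is defined only for "
                "terms occurring in at least one propagated annotation set"
            ) from None

    def __contains__(self, term: str) -> bool:
        return term in self.ic


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric variant-by-variant semantic similarity."""

    sample_ids: tuple[str, ...]
    values: np.ndarray
    measure: Measure

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("similarity matrix shape does not match sample ids")
        if not np.allclose(v, v.T, rtol=1e-10, atol=1e-12):
            raise ValueError("similarity matrix is not symmetric")


def parse_obo(path) -> OntologyGraph:
    """Parse an OBO flat file into an :class:`OntologyGraph`.

    Only ``is_a`` relations are honored; obsolete terms are dropped. The graph
    must be acyclic with a single parentless root, and every ``is_a`` target
    must itself be a [Term] stanza.
    """
    g = obonet.read_obo(str(path), ignore_obsolete=True)
    stanza_terms = {n for n, d in g.nodes(data=True) if d or g.degree(n) >= 0}
    # obonet creates implicit nodes for dangling is_a targets; a genuine
    # stanza always carries at least a name/data dict.
    declared = {n for n, d in g.nodes(data=True) if d}
    parents: dict[str, set[str]] = {t: set() for t in declared}
    for child, parent, key in g.edges(keys=True):
        if key != "is_a":
            continue
        if parent not in declared:
            raise OntologyError(f"term {child!r} has unknown parent id {parent!r}")
        if child not in declared:
            raise OntologyError(f"edge from undeclared term {child!r}")
        parents[child].add(parent)
    if not declared:
        raise OntologyError("ontology contains no terms")
    sub = nx.DiGraph((c, p) for c, ps in parents.items() for p in ps)
    sub.add_nodes_from(parents)
    if not nx.is_directed_acyclic_graph(sub):
        cyc = nx.find_cycle(sub)
        raise OntologyError(f"ontology contains a cycle through {cyc[0][0]!r}")
    roots = sorted(t for t, ps in parents.items() if not ps)
    if len(roots) != 1:
        raise OntologyError(
            f"expected exactly one root term, found {len(roots)}: {roots[:5]}"
        )
    return OntologyGraph(
        parents={t: frozenset(ps) for t, ps in parents.items()}, root=roots[0]
    )


def propagate(graph: OntologyGraph, raw: Iterable[str]) -> frozenset[str]:
    """Reflexive transitive ancestor closure of ``raw`` over parent edges."""
    raw = frozenset(raw)
    unknown = sorted(t for t in raw if t not in graph)
    if unknown:
        raise OntologyError(f"unknown term ids: {unknown}")
    out: set[str] = set()
    for t in raw:
        out |= graph.ancestors(t)
    return frozenset(out)


def information_content(graph: OntologyGraph, corpus: Sequence[TermSet]) -> ICMap:
    """IC over a corpus of propagated term sets: ic(t) = -log2(n_t / n)."""
    if not corpus:
        raise ValueError("IC requires a nonempty corpus of term sets")
    n = len(corpus)
    counts: dict[str, int] = {}
    for ts in corpus:
        for t in ts.propagated_terms:
            counts[t] = counts.get(t, 0) + 1
    ic = {t: -math.log2(c / n) for t, c in counts.items()}
    return ICMap(ic=ic, corpus_size=n)


def mica(graph: OntologyGraph, ic: ICMap, t1: str, t2: str) -> tuple[str, float]:
    """Most informative common ancestor of two terms (reflexive ancestors).

    Ties on IC are broken toward the lexicographically smallest term id.
    """
    common = graph.ancestors(t1) & graph.ancestors(t2)
    if not common:
        raise OntologyError(f"terms {t1!r} and {t2!r} share no common ancestor")
    best = min(common, key=lambda t: (-ic[t], t))
    return best, ic[best]


def _pair_score_tables(
    terms: Sequence[str], graph: OntologyGraph, ic: ICMap
) -> tuple[dict[str, int], np.ndarray, np.ndarray]:
    """Precompute MICA-IC for every pair of the given terms.

    Returns (term index map, resnik table, term IC vector). Vectorized as a
    max over ancestor terms: ancestor t contributes ic(t) to every pair of its
    descendants.
    """
    idx = {t: i for i, t in enumerate(terms)}
    k = len(terms)
    anc_terms = sorted({a for t in terms for a in graph.ancestors(t)})
    mask = np.zeros((k, len(anc_terms)), dtype=bool)
    a_idx = {a: j for j, a in enumerate(anc_terms)}
    for t, i in idx.items():
        for a in graph.ancestors(t):
            mask[i, a_idx[a]] = True
    ic_vec = np.array([ic[t] for t in terms])
    table = np.zeros((k, k))
    order = np.argsort([-ic[a] for a in anc_terms], kind="stable")
    remaining = np.ones((k, k), dtype=bool)
    for j in order:
        col = mask[:, j]
        block = np.outer(col, col) & remaining
        if block.any():
            table[block] = ic[anc_terms[j]]
            remaining &= ~block
        if not remaining.any():
            break
    return idx, table, ic_vec


def _aggregate(s: np.ndarray, how: str) -> float:
    if how == "bma":
        return 0.5 * (s.max(axis=1).mean() + s.max(axis=0).mean())
    if how == "max":
        return float(s.max())
    if how == "mean":
        return float(s.mean())
    raise ValueError(f"unknown aggregation {how!r}")


def set_similarity(
    measure: Measure,
    a: TermSet,
    b: TermSet,
    graph: OntologyGraph | None = None,
    ic: ICMap | None = None,
    aggregate: str = "bma",
    use_raw: bool = False,
) -> float:
    """Semantic similarity between two variants' term sets.

    Jaccard is a pure set overlap on propagated sets (or raw sets when
    ``use_raw``). Resnik/Lin score each term pair — IC(MICA) for Resnik,
    2·IC(MICA)/(IC(t1)+IC(t2)) for Lin, with the Lin pair score defined as 0
    when both term ICs are 0 — and aggregate with a symmetric best-match
    average (``bma``; ``max`` and ``mean`` are also accepted).
    """
    sa = a.raw_terms if use_raw else a.propagated_terms
    sb = b.raw_terms if use_raw else b.propagated_terms
    if not sa or not sb:
        raise ValueError(
            f"set similarity undefined for empty term sets ({a.variant_id}, {b.variant_id})"
        )
    if measure == "jaccard":
        return len(sa & sb) / len(sa | sb)
    if graph is None or ic is None:
        raise ValueError(f"{measure} similarity requires an ontology graph and IC map")
    ta, tb = sorted(sa), sorted(sb)
    s = np.zeros((len(ta), len(tb)))
    for i, t1 in enumerate(ta):
        ic1 = ic[t1]
        for j, t2 in enumerate(tb):
            _, m = mica(graph, ic, t1, t2)
            if measure == "resnik":
                s[i, j] = m
            else:
                denom = ic1 + ic[t2]
                s[i, j] = 2.0 * m / denom if denom > 0 else 0.0
    return _aggregate(s, aggregate)


def similarity_matrix(
    measure: Measure,
    corpus: Sequence[TermSet],
    graph: OntologyGraph | None = None,
    ic: ICMap | None = None,
    aggregate: str = "bma",
    use_raw: bool = False,
) -> SimilarityMatrix:
    """Pairwise semantic similarity over a corpus of term sets.

    Vectorized: Jaccard via binary membership algebra, Resnik/Lin via a
    precomputed term-pair MICA-IC table.
    """
    if len(corpus) < 2:
        raise ValueError("similarity matrix requires at least two term sets")
    ids = tuple(ts.variant_id for ts in corpus)
    sets = [
        sorted(ts.raw_terms if use_raw else ts.propagated_terms) for ts in corpus
    ]
    if any(not s for s in sets):
        empty = [ids[i] for i, s in enumerate(sets) if not s]
        raise ValueError(f"empty term sets in corpus: {empty}")
    n = len(corpus)
    if measure == "jaccard":
        vocab = sorted({t for s in sets for t in s})
        v_idx = {t: j for j, t in enumerate(vocab)}
        B = np.zeros((n, len(vocab)), dtype=np.float64)
        for i, s in enumerate(sets):
            B[i, [v_idx[t] for t in s]] = 1.0
        inter = B @ B.T
        sizes = B.sum(axis=1)
        union = sizes[:, None] + sizes[None, :] - inter
        vals = inter / union
        return SimilarityMatrix(ids, vals, "jaccard")
    if graph is None or ic is None:
        raise ValueError(f"{measure} similarity requires an ontology graph and IC map")
    terms = sorted({t for s in sets for t in s})
    missing = [t for t in terms if t not in ic]
    if missing:
        raise OntologyError(
            f"terms missing from the IC corpus: {missing[:5]} "
            "(propagated sets and IC map must come from the same corpus)"
        )
    idx, table, ic_vec = _pair_score_tables(terms, graph, ic)
    if measure == "lin":
        denom = ic_vec[:, None] + ic_vec[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            table = np.where(denom > 0, 2.0 * table / denom, 0.0)
    index_sets = [np.array([idx[t] for t in s]) for s in sets]
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = table[np.ix_(index_sets[i], index_sets[j])]
            vals[i, j] = vals[j, i] = _aggregate(s, aggregate)
    return SimilarityMatrix(ids, vals, measure)
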