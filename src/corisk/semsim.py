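"""Wang-style GO semantic similarity between terms and between genes.

Each term's meaning is encoded by its ancestor set ``T_A`` (the term and all
terms reachable through is_a / part_of edges).  Contributions decay upward:
the anchor contributes 1 to itself, and every ancestor ``t`` contributes

    S_A(t) = max over children c of t within T_A of  w_e(t, c) * S_A(c)

with edge weights w = 0.8 for is_a and 0.6 for part_of.  Term similarity is
the overlap of the two decayed ancestor profiles, normalized by the total
semantic value SV of each term; gene similarity aggregates term similarities
of the two annotation sets by best-match averaging.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .io_formats import IS_A, PART_OF, AnnotationMap, GODag

#: semantic contribution decay per edge, by relation type
EDGE_WEIGHTS = {IS_A: 0.8, PART_OF: 0.6}


class UnannotatedGeneError(KeyError):
    """Gene similarity is undefined (not zero) for unannotated genes."""


@dataclass(frozen=True)
class SValueTable:
    """Decayed semantic contributions of every ancestor of an anchor term."""

    anchor: str
    values: dict[str, float]  # term -> S_A(term), each in (0, 1]

    @property
    def sv(self) -> float:
        return float(sum(self.values.values()))


def s_values(dag: GODag, term: str,
             weights: dict[str, float] = EDGE_WEIGHTS) -> SValueTable:
    """S-value table of *term*: dynamic program over its ancestor DAG.

    Processed in topological order (children before parents) so each
    ancestor's value is the maximum weight-product over downward paths
    from the anchor.
    """
    anchor = dag.resolve(term)
    ancestors = dag.ancestors(anchor)
    sub = dag.graph.subgraph(ancestors)
    values: dict[str, float] = {anchor: 1.0}
    # edges point child -> parent, so topological order yields children first
    for node in nx.topological_sort(sub):
        if node not in values:
            continue
        for _, parent, rel in sub.out_edges(node, keys=True):
            w = weights[rel]
            cand = w * values[node]
            if cand > values.get(parent, 0.0):
                values[parent] = cand
    return SValueTable(anchor=anchor, values=values)


def sv(dag: GODag, term: str) -> float:
    """Semantic value of a term: the sum of its S-value table (>= 1)."""
    return s_values(dag, term).sv


def term_sim(dag: GODag, a: str, b: str) -> float:
    """Similarity of two terms from their shared, decayed ancestry.

    Sim(A,B) = sum over t in T_A & T_B of (S_A(t) + S_B(t)) / (SV(A) + SV(B)).
    Symmetric, in [0, 1], and 1 exactly when A == B.
    """
    ta = s_values(dag, a)
    tb = s_values(dag, b)
    return _term_sim_from_tables(ta, tb)


def _term_sim_from_tables(ta: SValueTable, tb: SValueTable) -> float:
    shared = ta.values.keys() & tb.values.keys()
    if not shared:
        return 0.0
    num = sum(ta.values[t] + tb.values[t] for t in shared)
    return float(num / (ta.sv + tb.sv))


class TermSimilarityCache:
    """Memoizes S-value tables and term-pair similarities for one DAG."""

    def __init__(self, dag: GODag):
        self.dag = dag
        self._tables: dict[str, SValueTable] = {}
        self._pairs: dict[tuple[str, str], float] = {}

    def table(self, term: str) -> SValueTable:
        term = self.dag.resolve(term)
        if term not in self._tables:
            self._tables[term] = s_values(self.dag, term)
        return self._tables[term]

    def term_sim(self, a: str, b: str) -> float:
        a, b = self.dag.resolve(a), self.dag.resolve(b)
        key = (a, b) if a <= b else (b, a)
        if key not in self._pairs:
            self._pairs[key] = _term_sim_from_tables(self.table(a),
                                                     self.table(b))
        return self._pairs[key]


def gene_sim(dag: GODag, ann: AnnotationMap, g1: str, g2: str,
             _cache: TermSimilarityCache | None = None) -> float:
    """Best-match-average similarity between two genes' annotation sets.

    With GO1 = {go1_1..go1_m}, GO2 = {go2_1..go2_n}:

        Sim(G1,G2) = ( sum_i max_j Sim(go1_i, go2_j)
                     + sum_j max_i Sim(go2_j, go1_i) ) / (m + n)

    Genes are compared on their direct annotation sets; ancestry enters
    only through the S-value machinery.
    """
    for g in (g1, g2):
        if g not in ann or not ann[g]:
            raise UnannotatedGeneError(f"gene {g!r} has no annotations; "
                                       "similarity is undefined")
    cache = _cache or TermSimilarityCache(dag)
    terms1, terms2 = sorted(ann[g1]), sorted(ann[g2])
    sim = np.array([[cache.term_sim(t1, t2) for t2 in terms2]
                    for t1 in terms1])
    total = sim.max(axis=1).sum() + sim.max(axis=0).sum()
    return float(total / (len(terms1) + len(terms2)))


def pairwise_gene_sim(dag: GODag, ann: AnnotationMap,
                      genes: Sequence[str]) -> tuple[list[str], np.ndarray, list[str]]:
    """All-pairs gene similarity.

    Returns ``(kept_genes, matrix, skipped)`` where *skipped* lists genes
    without annotations and *matrix* is symmetric with unit diagonal over
    *kept_genes* in input order.
    """
    kept = [g for g in genes if ann.get(g)]
    skipped = [g for g in genes if not ann.get(g)]
    cache = TermSimilarityCache(dag)
    n = len(kept)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = gene_sim(dag, ann, kept[i], kept[j],
                                             _cache=cache)
    return kept, mat, skipped
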