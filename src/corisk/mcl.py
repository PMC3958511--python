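"""Markov clustering (MCL) of the co-expression network.

MCL simulates stochastic flow on the graph: the column-stochastic transition
matrix is alternately expanded (matrix power — flow spreads) and inflated
(entrywise power with renormalization — strong flow is reinforced, weak flow
starved) until it reaches a doubly-idempotent attractor, from which densely
connected clusters are read off.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger("corisk")

DEFAULT_INFLATION = 1.8


@dataclass
class MCLResult:
    clusters: list[frozenset[str]]
    converged: bool
    iterations: int
    #: max |column sum - 1| recorded after each inflation step
    column_sum_error: list[float] = field(default_factory=list)


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    sums = m.sum(axis=0)
    sums[sums == 0.0] = 1.0
    return m / sums


def mcl_cluster(network: nx.Graph,
                inflation: float = DEFAULT_INFLATION,
                expansion: int = 2,
                prune: float = 1e-5,
                max_iter: int = 200,
                tol: float = 1e-8,
                weighted: bool = True) -> MCLResult:
    """Cluster *network* by Markov clustering.

    Self-loops are added with each node's maximum incident edge weight,
    columns are normalized, and expansion/inflation alternate (entries
    below *prune* are dropped, then columns renormalized) until successive
    matrices differ by less than *tol* in max norm.  Clusters are the
    weakly connected components of the attractor graph; overlapping
    attractor systems merge into one cluster, so the result is a partition
    of the node set.  Non-convergence returns the current clustering with
    ``converged=False``.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(network.nodes)  # fixed order => permutation invariance
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n))
    for u, v, data in network.edges(data=True):
        w = float(data.get("weight", 1.0)) if weighted else 1.0
        adj[index[u], index[v]] = adj[index[v], index[u]] = w
    loop = adj.max(axis=0)
    loop[loop == 0.0] = 1.0  # isolated nodes keep a unit self-loop
    np.fill_diagonal(adj, loop)

    m = _normalize_columns(adj)
    converged = False
    iterations = 0
    col_err: list[float] = []
    for iterations in range(1, max_iter + 1):
        expanded = np.linalg.matrix_power(m, expansion)
        inflated = np.power(expanded, inflation)
        inflated[inflated < prune] = 0.0
        inflated = _normalize_columns(inflated)
        col_err.append(float(np.abs(inflated.sum(axis=0) - 1.0).max()))
        diff = float(np.abs(inflated - m).max())
        m = inflated
        if diff < tol:
            converged = True
            break
    if not converged:
        logger.warning("MCL did not converge in %d iterations", max_iter)

    # attractor reading: connect i-j wherever flow i<-j (or j<-i) survives
    links = nx.Graph()
    links.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > prune)
    links.add_edges_from(zip(rows.tolist(), cols.tolist()))
    clusters = [frozenset(nodes[i] for i in comp)
                for comp in nx.connected_components(links)]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return MCLResult(clusters=clusters, converged=converged,
                     iterations=iterations, column_sum_error=col_err)


@dataclass
class GeneModule:
    """A named set of >=3 genes with its differential-expression flags."""

    id: str
    genes: frozenset[str]
    de_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.de_genes <= self.genes:
            raise ValueError(f"module {self.id}: de_genes not a subset")


def candidate_modules(clusters: Sequence[frozenset[str]],
                      de_results: Sequence,
                      min_size: int = 3) -> list[GeneModule]:
    """Clusters of >= *min_size* genes containing at least one DE-gene.

    *de_results* may be ``diffexpr.DEResult`` objects or anything with
    ``gene``/``is_de`` attributes.  Stable IDs M1, M2, ... are assigned by
    descending size, ties broken by the lexically first gene.
    """
    de_genes = {r.gene for r in de_results if r.is_de}
    eligible = [c for c in clusters if len(c) >= min_size and c & de_genes]
    eligible.sort(key=lambda c: (-len(c), tuple(sorted(c))))
    return [GeneModule(id=f"M{i}", genes=frozenset(c),
                       de_genes=frozenset(c & de_genes))
            for i, c in enumerate(eligible, start=1)]
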