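"""Independent brute-force oracles used by the test suite.

Everything here recomputes quantities by enumeration, direct numerical
integration or exhaustive pair counting, deliberately avoiding the code
paths under test.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.stats import hypergeom

from corisk.io_formats import GODag
from corisk.semsim import EDGE_WEIGHTS


# --- Wang similarity: exhaustive path enumeration --------------------------

def all_upward_paths(dag: GODag, start: str, target: str):
    """Every child->parent edge path from *start* to *target*."""
    if start == target:
        yield ()
        return
    for parent, rel in dag.parents(start):
        for rest in all_upward_paths(dag, parent, target):
            yield (rel,) + rest


def s_value_by_paths(dag: GODag, anchor: str, target: str) -> float:
    """max over all upward paths of the product of edge weights."""
    best = 0.0
    for path in all_upward_paths(dag, anchor, target):
        prod = 1.0
        for rel in path:
            prod *= EDGE_WEIGHTS[rel]
        best = max(best, prod)
    return best


def random_dag(rng: np.random.Generator, n_terms: int) -> GODag:
    """Random small DAG: edges only from later to earlier node indices."""
    names = [f"T{i}" for i in range(n_terms)]
    edges = []
    for child in range(1, n_terms):
        n_parents = int(rng.integers(1, min(child, 2) + 1))
        parents = rng.choice(child, size=n_parents, replace=False)
        for p in parents:
            rel = "is_a" if rng.random() < 0.6 else "part_of"
            edges.append((names[child], names[int(p)], rel))
    return GODag.from_edges(edges, extra_terms=names)


# --- Bayes factor: direct numerical integration -----------------------------

def bfln_by_integration(n1T: int, n2T: int, n1N: int, n2N: int) -> float:
    """log of [marginal likelihood under independent rates / common rate].

    The marginal likelihoods are integrated numerically over uniform
    priors; no Beta-function identities are used.
    """
    def marg(a, b):
        val, _ = quad(lambda t: t**a * (1 - t)**b, 0.0, 1.0)
        return val

    h1 = marg(n1T, n2T) * marg(n1N, n2N)
    h0 = marg(n1T + n1N, n2T + n2N)
    return float(np.log(h1) - np.log(h0))


def exact_permutation_p(table, bfln_fn, comparison: str = "midp") -> float:
    """Tail mass of the hypergeometric randomization null, enumerated."""
    n_tumor = table.n1T + table.n2T
    n_normal = table.n1N + table.n2N
    n_high = table.n1T + table.n1N
    total = n_tumor + n_normal
    lo = max(0, n_high - n_normal)
    hi = min(n_tumor, n_high)
    ks = np.arange(lo, hi + 1)
    weights = hypergeom.pmf(ks, total, n_high, n_tumor)
    vals = np.array([bfln_fn(type(table)(int(k), n_tumor - int(k),
                                         n_high - int(k),
                                         n_normal - n_high + int(k)))
                     for k in ks])
    obs = bfln_fn(table)
    greater = weights[vals > obs + 1e-12].sum()
    ties = weights[np.abs(vals - obs) <= 1e-12].sum()
    if comparison == "geq":
        return float(greater + ties)
    if comparison == "greater":
        return float(greater)
    return float(greater + 0.5 * ties)


# --- ROC: exhaustive Mann-Whitney pair counting -----------------------------

def auc_by_pair_counting(scores, labels) -> float:
    """P(score_pos > score_neg) + half the ties, over all pos/neg pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n)
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


# --- hypergeometric overlap: exhaustive draw enumeration --------------------

def overlap_tail_by_enumeration(universe: set, gene_set: set,
                                module_size: int, k: int) -> float:
    """P(|draw & gene_set| >= k) over all equally likely size-m draws."""
    hits = 0
    total = 0
    for draw in itertools.combinations(sorted(universe), module_size):
        total += 1
        if len(set(draw) & gene_set) >= k:
            hits += 1
    return hits / total
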