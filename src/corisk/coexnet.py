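"""Highly-confident co-expression network construction.

A gene pair enters the network only if it clears two joint thresholds:
Pearson correlation of the expression rows and Wang functional similarity
of the annotation sets.  The thresholds can be set manually (the shipped
defaults are r > 0.82 and sim > 0.582) or chosen from the data: mean
similarity is binned against |r| at a 0.05 pitch, a low-order polynomial is
fitted to the bin means, and the tangency/knee point of the fitted trend —
the bin center farthest from the chord joining the curve's endpoints —
supplies (r*, sim*).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import networkx as nx
import numpy as np

from .io_formats import AnnotationMap, ExpressionDataset, GODag
from .semsim import pairwise_gene_sim

logger = logging.getLogger("corisk")

#: joint thresholds at the tangency point of the similarity-vs-correlation trend
DEFAULT_R_THRESHOLD = 0.82
DEFAULT_SIM_THRESHOLD = 0.582


class ConstantVectorError(ValueError):
    """Correlation is undefined for a constant expression vector."""


class NoKneeError(RuntimeError):
    """The binned trend has no knee; thresholds must be set manually."""


class GenePairScores(NamedTuple):
    g1: str
    g2: str
    r: float    # Pearson correlation, in [-1, 1]
    sim: float  # functional similarity, in [0, 1]


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length sample vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be one-dimensional and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt(np.sum(dx * dx))
    sy = np.sqrt(np.sum(dy * dy))
    if sx == 0.0 or sy == 0.0:
        raise ConstantVectorError("correlation undefined for constant vector")
    return float(np.clip(np.sum(dx * dy) / (sx * sy), -1.0, 1.0))


def score_all_pairs(dataset: ExpressionDataset, dag: GODag,
                    ann: AnnotationMap) -> tuple[list[GenePairScores], int]:
    """Pearson r and functional similarity for every eligible gene pair.

    Pairs involving unannotated genes are excluded and counted; pairs
    involving constant-expression genes are silently excluded (their
    correlation is undefined).  Returns ``(scores, n_excluded_unannotated)``.
    """
    nonconstant = [g for g in dataset.genes
                   if np.ptp(dataset.gene_row(g)) > 0]
    kept, sim_mat, skipped = pairwise_gene_sim(dag, ann, nonconstant)
    n_all = len(nonconstant)
    excluded = (n_all * (n_all - 1)) // 2 - (len(kept) * (len(kept) - 1)) // 2
    if skipped:
        logger.info("excluded %d pair(s) involving %d unannotated gene(s)",
                    excluded, len(skipped))
    sub = dataset.values[dataset.gene_indices(kept)]
    corr = np.corrcoef(sub)
    scores = [
        GenePairScores(kept[i], kept[j],
                       float(np.clip(corr[i, j], -1.0, 1.0)),
                       float(sim_mat[i, j]))
        for i in range(len(kept)) for j in range(i + 1, len(kept))
    ]
    return scores, excluded


@dataclass
class TrendCurve:
    """Mean functional similarity per co-expression bin (0.05 pitch).

    Empty bins carry ``count == 0`` and ``NaN`` mean — an explicit marker,
    never a zero.
    """

    edges: np.ndarray       # bin edges over [0, 1]
    mean_sim: np.ndarray    # per-bin mean similarity, NaN where empty
    counts: np.ndarray      # per-bin pair count
    use_abs: bool = True
    coeffs: np.ndarray | None = None      # fitted polynomial, highest first
    knee: tuple[float, float] | None = None  # (r*, fitted sim at r*)

    @property
    def centers(self) -> np.ndarray:
        return (self.edges[:-1] + self.edges[1:]) / 2

    @property
    def populated(self) -> np.ndarray:
        return self.counts > 0


def bin_trend(scores: Iterable[GenePairScores], bin_width: float = 0.05,
              use_abs: bool = True) -> TrendCurve:
    """Bin pairs by |r| (half-open bins, last bin closed) and average sim."""
    scores = list(scores)
    if not scores:
        raise ValueError("need at least one score")
    r = np.array([s.r for s in scores])
    sim = np.array([s.sim for s in scores])
    if use_abs:
        r = np.abs(r)
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.floor(r / bin_width).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=sim, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return TrendCurve(edges=edges, mean_sim=means, counts=counts,
                      use_abs=use_abs)


def fit_tangent(trend: TrendCurve, degree: int = 3, tol: float = 0.01,
                weight_by_count: bool = False) -> tuple[float, float]:
    """Locate the tangency/knee point of the binned trend.

    A degree-*degree* polynomial is least-squares fitted to the populated
    bin means (bins weighted equally by default; *weight_by_count* weights
    each bin by its pair count).  The knee is the populated-bin center
    maximizing the perpendicular distance to the chord joining the fitted
    curve's endpoints.  A near-linear trend (max distance < *tol*) has no
    knee and raises :class:`NoKneeError`.
    """
    mask = trend.populated
    x = trend.centers[mask]
    y = trend.mean_sim[mask]
    if x.size < degree + 2:
        raise ValueError(f"need at least {degree + 2} populated bins, "
                         f"have {x.size}")
    w = np.sqrt(trend.counts[mask]) if weight_by_count else None
    coeffs = np.polyfit(x, y, degree, w=w)
    trend.coeffs = coeffs
    fitted = np.polyval(coeffs, x)
    # chord endpoints come from the smoothed curve; distances are taken at
    # the bin means themselves so the knee is not dragged by the smoothing
    p0 = np.array([x[0], fitted[0]])
    p1 = np.array([x[-1], fitted[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    dist = np.abs(chord[0] * (y - p0[1]) - chord[1] * (x - p0[0])) / norm
    if dist.max() < tol:
        raise NoKneeError(
            "binned trend is effectively linear (max chord distance "
            f"{dist.max():.2g} < {tol:g}); supply manual thresholds")
    k = int(np.argmax(dist))
    knee = (float(x[k]), float(fitted[k]))
    trend.knee = knee
    logger.info("tangency point at r*=%.3f, sim*=%.3f", *knee)
    return knee


def build_network(scores: Iterable[GenePairScores],
                  r_star: float = DEFAULT_R_THRESHOLD,
                  sim_star: float = DEFAULT_SIM_THRESHOLD,
                  use_abs: bool = True) -> nx.Graph:
    """Keep pairs with |r| > r_star AND sim > sim_star (strict inequalities).

    Edge attributes: ``r`` (signed), ``sim`` and ``weight`` (|r|, the MCL
    flow weight).  An empty network is allowed with a warning.
    """
    g = nx.Graph()
    for s in scores:
        r_mag = abs(s.r) if use_abs else s.r
        if r_mag > r_star and s.sim > sim_star and s.g1 != s.g2:
            g.add_edge(s.g1, s.g2, r=s.r, sim=s.sim, weight=abs(s.r))
    if g.number_of_edges() == 0:
        logger.warning("no gene pair cleared thresholds (r>%g, sim>%g): "
                       "empty network", r_star, sim_star)
    return g


def network_edges(g: nx.Graph) -> list[tuple[str, str, float, float]]:
    """Edge records (g1, g2, r, sim) in deterministic order, for writers."""
    return [(min(u, v), max(u, v), d["r"], d["sim"])
            for u, v, d in sorted(g.edges(data=True),
                                  key=lambda e: (min(e[0], e[1]),
                                                 max(e[0], e[1])))]
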