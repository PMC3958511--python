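"""Module risk scoring and module-based sample risk evaluation.

For each candidate module, every tumor sample's module-mean expression is
Z-tested against a reference built from the normal samples (mean and
population SD of the per-normal-sample module means).  M_risk is the
fraction of tumor samples whose test is significant; its significance comes
from 10,000 random equal-size gene sets.  Sample-level risk S_risk is, for
every sample, the fraction of cancer-risk modules for which that sample is
Z-test significant; samples with S_risk > 0.8 are called diseased, and the
tumor/normal discrimination of S_risk is summarized by an ROC curve.
"""
from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import erfc
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io_formats import NORMAL, TUMOR, ExpressionDataset
from .mcl import GeneModule

logger = logging.getLogger("corisk")

DEFAULT_ALPHA = 0.05
DEFAULT_CALL_THRESHOLD = 0.8
DEFAULT_LOW_CUT = 0.93


def truncate4(x: float) -> float:
    """Floor-truncate to 4 decimals (27/28 renders as 0.9642, not 0.9643)."""
    return math.floor(x * 10_000) / 10_000


@dataclass
class NormalReference:
    """Mean and population SD of per-normal-sample module means."""

    mean: float
    sd: float  # ddof=0

    @property
    def degenerate(self) -> bool:
        return self.sd == 0.0


@dataclass
class ModuleRisk:
    module: GeneModule
    z: np.ndarray            # per-tumor-sample Z
    p: np.ndarray            # per-tumor-sample two-sided p
    n_significant: int
    m_risk: float            # n_significant / n_tumor, exact
    null_p: float | None = None
    risk_class: str | None = None

    @property
    def m_risk_rendered(self) -> float:
        return truncate4(self.m_risk)


@dataclass
class SampleRisk:
    sample: str
    label: str
    indicators: np.ndarray   # per-risk-module 0/1 significance
    s_risk: float
    call: str                # "disease" or "normal"


@dataclass
class RocSummary:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


# ---------------------------------------------------------------------------
# Z-test machinery
# ---------------------------------------------------------------------------

def _module_means(dataset: ExpressionDataset, genes: Sequence[str]) -> np.ndarray:
    """Per-sample mean expression over the module's genes."""
    idx = dataset.gene_indices(genes)
    return dataset.values[idx].mean(axis=0)


def normal_reference(dataset: ExpressionDataset,
                     module: GeneModule | Sequence[str]) -> NormalReference:
    """Reference distribution of the module mean across normal samples."""
    genes = module.genes if isinstance(module, GeneModule) else module
    dataset.require_two_per_class()
    means = _module_means(dataset, sorted(genes))[dataset.normal_mask]
    ref = NormalReference(mean=float(means.mean()),
                          sd=float(means.std(ddof=0)))
    if ref.degenerate:
        logger.warning("degenerate normal reference (sd=0); Z undefined")
    return ref


def _two_sided_p(z: np.ndarray | float) -> np.ndarray | float:
    return erfc(np.abs(z) / math.sqrt(2.0))


def sample_z(dataset: ExpressionDataset, module: GeneModule | Sequence[str],
             ref: NormalReference, sample: str) -> tuple[float, float]:
    """Z and two-sided p of one sample's module mean against the reference.

    A degenerate reference yields (nan, 1.0) with a warning upstream.
    """
    genes = module.genes if isinstance(module, GeneModule) else module
    if ref.degenerate:
        return float("nan"), 1.0
    s = dataset.samples.index(sample)
    mu = float(dataset.values[dataset.gene_indices(sorted(genes)), s].mean())
    z = (mu - ref.mean) / ref.sd
    return float(z), float(_two_sided_p(z))


def m_risk(module: GeneModule | Sequence[str], dataset: ExpressionDataset,
           alpha: float = DEFAULT_ALPHA) -> ModuleRisk:
    """Fraction of tumor samples significantly shifted from the normal reference."""
    genes = module.genes if isinstance(module, GeneModule) else module
    mod = (module if isinstance(module, GeneModule)
           else GeneModule(id="module", genes=frozenset(genes)))
    ref = normal_reference(dataset, mod)
    means = _module_means(dataset, sorted(mod.genes))[dataset.tumor_mask]
    if ref.degenerate:
        z = np.full(means.shape, np.nan)
        p = np.ones_like(means)
    else:
        z = (means - ref.mean) / ref.sd
        p = _two_sided_p(z)
    n_sig = int(np.count_nonzero(p < alpha))
    return ModuleRisk(module=mod, z=z, p=p, n_significant=n_sig,
                      m_risk=n_sig / means.size)


# ---------------------------------------------------------------------------
# Random-module null
# ---------------------------------------------------------------------------

def _random_m_risks(dataset: ExpressionDataset, size: int,
                    background_idx: np.ndarray, draws: int,
                    rng: np.random.Generator, alpha: float,
                    chunk: int = 2000) -> np.ndarray:
    """M_risk for *draws* random same-size gene sets, vectorized in chunks."""
    values = dataset.values
    normal = dataset.normal_mask
    tumor = dataset.tumor_mask
    out = np.empty(draws)
    done = 0
    while done < draws:
        c = min(chunk, draws - done)
        # sample without replacement within each draw
        picks = np.argsort(rng.random((c, background_idx.size)),
                           axis=1)[:, :size]
        idx = background_idx[picks]                       # (c, size)
        means = values[idx].mean(axis=1)                  # (c, n_samples)
        nmeans = means[:, normal]
        mu = nmeans.mean(axis=1, keepdims=True)
        sd = nmeans.std(axis=1, ddof=0, keepdims=True)
        tmeans = means[:, tumor]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(sd > 0, (tmeans - mu) / sd, 0.0)
        p = erfc(np.abs(z) / math.sqrt(2.0))
        out[done:done + c] = (p < alpha).sum(axis=1) / tmeans.shape[1]
        done += c
    return out


def module_null_p(module: GeneModule | Sequence[str],
                  dataset: ExpressionDataset,
                  background_genes: Sequence[str],
                  draws: int = 10_000,
                  seed: int | np.random.Generator = 0,
                  alpha: float = DEFAULT_ALPHA) -> float:
    """Empirical p of a module's M_risk against random equal-size modules.

    Random modules are drawn without replacement from *background_genes*;
    p counts random M_risk >= observed (conservative tie handling).  An
    observed M_risk of 0 carries no evidence of risk and returns p = 1.
    """
    genes = sorted(module.genes if isinstance(module, GeneModule) else module)
    background = sorted(set(background_genes))
    if len(background) < len(genes):
        raise ValueError("background gene set smaller than the module")
    observed = m_risk(module, dataset, alpha=alpha).m_risk
    if observed == 0.0:
        return 1.0
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    bg_idx = dataset.gene_indices(background)
    rand = _random_m_risks(dataset, len(genes), bg_idx, draws, rng, alpha)
    return float(np.count_nonzero(rand >= observed - 1e-12) / draws)


def classify_risk(modules: Sequence[ModuleRisk],
                  low_cut: float = DEFAULT_LOW_CUT) -> list[ModuleRisk]:
    """Attach a high / middle / low risk class from M_risk (in place).

    high: every tumor sample significant (M_risk = 1); low: M_risk <=
    *low_cut*; middle otherwise.
    """
    for mod in modules:
        if mod.m_risk == 1.0:
            mod.risk_class = "high"
        elif mod.m_risk <= low_cut:
            mod.risk_class = "low"
        else:
            mod.risk_class = "middle"
    return list(modules)


def score_modules(candidates: Sequence[GeneModule],
                  dataset: ExpressionDataset,
                  background_genes: Sequence[str],
                  draws: int = 10_000,
                  seed: int = 0,
                  alpha: float = DEFAULT_ALPHA) -> list[ModuleRisk]:
    """M_risk + random-module null for every candidate; cancer-risk flagged.

    Per-module null substreams are derived from *seed* and the module id so
    results are independent of module order.
    """
    out = []
    for mod in candidates:
        risk = m_risk(mod, dataset, alpha=alpha)
        sub = np.random.default_rng([seed, zlib.crc32(mod.id.encode())])
        risk.null_p = module_null_p(mod, dataset, background_genes,
                                    draws=draws, seed=sub, alpha=alpha)
        out.append(risk)
    classify_risk(out)
    return out


def cancer_risk_modules(scored: Sequence[ModuleRisk],
                        alpha: float = DEFAULT_ALPHA) -> list[ModuleRisk]:
    """Modules whose M_risk beats the random-module null at p < alpha."""
    return [m for m in scored if m.null_p is not None and m.null_p < alpha]


# ---------------------------------------------------------------------------
# Sample-level risk
# ---------------------------------------------------------------------------

def s_risk(dataset: ExpressionDataset,
           risk_modules: Sequence[GeneModule | ModuleRisk],
           alpha: float = DEFAULT_ALPHA,
           call_threshold: float = DEFAULT_CALL_THRESHOLD,
           soft: bool = False) -> list[SampleRisk]:
    """Module-based disease risk of every sample (tumor and normal).

    For each cancer-risk module j and sample i, the indicator risk_ij is 1
    when the sample's module-mean is Z-test significant (p < alpha); S_risk
    is the mean indicator over the N risk modules, and samples with S_risk
    > *call_threshold* are called diseased.  Normal samples are scored
    leave-one-out against a reference from the other normal samples.  With
    ``soft=True`` the indicator is replaced by (1 - p).
    """
    if not risk_modules:
        raise ValueError("need at least one cancer-risk module")
    dataset.require_two_per_class()
    modules = []
    for i, m in enumerate(risk_modules):
        if isinstance(m, ModuleRisk):
            modules.append(m.module)
        elif isinstance(m, GeneModule):
            modules.append(m)
        else:  # bare gene collection
            modules.append(GeneModule(id=f"M{i + 1}", genes=frozenset(m)))
    n_samples = dataset.n_samples
    normal_idx = np.flatnonzero(dataset.normal_mask)
    scores = np.zeros((n_samples, len(modules)))
    for j, mod in enumerate(modules):
        means = _module_means(dataset, sorted(mod.genes))
        nvals = means[normal_idx]
        n = nvals.size
        full_mu, full_sd = nvals.mean(), nvals.std(ddof=0)
        z = np.zeros(n_samples)
        for i in range(n_samples):
            if dataset.labels[i] == TUMOR:
                mu, sd = full_mu, full_sd
            else:  # leave this normal sample out of its own reference
                pos = int(np.flatnonzero(normal_idx == i)[0])
                rest = np.delete(nvals, pos)
                mu, sd = rest.mean(), rest.std(ddof=0)
            z[i] = (means[i] - mu) / sd if sd > 0 else 0.0
        p = _two_sided_p(z)
        scores[:, j] = (1.0 - p) if soft else (p < alpha).astype(float)
    out = []
    for i, (sample, label) in enumerate(zip(dataset.samples, dataset.labels)):
        s = float(scores[i].mean())
        out.append(SampleRisk(
            sample=sample, label=label, indicators=scores[i], s_risk=s,
            call="disease" if s > call_threshold else "normal"))
    return out


def roc(sample_risks: Sequence[SampleRisk]) -> RocSummary:
    """ROC of S_risk against the tumor/normal labels (tumor = positive).

    Equal scores are grouped into one step; AUC is the trapezoidal area,
    which equals the Mann-Whitney statistic with the half-tie correction.
    """
    labels = np.array([1 if s.label == TUMOR else 0 for s in sample_risks])
    scores = np.array([s.s_risk for s in sample_risks])
    if labels.min() == labels.max():
        raise ValueError("ROC needs both tumor and normal samples")
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    return RocSummary(fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))
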