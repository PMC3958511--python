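"""Synthetic study generator with planted, functionally coherent modules.

Emulates the statistical structure the pipeline assumes: a two-class
expression matrix containing groups of co-expressed genes whose mean
expression is shifted in tumor samples, a toy ontology in which each
planted group owns a dedicated term subtree, annotations linking group
genes to their subtree, and a complex catalog echoing the groups.

Correlation within a planted module follows a single-factor model: gene
value = baseline + sd * (sqrt(rho) * factor + sqrt(1-rho) * noise), which
makes the expected pairwise correlation between two module genes exactly
rho.  Tumor samples add delta * sd to every module gene, so delta is the
mean shift in noise-SD units.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .io_formats import (NORMAL, TUMOR, AnnotationMap, ComplexCatalog,
                         ExpressionDataset, GODag)


class PlantedModule(NamedTuple):
    size: int
    rho: float    # within-module correlation, in [0, 1)
    delta: float  # tumor mean shift, in noise-SD units


def default_planted_modules(n_risk: int = 3, n_null: int = 20,
                            size: int = 5, rho: float = 0.7,
                            delta: float = 2.5) -> list[PlantedModule]:
    """The study conditions: *n_risk* shifted modules among *n_null* unshifted."""
    return ([PlantedModule(size, rho, delta)] * n_risk
            + [PlantedModule(size, rho, 0.0)] * n_null)


@dataclass
class SimulationConfig:
    n_genes: int = 200
    n_tumor: int = 20
    n_normal: int = 20
    modules: list[PlantedModule] = field(default_factory=default_planted_modules)
    noise_sd: float = 1.0
    baseline_mean: float = 8.0   # log2-scale-like expression baseline
    baseline_sd: float = 1.0
    coherence: float = 0.8       # P(module gene annotated to its own subtree)
    n_decoy_subtrees: int = 8
    leaves_per_subtree: int = 3
    n_decoy_complexes: int = 10
    seed: int = 0

    def validate(self) -> None:
        if sum(m.size for m in self.modules) > self.n_genes:
            raise ValueError("planted module sizes exceed n_genes")
        if any(not (0 <= m.rho < 1) for m in self.modules):
            raise ValueError("rho must be in [0, 1)")
        if any(m.size < 3 for m in self.modules):
            raise ValueError("planted modules need >= 3 genes")
        if not (0 <= self.coherence <= 1):
            raise ValueError("coherence must be in [0, 1]")


@dataclass
class SimulatedStudy:
    dataset: ExpressionDataset
    dag: GODag
    annotations: AnnotationMap
    complexes: ComplexCatalog
    truth: dict


def expected_pairwise_r(rho: float) -> float:
    """Theoretical correlation between two genes of one planted module.

    Both genes load sqrt(rho) on the shared factor and carry independent
    sqrt(1-rho)-scaled noise, so cov = rho and var = 1 per gene: r = rho.
    """
    if not (0 <= rho < 1):
        raise ValueError("rho must be in [0, 1)")
    return float(rho)


def _term_id(counter: list[int]) -> str:
    counter[0] += 1
    return f"GO:{counter[0]:07d}"


def simulate(config: SimulationConfig) -> SimulatedStudy:
    """Generate one fully seed-deterministic synthetic study."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_mod_genes = sum(m.size for m in config.modules)

    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    samples = ([f"T{i + 1:02d}" for i in range(config.n_tumor)]
               + [f"N{i + 1:02d}" for i in range(config.n_normal)])
    labels = [TUMOR] * config.n_tumor + [NORMAL] * config.n_normal
    n_samples = len(samples)
    tumor = np.array([l == TUMOR for l in labels])

    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=config.n_genes)
    values = (baseline[:, None]
              + config.noise_sd * rng.standard_normal((config.n_genes,
                                                       n_samples)))

    membership: list[list[str]] = []
    cursor = 0
    for m, planted in enumerate(config.modules):
        rows = slice(cursor, cursor + planted.size)
        member_genes = genes[cursor:cursor + planted.size]
        cursor += planted.size
        factor = rng.standard_normal(n_samples)
        noise = rng.standard_normal((planted.size, n_samples))
        signal = (np.sqrt(planted.rho) * factor[None, :]
                  + np.sqrt(1.0 - planted.rho) * noise)
        values[rows] = baseline[rows, None] + config.noise_sd * signal
        values[rows, :][:, tumor] += planted.delta * config.noise_sd
        membership.append(member_genes)

    dataset = ExpressionDataset(genes=genes, samples=samples, labels=labels,
                                values=values)

    # --- ontology: one root, one subtree per planted module, plus decoys ---
    counter = [0]
    root = _term_id(counter)
    edges: list[tuple[str, str, str]] = []
    subtree_leaves: list[list[str]] = []
    n_subtrees = len(config.modules) + config.n_decoy_subtrees
    for s in range(n_subtrees):
        parent = _term_id(counter)
        edges.append((parent, root, "is_a"))
        leaves = []
        for leaf_i in range(config.leaves_per_subtree):
            leaf = _term_id(counter)
            rel = "is_a" if leaf_i % 2 == 0 else "part_of"
            edges.append((leaf, parent, rel))
            leaves.append(leaf)
        subtree_leaves.append(leaves)
    dag = GODag.from_edges(edges)
    decoy_subtrees = subtree_leaves[len(config.modules):]

    def _pick_terms(leaves: list[str]) -> set[str]:
        k = int(rng.integers(1, min(2, len(leaves)) + 1))
        return set(rng.choice(leaves, size=k, replace=False))

    ann: AnnotationMap = {}
    for m, member_genes in enumerate(membership):
        for g in member_genes:
            if rng.random() < config.coherence:
                leaves = subtree_leaves[m]
            else:
                leaves = decoy_subtrees[int(rng.integers(len(decoy_subtrees)))]
            ann[g] = _pick_terms(leaves)
    for g in genes[n_mod_genes:]:
        leaves = decoy_subtrees[int(rng.integers(len(decoy_subtrees)))]
        ann[g] = _pick_terms(leaves)

    # --- complexes: exact copies of planted modules plus random decoys ---
    complexes: ComplexCatalog = {}
    for m, member_genes in enumerate(membership):
        complexes[f"CPX-P{m + 1:02d}"] = set(member_genes)
    for d in range(config.n_decoy_complexes):
        size = int(rng.integers(3, 7))
        complexes[f"CPX-D{d + 1:02d}"] = set(
            rng.choice(genes, size=size, replace=False))

    truth = {
        "seed": config.seed,
        "modules": [
            {"name": f"P{m + 1:02d}", "genes": member_genes,
             "rho": planted.rho, "delta": planted.delta,
             "shifted": planted.delta != 0.0,
             "subtree_leaves": subtree_leaves[m]}
            for m, (planted, member_genes) in enumerate(zip(config.modules,
                                                            membership))
        ],
        "background_genes": genes[n_mod_genes:],
    }
    return SimulatedStudy(dataset=dataset, dag=dag, annotations=ann,
                          complexes=complexes, truth=truth)


def write_truth(truth: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
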