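"""Hypergeometric overlap of risk modules with protein complexes or GO terms.

The question asked per (module, gene set) pair: drawing |module| genes from
the universe, how surprising is observing at least the seen number of
members of the gene set?  The default universe is the co-expression
network's gene set.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import false_discovery_control, hypergeom

from .io_formats import ComplexCatalog
from .mcl import GeneModule


@dataclass
class OverlapResult:
    module_id: str
    set_name: str
    k: int               # shared genes
    module_size: int
    set_size: int
    universe_size: int
    p: float             # upper-tail P(X >= k)

    @property
    def overlap_rate(self) -> float:
        """Shared genes as a fraction of the complex/term size."""
        return self.k / self.set_size


def hypergeom_overlap(module: GeneModule | Iterable[str],
                      gene_set: Iterable[str],
                      universe: Iterable[str],
                      set_name: str = "set") -> OverlapResult:
    """Upper-tail hypergeometric p for the module / gene-set intersection."""
    mod_genes = set(module.genes if isinstance(module, GeneModule) else module)
    mod_id = module.id if isinstance(module, GeneModule) else "module"
    gene_set = set(gene_set)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not mod_genes <= universe or not gene_set <= universe:
        raise ValueError("module and gene set must be subsets of the universe")
    k = len(mod_genes & gene_set)
    # P(X >= k) with population=|universe|, successes=|gene_set|, draws=|module|
    p = float(hypergeom.sf(k - 1, len(universe), len(gene_set), len(mod_genes)))
    return OverlapResult(module_id=mod_id, set_name=set_name, k=k,
                         module_size=len(mod_genes), set_size=len(gene_set),
                         universe_size=len(universe), p=min(p, 1.0))


def overlap_network(modules: Sequence[GeneModule],
                    catalog: ComplexCatalog,
                    universe: Iterable[str],
                    alpha: float = 0.05,
                    correction: str | None = None) -> list[tuple[OverlapResult, bool]]:
    """One edge per (module, complex) sharing >= 1 gene, with p < alpha flag.

    Complex members outside the universe are ignored in the test (the
    hypergeometric model requires both sets inside the population).  By
    default raw p-values are flagged; ``correction="bh"`` flags on
    Benjamini-Hochberg adjusted p-values instead.
    """
    universe = set(universe)
    results = []
    for mod in modules:
        for name in sorted(catalog):
            members = set(catalog[name]) & universe
            if not members or not (set(mod.genes) & members):
                continue
            results.append(hypergeom_overlap(mod, members, universe,
                                             set_name=name))
    if correction == "bh" and results:
        adjusted = false_discovery_control([r.p for r in results],
                                           method="bh")
        return [(r, q < alpha) for r, q in zip(results, adjusted)]
    if correction not in (None, "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    return [(r, r.p < alpha) for r in results]


def write_overlap(edges: Sequence[tuple[OverlapResult, bool]],
                  path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# module\tcomplex\tk\tmodule_size\tcomplex_size\t"
                 "overlap_rate\tp\tsignificant\n")
        for res, sig in edges:
            fh.write(f"{res.module_id}\t{res.set_name}\t{res.k}\t"
                     f"{res.module_size}\t{res.set_size}\t"
                     f"{res.overlap_rate:.6g}\t{res.p:.12g}\t{int(sig)}\n")
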