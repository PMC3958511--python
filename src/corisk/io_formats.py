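"""Readers and writers for every external representation the pipeline touches.

All tabular artifacts are UTF-8 TSV with a single ``#``-prefixed header line.
Reals are serialized with 12 significant digits so that a write/read round
trip reproduces values to at least 10 significant digits.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger("corisk")

TUMOR = "tumor"
NORMAL = "normal"

#: Label tokens accepted without an explicit user mapping.
DEFAULT_LABEL_SPEC: dict[str, str] = {
    "tumor": TUMOR, "tumour": TUMOR, "t": TUMOR, "cancer": TUMOR, "disease": TUMOR,
    "normal": NORMAL, "n": NORMAL, "control": NORMAL, "healthy": NORMAL,
}

REAL_FMT = "%.12g"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class CycleError(FormatError):
    """Raised when an ontology file contains a cycle."""


class AnnotationError(FormatError):
    """Raised when an annotation source yields no usable annotations."""


# ---------------------------------------------------------------------------
# Expression data
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """Gene x sample expression matrix with a tumor/normal label per sample.

    Values are assumed already normalized; rows are genes, columns samples.
    """

    genes: list[str]
    samples: list[str]
    labels: list[str]  # per-sample, each ``tumor`` or ``normal``
    values: np.ndarray  # shape (n_genes, n_samples), float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise FormatError("duplicate gene identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("duplicate sample identifiers")
        if len(self.labels) != len(self.samples):
            raise FormatError("one label required per sample")
        bad = sorted({l for l in self.labels} - {TUMOR, NORMAL})
        if bad:
            raise FormatError(f"unknown label token(s): {bad}")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples")
        if np.isnan(self.values).any():
            raise FormatError("missing (NaN) expression values are rejected; "
                              "impute upstream")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    # -- convenience accessors -------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def tumor_mask(self) -> np.ndarray:
        return np.array([l == TUMOR for l in self.labels])

    @property
    def normal_mask(self) -> np.ndarray:
        return np.array([l == NORMAL for l in self.labels])

    @property
    def n_tumor(self) -> int:
        return int(self.tumor_mask.sum())

    @property
    def n_normal(self) -> int:
        return int(self.normal_mask.sum())

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def gene_indices(self, genes: Iterable[str]) -> np.ndarray:
        return np.array([self._gene_index[g] for g in genes], dtype=int)

    def has_two_per_class(self) -> bool:
        return self.n_tumor >= 2 and self.n_normal >= 2

    def require_two_per_class(self) -> None:
        """Risk computations refuse datasets with <2 samples in a class."""
        if not self.has_two_per_class():
            raise ValueError(
                f"need >=2 tumor and >=2 normal samples, have "
                f"{self.n_tumor} tumor / {self.n_normal} normal")


def _normalize_label(token: str, label_spec: Mapping[str, str] | None) -> str:
    if label_spec and token in label_spec:
        token = label_spec[token]
    out = DEFAULT_LABEL_SPEC.get(token.strip().lower())
    if out is None:
        raise FormatError(f"unknown label token {token!r}; supply a label_spec "
                          "mapping it to 'tumor' or 'normal'")
    return out


def read_expression(path: str | Path,
                    label_spec: Mapping[str, str] | None = None,
                    labels_path: str | Path | None = None) -> ExpressionDataset:
    """Read a tab-separated expression matrix.

    First row: sample identifiers; second row: class labels (or a two-column
    side-car file given as *labels_path*); remaining rows: gene + values.
    Duplicate gene rows are collapsed by their mean (logged).
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                     comment=None, skip_blank_lines=True)
    header = [str(x) for x in df.iloc[0, 1:]]
    if str(df.iloc[0, 0]).startswith("#"):
        pass  # leading '#' on the header row is tolerated
    row = 1
    if labels_path is None:
        raw_labels = [str(x) for x in df.iloc[1, 1:]]
        row = 2
    else:
        side = pd.read_csv(labels_path, sep="\t", header=None, dtype=str)
        mapping = dict(zip(side.iloc[:, 0], side.iloc[:, 1]))
        try:
            raw_labels = [mapping[s] for s in header]
        except KeyError as exc:
            raise FormatError(f"label side-car missing sample {exc}") from None
    labels = [_normalize_label(tok, label_spec) for tok in raw_labels]

    body = df.iloc[row:]
    genes = [str(g) for g in body.iloc[:, 0]]
    try:
        values = body.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-numeric expression cell: {exc}") from None
    if np.isnan(values).any():
        raise FormatError("missing expression values are rejected; impute upstream")

    if len(set(genes)) != len(genes):
        frame = pd.DataFrame(values, index=genes)
        dupes = sorted(frame.index[frame.index.duplicated()].unique())
        logger.warning("collapsing %d duplicated gene row(s) by mean: %s",
                       len(dupes), ", ".join(dupes[:10]))
        frame = frame.groupby(level=0, sort=False).mean()
        genes = list(frame.index)
        values = frame.to_numpy()

    ds = ExpressionDataset(genes=genes, samples=header, labels=labels,
                           values=values)
    if not ds.has_two_per_class():
        logger.warning("dataset has <2 samples in a class "
                       "(%d tumor / %d normal); risk operations will refuse it",
                       ds.n_tumor, ds.n_normal)
    return ds


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(dataset.samples) + "\n")
        fh.write("label\t" + "\t".join(dataset.labels) + "\n")
        for g, rowvals in zip(dataset.genes, dataset.values):
            fh.write(g + "\t" + "\t".join(REAL_FMT % v for v in rowvals) + "\n")


# ---------------------------------------------------------------------------
# Gene Ontology DAG
# ---------------------------------------------------------------------------

IS_A = "is_a"
PART_OF = "part_of"
EDGE_TYPES = (IS_A, PART_OF)


@dataclass
class GODag:
    """Directed acyclic term graph with typed (is_a / part_of) edges.

    Edges point child -> parent.  Only the two relation types the semantic
    similarity machinery weights are retained; everything else in the source
    ontology is ignored.
    """

    graph: nx.MultiDiGraph
    alt_ids: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, str]],
                   extra_terms: Iterable[str] = (),
                   alt_ids: Mapping[str, str] | None = None) -> "GODag":
        g = nx.MultiDiGraph()
        for child, parent, rel in edges:
            if rel not in EDGE_TYPES:
                raise FormatError(f"unsupported edge type {rel!r}")
            g.add_edge(child, parent, key=rel)
        g.add_nodes_from(extra_terms)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise CycleError(f"ontology contains a cycle through edge "
                             f"{cycle[0][0]} -> {cycle[0][1]}")
        return cls(graph=g, alt_ids=dict(alt_ids or {}))

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {n for n in self.graph.nodes if self.graph.out_degree(n) == 0}

    def __contains__(self, term: str) -> bool:
        return term in self.graph or term in self.alt_ids

    def resolve(self, term: str) -> str:
        """Map an alt_id to its primary identifier (identity otherwise)."""
        if term in self.graph:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise KeyError(f"unknown term {term!r}")

    def parents(self, term: str) -> list[tuple[str, str]]:
        """(parent, relation) pairs for *term*."""
        term = self.resolve(term)
        return [(p, key) for _, p, key in self.graph.out_edges(term, keys=True)]

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable upward from *term*, including *term* itself."""
        term = self.resolve(term)
        return {term} | nx.descendants(self.graph, term)


def read_obo(path: str | Path, namespace: str | None = None) -> GODag:
    """Load an OBO 1.2 ontology, keeping is_a and part_of edges only.

    Obsolete terms are dropped (obonet default) and alt_ids resolve to their
    primary identifier.  A cycle is a hard error naming one offending edge.
    By default all namespaces are pooled; pass *namespace* (e.g.
    ``biological_process``) to restrict to one.
    """
    raw = obonet.read_obo(path, ignore_obsolete=True)
    if namespace is not None:
        keep = {n for n, d in raw.nodes(data=True)
                if d.get("namespace") == namespace}
        raw = raw.subgraph(keep)
    edges = [(c, p, rel) for c, p, rel in raw.edges(keys=True)
             if rel in EDGE_TYPES]
    alt_ids: dict[str, str] = {}
    for node, data in raw.nodes(data=True):
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    return GODag.from_edges(edges, extra_terms=raw.nodes, alt_ids=alt_ids)


def write_obo(dag: GODag, path: str | Path, namespace: str = "biological_process") -> None:
    """Serialize a ``GODag`` as a minimal OBO 1.2 document."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        fh.write("ontology: corisk-synthetic\n\n")
        for term in sorted(dag.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {term}\n")
            fh.write(f"namespace: {namespace}\n")
            for parent, rel in sorted(dag.parents(term)):
                if rel == IS_A:
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Gene -> GO annotations
# ---------------------------------------------------------------------------

#: gene -> set of GO term identifiers; genes without annotation are absent.
AnnotationMap = dict[str, set[str]]


def _filter_annotations(pairs: Iterable[tuple[str, str]],
                        dag: GODag | None) -> AnnotationMap:
    ann: AnnotationMap = {}
    dropped = 0
    for gene, term in pairs:
        if dag is not None:
            if term in dag:
                term = dag.resolve(term)
            else:
                dropped += 1
                continue
        ann.setdefault(gene, set()).add(term)
    if dropped:
        logger.info("dropped %d annotation(s) to terms absent from the DAG",
                    dropped)
    if not ann:
        raise AnnotationError("zero usable annotations")
    return ann


def read_gaf(path: str | Path, dag: GODag | None = None) -> AnnotationMap:
    """Read GAF 2.x annotations (gene symbol column 3, GO id column 5).

    Lines with a NOT qualifier are dropped; evidence codes are not filtered.
    Malformed lines are skipped with a log message.
    """
    pairs: list[tuple[str, str]] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 15:
                skipped += 1
                continue
            qualifier, symbol, term = cols[3], cols[2], cols[4]
            if "NOT" in qualifier.split("|"):
                continue
            if not symbol or not term:
                skipped += 1
                continue
            pairs.append((symbol, term))
    if skipped:
        logger.warning("skipped %d malformed GAF line(s)", skipped)
    return _filter_annotations(pairs, dag)


def read_annotation_tsv(path: str | Path, dag: GODag | None = None) -> AnnotationMap:
    """Read a two-column gene<TAB>term file ('#' lines are comments)."""
    pairs: list[tuple[str, str]] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2 or not cols[0] or not cols[1]:
                skipped += 1
                continue
            pairs.append((cols[0], cols[1]))
    if skipped:
        logger.warning("skipped %d malformed annotation line(s)", skipped)
    return _filter_annotations(pairs, dag)


def write_annotation_tsv(ann: AnnotationMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# gene\tterm\n")
        for gene in sorted(ann):
            for term in sorted(ann[gene]):
                fh.write(f"{gene}\t{term}\n")


# ---------------------------------------------------------------------------
# Protein-complex catalog
# ---------------------------------------------------------------------------

#: complex name -> set of member gene identifiers
ComplexCatalog = dict[str, set[str]]


def read_complexes(path: str | Path) -> ComplexCatalog:
    """Two-column complex-name<TAB>member-gene TSV, one member per line."""
    catalog: ComplexCatalog = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise FormatError(f"malformed complex line: {line!r}")
            catalog.setdefault(cols[0], set()).add(cols[1])
    return catalog


def write_complexes(catalog: ComplexCatalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# complex\tgene\n")
        for name in sorted(catalog):
            for gene in sorted(catalog[name]):
                fh.write(f"{name}\t{gene}\n")


# ---------------------------------------------------------------------------
# Computed artifacts: edge lists, module tables, risk reports
# ---------------------------------------------------------------------------

def write_network(edges: Iterable[tuple[str, str, float, float]],
                  path: str | Path) -> None:
    """Edge list as gene1<TAB>gene2<TAB>r<TAB>sim."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# gene1\tgene2\tr\tsim\n")
        for g1, g2, r, sim in edges:
            fh.write(f"{g1}\t{g2}\t{REAL_FMT % r}\t{REAL_FMT % sim}\n")


def read_network(path: str | Path) -> list[tuple[str, str, float, float]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            g1, g2, r, sim = line.rstrip("\n").split("\t")
            out.append((g1, g2, float(r), float(sim)))
    return out


def write_modules(modules: Sequence, path: str | Path) -> None:
    """Module table: ID, size, genes (DE-genes starred), M_risk, p, risk class.

    Accepts ``riskscore.ModuleRisk`` objects or bare ``mcl.GeneModule``
    (in which case the risk columns are written as NA).
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# id\tsize\tgenes\tm_risk\tp_value\trisk\n")
        for mod in modules:
            base = getattr(mod, "module", mod)
            de = set(getattr(base, "de_genes", ()))
            genes = ",".join(g + ("*" if g in de else "")
                             for g in sorted(base.genes))
            m_risk = getattr(mod, "m_risk", None)
            p = getattr(mod, "null_p", None)
            risk = getattr(mod, "risk_class", None) or "NA"
            fh.write("\t".join([
                base.id, str(len(base.genes)), genes,
                REAL_FMT % m_risk if m_risk is not None else "NA",
                REAL_FMT % p if p is not None else "NA",
                risk,
            ]) + "\n")


def read_modules(path: str | Path) -> list[dict]:
    """Read a module table back into plain records (id, genes, de_genes, ...)."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            mid, size, genes_s, m_risk, p, risk = line.rstrip("\n").split("\t")
            genes, de = [], []
            for tok in genes_s.split(","):
                if tok.endswith("*"):
                    tok = tok[:-1]
                    de.append(tok)
                genes.append(tok)
            if len(genes) != int(size):
                raise FormatError(f"module {mid}: size column disagrees with "
                                  f"gene list length")
            out.append({
                "id": mid, "genes": set(genes), "de_genes": set(de),
                "m_risk": None if m_risk == "NA" else float(m_risk),
                "null_p": None if p == "NA" else float(p),
                "risk_class": None if risk == "NA" else risk,
            })
    return out


def write_report(report: Sequence, path: str | Path) -> None:
    """Per-sample risk report: sample, label, S_risk, call."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# sample\tlabel\ts_risk\tcall\n")
        for row in report:
            fh.write(f"{row.sample}\t{row.label}\t{REAL_FMT % row.s_risk}\t"
                     f"{row.call}\n")


def read_report(path: str | Path) -> list[dict]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            sample, label, s_risk, call = line.rstrip("\n").split("\t")
            out.append({"sample": sample, "label": label,
                        "s_risk": float(s_risk), "call": call})
    return out


def write_de_table(results: Sequence, path: str | Path) -> None:
    """Differential-expression table (one row per gene)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# gene\tn1T\tn2T\tn1N\tn2N\tbfln\tp\tis_de\n")
        for r in results:
            t = r.table
            fh.write("\t".join([
                r.gene, str(t.n1T), str(t.n2T), str(t.n1N), str(t.n2N),
                REAL_FMT % r.bfln, REAL_FMT % r.p, str(int(r.is_de)),
            ]) + "\n")


def read_de_table(path: str | Path) -> list[dict]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            gene, n1T, n2T, n1N, n2N, bf, p, is_de = line.rstrip("\n").split("\t")
            out.append({"gene": gene,
                        "table": (int(n1T), int(n2T), int(n1N), int(n2N)),
                        "bfln": float(bf), "p": float(p),
                        "is_de": bool(int(is_de))})
    return out
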