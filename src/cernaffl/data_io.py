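"""Readers, writers and core typed containers.

This is the only module that touches the filesystem. Expression matrices are
tab-separated, features in rows (the usual bioinformatics orientation), with a
companion sample-metadata table carrying the condition label (normal/tumor)
and an optional pair id for paired designs. Regulatory edges travel as a TSV
with typed endpoints and a semicolon-joined evidence column; SIF and GraphML
exports are provided for network viewers.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cernaffl")

NODE_TYPES = frozenset({"TF", "miRNA", "gene", "lncRNA"})
SOURCE_TYPES = frozenset({"TF", "miRNA"})
CONDITIONS = frozenset({"normal", "tumor"})
SIGNS = frozenset({"activation", "repression", "unknown"})

#: SIF relation tokens, fixed mapping from edge sign.
SIF_RELATION = {"activation": "activates", "repression": "represses", "unknown": "regulates"}


class DataValidationError(ValueError):
    """Raised when an input file or in-memory object violates an invariant."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Features x samples expression values plus per-sample metadata.

    ``values`` is a DataFrame indexed by feature id with sample ids as
    columns. ``sample_meta`` is indexed by sample id and has at least a
    ``condition`` column ('normal' | 'tumor') and an optional ``pair_id``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    feature_type: str = "mRNA"

    def __post_init__(self) -> None:
        if self.feature_type not in {"mRNA", "miRNA", "lncRNA"}:
            raise DataValidationError(f"unknown feature_type {self.feature_type!r}")
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        vals = self.values
        if vals.index.has_duplicates:
            dups = vals.index[vals.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate feature ids: {dups[:5]}")
        if vals.columns.has_duplicates:
            raise DataValidationError("duplicate sample ids")
        if not np.issubdtype(np.asarray(vals.values).dtype, np.number):
            raise DataValidationError("non-numeric expression values")
        if set(vals.columns) != set(self.sample_meta.index):
            missing = set(vals.columns) ^ set(self.sample_meta.index)
            raise DataValidationError(f"metadata/matrix sample mismatch: {sorted(missing)[:5]}")
        bad = set(self.sample_meta["condition"]) - CONDITIONS
        if bad:
            raise DataValidationError(f"unknown condition labels: {sorted(bad)}")
        if "pair_id" in self.sample_meta.columns:
            pairs = self.sample_meta.dropna(subset=["pair_id"])
            for pid, grp in pairs.groupby("pair_id"):
                if len(grp) != 2 or set(grp["condition"]) != CONDITIONS:
                    raise DataValidationError(
                        f"pair_id {pid!r} must occur exactly twice with opposite conditions"
                    )

    # -- convenience --------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def condition_mask(self, condition: str) -> np.ndarray:
        meta = self.sample_meta.loc[self.values.columns]
        return (meta["condition"] == condition).to_numpy()

    def subset_features(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = [i for i in ids if i in self.values.index]
        return ExpressionMatrix(self.values.loc[ids], self.sample_meta, self.feature_type)


def read_expression_matrix(
    path: str | Path, feature_type: str, meta_path: str | Path | None = None
) -> ExpressionMatrix:
    """Read a features-in-rows TSV plus its companion metadata TSV.

    The metadata path defaults to ``<path stem>.meta.tsv`` next to the matrix.
    Duplicate feature rows are an error, never merged.
    """
    path = Path(path)
    if meta_path is None:
        meta_path = path.with_suffix(".meta.tsv")
    raw = pd.read_csv(path, sep="\t", index_col=0)
    try:
        vals = raw.astype(float)
    except ValueError as exc:
        raise DataValidationError(f"non-numeric cell in {path}: {exc}") from exc
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    return ExpressionMatrix(vals, meta, feature_type)


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    expr.values.to_csv(path, sep="\t", index_label="feature_id")
    expr.sample_meta.to_csv(path.with_suffix(".meta.tsv"), sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Regulatory edges and typed networks
# ---------------------------------------------------------------------------

@dataclass
class RegulatoryEdge:
    """A directed, typed regulatory interaction.

    ``evidence`` records which source databases reported the pair so that
    intersection-of-evidence rules remain checkable downstream. ``r``/``p``
    are filled in once expression correlation has been computed; ``sign`` is
    'unknown' until direction inference runs.
    """

    source: str
    source_type: str
    target: str
    target_type: str
    evidence: frozenset[str] = frozenset()
    r: float | None = None
    p: float | None = None
    sign: str = "unknown"

    def __post_init__(self) -> None:
        if self.source_type not in SOURCE_TYPES:
            raise DataValidationError(f"invalid source_type {self.source_type!r}")
        if self.target_type not in NODE_TYPES:
            raise DataValidationError(f"invalid target_type {self.target_type!r}")
        if self.source == self.target:
            raise DataValidationError(f"self-edge {self.source!r}")
        if self.sign not in SIGNS:
            raise DataValidationError(f"invalid sign {self.sign!r}")
        if self.source_type == "miRNA" and self.sign == "activation":
            raise DataValidationError("miRNA-source edges cannot activate")
        if self.r is not None and self.p is None:
            raise DataValidationError("edge with r but no p")
        self.evidence = frozenset(self.evidence)

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)

    @property
    def edge_class(self) -> tuple[str, str]:
        return (self.source_type, self.target_type)

    def replace(self, **kw) -> "RegulatoryEdge":
        return dataclasses.replace(self, **kw)


@dataclass
class AnnotationSets:
    """External annotation lists the pipeline consumes as plain id sets."""

    tf_genes: frozenset[str] = frozenset()
    lung_enriched: frozenset[str] = frozenset()
    onco_tsg: frozenset[str] = frozenset()
    cytoplasmic_lncrnas: frozenset[str] = frozenset()
    ppi_edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        self.tf_genes = frozenset(self.tf_genes)
        self.lung_enriched = frozenset(self.lung_enriched)
        self.onco_tsg = frozenset(self.onco_tsg)
        self.cytoplasmic_lncrnas = frozenset(self.cytoplasmic_lncrnas)
        edges = []
        for a, b in self.ppi_edges:
            if a == b:
                raise DataValidationError(f"PPI self-pair {a!r}")
            edges.append((a, b))
        self.ppi_edges = tuple(edges)


@dataclass
class TypedNetwork:
    """A validated signed regulatory network over TF/miRNA/gene/lncRNA nodes.

    Every edge must be signed with correlation attached; miRNA-source edges
    are repressive with r <= mirna_r_max and TF-source edges satisfy
    |r| >= tf_r_min, all with p < alpha (the thresholds the network was built
    with are stored for re-validation).
    """

    node_types: dict[str, str]
    edges: list[RegulatoryEdge]
    mirna_r_max: float = -0.15
    tf_r_min: float = 0.3
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for node, t in self.node_types.items():
            if t not in NODE_TYPES:
                raise DataValidationError(f"node {node!r} has invalid type {t!r}")
        seen = set()
        for e in self.edges:
            if e.key in seen:
                raise DataValidationError(f"duplicate edge {e.key}")
            seen.add(e.key)
            if e.sign == "unknown" or e.r is None or e.p is None:
                raise DataValidationError(f"unsigned/uncorrelated edge {e.key}")
            if e.source_type == "miRNA":
                if e.sign != "repression" or e.r > self.mirna_r_max:
                    raise DataValidationError(f"miRNA edge {e.key} violates repression rule")
            else:
                if abs(e.r) < self.tf_r_min:
                    raise DataValidationError(f"TF edge {e.key} below |r| threshold")
            if e.p >= self.alpha:
                raise DataValidationError(f"edge {e.key} not significant")
            for node, t in ((e.source, e.source_type), (e.target, e.target_type)):
                if self.node_types.get(node, t) != t:
                    raise DataValidationError(f"conflicting type for node {node!r}")

    @property
    def nodes(self) -> list[str]:
        return list(self.node_types)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for n, t in self.node_types.items():
            g.add_node(n, node_type=t)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign, r=e.r, p=e.p,
                       evidence=";".join(sorted(e.evidence)))
        return g


# ---------------------------------------------------------------------------
# Edge table I/O
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ["source", "source_type", "target", "target_type", "evidence", "r", "p", "sign"]


def read_edge_table(path: str | Path) -> list[RegulatoryEdge]:
    """Read a typed edge TSV; duplicate (source, target) rows union evidence."""
    df = pd.read_csv(Path(path), sep="\t", dtype={"source": str, "target": str})
    required = {"source", "source_type", "target", "target_type"}
    if not required.issubset(df.columns):
        raise DataValidationError(f"edge table missing columns {sorted(required - set(df.columns))}")
    merged: dict[tuple[str, str], RegulatoryEdge] = {}
    for row in df.itertuples(index=False):
        evid = getattr(row, "evidence", "") or ""
        if isinstance(evid, float) and np.isnan(evid):
            evid = ""
        evidence = frozenset(t for t in str(evid).split(";") if t)
        r = getattr(row, "r", None)
        p = getattr(row, "p", None)
        r = None if r is None or (isinstance(r, float) and np.isnan(r)) else float(r)
        p = None if p is None or (isinstance(p, float) and np.isnan(p)) else float(p)
        sign = getattr(row, "sign", "unknown")
        if not isinstance(sign, str) or not sign:
            sign = "unknown"
        edge = RegulatoryEdge(row.source, row.source_type, row.target, row.target_type,
                              evidence=evidence, r=r, p=p, sign=sign)
        prev = merged.get(edge.key)
        if prev is not None:
            edge = edge.replace(evidence=prev.evidence | edge.evidence)
        merged[edge.key] = edge
    return list(merged.values())


def write_edges(edges: Sequence[RegulatoryEdge], path: str | Path) -> None:
    rows = [
        {
            "source": e.source, "source_type": e.source_type,
            "target": e.target, "target_type": e.target_type,
            "evidence": ";".join(sorted(e.evidence)),
            "r": "" if e.r is None else f"{e.r:.6f}",
            "p": "" if e.p is None else f"{e.p:.6g}",
            "sign": e.sign,
        }
        for e in edges
    ]
    pd.DataFrame(rows, columns=_EDGE_COLUMNS).to_csv(Path(path), sep="\t", index=False)


def write_network(net: TypedNetwork, path: str | Path, format: str = "edge-TSV") -> None:
    """Export a network as edge-TSV (round-trippable), SIF, or GraphML."""
    path = Path(path)
    if format == "edge-TSV":
        write_edges(net.edges, path)
    elif format == "SIF":
        with open(path, "w") as fh:
            for e in net.edges:
                fh.write(f"{e.source}\t{SIF_RELATION[e.sign]}\t{e.target}\n")
    elif format == "GraphML":
        nx.write_graphml(net.to_digraph(), path)
    else:
        raise DataValidationError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# Annotations and config
# ---------------------------------------------------------------------------

def read_annotation_sets(path: str | Path) -> AnnotationSets:
    """Read annotation lists from a YAML document (keys = field names)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    return AnnotationSets(
        tf_genes=frozenset(doc.get("tf_genes", [])),
        lung_enriched=frozenset(doc.get("lung_enriched", [])),
        onco_tsg=frozenset(doc.get("onco_tsg", [])),
        cytoplasmic_lncrnas=frozenset(doc.get("cytoplasmic_lncrnas", [])),
        ppi_edges=tuple(tuple(p) for p in doc.get("ppi_edges", [])),
    )


def write_annotation_sets(ann: AnnotationSets, path: str | Path) -> None:
    doc = {
        "tf_genes": sorted(ann.tf_genes),
        "lung_enriched": sorted(ann.lung_enriched),
        "onco_tsg": sorted(ann.onco_tsg),
        "cytoplasmic_lncrnas": sorted(ann.cytoplasmic_lncrnas),
        "ppi_edges": [list(p) for p in ann.ppi_edges],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def log_stage(stage: str, **counts) -> None:
    """Uniform stage logging: one line, stage name plus named counts."""
    parts = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("[%s] %s", stage, parts)
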