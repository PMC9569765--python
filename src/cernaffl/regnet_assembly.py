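"""Assembly of the 4-node-type regulatory edge set and direction inference.

Edges arrive from multiple evidence sources; some edge classes (e.g.
miRNA->lncRNA) require corroboration by *every* listed source (intersection
rule), the rest keep the union. Regulation direction and sign are then
inferred from expression: a miRNA-source edge survives as repression when
Pearson r <= -0.15 with p < 0.05; a TF-source edge survives when |r| >= 0.3
with p < 0.05, signed activation/repression by the sign of r. The TF's
expression is proxied by its mRNA profile.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import (DataValidationError, ExpressionMatrix, RegulatoryEdge,
                      TypedNetwork, log_stage)


def merge_pair_sources(
    edge_lists: dict[str, list[RegulatoryEdge]],
    required_sources: dict[tuple[str, str], set[str]] | None = None,
) -> list[RegulatoryEdge]:
    """De-duplicate edges across sources, enforcing per-class evidence rules.

    ``edge_lists`` maps source-database name -> edges (each edge's evidence is
    widened with that name). An edge class listed in ``required_sources``
    keeps only edges whose final evidence covers every required source; other
    classes keep the union of all sources.
    """
    required_sources = required_sources or {}
    merged: dict[tuple[str, str], RegulatoryEdge] = {}
    node_types: dict[str, str] = {}
    for src_name, edges in edge_lists.items():
        for e in edges:
            for node, t in ((e.source, e.source_type), (e.target, e.target_type)):
                if node_types.setdefault(node, t) != t:
                    raise DataValidationError(f"conflicting node types for {node!r}")
            e = e.replace(evidence=e.evidence | {src_name})
            prev = merged.get(e.key)
            if prev is not None:
                e = e.replace(evidence=prev.evidence | e.evidence)
            merged[e.key] = e
    out = []
    for e in merged.values():
        rule = required_sources.get(e.edge_class)
        if rule is not None and not rule <= e.evidence:
            continue
        out.append(e)
    return out


def infer_direction(edges: list[RegulatoryEdge],
                    expr_by_type: dict[str, ExpressionMatrix],
                    mirna_r_max: float = -0.15, tf_r_min: float = 0.3,
                    alpha: float = 0.05) -> tuple[TypedNetwork, pd.DataFrame]:
    """Attach correlation-based signs and keep edges passing their class rule.

    Returns the validated TypedNetwork and a drop log (edge key + reason).
    TF profiles are looked up in the mRNA matrix; miRNA profiles in the miRNA
    matrix; targets in the matrix of their own type (a TF target's profile is
    its mRNA).
    """
    def profile(node: str, node_type: str) -> np.ndarray | None:
        ftype = {"TF": "mRNA", "gene": "mRNA", "miRNA": "miRNA", "lncRNA": "lncRNA"}[node_type]
        mat = expr_by_type.get(ftype)
        if mat is None or node not in mat.values.index:
            return None
        return mat.values.loc[node]

    shared = None
    for mat in expr_by_type.values():
        cols = set(mat.sample_ids)
        shared = cols if shared is None else shared & cols
    shared = sorted(shared or [])
    if len(shared) < 10:
        raise DataValidationError("need >= 10 shared samples across expression matrices")

    kept: list[RegulatoryEdge] = []
    dropped: list[dict] = []
    node_types: dict[str, str] = {}
    for e in edges:
        xs = profile(e.source, e.source_type)
        ys = profile(e.target, e.target_type)
        if xs is None or ys is None:
            dropped.append({"source": e.source, "target": e.target,
                            "reason": "missing_expression"})
            continue
        x = xs[shared].to_numpy(dtype=float)
        y = ys[shared].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            dropped.append({"source": e.source, "target": e.target, "reason": "constant"})
            continue
        res = stats.pearsonr(x, y)
        r, p = float(res.statistic), float(res.pvalue)
        if e.source_type == "miRNA":
            if r <= mirna_r_max and p < alpha:
                kept.append(e.replace(r=r, p=p, sign="repression"))
            else:
                dropped.append({"source": e.source, "target": e.target,
                                "reason": "below_mirna_threshold"})
        else:
            if abs(r) >= tf_r_min and p < alpha:
                sign = "activation" if r > 0 else "repression"
                kept.append(e.replace(r=r, p=p, sign=sign))
            else:
                dropped.append({"source": e.source, "target": e.target,
                                "reason": "below_tf_threshold"})
    for e in kept:
        node_types[e.source] = e.source_type
        node_types[e.target] = e.target_type
    net = TypedNetwork(node_types, kept, mirna_r_max=mirna_r_max,
                       tf_r_min=tf_r_min, alpha=alpha)
    log_stage("infer_direction", kept=len(kept), dropped=len(dropped))
    return net, pd.DataFrame(dropped, columns=["source", "target", "reason"])


def build_typed_network(edges: list[RegulatoryEdge],
                        node_types: dict[str, str] | None = None,
                        mirna_r_max: float = -0.15, tf_r_min: float = 0.3,
                        alpha: float = 0.05) -> TypedNetwork:
    """Validate signed edges into a TypedNetwork, dropping isolated nodes."""
    for e in edges:
        if e.sign == "unknown":
            raise DataValidationError(f"unsigned edge {e.key}")
    types: dict[str, str] = {}
    for e in edges:
        for node, t in ((e.source, e.source_type), (e.target, e.target_type)):
            if types.setdefault(node, t) != t:
                raise DataValidationError(f"conflicting node types for {node!r}")
    if node_types:
        for n, t in node_types.items():
            if n in types and types[n] != t:
                raise DataValidationError(f"conflicting node types for {n!r}")
    return TypedNetwork(types, list(edges), mirna_r_max=mirna_r_max,
                        tf_r_min=tf_r_min, alpha=alpha)
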