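"""Second screening arm, arm intersection, ROC gating and validation helpers.

Arm 2 ("biological significance") keeps the genes of the most
disease-correlated co-expression module that are both lung-enriched and
oncogenes/tumor suppressors, then retains validated miRNA-gene pairs with a
strong negative expression correlation (r < -0.3, p < 0.05). Candidates from
the two arms are intersected and gated by ROC AUC > 0.85 on the miRNA's own
expression against the tumor/normal labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import AnnotationSets, DataValidationError, ExpressionMatrix, RegulatoryEdge


@dataclass
class BiomarkerRecord:
    mirna: str
    arm1: bool
    arm2: bool
    auc: float = float("nan")
    final: bool = False
    important_genes: set[str] = field(default_factory=set)
    nog_genes: set[str] = field(default_factory=set)
    nog: int = 0
    tfp: float = 0.0


def filter_disease_genes(module_genes: set[str], ann: AnnotationSets) -> set[str]:
    """Module genes that are lung-enriched oncogenes/tumor suppressors."""
    return set(module_genes) & set(ann.lung_enriched) & set(ann.onco_tsg)


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def strong_pairs(expr_mirna: ExpressionMatrix, expr_mrna: ExpressionMatrix,
                 validated_edges: list[RegulatoryEdge], key_genes: set[str],
                 r_max: float = -0.3, alpha: float = 0.05) -> list[RegulatoryEdge]:
    """Validated miRNA->gene pairs with strong negative expression correlation.

    Only edges targeting ``key_genes`` are considered; survivors carry their
    Pearson r and p. The source miRNAs of survivors are the arm-2 candidates.
    """
    shared = [s for s in expr_mirna.sample_ids if s in set(expr_mrna.sample_ids)]
    if len(shared) < 3:
        raise DataValidationError("need >= 3 shared samples for correlation")
    mir_vals = expr_mirna.values[shared]
    gene_vals = expr_mrna.values[shared]
    kept = []
    for e in validated_edges:
        if e.target not in key_genes:
            continue
        if e.source not in mir_vals.index or e.target not in gene_vals.index:
            continue
        r, p = _pearson_with_p(mir_vals.loc[e.source].to_numpy(dtype=float),
                               gene_vals.loc[e.target].to_numpy(dtype=float))
        if r < r_max and p < alpha:
            kept.append(e.replace(r=r, p=p, sign="repression"))
    return kept


def intersect_candidates(arm1: set[str], arm2: set[str]) -> set[str]:
    return set(arm1) & set(arm2)


def roc_auc(scores, labels, auto_orient: bool = False) -> float:
    """AUC via the Mann-Whitney statistic, ties counted 1/2.

    ``labels`` are 0/1; orientation is as-given unless ``auto_orient``, which
    returns max(AUC, 1 - AUC) so markers shifted in either direction score
    symmetrically.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DataValidationError("both label classes required")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - len(pos) * (len(pos) + 1) / 2
    auc = u / (len(pos) * len(neg))
    return float(max(auc, 1 - auc)) if auto_orient else float(auc)


def cellline_correlation(x, y, z_max: float = 2.0) -> tuple[float, int]:
    """Pearson r after z-score outlier removal (|z| >= z_max in either variable).

    z-scores are computed once on the full vectors, not re-computed after
    removal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise DataValidationError("need >= 5 paired observations")
    zx = stats.zscore(x)
    zy = stats.zscore(y)
    keep = (np.abs(zx) < z_max) & (np.abs(zy) < z_max)
    if keep.sum() < 3:
        raise DataValidationError("fewer than 3 observations remain after outlier removal")
    r, _ = _pearson_with_p(x[keep], y[keep])
    return r, int(keep.sum())


def final_biomarkers(arm1: set[str], arm2: set[str], expr_mirna: ExpressionMatrix,
                     auc_min: float = 0.85, auto_orient: bool = True,
                     nog_info: dict[str, tuple[int, float, set[str]]] | None = None,
                     important_by_mirna: dict[str, set[str]] | None = None,
                     ) -> list[BiomarkerRecord]:
    """Intersect the arms and gate by ROC AUC of the miRNA's expression."""
    labels = (expr_mirna.sample_meta.loc[expr_mirna.sample_ids, "condition"]
              == "tumor").astype(int).to_numpy()
    records = []
    for m in sorted(arm1 | arm2):
        rec = BiomarkerRecord(m, arm1=m in arm1, arm2=m in arm2)
        if nog_info and m in nog_info:
            rec.nog, rec.tfp, rec.nog_genes = nog_info[m]
        if important_by_mirna and m in important_by_mirna:
            rec.important_genes = important_by_mirna[m]
        if rec.arm1 and rec.arm2 and m in expr_mirna.values.index:
            rec.auc = roc_auc(expr_mirna.values.loc[m].to_numpy(dtype=float),
                              labels, auto_orient=auto_orient)
            rec.final = rec.auc > auc_min
        records.append(rec)
    return records
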