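"""Differential expression calling on count matrices.

Normalization is median-of-ratios (library-composition size factors) and the
per-feature test is a rank test: Mann-Whitney U across groups for unpaired
designs, Wilcoxon signed-rank on within-pair differences for paired ones.
This deliberately trades the negative-binomial GLM machinery of dedicated DE
packages for an assumption-light procedure: downstream stages only consume
the *sets* of up/down features, called at |log2FC| >= 1.5 and BH-adjusted
p <= 0.05. Externally computed DE tables can be substituted via
``deresults_from_table``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import DataValidationError, ExpressionMatrix

#: pseudocount added to normalized group means before the log-ratio
PSEUDOCOUNT = 0.5

LFC_THRESHOLD = 1.5
PADJ_THRESHOLD = 0.05


@dataclass
class DEResult:
    feature_id: str
    log2fc: float
    p: float
    padj: float
    call: str  # 'up' | 'down' | 'none'


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    factor_j = median over all-nonzero features i of count_ij / geomean_i(count_i.).
    """
    vals = counts.values.to_numpy(dtype=float)
    nonzero = (vals > 0).all(axis=1)
    if not nonzero.any():
        raise DataValidationError("no feature with nonzero counts in every sample")
    sub = vals[nonzero]
    log_geomean = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geomean)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


def normalize_counts(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample by its size factor."""
    f = size_factors(counts)
    return ExpressionMatrix(counts.values / f, counts.sample_meta, counts.feature_type)


def log_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """log2(normalized count + 1): the variance-stabilized scale used for
    correlations and co-expression (Pearson r on raw counts is attenuated by
    the multiplicative noise of count data)."""
    norm = normalize_counts(counts)
    return ExpressionMatrix(np.log2(norm.values + 1.0), counts.sample_meta,
                            counts.feature_type)


def de_test(counts: ExpressionMatrix, paired: bool = False,
            lfc_threshold: float = LFC_THRESHOLD,
            padj_threshold: float = PADJ_THRESHOLD) -> list[DEResult]:
    """Call differential features between tumor and normal samples.

    log2FC = log2((mean tumor + 0.5) / (mean normal + 0.5)) on normalized
    counts; BH correction is applied over all tested features of the matrix
    (callers keep mRNA and miRNA families separate by testing each matrix on
    its own).
    """
    tumor_mask = counts.condition_mask("tumor")
    normal_mask = counts.condition_mask("normal")
    if tumor_mask.sum() < 2 or normal_mask.sum() < 2:
        raise DataValidationError("each condition needs >= 2 samples")

    norm = normalize_counts(counts).values
    arr = norm.to_numpy(dtype=float)
    t_mean = arr[:, tumor_mask].mean(axis=1)
    n_mean = arr[:, normal_mask].mean(axis=1)
    log2fc = np.log2((t_mean + PSEUDOCOUNT) / (n_mean + PSEUDOCOUNT))

    if paired:
        meta = counts.sample_meta
        if "pair_id" not in meta.columns or meta["pair_id"].isna().any():
            raise DataValidationError("paired test requires complete pair_ids")
        pairs = meta.groupby("pair_id")
        t_cols, n_cols = [], []
        for _, grp in sorted(pairs, key=lambda kv: str(kv[0])):
            t_cols.append(grp[grp["condition"] == "tumor"].index[0])
            n_cols.append(grp[grp["condition"] == "normal"].index[0])
        diffs = norm[t_cols].to_numpy() - norm[n_cols].to_numpy()
        pvals = np.ones(arr.shape[0])
        for i, d in enumerate(diffs):
            d = d[d != 0]
            if len(d) == 0:
                pvals[i] = 1.0
            else:
                pvals[i] = stats.wilcoxon(d).pvalue
    else:
        t_vals = arr[:, tumor_mask]
        n_vals = arr[:, normal_mask]
        pvals = np.empty(arr.shape[0])
        for i in range(arr.shape[0]):
            if np.ptp(np.concatenate([t_vals[i], n_vals[i]])) == 0:
                pvals[i] = 1.0
            else:
                pvals[i] = stats.mannwhitneyu(t_vals[i], n_vals[i],
                                              alternative="two-sided").pvalue

    padj = multipletests(pvals, method="fdr_bh")[1]
    results = []
    for fid, lfc, p, pa in zip(counts.feature_ids, log2fc, pvals, padj):
        if pa <= padj_threshold and lfc >= lfc_threshold:
            call = "up"
        elif pa <= padj_threshold and lfc <= -lfc_threshold:
            call = "down"
        else:
            call = "none"
        results.append(DEResult(fid, float(lfc), float(p), float(pa), call))
    return results


def de_sets(results: list[DEResult]) -> tuple[set[str], set[str]]:
    """(up, down) feature-id sets from DE results."""
    up = {r.feature_id for r in results if r.call == "up"}
    down = {r.feature_id for r in results if r.call == "down"}
    return up, down


def deresults_to_table(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.feature_id, r.log2fc, r.p, r.padj, r.call) for r in results],
        columns=["feature_id", "log2fc", "p", "padj", "call"],
    )


def deresults_from_table(df: pd.DataFrame) -> list[DEResult]:
    """Accept an externally computed DE table (e.g. from a NB-GLM tool)."""
    return [DEResult(str(r.feature_id), float(r.log2fc), float(r.p),
                     float(r.padj), str(r.call)) for r in df.itertuples(index=False)]
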