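"""Independent-regulation scoring of miRNAs on a bipartite miRNA-mRNA network.

The model ranks miRNAs by two statistics computed on the disease-specific
bipartite network:

* **NOG** — the number of genes a miRNA targets *uniquely*, i.e. targets
  whose only miRNA regulator in the network is that miRNA. A high NOG means
  the miRNA's regulatory effect cannot be compensated by other miRNAs.
* **TFP** — the fraction of a miRNA's targets that are transcription-factor
  genes, a proxy for the downstream reach of its regulon.

Candidates must score significantly high on both (leave-one-out one-sample
Wilcoxon signed-rank, p < 0.05) and then exceed the median NOG of the
significant set.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import DataValidationError, RegulatoryEdge


@dataclass
class BipartiteNet:
    """Directed bipartite miRNA -> gene network."""

    mirnas: set[str]
    genes: set[str]
    edges: set[tuple[str, str]]

    def __post_init__(self) -> None:
        for m, g in self.edges:
            if m not in self.mirnas or g not in self.genes:
                raise DataValidationError(f"edge ({m!r}, {g!r}) endpoint not in node sets")
        if self.mirnas & self.genes:
            raise DataValidationError("miRNA and gene id sets overlap")

    @classmethod
    def from_edges(cls, edges: set[tuple[str, str]]) -> "BipartiteNet":
        return cls({m for m, _ in edges}, {g for _, g in edges}, set(edges))

    def targets(self, m: str) -> set[str]:
        return {g for mm, g in self.edges if mm == m}

    def gene_indegree(self) -> Counter:
        return Counter(g for _, g in self.edges)


@dataclass
class MiRnaScore:
    mirna: str
    nog: int
    tfp: float
    out_degree: int
    nog_p: float = 1.0
    tfp_p: float = 1.0
    passes_screen: bool = False
    passes_median: bool = False


def extract_disease_network(global_edges: list[RegulatoryEdge],
                            de_mirnas: set[str], de_genes: set[str]) -> BipartiteNet:
    """Restrict a global miRNA->gene edge list to differential nodes.

    An edge survives iff both its miRNA and its gene are differentially
    expressed; nodes left without edges are dropped.
    """
    kept = {
        (e.source, e.target)
        for e in global_edges
        if e.source_type == "miRNA" and e.source in de_mirnas and e.target in de_genes
    }
    return BipartiteNet.from_edges(kept)


def nog(net: BipartiteNet, m: str) -> int:
    """Number of genes uniquely targeted by miRNA ``m`` (in-degree 1 targets)."""
    if m not in net.mirnas:
        raise DataValidationError(f"unknown miRNA {m!r}")
    indeg = net.gene_indegree()
    return sum(1 for g in net.targets(m) if indeg[g] == 1)


def tfp(net: BipartiteNet, m: str, tf_genes: set[str]) -> float:
    """Fraction of m's targets that are transcription-factor genes."""
    targets = net.targets(m)
    if not targets:
        raise DataValidationError(f"miRNA {m!r} has no targets")
    return len(targets & set(tf_genes)) / len(targets)


def score_mirnas(net: BipartiteNet, tf_genes: set[str]) -> list[MiRnaScore]:
    """NOG and TFP for every miRNA with >= 1 target, sorted by id."""
    indeg = net.gene_indegree()
    scores = []
    for m in sorted(net.mirnas):
        targets = net.targets(m)
        if not targets:
            continue
        n = sum(1 for g in targets if indeg[g] == 1)
        scores.append(MiRnaScore(m, n, len(targets & set(tf_genes)) / len(targets),
                                 len(targets)))
    return scores


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def _signed_rank_p_less(diffs: np.ndarray, exact_max_n: int = 14) -> float:
    """One-sided one-sample Wilcoxon signed-rank p for H1: location < 0.

    Zeros are dropped (Wilcoxon practice). For n <= ``exact_max_n`` the exact
    conditional null (all 2^n sign assignments, midranks for tied
    magnitudes) is enumerated; beyond that the normal approximation with tie
    correction is used.
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    if n <= exact_max_n:
        # exact: distribution of the positive-rank sum under random signs
        count = 0
        total = 2 ** n
        for signs in itertools.product((0, 1), repeat=n):
            w = sum(r for s, r in zip(signs, ranks) if s)
            if w <= w_pos + 1e-12:
                count += 1
        return count / total
    mu = n * (n + 1) / 4
    # tie-corrected variance of the signed-rank statistic
    t = stats.rankdata(np.abs(d), method="dense")
    _, tie_counts = np.unique(t, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24 - (tie_counts ** 3 - tie_counts).sum() / 48
    if var <= 0:
        return 1.0
    z = (w_pos + 0.5 - mu) / np.sqrt(var)
    return float(stats.norm.cdf(z))


def significance_screen(scores: list[MiRnaScore], alpha: float = 0.05) -> list[MiRnaScore]:
    """Flag miRNAs whose NOG and TFP are both significantly high.

    For candidate i the test compares {score_j - score_i : j != i} against 0
    with a one-sided signed-rank test (H1: the differences lie below 0, i.e.
    the candidate exceeds the population). ``passes_screen`` requires p <
    alpha for NOG and TFP simultaneously.
    """
    if len(scores) < 6:
        raise DataValidationError("need >= 6 miRNAs for an attainable signed-rank p < 0.05")
    nogs = np.array([s.nog for s in scores], dtype=float)
    tfps = np.array([s.tfp for s in scores], dtype=float)
    out = []
    for i, s in enumerate(scores):
        others = np.arange(len(scores)) != i
        s.nog_p = _signed_rank_p_less(nogs[others] - nogs[i])
        s.tfp_p = _signed_rank_p_less(tfps[others] - tfps[i])
        s.passes_screen = (s.nog_p < alpha) and (s.tfp_p < alpha)
        out.append(s)
    return out


def median_filter(passing: list[MiRnaScore]) -> list[MiRnaScore]:
    """Keep miRNAs with NOG strictly greater than the median NOG of ``passing``."""
    if not passing:
        return []
    med = float(np.median([s.nog for s in passing]))
    kept = []
    for s in passing:
        s.passes_median = s.nog > med
        if s.passes_median:
            kept.append(s)
    return kept


def candidate_mirnas(scores: list[MiRnaScore], alpha: float = 0.05) -> set[str]:
    """Full arm-1 screen: significance screen then median filter."""
    screened = significance_screen(scores, alpha=alpha)
    passing = [s for s in screened if s.passes_screen]
    return {s.mirna for s in median_filter(passing)}


def nog_power_check(scores: list[MiRnaScore]) -> tuple[float, float]:
    """Diagnostic log-log fit of the NOG frequency distribution.

    Regresses log10(frequency) on log10(NOG) over observed NOG values >= 1
    and returns (slope, R^2). A heavy-tailed (power-law-like) NOG
    distribution gives a strongly linear fit with negative slope. Never gates
    the pipeline.
    """
    nogs = [s.nog for s in scores if s.nog >= 1]
    if len(nogs) < 10:
        raise DataValidationError("need >= 10 miRNAs with NOG >= 1")
    counts = Counter(nogs)
    if len(counts) < 3:
        raise DataValidationError("need >= 3 distinct NOG values for a log-log fit")
    xs = np.log10(sorted(counts))
    ys = np.log10([counts[v] for v in sorted(counts)])
    fit = stats.linregress(xs, ys)
    return float(fit.slope), float(fit.rvalue ** 2)
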