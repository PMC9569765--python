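"""4-node feed-forward-loop enumeration, hub scoring and ceRNA filtering.

A motif is a quadruple (TF T, miRNA M, gene G, lncRNA L) whose core edges
M->G, M->L, T->G, T->L are all present, classified by the TF-miRNA linkage:

* type I   (TF-mediated):    T->M present, M->T absent
* type II  (miRNA-mediated): M->T present, T->M absent
* type III (composite):      both T->M and M->T (a feedback loop)

The three types partition the quadruples satisfying the core requirement, so
counts never double-book a composite loop as type I plus type II. The T->L
requirement can be relaxed (``require_tf_lncrna=False``) for the variant
grammar in which the TF touches only the gene side.

Hubs are scored on the motif-participating network by degree and by maximal
clique centrality (MCC: sum over maximal cliques containing the node of
(|clique| - 1)!, on the undirected simple projection); the top 5% by either
metric are key nodes. Genes additionally pass through a PPI degree filter
(top 10%) before the ceRNA step restricts lncRNAs to cytoplasmic ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .data_io import DataValidationError, RegulatoryEdge, TypedNetwork, log_stage


@dataclass
class FFLMotif:
    tf: str
    mirna: str
    gene: str
    lncrna: str
    ffl_type: str  # 'I' | 'II' | 'III'
    member_edges: tuple[RegulatoryEdge, ...]

    @property
    def nodes(self) -> tuple[str, str, str, str]:
        return (self.tf, self.mirna, self.gene, self.lncrna)


@dataclass
class HubReport:
    degree: dict[str, int]
    mcc: dict[str, int]
    key_nodes: set[str]
    ppi_hub_genes: set[str]


def enumerate_ffl(net: TypedNetwork, require_tf_lncrna: bool = True) -> list[FFLMotif]:
    """All 4-node FFL motifs of a typed network, one per valid quadruple."""
    edge_map = {e.key: e for e in net.edges}
    by_type: dict[str, list[str]] = {"TF": [], "miRNA": [], "gene": [], "lncRNA": []}
    for n, t in net.node_types.items():
        by_type[t].append(n)
    out_targets: dict[str, dict[str, set[str]]] = {}
    for e in net.edges:
        out_targets.setdefault(e.source, {}).setdefault(e.target_type, set()).add(e.target)

    motifs: list[FFLMotif] = []
    for m in sorted(by_type["miRNA"]):
        m_out = out_targets.get(m, {})
        m_genes = m_out.get("gene", set())
        m_lncs = m_out.get("lncRNA", set())
        m_tfs = m_out.get("TF", set())
        if not m_genes or not m_lncs:
            continue
        for t in sorted(by_type["TF"]):
            t_out = out_targets.get(t, {})
            tf_to_m = m in t_out.get("miRNA", set())
            m_to_tf = t in m_tfs
            if not tf_to_m and not m_to_tf:
                continue
            ffl_type = "III" if (tf_to_m and m_to_tf) else ("I" if tf_to_m else "II")
            genes = m_genes & t_out.get("gene", set())
            if require_tf_lncrna:
                lncs = m_lncs & t_out.get("lncRNA", set())
            else:
                lncs = m_lncs
            for g in sorted(genes):
                for l in sorted(lncs):
                    members = [edge_map[(m, g)], edge_map[(m, l)], edge_map[(t, g)]]
                    if require_tf_lncrna:
                        members.append(edge_map[(t, l)])
                    elif (t, l) in edge_map:
                        members.append(edge_map[(t, l)])
                    if tf_to_m:
                        members.append(edge_map[(t, m)])
                    if m_to_tf:
                        members.append(edge_map[(m, t)])
                    motifs.append(FFLMotif(t, m, g, l, ffl_type, tuple(members)))
    log_stage("enumerate_ffl", motifs=len(motifs))
    return motifs


def _top_by(metric: dict[str, float], k: int) -> set[str]:
    """Top-k nodes by metric value, all ties at the cutoff included."""
    if not metric or k <= 0:
        return set()
    ordered = sorted(metric.items(), key=lambda kv: (-kv[1], kv[0]))
    cutoff = ordered[min(k, len(ordered)) - 1][1]
    return {n for n, v in metric.items() if v >= cutoff}


def mcc_scores(g: nx.Graph) -> dict[str, int]:
    """Maximal clique centrality on an undirected graph.

    MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!; an
    isolated node scores 0 (its only 'clique' is itself).
    """
    scores = {n: 0 for n in g.nodes}
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue
        w = math.factorial(len(clique) - 1)
        for n in clique:
            scores[n] += w
    return scores


def hub_nodes(net: TypedNetwork, top_fraction: float = 0.05) -> HubReport:
    """Key nodes: top ceil(f*n) by total degree union top ceil(f*n) by MCC."""
    g = net.to_digraph()
    if g.number_of_nodes() == 0:
        raise DataValidationError("empty network")
    degree = {n: d for n, d in g.degree()}
    mcc = mcc_scores(g.to_undirected())
    k = math.ceil(top_fraction * g.number_of_nodes())
    key = _top_by(degree, k) | _top_by({n: float(v) for n, v in mcc.items()}, k)
    return HubReport(degree, mcc, key, set())


def ppi_hub_genes(ppi: list[tuple[str, str]], candidate_genes: set[str],
                  top_fraction: float = 0.10) -> set[str]:
    """Top-degree genes of the PPI subgraph induced by candidate genes."""
    g = nx.Graph()
    for a, b in ppi:
        if a in candidate_genes and b in candidate_genes:
            g.add_edge(a, b)
    if g.number_of_nodes() == 0:
        raise DataValidationError("PPI induced subgraph is empty")
    degree = {n: float(d) for n, d in g.degree()}
    k = math.ceil(top_fraction * g.number_of_nodes())
    return _top_by(degree, k)


def extract_hub_ffl(motifs: list[FFLMotif], hubs: HubReport) -> list[FFLMotif]:
    """Two-stage restriction: key-node membership, then PPI-hub gene."""
    stage1 = [m for m in motifs if set(m.nodes) & hubs.key_nodes]
    stage2 = [m for m in stage1 if m.gene in hubs.ppi_hub_genes]
    log_stage("extract_hub_ffl", input=len(motifs), key_stage=len(stage1),
              ppi_stage=len(stage2))
    return stage2


def cerna_filter(motifs: list[FFLMotif], cytoplasmic: set[str]) -> list[FFLMotif]:
    """Keep motifs whose lncRNA is cytoplasmic (can act as a ceRNA sponge)."""
    return [m for m in motifs if m.lncrna in cytoplasmic]


def mirna_subnetwork(motifs: list[FFLMotif], mirna: str) -> TypedNetwork:
    """Union of member edges over one miRNA's motifs (empty if absent)."""
    mine = [m for m in motifs if m.mirna == mirna]
    if not mine:
        log_stage("mirna_subnetwork", mirna=mirna, motifs=0)
        return TypedNetwork({}, [])
    edges: dict[tuple[str, str], RegulatoryEdge] = {}
    types: dict[str, str] = {}
    for mot in mine:
        for e in mot.member_edges:
            edges[e.key] = e
            types[e.source] = e.source_type
            types[e.target] = e.target_type
    # permissive re-validation thresholds: member edges passed the real ones upstream
    r_vals = [e.r for e in edges.values() if e.source_type == "miRNA"]
    return TypedNetwork(types, list(edges.values()),
                        mirna_r_max=max(r_vals) if r_vals else -0.15,
                        tf_r_min=0.0, alpha=1.0)


def motif_type_counts(motifs: list[FFLMotif]) -> dict[str, int]:
    counts = {"I": 0, "II": 0, "III": 0}
    for m in motifs:
        counts[m.ffl_type] += 1
    return counts
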