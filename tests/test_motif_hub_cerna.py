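import itertools

import networkx as nx
import numpy as np
import pytest

from cernaffl import motif_hub_cerna as mh
from cernaffl.data_io import DataValidationError, RegulatoryEdge, TypedNetwork


def signed_edge(src, stype, tgt, ttype):
    if stype == "miRNA":
        return RegulatoryEdge(src, stype, tgt, ttype, r=-0.5, p=0.01, sign="repression")
    return RegulatoryEdge(src, stype, tgt, ttype, r=0.5, p=0.01, sign="activation")


def net_from_pairs(pairs, types):
    edges = [signed_edge(s, types[s], t, types[t]) for s, t in pairs]
    return TypedNetwork(dict(types), edges)


def brute_force_ffl(pairs, types, require_tf_lncrna=True):
    """Independent oracle: scan every typed quadruple with itertools."""
    by = {k: [n for n, t in types.items() if t == k]
          for k in ("TF", "miRNA", "gene", "lncRNA")}
    found = []
    for t, m, g, l in itertools.product(by["TF"], by["miRNA"], by["gene"], by["lncRNA"]):
        core = {(m, g), (m, l), (t, g)}
        if require_tf_lncrna:
            core.add((t, l))
        if not core <= pairs:
            continue
        tm, mt = (t, m) in pairs, (m, t) in pairs
        if tm and mt:
            found.append(("III", (t, m, g, l)))
        elif tm:
            found.append(("I", (t, m, g, l)))
        elif mt:
            found.append(("II", (t, m, g, l)))
    return sorted(found)


TYPES_1 = {"t1": "TF", "m1": "miRNA", "g1": "gene", "l1": "lncRNA"}
CORE_1 = {("m1", "g1"), ("m1", "l1"), ("t1", "g1"), ("t1", "l1")}


class TestEnumerateFFL:
    def test_single_type_one_motif(self):
        net = net_from_pairs(CORE_1 | {("t1", "m1")}, TYPES_1)
        motifs = mh.enumerate_ffl(net)
        assert len(motifs) == 1 and motifs[0].ffl_type == "I"
        assert motifs[0].nodes == ("t1", "m1", "g1", "l1")

    def test_mutual_feedback_is_type_three_only(self):
        net = net_from_pairs(CORE_1 | {("t1", "m1"), ("m1", "t1")}, TYPES_1)
        motifs = mh.enumerate_ffl(net)
        assert [m.ffl_type for m in motifs] == ["III"]

    def test_no_linkage_no_motif(self):
        net = net_from_pairs(CORE_1, TYPES_1)
        assert mh.enumerate_ffl(net) == []

    def test_empty_network(self):
        assert mh.enumerate_ffl(TypedNetwork({}, [])) == []

    def test_relaxed_grammar_waives_tf_lncrna_edge(self):
        pairs = {("m1", "g1"), ("m1", "l1"), ("t1", "g1"), ("t1", "m1")}
        net = net_from_pairs(pairs, TYPES_1)
        assert mh.enumerate_ffl(net, require_tf_lncrna=True) == []
        motifs = mh.enumerate_ffl(net, require_tf_lncrna=False)
        assert len(motifs) == 1 and motifs[0].ffl_type == "I"

    @pytest.mark.parametrize("require_tf_lncrna", [True, False])
    def test_oracle_equivalence_random_networks(self, rng, require_tf_lncrna):
        """enumerate_ffl matches the quadruple-product oracle on 100 nets."""
        for _ in range(100):
            types = {}
            for i in range(rng.integers(2, 5)):
                types[f"t{i}"] = "TF"
            for i in range(rng.integers(2, 5)):
                types[f"m{i}"] = "miRNA"
            for i in range(rng.integers(2, 15)):
                types[f"g{i}"] = "gene"
            for i in range(rng.integers(1, 5)):
                types[f"l{i}"] = "lncRNA"
            sources = [n for n, t in types.items() if t in ("TF", "miRNA")]
            pairs = set()
            for _ in range(rng.integers(5, 40)):
                s = sources[rng.integers(len(sources))]
                t = list(types)[rng.integers(len(types))]
                if s != t and not (types[s] == "miRNA" and types[t] == "miRNA"):
                    pairs.add((s, t))
            net = net_from_pairs(pairs, types)
            got = sorted((m.ffl_type, m.nodes) for m in
                         mh.enumerate_ffl(net, require_tf_lncrna=require_tf_lncrna))
            assert got == brute_force_ffl(pairs, types, require_tf_lncrna)


def brute_force_maximal_cliques(g: nx.Graph):
    """Subset-enumeration clique oracle (networks <= ~15 nodes)."""
    nodes = list(g.nodes)
    cliques = []
    for size in range(2, len(nodes) + 1):
        for sub in itertools.combinations(nodes, size):
            if all(g.has_edge(a, b) for a, b in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    return [c for c in cliques
            if not any(c < other for other in cliques)]


class TestMcc:
    def test_triangle(self):
        g = nx.cycle_graph(3)
        assert set(mh.mcc_scores(g).values()) == {2}  # (3-1)! per node

    def test_path(self):
        g = nx.path_graph(3)  # a-b-c
        scores = mh.mcc_scores(g)
        assert scores[1] == 2  # cliques {01}, {12}: 1! + 1!
        assert scores[0] == 1

    def test_isolated_node_zero(self):
        g = nx.Graph()
        g.add_node("x")
        g.add_edge("a", "b")
        assert mh.mcc_scores(g)["x"] == 0

    def test_matches_subset_enumeration_oracle(self, rng):
        import math
        for _ in range(30):
            n = int(rng.integers(4, 13))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(1 << 30)))
            expected = {v: 0 for v in g.nodes}
            for clique in brute_force_maximal_cliques(g):
                for v in clique:
                    expected[v] += math.factorial(len(clique) - 1)
            assert mh.mcc_scores(g) == expected


class TestHubNodes:
    def _star_net(self):
        types = {"m0": "miRNA", **{f"g{i}": "gene" for i in range(10)}}
        pairs = {("m0", f"g{i}") for i in range(10)}
        return net_from_pairs(pairs, types)

    def test_star_center_is_sole_key_node(self):
        hubs = mh.hub_nodes(self._star_net(), top_fraction=0.05)
        assert hubs.key_nodes == {"m0"}
        assert hubs.degree["m0"] == 10

    def test_ties_at_cutoff_all_included(self):
        types = {"m0": "miRNA", "m1": "miRNA", "g0": "gene", "g1": "gene"}
        pairs = {("m0", "g0"), ("m1", "g1")}
        hubs = mh.hub_nodes(net_from_pairs(pairs, types), top_fraction=0.25)
        assert hubs.key_nodes == {"m0", "m1", "g0", "g1"}  # complete tie

    def test_empty_network_error(self):
        with pytest.raises(DataValidationError):
            mh.hub_nodes(TypedNetwork({}, []))


class TestPpiHubGenes:
    def test_dominant_degree_gene_selected(self):
        genes = {f"g{i}" for i in range(20)}
        ppi = [("g0", f"g{i}") for i in range(1, 20)]
        hubs = mh.ppi_hub_genes(ppi, genes, top_fraction=0.10)
        assert "g0" in hubs

    def test_disjoint_candidates_error(self):
        with pytest.raises(DataValidationError):
            mh.ppi_hub_genes([("a", "b")], {"x", "y"})

    def test_complete_tie_returns_all(self):
        ppi = [("a", "b"), ("c", "d")]
        hubs = mh.ppi_hub_genes(ppi, {"a", "b", "c", "d"}, top_fraction=0.25)
        assert hubs == {"a", "b", "c", "d"}


def _motif(tf="t1", mirna="m1", gene="g1", lncrna="l1", ffl_type="I"):
    types = {tf: "TF", mirna: "miRNA", gene: "gene", lncrna: "lncRNA"}
    edges = (signed_edge(mirna, "miRNA", gene, "gene"),
             signed_edge(mirna, "miRNA", lncrna, "lncRNA"),
             signed_edge(tf, "TF", gene, "gene"),
             signed_edge(tf, "TF", lncrna, "lncRNA"),
             signed_edge(tf, "TF", mirna, "miRNA"))
    return mh.FFLMotif(tf, mirna, gene, lncrna, ffl_type, edges)


class TestFilters:
    def test_hub_ffl_two_stage_logic(self):
        motifs = [_motif(gene="g1"), _motif(tf="t9", mirna="m9", gene="g2", lncrna="l9")]
        hubs = mh.HubReport({}, {}, key_nodes={"t1"}, ppi_hub_genes={"g1", "g2"})
        kept = mh.extract_hub_ffl(motifs, hubs)
        assert [m.gene for m in kept] == ["g1"]  # second motif has no key node

    def test_hub_ffl_ppi_stage(self):
        motifs = [_motif(gene="g1"), _motif(gene="g2", lncrna="l2")]
        hubs = mh.HubReport({}, {}, key_nodes={"t1"}, ppi_hub_genes={"g2"})
        kept = mh.extract_hub_ffl(motifs, hubs)
        assert [m.gene for m in kept] == ["g2"]

    def test_cerna_filter(self):
        motifs = [_motif(lncrna="l1"), _motif(lncrna="l2", gene="g2")]
        assert [m.lncrna for m in mh.cerna_filter(motifs, {"l1"})] == ["l1"]
        assert mh.cerna_filter(motifs, set()) == []
        assert mh.cerna_filter(motifs, {"l1", "l2"}) == motifs

    def test_funnel_is_monotone(self):
        motifs = [_motif(), _motif(gene="g2"), _motif(lncrna="l2")]
        hubs = mh.HubReport({}, {}, key_nodes={"t1"}, ppi_hub_genes={"g1"})
        hub_ffl = mh.extract_hub_ffl(motifs, hubs)
        cerna = mh.cerna_filter(hub_ffl, {"l1"})
        assert len(cerna) <= len(hub_ffl) <= len(motifs)


class TestMirnaSubnetwork:
    def test_union_of_member_edges(self):
        motifs = [_motif(gene="g1"), _motif(gene="g2")]
        sub = mh.mirna_subnetwork(motifs, "m1")
        keys = {e.key for e in sub.edges}
        assert ("m1", "g1") in keys and ("m1", "g2") in keys
        assert ("t1", "m1") in keys
        assert list(sub.node_types.values()).count("TF") == 1  # t1 appears once

    def test_unknown_mirna_empty(self):
        sub = mh.mirna_subnetwork([_motif()], "absent")
        assert sub.edges == [] and sub.node_types == {}
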