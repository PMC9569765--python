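"""Synthetic count matrices, interactomes and annotations with planted truth.

The generator states a small world with known answers so every pipeline stage
is testable without external data:

* counts are negative binomial (gamma-Poisson) around log2 means; tumor
  samples of planted DE features are shifted by the planted log2 fold change;
* co-expression modules share a per-sample latent Gaussian factor added on
  the log-mean scale, optionally tied to the tumor/normal trait;
* regulatory couplings subtract (repression) or add (activation) the source's
  per-sample log-scale deviation from the target's log mean, so planted edge
  signs reappear as expression correlations;
* the bipartite miRNA->gene network realizes each planted unique-target
  count exactly (dedicated in-degree-1 genes, plus shared genes held at
  in-degree >= 2 by a sponge decoy miRNA);
* planted FFL motifs are wired per the motif grammar, and decoy edges are
  rejection-sampled so they complete no additional motif.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import AnnotationSets, DataValidationError, ExpressionMatrix, RegulatoryEdge

#: log2-scale s.d. of per-sample regulator deviations that drive couplings
#: (1.0 ~ typical two-fold fluctuation of a regulator between samples)
REGULATOR_SD = 1.0
#: log2 units transferred per unit regulator deviation
COUPLING_STRENGTH = 1.0
#: module latent factor: trait term weight and residual noise s.d.
MODULE_TRAIT_WEIGHT = 1.0
MODULE_NOISE_SD = 1.0


@dataclass
class SimulationConfig:
    n_genes: int = 60
    n_mirnas: int = 12
    n_lncrnas: int = 4
    n_tfs: int = 3
    n_pairs: int = 30
    nb_dispersion: float = 0.1
    #: feature id -> log2 fold change (tumor vs normal); sign is direction
    planted_de: dict[str, float] = field(default_factory=dict)
    #: miRNA id -> ground-truth NOG (dedicated in-degree-1 gene targets)
    planted_unique_targets: dict[str, int] = field(default_factory=dict)
    #: (gene id tuple, factor loading, trait association sign in {-1, 0, +1})
    planted_modules: list[tuple[tuple[str, ...], float, int]] = field(default_factory=list)
    #: (ffl type 'I'|'II'|'III', (tf, mirna, gene, lncrna))
    planted_motifs: list[tuple[str, tuple[str, str, str, str]]] = field(default_factory=list)
    #: miRNA id -> how many of its shared targets to flag as TF genes
    planted_tf_targets: dict[str, int] = field(default_factory=dict)
    #: genes to mark lung-enriched + onco/TSG
    planted_important: tuple[str, ...] = ()
    #: genes to make PPI hubs (defaults to planted motif genes)
    ppi_hubs: tuple[str, ...] = ()
    n_shared_genes: int = 15
    n_decoy_edges: int = 0
    seed: int = 0

    # -- id helpers ---------------------------------------------------------
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]

    def mirna_ids(self) -> list[str]:
        return [f"M{i:03d}" for i in range(self.n_mirnas)]

    def lncrna_ids(self) -> list[str]:
        return [f"L{i:03d}" for i in range(self.n_lncrnas)]

    def tf_ids(self) -> list[str]:
        return [f"T{i:03d}" for i in range(self.n_tfs)]

    def validate(self) -> None:
        genes, mirnas = set(self.gene_ids()), set(self.mirna_ids())
        lncs, tfs = set(self.lncrna_ids()), set(self.tf_ids())
        seen_module_genes: set[str] = set()
        for gene_set, _, assoc in self.planted_modules:
            gs = set(gene_set)
            if not gs <= genes:
                raise DataValidationError("planted module references unknown genes")
            if gs & seen_module_genes:
                raise DataValidationError("planted module gene sets must be disjoint")
            if assoc not in (-1, 0, 1):
                raise DataValidationError("module trait association sign must be -1, 0 or +1")
            seen_module_genes |= gs
        total_unique = sum(self.planted_unique_targets.values())
        if total_unique > self.n_genes:
            raise DataValidationError("more planted unique targets than genes")
        if not set(self.planted_unique_targets) <= mirnas:
            raise DataValidationError("planted_unique_targets references unknown miRNAs")
        for ftype, (t, m, g, l) in self.planted_motifs:
            if ftype not in {"I", "II", "III"}:
                raise DataValidationError(f"unknown FFL type {ftype!r}")
            if t not in tfs or m not in mirnas or g not in genes or l not in lncs:
                raise DataValidationError(f"motif quadruple ({t},{m},{g},{l}) is type-inconsistent")


@dataclass
class GroundTruth:
    true_de: dict[str, float] = field(default_factory=dict)
    true_nog: dict[str, int] = field(default_factory=dict)
    true_module_labels: dict[str, int] = field(default_factory=dict)
    true_motifs: list[tuple[str, tuple[str, str, str, str]]] = field(default_factory=list)
    true_edge_signs: dict[tuple[str, str], str] = field(default_factory=dict)


#: internal sponge miRNA that keeps shared genes at in-degree >= 2
SPONGE_MIRNA = "M_sponge"


# ---------------------------------------------------------------------------
# Deterministic world plan shared by counts and interactome generators
# ---------------------------------------------------------------------------

@dataclass
class _WorldPlan:
    edges: dict[tuple[str, str], tuple[str, str, str]]  # key -> (stype, ttype, sign)
    node_types: dict[str, str]
    unique_targets: dict[str, list[str]]
    shared_genes: list[str]
    tf_flagged: set[str]


def _plan_world(cfg: SimulationConfig) -> _WorldPlan:
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_ids()
    node_types: dict[str, str] = {}
    for g in genes:
        node_types[g] = "gene"
    for m in cfg.mirna_ids():
        node_types[m] = "miRNA"
    for l in cfg.lncrna_ids():
        node_types[l] = "lncRNA"
    for t in cfg.tf_ids():
        node_types[t] = "TF"

    edges: dict[tuple[str, str], tuple[str, str, str]] = {}

    def add(src: str, tgt: str, sign: str) -> None:
        edges[(src, tgt)] = (node_types[src], node_types[tgt], sign)

    # dedicated unique targets: consecutive gene blocks, in-degree 1 by design
    unique_targets: dict[str, list[str]] = {}
    cursor = 0
    for m in cfg.mirna_ids():
        k = cfg.planted_unique_targets.get(m, 0)
        unique_targets[m] = genes[cursor:cursor + k]
        cursor += k
        for g in unique_targets[m]:
            add(m, g, "repression")

    # shared genes: co-targeted by two distinct real miRNAs so they never
    # count toward any NOG, in the global network or any DE-restricted one;
    # a sponge decoy miRNA steps in only when there is a single real miRNA
    n_shared = min(cfg.n_shared_genes, cfg.n_genes - cursor)
    shared_genes = genes[cursor:cursor + n_shared]
    # wire shared genes among the miRNAs that carry planted unique targets
    # (the network miRNAs); background miRNAs stay out of the bipartite net
    mirnas = [m for m in cfg.mirna_ids() if cfg.planted_unique_targets.get(m, 0) > 0] \
        or cfg.mirna_ids()
    if shared_genes and mirnas:
        for i, g in enumerate(shared_genes):
            if len(mirnas) >= 2:
                add(mirnas[i % len(mirnas)], g, "repression")
                add(mirnas[(i + 1) % len(mirnas)], g, "repression")
            else:
                node_types[SPONGE_MIRNA] = "miRNA"
                add(SPONGE_MIRNA, g, "repression")
                add(mirnas[0], g, "repression")

    # planted motifs: wire the grammar edges
    for ftype, (t, m, g, l) in cfg.planted_motifs:
        add(m, g, "repression")
        add(m, l, "repression")
        tf_sign = "activation" if rng.random() < 0.5 else "repression"
        add(t, g, tf_sign)
        add(t, l, tf_sign)
        if ftype in ("I", "III"):
            add(t, m, "activation" if rng.random() < 0.5 else "repression")
        if ftype in ("II", "III"):
            add(m, t, "repression")

    # TF flags go on each miRNA's dedicated targets: TFP stays private to the
    # planted miRNA instead of leaking through shared genes
    tf_flagged: set[str] = set()
    for m, n_tf in cfg.planted_tf_targets.items():
        if n_tf > len(unique_targets.get(m, [])):
            raise DataValidationError(
                f"planted_tf_targets[{m!r}] exceeds its unique-target count")
        tf_flagged.update(unique_targets[m][:n_tf])

    return _WorldPlan(edges, node_types, unique_targets, shared_genes, tf_flagged)


def count_motifs_raw(edge_keys: set[tuple[str, str]], node_types: dict[str, str],
                     require_tf_lncrna: bool = True) -> list[tuple[str, tuple[str, str, str, str]]]:
    """Exhaustive FFL scan on a raw edge set; used for decoy rejection/truth."""
    by_type: dict[str, list[str]] = {"TF": [], "miRNA": [], "gene": [], "lncRNA": []}
    for n, t in node_types.items():
        by_type[t].append(n)
    found = []
    for t in by_type["TF"]:
        for m in by_type["miRNA"]:
            tf_to_m = (t, m) in edge_keys
            m_to_tf = (m, t) in edge_keys
            if not tf_to_m and not m_to_tf:
                continue
            ftype = "III" if (tf_to_m and m_to_tf) else ("I" if tf_to_m else "II")
            for g in by_type["gene"]:
                if (m, g) not in edge_keys or (t, g) not in edge_keys:
                    continue
                for l in by_type["lncRNA"]:
                    if (m, l) not in edge_keys:
                        continue
                    if require_tf_lncrna and (t, l) not in edge_keys:
                        continue
                    found.append((ftype, (t, m, g, l)))
    return found


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------

def _sample_frame(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    for p in range(cfg.n_pairs):
        pid = f"P{p:03d}"
        rows.append({"sample_id": f"{pid}_N", "condition": "normal", "pair_id": pid})
        rows.append({"sample_id": f"{pid}_T", "condition": "tumor", "pair_id": pid})
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_counts(cfg: SimulationConfig) -> tuple[dict[str, ExpressionMatrix], GroundTruth]:
    """Generate miRNA / mRNA / lncRNA count matrices with planted structure.

    The mRNA matrix carries both ordinary genes and TF transcripts (a TF's
    expression is observed through its mRNA). Returns matrices keyed by
    feature type plus the ground truth realized.
    """
    plan = _plan_world(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    meta = _sample_frame(cfg)
    n_samples = len(meta)
    tumor = (meta["condition"] == "tumor").to_numpy(dtype=float)

    mirnas = cfg.mirna_ids() + ([SPONGE_MIRNA] if SPONGE_MIRNA in plan.node_types else [])
    mrna_features = cfg.gene_ids() + cfg.tf_ids()
    lnc_features = cfg.lncrna_ids()

    # per-sample log2 deviations of every regulator (miRNA and TF)
    deviations = {
        reg: rng.normal(0.0, REGULATOR_SD, n_samples)
        for reg in mirnas + cfg.tf_ids()
    }

    # module latent factors
    factors = []
    for gene_set, loading, assoc in cfg.planted_modules:
        f = assoc * (tumor - 0.5) * 2.0 * MODULE_TRAIT_WEIGHT \
            + rng.normal(0.0, MODULE_NOISE_SD, n_samples)
        factors.append((set(gene_set), loading, f))

    def log2_mean(feature: str, ftype: str) -> np.ndarray:
        base = rng.uniform(5.0, 9.0)
        mu = np.full(n_samples, base)
        mu += cfg.planted_de.get(feature, 0.0) * tumor
        if feature in deviations:  # regulators fluctuate around their mean
            mu += deviations[feature]
        for gene_set, loading, f in factors:
            if feature in gene_set:
                mu += loading * f
        # incoming planted couplings
        for (src, tgt), (_, _, sign) in plan.edges.items():
            if tgt != feature:
                continue
            delta = deviations.get(src)
            if delta is None:
                continue
            s = -1.0 if sign == "repression" else 1.0
            mu += s * COUPLING_STRENGTH * delta
        return mu

    def nb_matrix(features: list[str], ftype: str) -> pd.DataFrame:
        rows = np.empty((len(features), n_samples))
        for i, feat in enumerate(features):
            mean = 2.0 ** log2_mean(feat, ftype)
            shape = 1.0 / cfg.nb_dispersion
            lam = rng.gamma(shape, mean / shape)
            rows[i] = rng.poisson(lam)
        return pd.DataFrame(rows, index=features, columns=meta.index)

    matrices = {
        "miRNA": ExpressionMatrix(nb_matrix(mirnas, "miRNA"), meta, "miRNA"),
        "mRNA": ExpressionMatrix(nb_matrix(mrna_features, "mRNA"), meta, "mRNA"),
        "lncRNA": ExpressionMatrix(nb_matrix(lnc_features, "lncRNA"), meta, "lncRNA"),
    }
    return matrices, _ground_truth(cfg, plan)


def _ground_truth(cfg: SimulationConfig, plan: _WorldPlan) -> GroundTruth:
    gt = GroundTruth()
    gt.true_de = dict(cfg.planted_de)
    # NOG from the realized edge list (must match the plant by construction)
    indeg: dict[str, int] = {}
    for (src, tgt), (stype, ttype, _) in plan.edges.items():
        if stype == "miRNA" and ttype == "gene":
            indeg[tgt] = indeg.get(tgt, 0) + 1
    for m in list(cfg.mirna_ids()) + ([SPONGE_MIRNA] if SPONGE_MIRNA in plan.node_types else []):
        targets = [tgt for (src, tgt), (stype, ttype, _) in plan.edges.items()
                   if src == m and ttype == "gene"]
        gt.true_nog[m] = sum(1 for g in targets if indeg[g] == 1)
    for i, (gene_set, _, _) in enumerate(cfg.planted_modules, start=1):
        for g in gene_set:
            gt.true_module_labels[g] = i
    gt.true_motifs = list(cfg.planted_motifs)
    gt.true_edge_signs = {k: sign for k, (_, _, sign) in plan.edges.items()}
    return gt


def simulate_interactome(cfg: SimulationConfig
                         ) -> tuple[list[RegulatoryEdge], AnnotationSets, GroundTruth]:
    """Materialize the planned typed edge list, annotations and PPI edges.

    Decoy edges (``cfg.n_decoy_edges``) are rejection-sampled so that they
    neither complete a new FFL motif nor perturb any miRNA's NOG.
    """
    plan = _plan_world(cfg)
    rng = np.random.default_rng(cfg.seed + 2)
    edges = dict(plan.edges)
    node_types = dict(plan.node_types)

    base_motifs = set(count_motifs_raw(set(edges), node_types))

    indeg: dict[str, int] = {}
    for (src, tgt), (stype, ttype, _) in edges.items():
        if stype == "miRNA" and ttype == "gene":
            indeg[tgt] = indeg.get(tgt, 0) + 1
    shared_pool = [g for g in cfg.gene_ids() if indeg.get(g, 0) >= 2]

    mirnas = cfg.mirna_ids()
    tfs = cfg.tf_ids()
    added = 0
    attempts = 0
    while added < cfg.n_decoy_edges and attempts < cfg.n_decoy_edges * 50 + 100:
        attempts += 1
        if rng.random() < 0.5 and mirnas and shared_pool:
            src = mirnas[rng.integers(len(mirnas))]
            tgt = shared_pool[rng.integers(len(shared_pool))]
            sign = "repression"
        elif tfs:
            src = tfs[rng.integers(len(tfs))]
            pool = cfg.gene_ids() + cfg.lncrna_ids() + mirnas
            tgt = pool[rng.integers(len(pool))]
            sign = "activation" if rng.random() < 0.5 else "repression"
        else:
            break
        if src == tgt or (src, tgt) in edges:
            continue
        trial = dict(edges)
        trial[(src, tgt)] = (node_types[src], node_types[tgt], sign)
        if set(count_motifs_raw(set(trial), node_types)) != base_motifs:
            continue  # decoy would complete a motif
        edges = trial
        added += 1

    edge_objs = [
        RegulatoryEdge(src, stype, tgt, ttype, evidence=frozenset({"synthetic"}), sign=sign)
        for (src, tgt), (stype, ttype, sign) in sorted(edges.items())
    ]

    # annotations
    tf_genes = set(tfs) | plan.tf_flagged
    important = set(cfg.planted_important)
    motif_genes = {g for _, (_, _, g, _) in cfg.planted_motifs}
    hubs = set(cfg.ppi_hubs) or motif_genes
    candidate_genes = sorted({tgt for (src, tgt), (stype, ttype, _) in edges.items()
                              if stype == "miRNA" and ttype == "gene"})
    ppi: list[tuple[str, str]] = []
    for h in sorted(hubs):
        for g in candidate_genes:
            if g != h:
                ppi.append((h, g))
    others = [g for g in candidate_genes if g not in hubs]
    for i in range(0, max(len(others) - 1, 0), 3):  # sparse background edges
        ppi.append((others[i], others[i + 1]))
    cytoplasmic = {l for _, (_, _, _, l) in cfg.planted_motifs} or set(cfg.lncrna_ids())

    ann = AnnotationSets(
        tf_genes=frozenset(tf_genes),
        lung_enriched=frozenset(important),
        onco_tsg=frozenset(important),
        cytoplasmic_lncrnas=frozenset(cytoplasmic),
        ppi_edges=tuple(dict.fromkeys(ppi)),
    )
    return edge_objs, ann, _ground_truth(cfg, plan)


# ---------------------------------------------------------------------------
# Worked scenario: one recoverable biomarker among decoys
# ---------------------------------------------------------------------------

def biomarker_scenario(seed: int = 0, n_pairs: int = 30) -> SimulationConfig:
    """A stated world with one recoverable biomarker (M000) among decoys.

    M000 has the most uniquely targeted genes, several TF-gene targets,
    strongly repressed important (onco/TSG, lung-enriched) targets sitting in
    a tumor-associated co-expression module, a large expression shift, and
    one planted FFL motif of each type around it. Two runner-up miRNAs pass
    the significance screen but fall at the median-NOG filter; the remaining
    decoys have NOG 1 and near-zero TFP.
    """
    # majority of genes and miRNAs stay non-differential so median-of-ratios
    # normalization has a stable anchor, as in real count data: miRNAs
    # M010..M029 are untargeted null background
    n_genes, n_mirnas = 120, 30
    n_network_mirnas = 10
    uniq = {"M000": 12, "M001": 7, "M002": 6,
            **{f"M{i:03d}": 1 for i in range(3, n_network_mirnas)}}
    cfg = SimulationConfig(
        n_genes=n_genes, n_mirnas=n_mirnas, n_lncrnas=4, n_tfs=3,
        n_pairs=n_pairs, nb_dispersion=0.1, seed=seed,
        planted_unique_targets=uniq,
        planted_tf_targets={"M000": 5, "M001": 3, "M002": 3},
        n_shared_genes=15, n_decoy_edges=6,
    )
    genes = cfg.gene_ids()
    n_unique = sum(uniq.values())  # dedicated blocks fill genes[:n_unique]
    unique_m0 = genes[:12]
    # module 1 holds M000's targets and is anti-associated with the tumor
    # trait; module 2 is co-expressed but trait-neutral, so module 1 is
    # always the selected disease module
    cfg.planted_modules = [(tuple(genes[:20]), 0.9, -1),
                           (tuple(genes[100:120]), 0.9, 0)]
    cfg.planted_important = tuple(unique_m0[:4])
    # every network miRNA and every targeted gene is differential; the
    # biomarker gets a 16-fold shift, emulating a top-table candidate whose
    # ROC comfortably clears the 0.85 gate despite its regulator couplings
    de: dict[str, float] = {f"M{i:03d}": (3.0 if i % 2 == 0 else -3.0)
                            for i in range(n_network_mirnas)}
    de["M000"] = 4.0
    n_targeted = n_unique + cfg.n_shared_genes
    for g in genes[:n_targeted]:
        de[g] = -3.0
    cfg.planted_de = de
    # one FFL of each type around M000; motif genes sit in the shared block
    cfg.planted_motifs = [
        ("I", ("T000", "M000", genes[n_unique], "L000")),
        ("II", ("T001", "M000", genes[n_unique + 1], "L001")),
        ("III", ("T002", "M000", genes[n_unique + 2], "L002")),
    ]
    return cfg


# ---------------------------------------------------------------------------
# Printed-table fixture
# ---------------------------------------------------------------------------

#: per-candidate (unique-target gene list, total target count, TF-gene count);
#: totals/TF counts chosen so NOG and the 4-decimal TFP match the published
#: candidate table exactly (TFP = tf_count / total).
_TABLE1 = {
    "miR-101-3p": (["OCIAD2", "BRIP1", "NPC1L1", "KL", "FOXF1", "AJAP1", "NKX6-1", "MAOB"],
                   130, 23),
    "miR-708-5p": (["JAM2", "TMEM88", "MAG", "KANK4", "DNAH10", "FAM107A"], 43, 7),
}
_TABLE2 = {
    "miR-101-3p": (["SNX31", "CNTN4", "PHACTR3", "RNASE4", "RNASE1", "KL", "FOXF1",
                    "C17orf104", "KRT10", "CACNA1D", "ADD2", "MAOB"], 159, 25),
    "miR-140-5p": (["TEX19", "RASL11B", "GRIN1", "SRD5A1", "FAM162A", "ADA", "CADPS2"],
                   41, 9),
    "miR-183-5p": (["E2F8", "RAI2", "HIST1H2AI", "GBP4", "DNAH3", "FAM83A", "FMN1"],
                   50, 8),
    "miR-766-5p": (["EFR3B", "NPM3", "CALCOCO1", "CYP27C1", "ASIC1", "IL16", "PCDHA3",
                    "GPBAR1", "PPFIA4", "KCTD1"], 42, 7),
    "miR-766-3p": (["SP8", "TRIM45", "TRIM15", "TTBK1", "TTC25", "IL1RL2", "RCCD1",
                    "TEKT1", "HIST2H2AB", "ZNF670", "CENPH", "TRPV3", "CGNL1", "VAMP5",
                    "KIRREL2", "TNNT1"], 63, 10),
}

#: decoy-hub miRNA that co-targets every decoy gene so they never count as unique
_DECOY_HUB = "miR-decoy-hub"


def fixture_table12(table: str = "both") -> tuple[list[RegulatoryEdge], AnnotationSets]:
    """Bipartite network realizing the published candidate-miRNA table rows.

    Each candidate miRNA is the sole regulator of its listed unique-target
    genes; the remainder of its regulon is filled with decoy genes co-targeted
    by a decoy-hub miRNA (in-degree 2, contributing nothing to any NOG). Decoy
    counts and TF-gene flags are chosen so both NOG and the published
    4-decimal TFP reproduce exactly. ``table`` selects '1', '2' or 'both'.
    """
    if table not in {"1", "2", "both"}:
        raise DataValidationError(f"table must be '1', '2' or 'both', got {table!r}")
    sources = []
    if table in {"1", "both"}:
        sources.append(("T1", _TABLE1))
    if table in {"2", "both"}:
        sources.append(("T2", _TABLE2))
    edges: dict[tuple[str, str], RegulatoryEdge] = {}
    tf_genes: set[str] = set()

    def add(m: str, g: str) -> None:
        key = (m, g)
        if key not in edges:
            edges[key] = RegulatoryEdge(m, "miRNA", g, "gene",
                                        evidence=frozenset({"table_fixture"}))

    for tag, tbl in sources:
        for mirna, (nog_genes, total, n_tf) in tbl.items():
            for g in nog_genes:
                add(mirna, g)
            n_decoys = total - len(nog_genes)
            decoys = [f"{tag}_{mirna}_decoy{i:03d}" for i in range(n_decoys)]
            for g in decoys:
                add(mirna, g)
                add(_DECOY_HUB, g)
            tf_genes |= set(decoys[:n_tf])
    ann = AnnotationSets(tf_genes=frozenset(tf_genes))
    return list(edges.values()), ann
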