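"""End-to-end orchestration of the two biomarker arms and network build.

``run_biomarkers`` executes differential expression -> disease-specific
bipartite network -> independent-regulation screen (arm 1) in parallel with
co-expression module selection -> disease-gene filtering -> strong negative
pairs (arm 2), intersects the arms and gates the survivors by ROC AUC.
``run_network`` then infers edge directions from expression, enumerates the
FFL motifs around the biomarkers, restricts to hub nodes / PPI-important
genes and finally to cytoplasmic lncRNAs (the ceRNA-hub-FFL network).

All thresholds live in :class:`PipelineConfig` with the published defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import biomarker_selection as bsel
from . import coexpression, diffexpr, indep_regulation, motif_hub_cerna, regnet_assembly
from .data_io import (AnnotationSets, DataValidationError, ExpressionMatrix,
                      RegulatoryEdge, log_stage, write_edges, write_network)


@dataclass
class PipelineConfig:
    lfc: float = 1.5
    padj: float = 0.05
    alpha: float = 0.05
    paired_de: bool = False
    keep_fraction: float = 0.75
    min_module_size: int = 30
    cut_height: float = 0.99
    merge_r: float = 0.75
    r2_target: float = 0.8
    strong_r: float = -0.3
    auc_min: float = 0.85
    auto_orient: bool = True
    mirna_r_max: float = -0.15
    tf_r_min: float = 0.3
    top_node_fraction: float = 0.05
    ppi_fraction: float = 0.10
    z_max: float = 2.0
    require_tf_lncrna: bool = True
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if not (0 < self.keep_fraction <= 1 and 0 < self.top_node_fraction <= 1
                and 0 < self.ppi_fraction <= 1):
            raise DataValidationError("fractions must be in (0, 1]")
        if not (0 < self.alpha < 1 and 0 < self.padj <= 1):
            raise DataValidationError("alpha/padj must be probabilities")
        if self.strong_r >= 0 or self.mirna_r_max >= 0 or self.tf_r_min <= 0:
            raise DataValidationError("correlation thresholds have fixed signs")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class BiomarkerRunResult:
    records: list[bsel.BiomarkerRecord]
    final: set[str]
    arm1: set[str]
    arm2: set[str]
    scores: list[indep_regulation.MiRnaScore]
    module_result: coexpression.ModuleResult
    key_genes: set[str]
    de_mirnas: set[str]
    de_genes: set[str]
    report: pd.DataFrame


def run_biomarkers(matrices: dict[str, ExpressionMatrix],
                   edges: list[RegulatoryEdge],
                   ann: AnnotationSets,
                   cfg: PipelineConfig | None = None) -> BiomarkerRunResult:
    cfg = cfg or PipelineConfig()
    cfg.validate()

    # stage 1: differential expression, per feature family
    de_mirna = diffexpr.de_test(matrices["miRNA"], paired=cfg.paired_de,
                                lfc_threshold=cfg.lfc, padj_threshold=cfg.padj)
    de_mrna = diffexpr.de_test(matrices["mRNA"], paired=cfg.paired_de,
                               lfc_threshold=cfg.lfc, padj_threshold=cfg.padj)
    up_m, down_m = diffexpr.de_sets(de_mirna)
    up_g, down_g = diffexpr.de_sets(de_mrna)
    de_mirnas, de_genes = up_m | down_m, up_g | down_g
    log_stage("diffexpr", de_mirnas=len(de_mirnas), de_genes=len(de_genes))

    # arm 1: independent regulation on the disease-specific bipartite net
    mirna_gene_edges = [e for e in edges
                       if e.source_type == "miRNA" and e.target_type == "gene"]
    disease_net = indep_regulation.extract_disease_network(
        mirna_gene_edges, de_mirnas, de_genes)
    scores = indep_regulation.score_mirnas(disease_net, set(ann.tf_genes))
    # a signed-rank p < 0.05 is unattainable below 6 miRNAs: no candidates
    arm1 = (indep_regulation.candidate_mirnas(scores, alpha=cfg.alpha)
            if len(scores) >= 6 else set())
    log_stage("arm1", network_mirnas=len(disease_net.mirnas), candidates=len(arm1))

    # arm 2: co-expression module -> disease genes -> strong negative pairs;
    # correlations run on the log2(normalized + 1) scale
    log_mirna = diffexpr.log_normalize(matrices["miRNA"])
    log_mrna = diffexpr.log_normalize(matrices["mRNA"])
    module_result = coexpression.run_wgcna(
        log_mrna, keep_fraction=cfg.keep_fraction,
        min_module_size=cfg.min_module_size, cut_height=cfg.cut_height,
        merge_r=cfg.merge_r, r2_target=cfg.r2_target)
    if module_result.selected_module is None:
        module_genes: set[str] = set()
    else:
        labels = module_result.labels
        module_genes = set(labels[labels == module_result.selected_module].index)
    key_genes = bsel.filter_disease_genes(module_genes, ann)
    strong = bsel.strong_pairs(log_mirna, log_mrna, mirna_gene_edges, key_genes,
                               r_max=cfg.strong_r, alpha=cfg.alpha) if key_genes else []
    arm2 = {e.source for e in strong}
    log_stage("arm2", module_genes=len(module_genes), key_genes=len(key_genes),
              strong_pairs=len(strong), candidates=len(arm2))

    # intersection + ROC gate
    indeg = disease_net.gene_indegree()
    nog_info = {
        s.mirna: (s.nog, s.tfp,
                  {g for g in disease_net.targets(s.mirna) if indeg[g] == 1})
        for s in scores
    }
    important_by_mirna = {
        m: {e.target for e in strong if e.source == m} for m in arm2
    }
    records = bsel.final_biomarkers(arm1, arm2, log_mirna, auc_min=cfg.auc_min,
                                    auto_orient=cfg.auto_orient, nog_info=nog_info,
                                    important_by_mirna=important_by_mirna)
    final = {r.mirna for r in records if r.final}
    log_stage("final", intersection=len(arm1 & arm2), final=len(final))

    report = pd.DataFrame(
        [{
            "miRNA ID": r.mirna,
            "NOG Value": r.nog,
            "TFP Value": round(r.tfp, 4),
            "Important Gene": ", ".join(sorted(r.important_genes)),
            "NOG Gene": ", ".join(sorted(r.nog_genes)),
            "AUC": "" if pd.isna(r.auc) else round(r.auc, 3),
        } for r in records if r.arm1 and r.arm2],
        columns=["miRNA ID", "NOG Value", "TFP Value", "Important Gene",
                 "NOG Gene", "AUC"],
    )
    return BiomarkerRunResult(records, final, arm1, arm2, scores, module_result,
                              key_genes, de_mirnas, de_genes, report)


@dataclass
class NetworkRunResult:
    network: "regnet_assembly.TypedNetwork"
    motifs: list[motif_hub_cerna.FFLMotif]
    hub_motifs: list[motif_hub_cerna.FFLMotif]
    cerna_motifs: list[motif_hub_cerna.FFLMotif]
    hubs: motif_hub_cerna.HubReport
    type_counts: dict[str, int]
    subnetworks: dict[str, "regnet_assembly.TypedNetwork"] = field(default_factory=dict)
    drop_log: pd.DataFrame | None = None


def run_network(matrices: dict[str, ExpressionMatrix],
                edges: list[RegulatoryEdge],
                ann: AnnotationSets,
                biomarkers: set[str],
                cfg: PipelineConfig | None = None) -> NetworkRunResult:
    cfg = cfg or PipelineConfig()
    cfg.validate()
    if not biomarkers:
        raise DataValidationError("no biomarkers supplied to network construction")

    # miRNA edges restricted to the biomarkers; TF edges kept in full
    scoped = [e for e in edges
              if e.source_type != "miRNA" or e.source in biomarkers
              or e.target in biomarkers]
    expr_by_type = {t: diffexpr.log_normalize(m) for t, m in matrices.items()}
    net, drop_log = regnet_assembly.infer_direction(
        scoped, expr_by_type, mirna_r_max=cfg.mirna_r_max,
        tf_r_min=cfg.tf_r_min, alpha=cfg.alpha)
    if not net.edges:
        raise DataValidationError("signed network is empty after correlation filtering")

    motifs = motif_hub_cerna.enumerate_ffl(net, require_tf_lncrna=cfg.require_tf_lncrna)
    hubs = motif_hub_cerna.hub_nodes(net, top_fraction=cfg.top_node_fraction)
    candidate_genes = {e.target for e in net.edges
                       if e.source_type == "miRNA" and e.target_type == "gene"}
    try:
        hubs.ppi_hub_genes = motif_hub_cerna.ppi_hub_genes(
            list(ann.ppi_edges), candidate_genes, top_fraction=cfg.ppi_fraction)
    except DataValidationError:
        hubs.ppi_hub_genes = set()
    hub_motifs = motif_hub_cerna.extract_hub_ffl(motifs, hubs)
    cerna = motif_hub_cerna.cerna_filter(hub_motifs, set(ann.cytoplasmic_lncrnas))
    subnets = {m: motif_hub_cerna.mirna_subnetwork(cerna, m) for m in sorted(biomarkers)}
    counts = motif_hub_cerna.motif_type_counts(motifs)
    log_stage("run_network", ffl=len(motifs), hub_ffl=len(hub_motifs),
              cerna_hub_ffl=len(cerna))
    return NetworkRunResult(net, motifs, hub_motifs, cerna, hubs, counts,
                            subnets, drop_log)


def write_outputs(outdir: str | Path, bio: BiomarkerRunResult,
                  net: NetworkRunResult | None, cfg: PipelineConfig) -> None:
    """Write the auditable report files for a pipeline run."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.json", "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=1, sort_keys=True)
    bio.report.to_csv(out / "biomarker_report.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(s.mirna, s.nog, s.tfp, s.nog_p, s.tfp_p, s.passes_screen, s.passes_median)
         for s in bio.scores],
        columns=["mirna", "nog", "tfp", "nog_p", "tfp_p",
                 "passes_screen", "passes_median"],
    ).to_csv(out / "mirna_scores.tsv", sep="\t", index=False)
    bio.module_result.labels.rename("module_id").to_csv(
        out / "modules.tsv", sep="\t", index_label="gene")
    if net is not None:
        pd.DataFrame(
            [(m.tf, m.mirna, m.gene, m.lncrna, m.ffl_type) for m in net.cerna_motifs],
            columns=["tf", "mirna", "gene", "lncrna", "ffl_type"],
        ).to_csv(out / "cerna_hub_ffl_motifs.tsv", sep="\t", index=False)
        with open(out / "motif_counts.json", "w") as fh:
            json.dump(net.type_counts, fh, indent=1, sort_keys=True)
        write_network(net.network, out / "signed_network.tsv", "edge-TSV")
        for m, sub in net.subnetworks.items():
            if sub.edges:
                write_network(sub, out / f"subnetwork_{m}.graphml", "GraphML")
        if net.drop_log is not None:
            net.drop_log.to_csv(out / "dropped_edges.tsv", sep="\t", index=False)


def run_demo(seed: int = 0, outdir: str | Path | None = None,
             n_pairs: int = 30) -> tuple[BiomarkerRunResult, NetworkRunResult | None]:
    """Simulate the worked biomarker scenario and run both pipeline halves."""
    from .synthetic_data import biomarker_scenario, simulate_counts, simulate_interactome

    sim = biomarker_scenario(seed=seed, n_pairs=n_pairs)
    matrices, _ = simulate_counts(sim)
    edges, ann, _ = simulate_interactome(sim)
    cfg = PipelineConfig(seed=seed, min_module_size=10)
    bio = run_biomarkers(matrices, edges, ann, cfg)
    net = None
    if bio.final:
        net = run_network(matrices, edges, ann, bio.final, cfg)
    if outdir is not None:
        write_outputs(outdir, bio, net, cfg)
    return bio, net
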