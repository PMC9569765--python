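# Methods

## Problem

`cernaffl` screens miRNA biomarkers for tumor/normal contrasts (the built-in
worked example emulates the two non-small-cell lung cancer subtypes) by
combining two independent lines of evidence, then explains the retained
markers through a 4-node directed competitive regulatory network of
transcription factors (TFs), miRNAs, mRNAs and lncRNAs.

## Independent-regulation arm (arm 1)

On the disease-specific bipartite miRNA→mRNA network (global interaction
pairs restricted to differentially expressed miRNAs and genes):

* **NOG** — number of genes uniquely targeted by a miRNA: targets whose
  in-degree in the bipartite network is exactly 1. A miRNA with many
  unique targets cannot be compensated by other miRNAs.
* **TFP** — fraction of a miRNA's targets that are TF genes.

A candidate must be significantly high on **both** statistics. The
significance construction is a leave-one-out one-sample Wilcoxon signed-rank
test: for miRNA *i*, the differences {score_j − score_i : j ≠ i} are tested
one-sided against location 0 (alternative: the differences lie below zero,
i.e. the candidate exceeds the population). Zeros are dropped; for n ≤ 14
the exact conditional null over all 2ⁿ sign assignments (midranks for ties)
is enumerated, otherwise the tie-corrected normal approximation is used.
Survivors are further filtered to NOG strictly greater than the median NOG
of the surviving set. The screen needs ≥ 6 miRNAs; below that no signed-rank
p can reach 0.05 and the arm returns no candidates.

A diagnostic (`nog_power_check`) fits log10 frequency against log10 NOG by
least squares over observed NOG ≥ 1; heavy-tailed NOG distributions give a
strongly linear fit with negative slope. It never gates the pipeline.

## Biological-significance arm (arm 2)

1. **Co-expression modules** (WGCNA-style): genes pass a MAD filter (top 75%
   by median absolute deviation, ties by input order), the soft threshold β
   is the smallest power whose unsigned adjacency |cor|^β yields scale-free
   fit R² ≥ 0.8 (R² of log-frequency vs log-connectivity over 10 logarithmic
   bins, zero bins dropped; fits with *positive* slope score 0, since
   scale-free topology requires frequency decreasing in connectivity). When
   no power qualifies — common at simulation scale — β falls back to the
   conventional unsigned-network defaults by sample size (10/9/8/7/6 for
   < 20/30/40/60/≥ 60 samples) rather than an arg-max over spurious fits.
2. The topological overlap matrix TOM_ij = (Σ_u a_iu a_uj + a_ij) /
   (min(k_i, k_j) + 1 − a_ij) feeds average-linkage clustering of 1 − TOM
   with a static height cut (default 0.99) and minimum module size (default
   30; the synthetic demo uses 10 at its smaller scale). This replaces the
   dynamic tree cut of the reference R implementation: module *recovery* of
   planted structure, not an exact module count, is the supported behaviour.
3. Module eigengenes are the first principal component of the standardized
   module submatrix (samples as observations), unit norm, oriented to
   correlate positively with the module genes on average. Modules whose
   eigengenes correlate above 0.75 are merged iteratively (highest r first,
   eigengenes recomputed after each merge).
4. The module with the largest |Pearson r| against the binary tumor trait
   (p < 0.05) is selected; its genes are intersected with the lung-enriched
   and oncogene/tumor-suppressor annotation lists, and validated miRNA→gene
   pairs targeting those genes are kept when expression correlation is
   strongly negative (r < −0.3, p < 0.05). Source miRNAs of surviving pairs
   are the arm-2 candidates.

## Intersection and ROC gate

Final biomarkers are the intersection of the two arms with ROC AUC > 0.85,
where AUC is the Mann–Whitney statistic (ties ½) of the miRNA's expression
against the tumor labels. Because markers can shift in either direction, the
default takes max(AUC, 1 − AUC) (`auto_orient`); set it off to score
orientation as-given.

## Expression scale

Counts are normalized by median-of-ratios size factors (computed over
features with no zero count, rescaled to geometric mean 1). Differential
calls use log2((mean tumor + 0.5)/(mean normal + 0.5)) with a Mann–Whitney
(unpaired, the default) or signed-rank (paired) test and
Benjamini–Hochberg correction per feature family; the thresholds are
|log2FC| ≥ 1.5, adjusted p ≤ 0.05. All *correlations* (module detection,
strong pairs, direction inference) run on log2(normalized + 1): Pearson r on
the raw count scale is attenuated by multiplicative noise, and the log is
the standard variance-stabilizing stand-in. Externally computed DE tables
can be injected via `diffexpr.deresults_from_table`.

## Network construction

Edges are merged across evidence sources with per-class rules: a class
listed in `required_sources` (e.g. miRNA→lncRNA requiring both of its two
databases) keeps only edges corroborated by every listed source; other
classes keep the union. Direction inference attaches Pearson r over shared
samples: miRNA-source edges survive as repression when r ≤ −0.15, p < 0.05;
TF-source edges survive when |r| ≥ 0.3, p < 0.05, signed by the sign of r.
One threshold applies to every TF target class (gene, miRNA, lncRNA), and a
TF's expression is proxied by its mRNA.

**FFL grammar.** A motif is a quadruple (TF T, miRNA M, gene G, lncRNA L)
with core edges M→G, M→L, T→G and T→L, classified by the TF–miRNA linkage:
type I (TF-mediated) iff T→M only, type II (miRNA-mediated) iff M→T only,
type III (composite) iff both. The three predicates partition the core-valid
quadruples, so a composite loop is never double-counted as I and II. The
T→L requirement can be waived (`require_tf_lncrna=False`), a documented
variant since the source topology figure admits both readings.

**Hubs.** On the motif network, key nodes are the union of the top ⌈5%·n⌉ by
total degree and by maximal clique centrality (MCC(v) = Σ over maximal
cliques C ∋ v of (|C|−1)!, computed on the undirected simple projection;
isolated nodes score 0). Ties at the cutoff include all tied nodes. Motifs
keep going if they contain a key node **and** their gene is in the top
⌈10%·n⌉ by degree of the PPI subgraph induced on miRNA-regulated genes.
Finally only motifs with a cytoplasmic lncRNA — the ceRNA-capable ones —
remain (the ceRNA-hub-FFL network).

## Synthetic world

The generator states a world with known answers:

* counts ~ gamma-Poisson (negative binomial), shared dispersion 0.1, base
  log2 means uniform on [5, 9]; planted DE features shift tumor means by the
  planted log2FC;
* each regulator (miRNA, TF) carries a per-sample log2 deviation of s.d. 1
  (~two-fold typical fluctuation); a planted edge adds ±1 × that deviation
  to its target's log mean, so planted signs reappear as correlations;
* module genes share a latent factor (trait term ± noise of s.d. 1) with a
  stated loading;
* the bipartite network realizes each planted unique-target count exactly:
  dedicated in-degree-1 genes per miRNA, shared genes co-targeted by two
  network miRNAs (a sponge decoy miRNA steps in only when a single real
  miRNA exists), so NOG is exact both globally and in any DE-restricted
  subnetwork;
* planted motifs are wired per the grammar with random TF signs; decoy
  edges are rejection-sampled so they complete no motif and touch no
  in-degree-1 gene.

The worked scenario (`biomarker_scenario`) plants one decisively strong
marker (M000: NOG 12, five TF-gene targets, important onco/TSG targets in a
tumor-anticorrelated module, 16-fold expression shift, one FFL of each type)
among two runners-up that pass the significance screen but fall at the
median filter, seven low-NOG decoys, and twenty null background miRNAs. The
backgrounds matter: median-of-ratios normalization needs a majority of
non-differential features, in the gene and the miRNA family alike.

What a green test does **not** establish: the generator has no batch
effects, GC/length bias, library-size gradients, per-feature dispersions or
correlated decoy structure, so recovery rates here do not predict
performance on real cohorts. Planted type-III motifs with an *activating*
TF→miRNA arm partially cancel their own expression correlations (the
feedback pushes the pair in opposite directions), so expression-level edge
inference keeps composite motifs only when the feedback is repressive —
exact motif-count recovery is therefore asserted at the network-enumeration
layer, while the pipeline layer asserts the monotone FFL → hub-FFL →
ceRNA-hub-FFL funnel and biomarker recovery.

## Numerical choices

* Exact signed-rank null enumerated up to n = 14 (16 384 assignments).
* MAD ties broken by input order; top-k cutoffs elsewhere include all ties.
* Eigengene sign fixed by mean correlation with module genes; merge order is
  highest-r-first with ties by module id; modules renumbered by size.
* Pseudocount 0.5 in the DE log-ratio; +1 in the log-normalized scale.
* Correlation p-values are the t-transform of r (two-sided).
* z-score outlier removal (cell-line correlation utility) computes z once on
  the full vectors, not iteratively.
* All randomness flows from one integer seed; reruns are byte-identical.

## Known limitations

* The static-height module cut needs a β large enough that unrelated genes
  have TOM ≈ 0; the sample-size fallback provides that, but data that are
  genuinely scale-free at β = 1–2 with dense inter-module TOM may still
  merge into one module.
* The screen's leave-one-out signed-rank construction is one defensible
  reading of "significantly high NOG and TFP"; other constructions (e.g.
  rank-sum against the population) would shift borderline candidates.
* miRNA identifiers are opaque strings; no mature/precursor reconciliation
  or alias resolution is attempted.
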