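# Methods

This note documents the models and procedures implemented in `scegrn`, the
parameters that matter, the assumptions of the synthetic data generator, and
the numerical conventions that pin down exact behaviour.

## 1. The inference chain

### Quality control and normalization

Cells must pass all filters jointly: ≥ 200 detected genes, ≤ 15%
mitochondrial counts (genes recognized by configurable name prefixes,
default `mt:`, `mt-`, `MT-`), log10(total ATAC fragments) ≥ 3.5, fraction of
reads in the consensus peak set ≥ 0.60, and TSS enrichment ≥ 2. The fragment
filter admits a second, literal reading (a raw threshold instead of a
threshold on the log10 scale); both are selectable via
`QCThresholds.fragment_filter_literal` because the convention is genuinely
ambiguous in the field's reporting. Genes detected in fewer than 3 cells are
dropped. Cluster-level QC removes clusters whose mean detected-genes-per-cell
falls below the global (per-cell) mean minus one SD; computing the reference
statistics over cluster means instead is available as a flag.

Expression is normalized per cell to a fixed total of 10⁴ followed by
natural-log `log1p`. The target sum and the choice of natural logarithm are
conventional defaults.

Consensus peaks: peaks are standardized to a fixed width (500 bp around the
summit), then merged by iterative overlap — repeatedly keep the
highest-scoring remaining peak and discard everything overlapping it by ≥ 1
bp. Score ties resolve by (chrom, start); the output is deterministic, sorted
and non-overlapping.

### Topic model

Chromatin accessibility is modelled by latent Dirichlet allocation on the
binarized region×cell matrix, fitted by collapsed Gibbs sampling (a seeded,
single-threaded numba kernel; one token per accessible (cell, region) entry).
Priors default to α = 50/T and β = 0.1, 300 iterations by default with
point estimates taken from the final sample — these match the conventions of
the topic-modelling tools used for single-cell ATAC. (`EGRNModel` uses 150
iterations by default: at the reference study's size the chains plateau well
before that, and doubling the iterations does not change the recovery
metrics.) `T = 1` is handled in
closed form. Model selection across a topic-count grid maximizes the median
UMass coherence over each topic's top-10 regions; coherence is computed on
cell-level co-occurrence counts. The coherence metric is a package choice —
"best coherence" admits several definitions — and is configurable.

Imputed accessibility is the matrix product θφ; each cell's row is a
probability simplex by construction. Two practical notes:

- **The topic count should exceed the number of expected programs.** Shared
  (housekeeping) chromatin competes with type-specific programs for topics;
  with too few topics, small populations lose their topic and their
  differential regions vanish. The `EGRNModel` default grid is 8 topics for
  the reference 5-type study; for other data, fit a grid and let coherence
  select.
- **Imputation only preserves topic-aligned signal.** Accessibility patterns
  orthogonal to the topic structure are smoothed away; downstream stages that
  consume imputed values inherit this limit (see §3).

### Differential accessible regions

Per cell group, a two-sided Wilcoxon rank-sum test (normal approximation with
tie correction) per region on imputed accessibility, Benjamini–Hochberg
adjustment across regions, and log2FC = log2((mean₁+ε)/(mean₂+ε)) with
ε = 10⁻⁸ (imputed values are small probabilities). A region passes at
p-adj < 5·10⁻³ and log2FC > 1.5. The model computes group-vs-rest,
group-vs-group (pairwise) and rest-vs-group contrasts: pairwise and
complement contrasts expose chromatin that is broadly open but shut in one
group — the signature of repression — which group-vs-rest tests dilute.

### Pseudo-bulk track differencing

Tracks are per-group binned sums (each region's counts assigned to its
midpoint bin); depth normalization scales the deeper track down to the
shallower. Per bin, with normalized x₁, x₂ and m = (x₁+x₂)/2, the signed
statistic is sign(x₁−x₂)·[x₁ln(x₁/m) + x₂ln(x₂/m)]/ln10 with 0·ln0 := 0 — a
Poisson likelihood-ratio statistic on the common-mean null, a documented
simplification of the bedGraph-differencing tools it mirrors. Bins with
|LLR| > 1.5 are assigned to the higher condition, merged across gaps ≤ 150 bp
and dropped below 300 bp. Bins above a background level (the 10th percentile
of nonzero bin means) in both tracks without being differential form the
"common" set. The caller is exactly antisymmetric under swapping tracks.

### Motif enrichment and cistromes

Each motif ranks all database regions by decreasing score (ties by region
index). For a query region set, the recovery curve H(k) counts query members
among the top k ranks; the normalized AUC is ΣH(k)/Σmin(k,|Q|) over
k ≤ R, so a query occupying the best ranks scores exactly 1. The integration
depth is R = max(min_ranks, ⌊auc_fraction·n⌋) with auc_fraction = 0.005. The
`min_ranks` floor (library default 1; `EGRNModel` default 20) matters for
small databases: 0.005 of 800 regions is 4 ranks, too coarse for the
statistic to discriminate — the fraction convention presumes full-scale
databases of ~10⁵ regions. NES standardizes AUCs across all database motifs
(sample SD, n−1). Motifs with NES > 3 contribute *hits* — query regions
within the top 5% (`rank_fraction`) of their ranking — to cistromes: direct
cistromes from direct TF annotations only; extended cistromes also from
similarity (FDR ≤ 0.001) and orthology (identity ≥ 0.6) annotations. Motifs
sharing a merged-consensus group are credited once per TF. Query sets that
are a large fraction (≳ 20–30%) of the database compress NES for every motif;
enrichment should be run per differential set, not on pooled unions.

### Region–gene and TF–gene links

Candidate pairs: regions whose nearest edge lies within [100 bp, 50 kb] of a
gene's TSS (distance 0 when the region covers the TSS; such pairs are
excluded by the 100 bp minimum — the window is applied literally, which
effectively excludes promoters). Strand is ignored. Per gene, a seeded
LightGBM regressor (500 rounds, learning rate 0.01, depth 3, 90% feature
subsample per round, no row bagging — keeping results invariant to cell
order) predicts expression from candidate regions' imputed accessibility;
importances are normalized split-gain shares. The same machinery regresses
each gene on all TFs' expression (self excluded). Spearman ρ accompanies
every edge; zero-variance targets yield zero importances and undefined ρ,
flagged.

### Assembly

Edges with ρ > 0.03 are activating, ρ < −0.03 repressing, |ρ| ≤ 0.03
discarded. (The threshold's source states the repressing branch with the
same sign; the only coherent reading is the symmetric one implemented here.)
Within each sign class, per-gene region pruning by nine rules: the
minimum-variance two-group split of the importance vector (exhaustive scan
over sorted cut points; an unsplittable all-equal vector keeps the gene
whole), importance ≥ the per-gene q-quantile for q ∈ {0.75, 0.80, 0.85,
0.90, 0.95} (linear/type-7 interpolation), and per-gene top-k for
k ∈ {5, 10, 15}. For each cistrome, sign and rule, the pruned edges inside
the cistrome propose a gene set tested by GSEA against the TF's TF→gene
importance ranking (weight exponent p = 1, importances as weights; ranking
ties broken by gene identifier; a tie in extremum magnitude — to numerical
rounding — resolves positive; no permutation test). Leading-edge genes and their regions are
retained; the union over rules forms one eGRN per (TF, class, sign), with
per-edge provenance.

### Activity, quality filter, specificity

AUCell activity of a feature set in a cell is the same normalized
recovery-curve AUC along the cell's feature ranking (ties by feature index —
deterministic, unlike randomized-tie AUCell builds; top_fraction = 0.05).
Pseudo-bulks: 150 profiles per group, each the mean of 15 cells sampled
without replacement within a profile (with replacement when the group is
smaller, recorded). eGRNs are kept when |Pearson ρ(TF expression, eGRN
activity)| > 0.2 across pseudo-bulks; the sign of ρ is the
activator/repressor call. When any direct eGRN of a TF survives, its
extended eGRNs are dropped. RSS(eGRN, group) = 1 − √JSD₂(P, Q) where P is
the activity vector normalized to sum 1 and Q the uniform distribution over
the group's cells; gene-based (expression) and region-based (imputed
accessibility) variants share one code path and are both reported.

Overlap and signature statistics: two-sided Fisher's exact test on 2×2
membership tables; one-tailed or paired t-tests with Bonferroni adjustment
across comparisons.

## 2. The synthetic multiome generator

The generator's distributional choices are its own — no published generative
model exists for this assay — and encode the statistical structure the
inference assumes:

- **Cells and topics.** 5 cell types of 600/500/450/390/60 cells (one rare,
  3%); per-cell topic mixtures are Dirichlet draws (concentration 50) around
  a type mixture with 0.8 on the type's home topic. Topic-region
  distributions place half their mass on a shared housekeeping block (70% of
  regions) and most of the rest (0.45) on a small type-specific block —
  chosen so that type-specific chromatin is a minority of regions (real
  consensus peak sets have a few percent of DARs per type) with unambiguous
  (~4×) imputed fold-changes.
- **Counts.** ATAC counts are Binomial(2, p) — near-binary, like real
  fragment counts — with p the (rescaled to mean 0.12) θφ product, shifted on
  the logit scale by weight × standardized log TF expression for each planted
  (TF, region) edge and clamped to [10⁻⁶, 1−10⁻⁶] (clamp count recorded). RNA
  counts are negative binomial (size 10) around type-specific means; a
  target gene's mean is multiplied by exp(link_strength × mean standardized
  accessibility of its linked regions).
- **Planted networks.** 10 TFs (the first 10 genes), 8 disjoint non-TF
  targets each, one region per target (each region linked to up to 3 of the
  TF's targets when their TSSs fall in-window); ~15% of links deliberately
  placed outside the 100 bp–50 kb window and flagged, to exercise window
  filtering. Activators are expressed in one home type (NB mean 20 vs 2) and
  their target regions carry a flat shared-block baseline — with zero effect
  size there is no TF–region association, so the planted signal is entirely
  causal. Repressors are broadly expressed (present in every type except one)
  and their targets are the repressed type's own enhancers (its topic block):
  the network is "off exactly where the TF is on", which is both the
  textbook repressor geometry and the configuration detectable by this
  pipeline — a repressor confined to one type, or with targets scattered
  across many programs, leaves too faint a footprint in any single
  differential set (a real limitation of the method, not only of the
  generator). A structural consequence: a repressor's TF–region
  anticorrelation has a baseline component from the type geometry even at
  zero effect size.
- **Motif database.** One direct motif per TF scoring ~N(10, 1) in its target
  regions, one weaker similarity-annotated motif (0.7×), 200 unannotated
  decoys; background scores Exponential(mean 1).
- **QC metrics** are drawn directly per cell (log10 fragments ~ N(4, 0.25),
  FRiP ~ Beta(24, 6), TSS enrichment ~ Gamma(8, 0.5)) rather than from
  fragment-level simulation; the filters are exercised, the metrics carry no
  biological signal.
- **Determinism.** One global seed expands into fixed per-stage child seeds
  (truth / simulation / motif database / QC), so stages are independently
  reproducible and byte-identical across reruns.

What the generator does **not** emulate: batch effects, doublets, ambient
contamination, fragment-level biases, sequence-level motif placement,
gene-body/strand effects, continuous differentiation trajectories, or
TF–TF cooperativity. Passing the recovery studies therefore shows the
inference chain is correct and well-calibrated under its own assumptions —
not that it is robust to these real-data complications.

## 3. Validation studies and their problem sizes

All studies run from seeded simulations at desk scale, chosen so the full
suite completes in minutes on one CPU:

- scoring statistics vs brute-force oracles (500 random instances each,
  ≤ 50 features; 1,000 vectors for the 1-D split; agreement to 1e-12/exact);
- motif step: 100 seeded databases (800 regions, 10 planted TFs + decoys),
  one differential-set-like query per TF (its targets + 50 background
  regions); planted motifs must reach NES > 3 with ≥ 90% cistrome recovery;
- topic recovery: 10 seeded simulations, LDA at the planted topic count (150
  iterations), mean best-bipartite-match Pearson r ≥ 0.8 between recovered
  and planted topic-region rows;
- end-to-end: the reference study (~2,000 cells), median per-TF target-gene
  precision ≥ 0.7 and recall ≥ 0.6, repressors labelled repressing, RSS
  peaking in the home type for ≥ 8/10 TFs (the two broadly-expressed
  repressors are the expected exceptions);
- error control: DAR pass rate ≤ 0.5% under label permutation on null data;
  exact recovery, with zero spurious calls, of noise-free ≥ 600 bp planted
  track blocks.

## 4. Known limitations

- The repressor detectability condition above: repression is only visible
  when the repressed program is coherent and well represented among cells.
- NES values depend on the whole database's AUC distribution; mixing many
  saturated motifs (or querying a large fraction of the database) compresses
  them. The NES > 3 convention assumes queries that are small relative to
  the database.
- The minimum-variance split, quantile and top-k pruning rules are applied
  per gene; genes with very few candidate regions are barely pruned, so the
  GSEA leading-edge step carries most of the selectivity for them.
- Collapsed Gibbs point estimates from a single final sample retain Monte
  Carlo noise; topic-recovery correlations plateau near 0.81 on the
  reference study regardless of iteration count (the remaining gap is
  smoothing bias from the priors, not lack of convergence).
- GSEA leading edges with ES ≤ 0 contribute nothing; a TF whose true targets
  rank low in its TF→gene importances (e.g. very weak expression coupling)
  is silently lost at this stage.
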