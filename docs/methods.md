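# Methods

This package re-creates, end to end, an immune-contexture analysis of
tumor-infiltrating T-cells: supervised flow-cytometry profiling of immune
checkpoint proteins (ICPs) on T-cell subsets, unsupervised cytometry
clustering, an scRNA-seq processing stage with paired single-cell TCR
data, and a joint stratification of T-cells by clonal expansion and
checkpoint expression. Because the real patient cohorts behind this kind
of study are not publicly deposited, the package is exercised against a
synthetic-cohort generator whose ground truth drives recovery tests. This
note documents the models, the numerical choices, and what the synthetic
results do and do not demonstrate.

## The synthetic cohorts

### Flow cytometry (`ticp.simulate.generate_flow_cohort`)

Each cell belongs to a latent subset drawn from a fixed simplex over
{CD8, CD4FoxP3neg, CD4FoxP3pos, DP, DN, nonT}. The default proportions
put the three reported subsets at 36.5% / 38.6% / 9.5% of T-cells —
the reference cohort medians for intratumoral CD8+, CD4+FoxP3− and
CD4+FoxP3+ cells — with small CD4+CD8+ (3%) and CD4−CD8− (12.4%)
T-cell populations and a 15% non-T contaminant fraction so gating has
something to exclude (half of the contaminants stain CD45+ to mimic
non-T immune cells).

Every marker value is drawn from a two-component log-normal: location
`neg_mean` (default 50) or `pos_mean` (default 5000) in arbitrary
fluorescence units, log-space SD `noise_sd` (default 0.5). Positivity of
a lineage marker is determined by the subset; positivity of each of the
10 panel checkpoints is an independent Bernoulli draw with
subset-specific rates, strongly skewed toward the regulatory subset
(e.g. CD39 on Tregs at 0.822, the reference cohort median). The model
produces unimodal positive and negative peaks per channel, so a
threshold at the geometric midpoint of the two component means
(`true_thresholds`) separates them almost perfectly; gating accuracy
against the planted labels exceeds 98% under the defaults. What this
model does *not* emulate: spectral spillover/compensation artifacts,
dead cells and viability dyes, correlated marker noise within a cell,
and continuous (rather than binary) positivity. Passing recovery tests
therefore show the *analysis* is correct, not that gating real cytometry
is this easy.

### scRNA-seq + TCR (`ticp.simulate.generate_sc_cohort`)

Counts are negative-binomial (gamma–Poisson, default shape θ = 1) over a
~300-gene universe: canonical lineage/effector markers, the 10
checkpoint genes, 8 mitochondrial genes, a small cell-cycle signature,
and ~260 filler genes with log-normal baseline means. Four default
clusters (two CD8, one conventional CD4, one FOXP3+ regulatory) carry
up-regulated gene programs in log2 units; the regulatory program carries
8 of the 10 checkpoint genes (not PDCD1/CD274, mirroring the observation
that the FOXP3+ cluster co-expresses all checkpoint genes except PD-1
and PD-L1). Program effects default to 3–7 log2 units so that lineages
separate in PCA space the way near-binary canonical markers (CD8A, CD4,
FOXP3) do in real T-cell data. Per-cell library-size factors are
log-normal (σ = 0.3).

TCR structure: each cell is productive with probability 0.84 (the
reference rate of T-cells with productive TCRs). Productive cells in
each cluster are partitioned into clones with zero-truncated geometric
sizes; the success parameters (0.3472 for CD8, 0.6836 for CD4) are
solved so that the expected fraction of cells in clones of ≥3 is 72.2%
(CD8) and 23.7% (CD4), the reference expansion rates. For the expected
cell-level fraction in clones ≥ 3 under a zero-truncated geometric with
parameter p, `1 − p²(3 − 2p)`. Each clone gets one TRA and one TRB chain
(random V/J calls and in-frame, stop-free CDR3s of 30–45 nt); clonotype
identifiers are patient-scoped and never reused. A configurable fraction
of clonotypes (default 5.4%, the reference sharing rate) has one cell
moved to another cluster of the same lineage, which is the only source
of cross-cluster clonotype sharing.

The planted association that the stratification must detect: expanded
(≥3-cell) clones in the regulatory cluster receive a +1 log2 boost on
the checkpoint genes (`planted_icp_effect`). Setting it to 0 yields an
exact null used by the false-positive tests. Not emulated: doublets,
ambient RNA, empty droplets, batch effects, UMI saturation, chain
dropout or dual-TRA cells — the generator emits called singlet cells, so
the QC stage exercises only the four count-based filters.

## Flow analysis

Gating is a fixed hierarchy (CD45+ → CD3+ → CD4/CD8 quadrants, FoxP3
splitting the CD4 single-positives); cutoffs are configuration, never
estimated from the data being gated. MFI is the arithmetic mean of raw
fluorescence; the Treg/Tconv ratio summary divides cohort *medians* of
per-sample MFIs, matching the convention of the ratio heat map it
reproduces. Group comparisons use Kruskal–Wallis with tie correction
followed by classical Dunn z-tests; the Dunn adjustment multiplies each
pairwise p by the number of comparisons (Bonferroni-style), the textbook
form of "Dunn's multiple comparison test". Two-group comparisons use
Mann–Whitney U: exact enumeration of all rank assignments when both
groups have ≤ 8 observations (two-sided by distance of U from its null
mean, tie-safe via midranks), otherwise the tie-corrected normal
approximation with continuity correction.

## Unsupervised cytometry clustering

The recipe is logicle transform → kNN graph → Jaccard re-weighting →
Louvain, with k = 30 and 12 channels (the 10 checkpoints + CD4 + CD8;
FoxP3 is deliberately excluded so the clustering must rediscover the
regulatory phenotype from checkpoint co-expression — the channel set is
configurable).

**Logicle.** Parks–Roederer–Moore biexponential with T = channel max,
M = 4.5 decades, A = 0. The auto-width rule is
`W = max(0, (M − log10(T/|r|))/2)` with r the 5th percentile of negative
events, `W = 0.5` when there are none. The inverse (display → data) is
closed-form; the forward transform inverts it by 60 rounds of vectorized
bisection plus Newton polishing (≤ 1e-9·T error; round-trip verified at
1e-6·T over a 10,000-point grid). The d-coefficient solves
`2 ln(d/b) + W'(b + d) = 0` by Brent's method.

**Jaccard weights** are computed over *self-inclusive* neighbourhoods
N(i) = {i} ∪ kNN(i). With self-exclusive sets, a weight of exactly 1 is
unattainable for any actual edge (j ∈ kNN(i) while j ∉ kNN(j)), whereas
duplicated points should — and here do — get weight 1. Ties in the kNN
search break by cell index after a stable sort.

**Louvain** is implemented in the package (local moving + aggregation)
so that the only randomness is the node visiting order drawn from the
seeded generator; this makes runs reproducible and the whole pipeline
permutation-equivariant (shuffling cells and mapping the visiting order
through the permutation yields the identical partition up to labels).
Moves require a strict modularity gain (tolerance 1e-12); labels are
renumbered by first appearance. Correctness is checked against
exhaustive partition search on 6-node graphs. Like any modularity
optimizer, it happily subdivides large diffuse populations (the
resolution limit works in reverse on kNN graphs); population-recovery
tests use compact planted populations with k sized generously relative
to the population (k = 30–45 at 150–200 cells per population).

## scRNA-seq stage

QC applies, in order: genes detected in < 5 cells removed (computed on
the input cells); then cells with < 1000 UMIs, < 200 detected genes, or
> 20% mitochondrial counts (prefix `MT-`) removed. Normalization is
`ln(1 + 10⁴·count/cell_total)`. HVG selection is the
variance-stabilizing scheme: a lowess fit (span 0.3) of log10 variance
on log10 mean gives each gene an expected SD; standardized values are
clipped at √n_cells and their variance ranks genes, ties broken by gene
order.

Dimensionality/clustering is swept over a grid — dimensions 3–49 in
steps of 2 (24 candidates) × resolutions 0.1–1.2 in steps of 0.1 — on a
centered truncated-SVD (PCA) embedding of the HVG matrix. The factor
model originally used for this embedding is a published external method;
this package deliberately substitutes plain centered PCA and treats the
embedding as an interchangeable input to the analysis around it, which
is the part under test. Each dimensionality gets a k = 20 Jaccard kNN
graph; partitions per resolution come from RB-modularity optimization
(leidenalg, seeded). Stability of a grid point is the mean adjusted Rand
index against the partitions at adjacent resolutions; the selected point
maximizes mean silhouette width subject to stability ≥ 0.5 (configurable
floor; silhouette on ≤ 2000 seeded-subsampled cells), replacing the
manual "best structure in the UMAP" judgement with a reproducible rule.
Tests and the bundled analyses run reduced grids (3–4 dimensionalities ×
3–4 resolutions) because the synthetic cohorts are low-rank by
construction; the full default grid is retained in the configuration.

Cell-cycle scoring is the binned-control module score: genes are binned
into 24 expression bins; each signature gene contributes up to 100
same-bin control genes (seeded draw); score = mean(signature) −
mean(controls); phase = argmax(S, G2M) if positive else G1. The bundled
S/G2M lists are the standard human signatures and are configurable.

Lineage assignment z-scores each cluster's mean expression of canonical
marker sets (CD8: CD8A/CD8B; CD4: CD4/IL7R; Treg: FOXP3/IL2RA) across
clusters and takes the argmax, with two guards: the regulatory label
additionally requires FOXP3 detected in > 30% of the cluster's cells
(otherwise the next-best lineage is used), and ties break by lineage
order with a warning.

Differential expression: `avg_log2FC = log2(mean(expm1 xA)+1) −
log2(mean(expm1 xB)+1)` (the +1 pseudocount bounds fold changes on
sparse data and makes 0.58 log2 units correspond to the 1.5-fold
cutoff); `pct` = fraction of cells with a nonzero count. Genes are
pre-filtered (max pct ≥ 0.25 and |log2FC| ≥ 0.58) *before* testing, so
the BH correction runs over the tested genes only; the Wilcoxon
rank-sum test is the same implementation as the flow stage's
Mann–Whitney. Only genes with BH-adjusted p < 0.05 are returned.

## TCR and the clonality × expression stratification

A clonotype is the sorted multiset of (chain, V gene, J gene, CDR3
nucleotide) over a cell's productive contigs — the strict key; cells
sharing only one chain of a pair are distinct clonotypes. Alternative
keys (genes-only, CDR3-aa, CDR3-nt) are configurable. Clone size is
counted within patient over whichever barcode universe is supplied;
repertoire statistics (expansion rates, diversity) are computed on the
full contig/barcode set, while expression-linked statistics use the
QC-surviving cells. HC means clone size ≥ 3; size classes are
{1, 2, 3–10, 11–100, >100}, honoring both the 3-cell expansion boundary
and the ">100 cells" remark for hyper-expanded clones.

Per patient and per checkpoint gene, the median normalized expression
over all clonotyped T-cells defines the HE/LE reference. A cell is HE
when it exceeds the patient median for at least ⌈panel/2⌉ (5 of 10)
checkpoint genes — the reference definition fixes the per-ICP medians
but not the per-cell aggregation, so the majority-of-indicators rule is
the default and a mean-score rule is available as configuration. On
sparse data most per-gene medians are 0 and the indicator reduces to
"detected", which is why the per-cell checkpoint *burden* (number of
panel genes with a nonzero count, 0–10) is counted on detection rather
than on above-median expression. The LC→HC differential map reports,
per cluster × gene, the median across contributing patients of the
per-patient `log2(mean expm1 HC + 1) − log2(mean expm1 LC + 1)`; a
patient contributes only where both classes have ≥ 10 cells, and a
log2-of-median-ratio reading is available as configuration.

## Reproducibility and problem sizes

All randomness flows from one integer seed through per-stage
`SeedSequence` substreams, so disabling a stage never shifts another
stage's draws, and reruns with the same configuration are byte-identical
(hash-verified in the manifest). The bundled analyses and the
acceptance script use a 10-sample × 10,000-cell flow cohort and a
5-patient × 5,000-cell single-cell cohort — one order below the real
study's ~28,000 profiled cells, chosen as comfortable desk-scale sizes
at which every recovery band in the test suite is several sampling
standard errors wide. Recovery tests average over 5 fixed seeds; null
checks use 5–20 replicates.

## Known limitations

- The generator's binary checkpoint positivity makes unsupervised flow
  clusters correspond to discrete positivity combinations; cluster
  counts are therefore a property of the panel, not of biological
  substructure.
- Multi-patient scRNA-seq runs are concatenated without batch
  correction; the per-patient path is the default and integration is
  out of scope.
- The regulatory HC-vs-LC burden shift saturates: with 8 of 10
  checkpoint genes already near-certain detection in regulatory cells, a
  +1 log2 planted effect moves the mean burden by ~0.7 rather than a
  full checkpoint, so the burden statistic is reported but not used as a
  recovery criterion under the default conditions.
- Mann–Whitney normal approximation deviates from the exact p by more
  than 0.01 in the far tail at very small n; the implementation switches
  to exact enumeration there, so the approximation is never used where
  it is unreliable.
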