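# ticp — immune-contexture profiling of tumor-infiltrating T-cells

`ticp` is an analysis toolkit for the question that drives patient
selection in checkpoint-immunotherapy trials: *which intratumoral T-cell
subsets actually express the drug targets?* It covers the full chain of
analyses used to answer it at single-cell resolution:

- **Supervised flow cytometry** — hierarchical gating
  (CD45⁺ → CD3⁺ → CD8 / CD4FoxP3⁻ / CD4FoxP3⁺), per-subset percent
  positivity and MFI for a 10-protein immune-checkpoint (ICP) panel
  (CD25, CD28, CD39, 4-1BB, CTLA-4, ICOS, OX40, PD-1, PD-L1, TIGIT),
  Treg/Tconv MFI ratios, pairwise co-positivity, and Kruskal–Wallis +
  Dunn / Mann–Whitney cohort statistics.
- **Unsupervised cytometry clustering** — the PhenoGraph recipe:
  auto-logicle transform, k = 30 nearest-neighbour graph with Jaccard
  edge weights, seeded Louvain modularity optimization, normalized
  cluster profiles and per-sample abundances, UMAP embedding.
- **scRNA-seq** — QC (genes in ≥ 5 cells; cells with ≥ 1000 UMIs, ≥ 200
  genes, ≤ 20% mitochondrial), log-normalization, 3000 variance-
  stabilized HVGs, clustering over a dimensions × resolution grid with a
  stability report, cell-cycle scoring, canonical-marker lineage
  assignment, and Wilcoxon differential expression filtered at
  |log2FC| ≥ 0.58 (1.5-fold), ≥ 25% expressing cells, BH FDR < 0.05.
- **TCR repertoire** — strict-key clonotype calling from 10x-style
  contig annotations, diversity and clone-size classes, the
  high-clonality boundary at clones of ≥ 3 cells (HC vs LC), and
  cross-cluster clonotype sharing.
- **Clonality × expression stratification** — per-patient per-ICP
  median expression, per-cell high/low-expression classes (HE/LE), the
  four compartments HC_HE / HC_LE / LC_HE / LC_LE, per-cell ICP burden,
  and LC→HC fold-change maps per cluster.

Real cohorts of this kind are not publicly deposited, so the package
ships a first-class synthetic-cohort generator (`ticp.simulate`) that
emulates the study's statistical structure with known ground truth —
subset proportions, Treg-skewed checkpoint positivity, heavy-tailed
patient-private clonotypes with more expansion in CD8 cells, and a
planted association between clonal expansion and checkpoint expression
in the FoxP3⁺ cluster. Every analysis is validated by recovering what
the generator planted; `docs/methods.md` describes the models and what
the synthetic results do and do not show.

## Worked example

Run the numbered analyses (each is a thin driver over the library and
writes TSVs under `results/`):

```bash
python analysis/01_simulate_cohorts.py   # 10 flow samples + 5 sc patients
python analysis/02_flow_supervised.py
python analysis/03_flow_clustering.py
python analysis/04_sc_pipeline.py
python analysis/05_tcr_repertoire.py
python analysis/06_clonality_icp.py
```

`02` gates the flow cohort and prints the cohort medians:

```
median %% of T-cells: {'CD8': 36.2, 'CD4FoxP3neg': 38.7, 'CD4FoxP3pos': 9.5}
Treg CD39+ %: 81.8
Treg/Tconv MFI ratio extremes: {'CD28': 1.07, '4-1BB': 4.97}
```

— the three subsets sit at their planted cohort medians (≈ 36.5 / 38.6 /
9.5% of T-cells), CD39 is positive on ≈ 82% of regulatory cells, and the
MFI-ratio vector shows every checkpoint except CD28 elevated on Tregs
relative to conventional CD4 cells.

`05`–`06` call clonotypes, stratify, and print the headline association:

```
lineage  n_cells  pct_expanded
    CD4     4821          19.0
    CD8     9627          65.3
   Treg     3261          22.3
clonotype sharing: 4.7% of 9612 clonotypes span ≥2 clusters

HC_HE CD4 cells: 741; 98.0% belong to the FoxP3+/regulatory cluster
regulatory-cluster checkpoint burden (HC vs LC):
cluster  hc_mean  lc_mean  p_adj
   P1.3    7.829    7.130    0.0
   ...
```

— CD8 clusters are dominated by expanded clones while CD4 clusters are
not, clonotype sharing across clusters is rare, and nearly all CD4 cells
that are simultaneously highly clonal and checkpoint-high sit in the
regulatory cluster, with a significant HC-over-LC checkpoint-burden
shift there and nowhere else. That concentration of expanded,
checkpoint-co-expressing T-cells in the CD4⁺FoxP3⁺ compartment is the
study's central observation, here recovered from the planted effect.

A single command runs everything on a small configuration:

```bash
ticp all --seed 1 --outdir results/demo
```

## Layout

```
src/ticp/          library: simulate, flow, logicle, phenograph, sc,
                   tcr, clonality, stats, io, config, pipeline, cli
analysis/          numbered narrative drivers (01–06)
scripts/           acceptance.py
tests/             pytest suite (unit, property, recovery, acceptance)
docs/methods.md    models, parameters, numerical choices, limitations
```
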