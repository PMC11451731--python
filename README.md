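# mprog

**NMF metaprogram discovery and validation for single-cell tumor cohorts.**

Malignant cells within and across tumors reuse a limited repertoire of
gene-expression programs — *metaprograms* (MPs). `mprog` implements a
complete, reproducible pipeline for discovering such programs from
gene × cell count matrices of two tumor model cohorts, validating them
against an independent (e.g. human) cohort, and testing their association
with patient outcome. It is aimed at computational biologists analysing
matched mouse-model / patient single-cell RNA-seq data.

## The method

Discovery runs separately per cohort on malignant cells:

1. **Gene filtering** — keep genes expressed in ≥ 1% of pooled malignant
   cells; expression is log1p(counts-per-10k) per cell.
2. **NMF** — factorize each cohort's matrix `X ≈ W H` (rank 30 by default,
   Frobenius loss, multiplicative updates, no regularization).
3. **Gene prioritization** — per factor, z-score each gene's loading
   *across factors* and keep genes with `z > 1.5`; among those candidates
   build a co-expression graph (edges where Spearman ρ > 0.4 across the
   cohort's cells) and keep the largest connected component. Factors with
   < 10 prioritized genes are discarded.
4. **Activity scoring** — AUCell-style rank-AUC: a cell's activity for a
   gene set is the normalized area under the recovery curve of set members
   within the top 5% of that cell's gene ranks. A program's activity
   threshold is mean + 1 sd of a normal fit to its scores over all cells.
5. **Metaprogram assembly** — Pearson-correlate factor activities over
   pooled cells, cluster factors hierarchically (average linkage on
   1 − r, cluster count chosen by maximum silhouette), keep consensus
   genes present in ≥ 25% of a cluster's factors, and drop metaprograms
   active in < 10% of cells in every cohort.
6. **Stability selection** — repeat 1–5 one hundred times with independent
   seeds; score each run by the 5-fold CV auROC of a logistic regression
   separating the two cohorts from MP activities, and keep the run with
   the *median* auROC.

Downstream validation: cells are clustered in z-scored MP-activity space
via a Mahalanobis k-nearest-neighbor graph (k = 30) and best-of-100
Louvain runs (resolution 0.4, selected by silhouette); MP catalogues from
different species are compared by per-tumor Spearman correlation of their
activities, calling a pair *shared* when the tumor-wise correlations are
significantly above 0.2 (one-sided Wilcoxon signed-rank, α = 0.05); and
pseudobulk (per-sample summed counts, log2(CPM + 0.001)) signature scores
— mean per-gene z across samples — are split at the median into High
(≥ median) / Low groups and compared by the log-rank (Mantel–Cox) test on
progression-free survival.

Because real deposits are not required, the package ships a synthetic
cohort generator that plants known programs (gene sets, per-cell Bernoulli
activities, multiplicative effects on Poisson rates), homologous human
programs, and survival times whose hazard is tied to program activity —
giving every stage a ground truth to recover.

## Worked example

```python
from mprog import MetaprogramDiscovery, PipelineConfig, default_spec, generate_mouse_cohorts

counts, truth = generate_mouse_cohorts(default_spec(seed=1))
config = PipelineConfig(n_stability_runs=10, master_seed=1)
results = MetaprogramDiscovery(counts, config).fit()
print(results.summary())
```

```
Metaprogram discovery (stability-selected NMF)
====================================================
cohorts:            A vs B
stability runs:     10 (0 failed)
selected run:       #7 (median auROC = 0.948)
metaprograms:       5

MP     genes  factors  active fraction per cohort
MP1       29        2  A: 0.00, B: 0.65
MP2       22        1  A: 0.61, B: 0.00
MP3       24        4  A: 0.33, B: 0.28
MP4       24        2  A: 0.31, B: 0.28
MP5       27        3  A: 0.30, B: 0.27
```

The selected run separates the two cohorts at auROC 0.948 (chance would be
0.5): MP1 and MP2 are the cohort-exclusive planted programs, MP3–MP5 the
shared ones, and all five match their planted gene sets at Jaccard ≥ 0.5.
Cell states, cross-cohort calls and survival splits continue from the
fitted results:

```python
from mprog import CellStateModel

states = CellStateModel(results.activities(), config.replace(n_louvain_runs=10)).fit()
print(states.summary())
```

```
Cell-state clustering (Mahalanobis kNN + consensus Louvain)
==========================================================
cells:       1200
clusters:    15
silhouette:  0.568
```

With five independent binary programs the cells occupy many combinatorial
activity states, so Louvain resolves more clusters here than the three
archetypes of the dedicated cell-state benchmark.

The same pipeline is available from the shell:

```bash
mprog simulate --seed 1 --out-dir fixture/
mprog discover --mtx fixture/mouse.mtx --genes fixture/mouse.genes.tsv \
               --cells fixture/mouse.cells.tsv --seed 1 --out-dir out/
```

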