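# Methods

This note records the models, parameter choices and numerical conventions
behind `mprog`, including the decisions taken where the procedure left a
genuine choice open.

## Discovery model

Metaprogram discovery treats each cohort's malignant-cell expression as
approximately low-rank nonnegative: `X ≈ W H`, with `X` the
log1p(counts-per-10k) matrix (genes × cells), `W` the gene loadings and
`H` the per-cell factor weights. Factors are candidate programs; their
biological content is distilled in two steps, then recurrent content is
pooled across cohorts:

- **Loading z-scores across factors.** For each gene, its loadings over
  the `k` factors are standardized (sample sd; genes with constant
  loadings get all-zero z). A gene is a candidate for a factor when its
  z there exceeds 1.5 — i.e. the factor uses the gene distinctly more
  than the gene's other factors do.
- **Co-expression filtering.** Candidates must also co-vary in the data:
  edges connect candidate pairs with Spearman ρ > 0.4 across the cohort's
  own cells, and only the largest connected component survives. Ties on
  component size break by summed loading, then lexicographic gene order
  (determinism). The graph is scoped to the factor's candidates, not all
  genes. Factors keeping fewer than 10 genes are dropped.
- **Assembly.** Retained factors from both cohorts are scored on the
  pooled cells (rank-AUC, below); their activity columns are
  Pearson-correlated; average-linkage hierarchical clustering on
  `1 − r` groups them, with the cluster count chosen by maximum mean
  silhouette over k = 2 … min(15, n−1), ties to the smaller k. A
  cluster's consensus list keeps genes present in ≥ 25% (ceiling rule) of
  its member factors, ordered by occurrence then gene id. Metaprograms
  whose binarized activity covers < 10% of cells in *every* cohort are
  discarded — a program active in only one model is a model-enriched
  program, not noise; a stricter any-cohort reading is available via
  `drop_inactive_mode="any"`. Survivors are renumbered MP1… by descending
  total active fraction.

NMF uses multiplicative updates (Frobenius loss, no regularization),
random nonnegative initialization from the run seed, and stops when the
relative error change falls below 1e-5 or at 500 iterations — tight
enough that repeated runs are dominated by initialization, cheap enough
that 100 repeats remain desk-feasible. The rank scan for elbow inspection
warm-starts each rank from the previous solution padded with a tiny
(1e-8-scaled) random component, which makes the reported error sequence
non-increasing by construction; rank choice itself is left to the caller.

### Stability selection

NMF solutions are non-unique, so the whole discovery procedure is
repeated (default 100 times) with seeds derived from the master seed and
the run index only — results are independent of execution order and
parallelizable. Each run is scored by how well its metaprogram activities
separate the two cohorts: stratified 5-fold CV, L2 logistic regression
(C = 1) per training fold, and one auROC on the pooled out-of-fold
probabilities (pooling is lower-variance than averaging per-fold auROCs
at these sample sizes). The *median*-auROC run is selected — typical, not
extreme; with an even run count the lower-middle run is taken so an
actual run is always returned, auROC ties breaking by run index. Runs
that produce no metaprograms are excluded from the median (a failed run
is not a candidate decomposition), with a warning. Both the NMF
initialization and the CV folds are re-randomized per run.

## Rank-AUC activity and the global threshold

A cell's activity for a gene set is the area under the recovery curve of
set members within the top `ceil(0.05 × G)` ranked genes of that cell,
normalized by the maximum attainable area (all members at the top). 0.05
is the upstream tool's default rank cutoff. Scores depend only on
within-cell ranks, hence are invariant to per-cell monotone normalization
and to rescaling counts. Sparse counts tie massively at zero; ties are
broken by a fixed pseudorandom key derived (SHA-256) from gene identity,
cell identity and the seed, which makes scores deterministic, invariant
to gene order in the input, and unbiased with respect to gene index.

The per-program activity cutoff is the mean + 1·sd of a normal fit (MLE)
to the program's scores over all cells — a global, k = 1 threshold; cells
strictly above it are *active*. With zero variance the threshold equals
the mean and no cell is active. Thresholds are only fitted with ≥ 20
cells. Alternative threshold rules (density-based, per-cohort) are out of
scope.

## Cell states

Metaprogram activities are z-scored per program over all cells (sample
sd; constant programs become zero columns with a warning). Cell–cell
distances use the Mahalanobis metric — Euclidean after whitening by the
inverse Cholesky factor of the sample covariance — because program
activities can be strongly correlated; a ridge of `1e-6·trace(Σ)/p` is
added when the covariance is ill-conditioned (near-collinear programs).
The k = 30 nearest-neighbor graph (symmetrized union of directed edges,
unweighted) is clustered by Louvain at resolution 0.4
(resolution-scaled modularity, as implemented in igraph), 100 runs with
derived seeds, keeping the run with the highest mean silhouette under the
same Mahalanobis distances; if every run collapses to one cluster the
trivial clustering is returned with silhouette flagged NaN. UMAP
coordinates (seeded) are for visualization only and never feed the
clustering.

## Cross-cohort correlation calling

Two program catalogues scored on the same cells are compared per tumor:
Spearman ρ of their activities across the tumor's cells, for every
program pair. Tumors with < 20 cells are skipped (rank correlations are
unstable at small n; the threshold is configurable). A pair is *shared*
within a cohort when the vector of tumor-wise ρ values is significantly
above 0.2 by a one-sided Wilcoxon signed-rank test (exact null for
n ≤ 25, normal approximation with continuity correction above, zeros
dropped) at α = 0.05 *and* the median ρ itself exceeds the floor; the
test is applied to the full tumor-wise vector, with the median retained
for reporting. No multiple-testing correction is applied across pairs by
default, matching the literal procedure; a Benjamini–Hochberg option
(`bh_correct=True`) adjusts within a cohort. Pairs are then counted across cohorts and every pair
significant in ≥ 1 cohort is emitted.

## Outcome association

Pseudobulk expression sums counts per sample and normalizes as
log2(CPM + 0.001). A signature score is the mean over signature genes of
each gene's z-score across samples (sample sd; genes absent from the
matrix are omitted; an empty intersection is an error). Samples split at
the median score — ties going to High (score ≥ median) exactly as the
rule is stated — and the groups' progression-free survival is compared by
the log-rank (Mantel–Cox) test in its grouped hypergeometric form:
observed − expected events in the High group accumulated over distinct
event times, variance by the hypergeometric formula with standard tie
handling, χ² with 1 df. Implementing the statistic directly (rather than
through a survival library) exposes the sign of O − E, i.e. whether High
fares worse — needed for direction checks; `lifelines` is used as an
independent cross-check in the tests and for Kaplan–Meier summaries.
Signature–signature associations use Spearman ρ with an exact
(full-enumeration) two-sided p for n ≤ 9. No Cox regression or covariate
adjustment is provided.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes —
nothing more. Per gene, a Gamma(0.3, 1) baseline rate; per cell, a
log-normal library size (log-mean ln 2500, log-sd 0.3) and Bernoulli
activity per planted program with cohort-specific probability; active
programs multiply their genes' rates by `effect_size`; the rate vector is
renormalized to sum to one before scaling by library size (so effects
change composition, not totals); counts are Poisson, with optional
Gamma-mixed negative-binomial overdispersion for robustness experiments.
The activity *dose* (the exponent on the effect) is the binary activity
by default; `dose_sd` adds jitter for continuous-dose experiments.

Default study conditions: 2000 genes, 600 cells per cohort, five disjoint
40-gene programs at effect 6. Two programs are cohort-exclusive with
penetrance 0.7 in their own cohort — high penetrance is what makes the
programs model-defining; it puts the Bayes-optimal cohort-separation
auROC near 0.95, whereas penetrance 0.5 would leave ~25% of cross-cohort
cell pairs carrying no cohort information and cap any classifier at
~0.875. Three programs are shared across cohorts (penetrance 0.3–0.4)
and also planted, through a one-to-one homolog map, in a human-like
cohort of 12 tumors × 50 cells. One shared program carries a hazard
coefficient of 1: progression-free survival per tumor is exponential with
rate `exp(Σ coef · z(score))` where the score is the tumor's mean program
dose standardized across tumors, and censoring is Uniform(0, 2 × mean
PFS) — keeping roughly a third to a half of tumors censored without
extra parameters.

What the generator does **not** model: doublets, ambient RNA, batch
effects, cell-cycle structure, overlapping program gene sets, or
continuous activity gradients (by default). Passing recovery tests
therefore demonstrates the pipeline's correctness under its own
assumptions, not robustness to those real-data complications.

## Benchmarks and problem sizes

`mprog.benchmarks` (driven by `scripts/acceptance.py` and the acceptance
tests) measures: exact agreement of the rank-AUC scorer with brute-force
recovery-curve integration (200 random instances) and of the
largest-component rule with a union-find reference (100 random graphs up
to 50 nodes); exact Wilcoxon p-values against full sign-pattern
enumeration (n ≤ 10, including the all-positive n = 5 case, p = 1/32);
planted-program recovery and cohort separation at the full default
conditions with 10 stability repeats; recovery of three activity
archetypes by the cell-state stage and exact reduction of the
Mahalanobis kNN graph to Euclidean under identity covariance;
cross-cohort calling power on 50 simulated cohorts and its false-call
rate on 200 null cohorts with disjoint gene sets (catalogues that share
genes share true signal, so the null draws disjoint sets); log-rank
type-I error over 1000 null splits at 100 samples and the direction of
the median-split effect over 100 cohorts with a positive hazard. The
per-stage simulations use scaled-down cohorts (400 genes, 150 cells per
cohort, 12 tumors × 30 cells) chosen to exercise the full code path at
interactive cost; the discovery benchmark runs at full scale.

## Numerical conventions and degenerate inputs

- All z-scores use the sample (n − 1) standard deviation, except the
  normal fit behind the activity threshold, which is MLE.
- "At least x%" thresholds use ceiling counts (`ceil(frac × n)`), so
  exactly-at-threshold cases are kept.
- Constant vectors: correlations involving a constant factor are defined
  as 0 (flagged); constant score vectors within a tumor give NaN ρ,
  dropped before the Wilcoxon test; constant z-score columns become 0.
- Gene/cell identifiers are case-sensitive and matched exactly. A
  one-to-many homolog relation resolves to the alphabetically first
  target present in the data — a deterministic rule chosen here, since no
  convention was inherited.
- Every stochastic stage draws its seed as
  `SHA-256(master_seed : stage_name : index)` truncated to 31 bits, so
  the pipeline is a pure function of (inputs, config, master seed) and
  stages can run in any order.

## Known limitations

- The activity-threshold rule is one fixed convention ("global, mean +
  1 sd"); results with heavily skewed score distributions may warrant the
  density-based alternatives that are deliberately out of scope.
- The co-expression graph is scoped to each factor's candidate genes;
  including non-candidate genes as bridge vertices could merge components
  and is not supported.
- Rank selection for NMF is by inspection of the elbow scan; no automatic
  criterion is provided.
- The null calibration of cross-cohort calling assumes catalogues with
  disjoint gene sets; overlapping catalogues genuinely correlate and will
  be called shared.
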