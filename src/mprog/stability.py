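"""Stability selection over repeated discovery runs.

NMF factorizations are non-unique, so the whole discovery procedure
(factorize per cohort → prioritize genes → score factor activities →
cluster into metaprograms → drop inactive) is repeated with independent
seeds. Each run is scored by the cross-validated auROC of a logistic
regression distinguishing the two cohorts from metaprogram activities, and
the run with the *median* auROC is selected — a run that separates the
cohorts as well as a typical decomposition does, not an outlier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._seeds import derive_seed
from .assembly import Metaprogram, assemble_metaprograms, drop_inactive
from .config import PipelineConfig
from .datamodel import CountMatrix, GeneSetCollection
from .factorization import (
    factors_to_gmt,
    filter_genes,
    prioritize_factor_genes,
    run_nmf,
)
from .scoring import ActivityMatrix, score_programs

logger = logging.getLogger(__name__)

__all__ = ["RunResult", "score_run", "select_median_run", "run_stability", "single_run"]


@dataclass
class RunResult:
    """One repeat of the discovery procedure and its cohort-separation score."""

    run_index: int
    seed: int
    metaprograms: list[Metaprogram]
    auroc: float | None  # None when the run produced no metaprograms

    def __post_init__(self) -> None:
        if self.auroc is not None and not (0.0 <= self.auroc <= 1.0):
            raise ValueError(f"auroc {self.auroc} outside [0,1]")


def score_run(
    mp_activities: ActivityMatrix,
    cohort_labels: np.ndarray,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """auROC of a CV logistic regression separating the two cohorts.

    Stratified k-fold; an L2-regularized logistic regression (C=1) is fit
    per training fold and the auROC is computed once on the pooled
    out-of-fold predicted probabilities.
    """
    labels = np.asarray(cohort_labels, dtype=object)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two cohorts, got {list(classes)}")
    y = (labels == classes[1]).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("one cohort is empty")
    x = mp_activities.scores.values
    oof = np.zeros(len(y))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(x, y):
        clf = LogisticRegression(C=1.0, max_iter=2000)  # L2 by default
        clf.fit(x[train], y[train])
        oof[test] = clf.predict_proba(x[test])[:, 1]
    if np.all(oof == oof[0]):
        return 0.5  # uninformative features: no ranking at all
    return float(roc_auc_score(y, oof))


def select_median_run(runs: list[RunResult]) -> RunResult:
    """The run with the median auROC.

    Runs are sorted by (auroc, run_index); with an even count the lower of
    the two middle values is taken, so an actual run is always returned.
    """
    scored = [r for r in runs if r.auroc is not None]
    if not scored:
        raise ValueError("no scored runs to select from")
    ordered = sorted(scored, key=lambda r: (r.auroc, r.run_index))
    return ordered[(len(ordered) - 1) // 2]


def single_run(
    counts: CountMatrix, config: PipelineConfig, run_index: int
) -> RunResult:
    """One discovery repeat on a malignant, gene-filtered count matrix."""
    seed = derive_seed(config.master_seed, "stability-run", run_index)
    cohorts = sorted(set(counts.cohort))

    factor_sets = []
    for c_i, cohort in enumerate(cohorts):
        fs = run_nmf(
            counts,
            cohort,
            config.n_factors,
            derive_seed(seed, f"nmf:{cohort}"),
        )
        fs = prioritize_factor_genes(
            fs,
            counts,
            z_thr=config.loading_z_threshold,
            corr_thr=config.coexpr_corr_threshold,
            min_genes=config.min_prioritized_genes,
        )
        factor_sets.append(fs)

    factor_gmt_sets: dict[str, list[str]] = {}
    for fs in factor_sets:
        factor_gmt_sets.update(factors_to_gmt(fs).sets)
    if len(factor_gmt_sets) < 3:
        logger.warning("run %d: fewer than 3 retained factors; no MPs", run_index)
        return RunResult(run_index, seed, [], None)
    factor_programs = GeneSetCollection(factor_gmt_sets)

    factor_activities = score_programs(
        counts,
        factor_programs,
        top_frac=config.auc_top_frac,
        seed=derive_seed(seed, "aucell-factors"),
    )
    try:
        mps = assemble_metaprograms(
            factor_sets,
            factor_activities,
            consensus_frac=config.consensus_gene_frac,
        )
    except ValueError as exc:
        logger.warning("run %d: assembly failed (%s); no MPs", run_index, exc)
        return RunResult(run_index, seed, [], None)
    if not mps:
        return RunResult(run_index, seed, [], None)

    mp_activities = score_programs(
        counts,
        GeneSetCollection({mp.id: mp.genes for mp in mps}),
        top_frac=config.auc_top_frac,
        seed=derive_seed(seed, "aucell-mps"),
    )
    mps = drop_inactive(
        mps,
        mp_activities,
        counts.cohort,
        config.min_active_cell_frac,
        mode=config.drop_inactive_mode,
    )
    if not mps:
        logger.warning("run %d: all metaprograms inactive; excluded", run_index)
        return RunResult(run_index, seed, [], None)

    final_activities = score_programs(
        counts,
        GeneSetCollection({mp.id: mp.genes for mp in mps}),
        top_frac=config.auc_top_frac,
        seed=derive_seed(seed, "aucell-final"),
    )
    auroc = score_run(
        final_activities,
        counts.cohort,
        folds=config.cv_folds,
        seed=derive_seed(seed, "cv-folds"),
    )
    return RunResult(run_index, seed, mps, auroc)


def run_stability(
    counts: CountMatrix, config: PipelineConfig
) -> tuple[RunResult, list[RunResult]]:
    """Repeat discovery ``config.n_stability_runs`` times; select the median.

    ``counts`` is restricted to malignant cells and filtered to genes
    expressed in at least ``min_gene_cell_frac`` of the pooled cells before
    any run. Per-run seeds derive from the master seed and run index only,
    so results do not depend on execution order.
    """
    malignant = counts.malignant_cells()
    filtered = filter_genes(malignant, config.min_gene_cell_frac)
    runs = [
        single_run(filtered, config, i) for i in range(config.n_stability_runs)
    ]
    failed = sum(1 for r in runs if r.auroc is None)
    if failed:
        logger.warning("%d of %d runs produced no metaprograms", failed, len(runs))
    selected = select_median_run(runs)
    return selected, runs
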