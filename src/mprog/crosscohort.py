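"""Cross-cohort metaprogram correlation calling.

Two metaprogram catalogues (e.g. mouse programs mapped through homologs,
and programs discovered in human tumors) are scored on the same cells.
For every program pair, the Spearman correlation of their activities is
computed within each tumor; a pair is called *shared* within a cohort when
the set of tumor-wise correlations is significantly above a floor (0.2)
by a one-sided Wilcoxon signed-rank test. Pairs are then counted across
cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr, wilcoxon

from .scoring import ActivityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PairCorrelationResult",
    "tumorwise_mp_correlation",
    "wilcoxon_above",
    "call_shared_pairs",
    "shared_pair_network",
]

EXACT_WILCOXON_MAX_N = 25


@dataclass
class PairCorrelationResult:
    """Per-cohort correlation evidence for one metaprogram pair."""

    mp_a: str
    mp_b: str
    cohort: str
    tumorwise_rhos: list[float] = field(default_factory=list)
    median_rho: float = float("nan")
    p_value: float = float("nan")
    significant: bool = False


def tumorwise_mp_correlation(
    activities_a: ActivityMatrix,
    activities_b: ActivityMatrix,
    sample_ids: np.ndarray,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Spearman rho per (pair of programs, tumor).

    Both catalogues must be scored on the same cells. Tumors with fewer
    than ``min_cells`` cells are skipped with a warning (rank correlations
    are unstable at small n); a rho is NaN when either score vector is
    constant within the tumor. Returns a long DataFrame with columns
    (mp_a, mp_b, sample_id, rho).
    """
    if list(activities_a.scores.index) != list(activities_b.scores.index):
        raise ValueError("the two catalogues are not scored on the same cells")
    sample_ids = np.asarray(sample_ids, dtype=object)
    rows = []
    usable = 0
    for tumor in pd.unique(sample_ids):
        mask = sample_ids == tumor
        if mask.sum() < min_cells:
            logger.warning(
                "tumor %s has %d cells (< %d); skipped", tumor, mask.sum(), min_cells
            )
            continue
        usable += 1
        a = activities_a.scores.values[mask]
        b = activities_b.scores.values[mask]
        for i, mp_a in enumerate(activities_a.program_names):
            for j, mp_b in enumerate(activities_b.program_names):
                if np.all(a[:, i] == a[0, i]) or np.all(b[:, j] == b[0, j]):
                    rho = float("nan")
                else:
                    rho = float(spearmanr(a[:, i], b[:, j]).statistic)
                rows.append((mp_a, mp_b, tumor, rho))
    if usable == 0:
        raise ValueError(f"no tumor has at least {min_cells} cells")
    return pd.DataFrame(rows, columns=["mp_a", "mp_b", "sample_id", "rho"])


def wilcoxon_above(rhos: list[float] | np.ndarray, floor: float = 0.2) -> float:
    """One-sided Wilcoxon signed-rank p-value that rhos exceed ``floor``.

    Exact null distribution for n ≤ 25, normal approximation with
    continuity correction above; differences exactly at the floor are
    dropped (standard convention). Requires ≥ 3 non-NaN values.
    """
    rhos = np.asarray(rhos, dtype=float)
    rhos = rhos[~np.isnan(rhos)]
    if rhos.size < 3:
        raise ValueError(f"need at least 3 correlations, got {rhos.size}")
    diff = rhos - floor
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        return 1.0
    method = "exact" if nonzero.size <= EXACT_WILCOXON_MAX_N else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = wilcoxon(
            nonzero,
            alternative="greater",
            method=method,
            correction=(method == "approx"),
        )
    return float(res.pvalue)


def call_shared_pairs(
    tumorwise: pd.DataFrame,
    cohort: str,
    floor: float = 0.2,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[PairCorrelationResult]:
    """Turn tumor-wise rhos into per-pair significance calls for one cohort.

    A pair is significant when the Wilcoxon test puts the tumor-wise rhos
    above the floor at level ``alpha`` *and* the median rho itself exceeds
    the floor (one-sided direction). ``bh_correct`` applies a
    Benjamini–Hochberg adjustment across the cohort's pairs before the
    alpha comparison (off by default, matching the uncorrected procedure).
    """
    results = []
    for (mp_a, mp_b), grp in tumorwise.groupby(["mp_a", "mp_b"], sort=True):
        rhos = grp["rho"].to_numpy(dtype=float)
        valid = rhos[~np.isnan(rhos)]
        if valid.size < rhos.size:
            logger.warning(
                "pair (%s, %s): %d NaN rho(s) dropped", mp_a, mp_b, rhos.size - valid.size
            )
        median = float(np.median(valid)) if valid.size else float("nan")
        try:
            p = wilcoxon_above(valid, floor)
        except ValueError:
            p = float("nan")
        results.append(
            PairCorrelationResult(
                mp_a=str(mp_a),
                mp_b=str(mp_b),
                cohort=cohort,
                tumorwise_rhos=[float(r) for r in valid],
                median_rho=median,
                p_value=float(p),
                significant=False,
            )
        )
    pvals = np.array([r.p_value for r in results])
    effective = pvals.copy()
    if bh_correct and np.isfinite(pvals).any():
        from statsmodels.stats.multitest import multipletests

        finite = np.isfinite(pvals)
        effective[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
    for r, p_eff in zip(results, effective):
        r.significant = bool(
            np.isfinite(p_eff) and p_eff < alpha and r.median_rho > floor
        )
    return results


def shared_pair_network(
    results: list[PairCorrelationResult],
) -> pd.DataFrame:
    """Count, per pair, the cohorts where it is significant; keep count ≥ 1.

    Returns an edge list (mp_a, mp_b, n_significant_cohorts).
    """
    counts: dict[tuple[str, str], int] = {}
    for r in results:
        key = (r.mp_a, r.mp_b)
        counts.setdefault(key, 0)
        if r.significant:
            counts[key] += 1
    rows = [
        (a, b, n) for (a, b), n in sorted(counts.items()) if n >= 1
    ]
    return pd.DataFrame(rows, columns=["mp_a", "mp_b", "n_significant_cohorts"])
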