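"""Pseudobulk signature scoring and survival association.

Per-sample expression is obtained by summing single-cell counts, CPM
normalizing and taking log2(CPM + 0.001). A signature score is the mean,
over signature genes, of each gene's z-score across samples. Samples are
split at the median score into High (≥ median) and Low (< median) groups
and compared by the log-rank (Mantel–Cox) test on progression-free
survival.

The log-rank statistic is computed directly from the grouped
hypergeometric formulation (observed − expected events in the High group,
variance summed over event times), which also yields the *direction* of
the association — whether the High group fares worse.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import spearmanr

from .datamodel import CountMatrix, GeneSetCollection

__all__ = [
    "pseudobulk",
    "signature_score",
    "signature_scores",
    "signature_correlation",
    "logrank_test",
    "median_split_logrank",
    "km_summary",
]

CPM_PSEUDOCOUNT = 0.001


def pseudobulk(counts: CountMatrix) -> pd.DataFrame:
    """Per-sample summed counts, normalized as log2(CPM + 0.001).

    Returns genes × samples. A sample with zero total counts is an error.
    """
    samples = pd.unique(counts.sample_id)
    mat = np.zeros((counts.n_genes, len(samples)))
    for j, s in enumerate(samples):
        mask = counts.sample_id == s
        mat[:, j] = np.asarray(counts.values[:, np.flatnonzero(mask)].sum(axis=1)).ravel()
    totals = mat.sum(axis=0)
    if np.any(totals == 0):
        bad = [str(samples[i]) for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"samples with zero total counts: {bad}")
    cpm = mat / totals[None, :] * 1e6
    return pd.DataFrame(
        np.log2(cpm + CPM_PSEUDOCOUNT), index=counts.gene_ids, columns=[str(s) for s in samples]
    )


def signature_score(pb: pd.DataFrame, signature: list[str], name: str = "signature") -> pd.Series:
    """Mean z-score of signature genes per sample.

    Each gene is z-scored across samples (sample sd); genes absent from
    the matrix are omitted. Genes constant across samples contribute 0.
    """
    if pb.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    present = [g for g in signature if g in pb.index]
    if not present:
        raise ValueError(f"signature {name!r} has no genes in the pseudobulk matrix")
    x = pb.loc[present]
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1).replace(0.0, np.inf)
    z = x.sub(mean, axis=0).div(sd, axis=0)
    out = z.mean(axis=0)
    out.name = name
    return out


def signature_scores(pb: pd.DataFrame, signatures: GeneSetCollection) -> pd.DataFrame:
    """Score every signature; samples × signatures."""
    return pd.DataFrame(
        {name: signature_score(pb, genes, name) for name, genes in signatures}
    )


EXACT_SPEARMAN_MAX_N = 9


def _exact_spearman_p(a: np.ndarray, b: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p of Spearman rho by full enumeration."""
    from itertools import permutations

    from scipy.stats import rankdata

    ra = rankdata(a)
    rb = rankdata(b)
    ra = (ra - ra.mean()) / ra.std()
    count = total = 0
    for perm in permutations(rb):
        r = float(np.dot(ra, (np.asarray(perm) - rb.mean()) / rb.std())) / len(ra)
        total += 1
        if abs(r) >= abs(rho_obs) - 1e-12:
            count += 1
    return count / total


def signature_correlation(
    scores_a: pd.Series, scores_b: pd.Series
) -> tuple[float, float]:
    """Spearman rho and two-sided p between two per-sample score vectors.

    The p-value is exact (full permutation enumeration) for n ≤ 9, the
    usual t approximation above. Constant vectors give NaN.
    """
    a, b = scores_a.align(scores_b, join="inner")
    if len(a) < 4:
        raise ValueError("need at least 4 paired samples")
    if np.all(a.values == a.values[0]) or np.all(b.values == b.values[0]):
        return float("nan"), float("nan")
    res = spearmanr(a.values, b.values)
    rho = float(res.statistic)
    if len(a) <= EXACT_SPEARMAN_MAX_N:
        return rho, float(_exact_spearman_p(a.values, b.values, rho))
    return rho, float(res.pvalue)


def logrank_test(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[float, float, float]:
    """Two-group log-rank (Mantel–Cox) test.

    Grouped hypergeometric formulation with standard tie handling: at each
    distinct event time, observed minus expected events in group 1 and the
    hypergeometric variance are accumulated. Returns (chi2, p,
    observed_minus_expected_in_group1); a positive last component means
    group 1 experiences more events than expected, i.e. fares worse.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group, dtype=int)
    if set(np.unique(group)) - {0, 1}:
        raise ValueError("group must be coded 0/1")
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = (event & (time == t)).sum()
        d1 = (event & (time == t) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0, float(o_minus_e)
    chi2 = o_minus_e**2 / var
    p = float(chi2_dist.sf(chi2, df=1))
    return float(chi2), p, float(o_minus_e)


def median_split_logrank(
    scores: pd.Series, survival: pd.DataFrame
) -> tuple[pd.Series, float, float, bool]:
    """Median-split survival comparison of a signature.

    Samples with score ≥ median form the High group, the rest Low; the
    groups' progression-free survival is compared by the log-rank test.
    Returns (group labels, chi2, p, high_worse) where ``high_worse`` is
    True when the High group has more events than expected.
    """
    surv = survival.set_index("sample_id")
    missing = [s for s in scores.index if s not in surv.index]
    if missing:
        raise ValueError(f"samples without survival records: {missing}")
    med = float(scores.median())
    groups = pd.Series(
        np.where(scores.values >= med, "High", "Low"), index=scores.index
    )
    n_high = int((groups == "High").sum())
    n_low = int((groups == "Low").sum())
    if n_high < 2 or n_low < 2:
        raise ValueError(
            f"degenerate median split: {n_high} High / {n_low} Low samples"
        )
    surv = surv.loc[scores.index]
    chi2, p, ome = logrank_test(
        surv["time"].to_numpy(),
        surv["event"].to_numpy(dtype=bool),
        (groups == "High").to_numpy(dtype=int),
    )
    return groups, chi2, p, ome > 0


def km_summary(
    survival: pd.DataFrame, groups: pd.Series
) -> pd.DataFrame:
    """Kaplan–Meier per-group summary (n, events, median survival)."""
    from lifelines import KaplanMeierFitter

    surv = survival.set_index("sample_id").loc[groups.index]
    rows = []
    for g in sorted(groups.unique()):
        mask = (groups == g).values
        km = KaplanMeierFitter().fit(
            surv["time"].values[mask], surv["event"].values[mask]
        )
        rows.append(
            {
                "group": g,
                "n": int(mask.sum()),
                "events": int(surv["event"].values[mask].sum()),
                "median_survival": float(km.median_survival_time_),
            }
        )
    return pd.DataFrame(rows)
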