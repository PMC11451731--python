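"""Cluster factors across cohorts into metaprograms.

Retained factors from every cohort are scored on the pooled cells; the
factor × factor Pearson correlation of those activities drives average-
linkage hierarchical clustering with distance 1 − r, with the number of
clusters chosen to maximize the mean silhouette. Each cluster becomes a
metaprogram whose consensus gene list keeps genes present in at least a
fraction of its member factors; metaprograms that are rarely active are
dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .scoring import ActivityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Metaprogram",
    "factor_activity_correlation",
    "cluster_factors",
    "consensus_genes",
    "drop_inactive",
    "assemble_metaprograms",
]


@dataclass
class Metaprogram:
    """A cluster of factors with a consensus gene list."""

    id: str
    member_factors: list[tuple[str, int]]  # (cohort, factor index)
    genes: list[str]
    active_frac: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"metaprogram {self.id} has an empty gene list")
        for c, f in self.active_frac.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"active_frac[{c!r}]={f} outside [0,1]")


def factor_activity_correlation(activities: ActivityMatrix) -> pd.DataFrame:
    """Pearson correlation between all factor activity columns.

    Computed on pooled cells from all cohorts. A constant-score factor has
    undefined correlation; it is set to 0 against every other factor (and
    1 on the diagonal) with a log flag.
    """
    x = activities.scores.values
    constant = np.all(x == x[0:1, :], axis=0)
    if constant.any():
        logger.warning(
            "%d factor(s) have constant activity; correlations set to 0",
            int(constant.sum()),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corr = np.corrcoef(x, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    names = activities.program_names
    return pd.DataFrame(corr, index=names, columns=names)


def cluster_factors(
    corr: pd.DataFrame, k_candidates: list[int] | range | None = None
) -> tuple[pd.Series, int, dict[int, float]]:
    """Average-linkage clustering of factors on distance 1 − correlation.

    The cluster count is the ``k_candidates`` value maximizing the mean
    silhouette on the same distance (ties to the smaller k). Returns
    (labels for chosen k, chosen k, per-k silhouettes).
    """
    n = corr.shape[0]
    if n < 3:
        raise ValueError("need at least 3 factors to cluster")
    if k_candidates is None:
        k_candidates = range(2, min(15, n - 1) + 1)
    k_candidates = sorted(set(int(k) for k in k_candidates))
    if any(k < 2 or k > n - 1 for k in k_candidates):
        raise ValueError(f"k_candidates must lie in [2, {n - 1}]")

    dist = 1.0 - corr.values
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    if np.allclose(dist[np.triu_indices(n, 1)], dist[0, 1]):
        raise ValueError(
            "all pairwise correlations are equal; silhouette undefined — "
            "choose k manually"
        )
    Z = linkage(squareform(dist, checks=False), method="average")

    silhouettes: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_candidates:
        labels = fcluster(Z, t=k, criterion="maxclust")
        labels_by_k[k] = labels
        if len(np.unique(labels)) < 2:
            silhouettes[k] = float("nan")
            continue
        silhouettes[k] = float(silhouette_score(dist, labels, metric="precomputed"))
    finite = {k: s for k, s in silhouettes.items() if np.isfinite(s)}
    if not finite:
        raise ValueError("silhouette undefined for every candidate k")
    best = max(finite.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    return pd.Series(labels_by_k[best], index=corr.index), int(best), silhouettes


def consensus_genes(member_gene_lists: list[list[str]], min_frac: float) -> list[str]:
    """Genes present in at least ceil(min_frac × n_members) member lists,
    ordered by (occurrence count descending, gene id ascending)."""
    if not member_gene_lists:
        raise ValueError("metaprogram needs at least one member factor")
    need = int(np.ceil(min_frac * len(member_gene_lists)))
    counts: dict[str, int] = {}
    for genes in member_gene_lists:
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    kept = [g for g, c in counts.items() if c >= need]
    return sorted(kept, key=lambda g: (-counts[g], g))


def drop_inactive(
    mps: list[Metaprogram],
    activities: ActivityMatrix,
    cohorts: np.ndarray,
    min_active_frac: float,
    mode: str = "all",
) -> list[Metaprogram]:
    """Drop rarely-active metaprograms and relabel survivors MP1..MPm.

    With ``mode="all"`` (default) an MP is discarded only when its active
    fraction is below the threshold in *every* cohort, so model-enriched
    programs survive; ``mode="any"`` discards as soon as one cohort is
    below. Survivors are renumbered by descending total active fraction.
    """
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    frac = activities.active_fraction(groups=cohorts)  # cohorts × programs
    survivors = []
    for mp in mps:
        per_cohort = frac[mp.id]
        mp.active_frac = {str(c): float(v) for c, v in per_cohort.items()}
        below = per_cohort < min_active_frac
        dropped = bool(below.all()) if mode == "all" else bool(below.any())
        if dropped:
            logger.warning(
                "metaprogram %s inactive (fractions %s); dropped",
                mp.id,
                mp.active_frac,
            )
        else:
            survivors.append(mp)
    order = sorted(
        survivors, key=lambda m: (-sum(m.active_frac.values()), m.id)
    )
    relabeled = []
    for i, mp in enumerate(order, start=1):
        relabeled.append(
            Metaprogram(
                id=f"MP{i}",
                member_factors=mp.member_factors,
                genes=mp.genes,
                active_frac=mp.active_frac,
            )
        )
    return relabeled


def assemble_metaprograms(
    factor_sets: list,
    factor_activities: ActivityMatrix,
    consensus_frac: float = 0.25,
    k_candidates: list[int] | None = None,
) -> list[Metaprogram]:
    """Cluster retained factors (named ``<cohort>.F<j>``) into metaprograms.

    ``factor_activities`` must hold pooled-cell activities of exactly the
    retained factors of ``factor_sets``. Metaprograms whose consensus list
    is empty are dropped with a warning. Activity-based filtering and
    relabeling happen later in :func:`drop_inactive`.
    """
    gene_lists: dict[str, list[str]] = {}
    members: dict[str, tuple[str, int]] = {}
    for fs in factor_sets:
        for j in fs.retained_indices():
            name = f"{fs.cohort}.F{j}"
            gene_lists[name] = fs.prioritized_genes[j]
            members[name] = (fs.cohort, j)
    names = factor_activities.program_names
    missing = set(names) - set(gene_lists)
    if missing:
        raise ValueError(f"activities include unknown factors: {sorted(missing)}")

    corr = factor_activity_correlation(factor_activities)
    labels, chosen_k, _ = cluster_factors(corr, k_candidates)
    mps: list[Metaprogram] = []
    for c in sorted(labels.unique()):
        factor_names = [n for n in names if labels[n] == c]
        genes = consensus_genes([gene_lists[n] for n in factor_names], consensus_frac)
        if not genes:
            logger.warning("cluster %s has empty consensus; dropped", c)
            continue
        mps.append(
            Metaprogram(
                id=f"cluster{c}",
                member_factors=[members[n] for n in factor_names],
                genes=genes,
            )
        )
    return mps
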