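"""Per-cohort gene filtering, NMF and factor gene prioritization.

The expression matrix is log1p(counts-per-10k) per cell — nonnegative by
construction, the conventional scale for NMF program discovery on
scRNA-seq. A factor's genes are prioritized in two steps: loading z-score
across factors (> z threshold), then the largest connected component of
the Spearman co-expression graph among those candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata
from sklearn.decomposition import NMF

from .datamodel import CountMatrix, GeneSetCollection

__all__ = [
    "FactorSet",
    "filter_genes",
    "normalize_log1p_cp10k",
    "run_nmf",
    "elbow_rank_scan",
    "prioritize_factor_genes",
    "zscore_loadings",
    "factors_to_gmt",
]


@dataclass
class FactorSet:
    """One cohort's NMF decomposition plus per-factor prioritized genes.

    ``loadings`` is genes × factors (W), ``cell_weights`` factors × cells
    (H); ``prioritized_genes[j]`` is factor j's gene list (empty until
    :func:`prioritize_factor_genes` runs) and ``retained[j]`` marks factors
    that kept at least ``min_prioritized_genes`` genes.
    """

    cohort: str
    loadings: np.ndarray
    cell_weights: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    seed: int
    reconstruction_err: float
    prioritized_genes: list[list[str]] | None = None
    retained: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.loadings < 0) or np.any(self.cell_weights < 0):
            raise ValueError("NMF loadings/weights must be nonnegative")
        if self.loadings.shape[1] != self.cell_weights.shape[0]:
            raise ValueError("loadings and cell_weights disagree on factor count")

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def retained_indices(self) -> list[int]:
        if self.retained is None:
            raise ValueError("prioritize_factor_genes has not run")
        return [int(i) for i in np.flatnonzero(self.retained)]


def filter_genes(counts: CountMatrix, min_frac: float) -> CountMatrix:
    """Keep genes with nonzero counts in at least ceil(min_frac × n_cells)
    of the pooled cells ("at least 1%" semantics: >= the ceiling)."""
    n = counts.n_cells
    need = int(np.ceil(min_frac * n))
    nnz = np.asarray((counts.values > 0).sum(axis=1)).ravel()
    keep = nnz >= need
    if not keep.any():
        raise ValueError(f"no genes pass the {min_frac:.2%} expression filter")
    return counts.subset_genes(keep)


def normalize_log1p_cp10k(counts: CountMatrix) -> sp.csr_matrix:
    """log1p of counts-per-10k per cell, genes × cells, sparse."""
    totals = np.asarray(counts.values.sum(axis=0)).ravel().astype(float)
    if np.any(totals == 0):
        raise ValueError("cells with zero total counts cannot be normalized")
    x = counts.values.astype(float).multiply(1e4 / totals[None, :]).tocsr()
    x.data = np.log1p(x.data)
    return x


def _fit_nmf(
    x: np.ndarray, n_factors: int, seed: int, init=None
) -> tuple[np.ndarray, np.ndarray, float]:
    kwargs = dict(
        n_components=n_factors,
        solver="mu",
        beta_loss="frobenius",
        tol=1e-5,
        max_iter=500,
        random_state=seed,
    )
    if init is None:
        model = NMF(init="random", **kwargs)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # max_iter reached is acceptable
            w = model.fit_transform(x)
    else:
        model = NMF(init="custom", **kwargs)
        w0, h0 = init
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = model.fit_transform(x, W=np.ascontiguousarray(w0), H=np.ascontiguousarray(h0))
    return w, model.components_, float(model.reconstruction_err_)


def run_nmf(counts: CountMatrix, cohort: str, n_factors: int, seed: int) -> FactorSet:
    """Rank-``n_factors`` NMF of one cohort's normalized expression.

    Multiplicative-update minimization of Frobenius error, no
    regularization, random nonnegative init from ``seed``; converges when
    the relative error change drops below 1e-5 or after 500 iterations.
    """
    mask = counts.cohort == cohort
    if not mask.any():
        raise ValueError(f"no cells with cohort {cohort!r}")
    sub = counts.subset_cells(mask)
    if n_factors > min(sub.n_genes, sub.n_cells):
        raise ValueError(
            f"n_factors={n_factors} exceeds matrix dimensions {sub.n_genes}×{sub.n_cells}"
        )
    if sub.n_cells < n_factors:
        raise ValueError("fewer cells than factors")
    x = np.asarray(normalize_log1p_cp10k(sub).todense())
    w, h, err = _fit_nmf(x, n_factors, seed)
    return FactorSet(
        cohort=cohort,
        loadings=w,
        cell_weights=h,
        gene_ids=sub.gene_ids,
        cell_ids=sub.cell_ids,
        seed=seed,
        reconstruction_err=err,
    )


def elbow_rank_scan(
    counts: CountMatrix, ranks: list[int], seed: int = 0
) -> dict[int, float]:
    """Reconstruction error per rank, for caller-side elbow inspection.

    Ranks must be sorted ascending. Each rank warm-starts from the previous
    solution padded with a tiny random component, so the error sequence is
    non-increasing; no automatic elbow selection is done.
    """
    if list(ranks) != sorted(ranks):
        raise ValueError("ranks must be sorted ascending")
    x = np.asarray(normalize_log1p_cp10k(counts).todense())
    rng = np.random.default_rng(seed)
    errors: dict[int, float] = {}
    prev = None
    for r in ranks:
        if r > min(x.shape):
            raise ValueError(f"rank {r} exceeds matrix dimensions {x.shape}")
        if prev is None:
            w, h, err = _fit_nmf(x, r, seed)
        else:
            w0, h0, r0 = prev
            pad = r - r0
            eps = 1e-8 * max(x.mean(), 1e-12)
            w_init = np.hstack([w0, eps * rng.random((x.shape[0], pad))])
            h_init = np.vstack([h0, eps * rng.random((pad, x.shape[1]))])
            w, h, err = _fit_nmf(x, r, seed, init=(w_init, h_init))
        errors[r] = err
        prev = (w, h, r)
    return errors


def zscore_loadings(loadings: np.ndarray) -> np.ndarray:
    """Per gene, z-score its loadings across the factor axis (sample sd).

    Genes with constant loadings get all-zero z.
    """
    mean = loadings.mean(axis=1, keepdims=True)
    sd = loadings.std(axis=1, ddof=1, keepdims=True)
    z = np.zeros_like(loadings, dtype=float)
    ok = (sd > 0).ravel()
    z[ok] = (loadings[ok] - mean[ok]) / sd[ok]
    return z


def _largest_component(
    adj: np.ndarray, loading: np.ndarray, genes: list[str]
) -> list[int]:
    """Vertices of the largest connected component of ``adj``.

    Size ties break by summed loading (descending), then by lexicographic
    gene order of the sorted member list.
    """
    n_comp, labels = connected_components(sp.csr_matrix(adj), directed=False)
    best, best_size, best_load, best_genes = [], -1, -np.inf, None
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        size = len(members)
        load = float(loading[members].sum())
        names = tuple(sorted(genes[m] for m in members))
        wins = (
            size > best_size
            or (size == best_size and load > best_load)
            or (size == best_size and load == best_load and names < best_genes)
        )
        if wins:
            best, best_size, best_load, best_genes = list(members), size, load, names
    return best


def prioritize_factor_genes(
    factors: FactorSet,
    expr: CountMatrix,
    z_thr: float = 1.5,
    corr_thr: float = 0.4,
    min_genes: int = 10,
) -> FactorSet:
    """Attach prioritized gene lists to a FactorSet.

    Candidates for a factor are genes whose loading z-score (across
    factors) exceeds ``z_thr``. Among candidates, a co-expression graph
    connects pairs whose Spearman correlation across the cohort's cells
    exceeds ``corr_thr``; the prioritized list is the largest connected
    component, ordered by loading (descending, gene id as tie-break).
    Factors keeping fewer than ``min_genes`` genes are marked not retained.
    """
    if expr.gene_ids != factors.gene_ids:
        raise ValueError("expression matrix and FactorSet disagree on genes")
    mask = expr.cohort == factors.cohort
    sub = expr.subset_cells(mask)
    x = np.asarray(normalize_log1p_cp10k(sub).todense())  # genes × cells
    ranks = rankdata(x, axis=1)  # Spearman = Pearson of ranks

    z = zscore_loadings(factors.loadings)
    genes = factors.gene_ids
    prioritized: list[list[str]] = []
    retained = np.zeros(factors.n_factors, dtype=bool)
    for j in range(factors.n_factors):
        cand = np.flatnonzero(z[:, j] > z_thr)
        if len(cand) < 2:
            prioritized.append([])
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant rows yield NaN rho
            rho = np.corrcoef(ranks[cand])
        rho = np.nan_to_num(rho, nan=0.0)
        adj = (rho > corr_thr).astype(np.int8)
        np.fill_diagonal(adj, 0)
        cand_genes = [genes[i] for i in cand]
        members = _largest_component(adj, factors.loadings[cand, j], cand_genes)
        order = sorted(
            members, key=lambda m: (-factors.loadings[cand[m], j], cand_genes[m])
        )
        chosen = [cand_genes[m] for m in order]
        prioritized.append(chosen)
        retained[j] = len(chosen) >= min_genes
    factors.prioritized_genes = prioritized
    factors.retained = retained
    return factors


def factors_to_gmt(factors: FactorSet) -> GeneSetCollection:
    """Retained factors as gene sets named ``<cohort>.F<index>``."""
    if factors.prioritized_genes is None or factors.retained is None:
        raise ValueError("prioritize_factor_genes has not run")
    sets = {
        f"{factors.cohort}.F{j}": factors.prioritized_genes[j]
        for j in factors.retained_indices()
    }
    return GeneSetCollection(sets)
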