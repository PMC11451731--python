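"""Rank-based AUC gene-set activity scoring (AUCell-style).

A cell's activity for a gene set is the normalized area under the recovery
curve of set members within the top-ranked genes of that cell: rank all
genes by decreasing expression, walk the top ``ceil(top_frac × G)`` ranks
accumulating set members, integrate the step curve and divide by its
maximum possible value. Scores live in [0, 1] and depend only on ranks, so
any per-cell monotone normalization of expression leaves them unchanged.

A per-program activity threshold ("global k=1") is the mean + 1 sd of a
normal fit to the program's scores over all cells; a cell is *active* when
its score strictly exceeds the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._seeds import derive_seed
from .datamodel import CountMatrix, GeneSetCollection

__all__ = ["ActivityMatrix", "rank_auc", "score_programs", "global_k1_threshold"]

MIN_CELLS_FOR_THRESHOLD = 20


@dataclass
class ActivityMatrix:
    """Cells × programs rank-AUC scores with per-program thresholds."""

    scores: pd.DataFrame
    thresholds: pd.Series
    top_frac: float

    def __post_init__(self) -> None:
        vals = self.scores.values
        if vals.size and (np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1 + 1e-12):
            raise ValueError("activity scores must lie in [0, 1]")
        if list(self.thresholds.index) != list(self.scores.columns):
            raise ValueError("thresholds index must match score columns")

    @property
    def active(self) -> pd.DataFrame:
        """Binary activity: score strictly above the program threshold."""
        return self.scores.gt(self.thresholds, axis=1)

    @property
    def program_names(self) -> list[str]:
        return list(self.scores.columns)

    def active_fraction(self, groups: np.ndarray | None = None) -> pd.DataFrame:
        """Fraction of active cells per program, overall or per group."""
        act = self.active
        if groups is None:
            return act.mean().to_frame("all").T
        return act.groupby(np.asarray(groups, dtype=object)).mean()


def _auc_from_positions(positions: np.ndarray, n_set: int, cutoff: int) -> float:
    """Normalized recovery-curve area given 1-based member rank positions.

    The cumulative-hits step curve summed over ranks 1..cutoff equals
    sum over members of max(0, cutoff − pos + 1); the maximum is attained
    when members occupy the top ranks.
    """
    contrib = cutoff - positions + 1
    auc = float(contrib[contrib > 0].sum())
    top = np.arange(1, min(n_set, cutoff) + 1)
    max_auc = float((cutoff - top + 1).sum())
    return auc / max_auc


def rank_auc(
    expr_cell: np.ndarray,
    gene_ids: list[str],
    gene_set: list[str],
    top_frac: float = 0.05,
    tie_key: np.ndarray | None = None,
) -> float:
    """Rank-AUC activity of one gene set in one cell.

    ``tie_key`` breaks expression ties (smaller key ranks first); by
    default a fixed pseudorandom key is derived from gene identity so the
    result does not depend on gene order in the input.
    """
    expr_cell = np.asarray(expr_cell, dtype=float)
    G = expr_cell.size
    if tie_key is None:
        tie_key = _gene_keys(gene_ids, seed=0)
    cutoff = int(np.ceil(top_frac * G))
    index = {g: i for i, g in enumerate(gene_ids)}
    members = np.array([index[g] for g in gene_set if g in index], dtype=int)
    if members.size == 0:
        warnings.warn("gene set has no genes in the expression universe; score 0")
        return 0.0
    order = np.lexsort((tie_key, -expr_cell))
    pos = np.empty(G, dtype=int)
    pos[order] = np.arange(1, G + 1)
    return _auc_from_positions(pos[members], members.size, cutoff)


def _gene_keys(gene_ids: list[str], seed: int) -> np.ndarray:
    """Deterministic pseudorandom tie-break key per gene identity."""
    return np.array(
        [derive_seed(seed, f"aucell-gene:{g}") for g in gene_ids], dtype=np.int64
    )


def _cell_keys(cell_ids: list[str], seed: int) -> np.ndarray:
    return np.array(
        [derive_seed(seed, f"aucell-cell:{c}") for c in cell_ids], dtype=np.int64
    )


def score_programs(
    expr: CountMatrix,
    programs: GeneSetCollection,
    top_frac: float = 0.05,
    seed: int = 0,
    with_thresholds: bool = True,
) -> ActivityMatrix:
    """Rank-AUC scores of every program in every cell.

    Ranks are computed on raw counts — identical to ranks of any per-cell
    monotone normalization. Ties are broken by a pseudorandom key combining
    gene and cell identity (seeded), so scores are invariant to gene order
    and reproducible. Thresholds are fitted when at least
    ``MIN_CELLS_FOR_THRESHOLD`` cells are present, else left at +inf (no
    active calls) with a warning.
    """
    G, n = expr.n_genes, expr.n_cells
    cutoff = int(np.ceil(top_frac * G))
    x = np.asarray(expr.values.todense(), dtype=float)  # genes × cells
    gkeys = _gene_keys(expr.gene_ids, seed)
    ckeys = _cell_keys(expr.cell_ids, seed)

    index = {g: i for i, g in enumerate(expr.gene_ids)}
    member_idx = {}
    for name, genes in programs:
        idx = np.array([index[g] for g in genes if g in index], dtype=int)
        if idx.size == 0:
            warnings.warn(f"program {name!r} has no genes in the universe; scores 0")
        member_idx[name] = idx

    scores = np.zeros((n, len(programs.sets)))
    names = programs.names
    for c in range(n):
        # per-cell tie key mixes gene and cell identity: deterministic,
        # order-invariant, and different across cells
        key = (gkeys + ckeys[c]) & 0x7FFFFFFF
        order = np.lexsort((key, -x[:, c]))
        pos = np.empty(G, dtype=int)
        pos[order] = np.arange(1, G + 1)
        for p, name in enumerate(names):
            idx = member_idx[name]
            if idx.size:
                scores[c, p] = _auc_from_positions(pos[idx], idx.size, cutoff)
    df = pd.DataFrame(scores, index=expr.cell_ids, columns=names)

    if with_thresholds and n >= MIN_CELLS_FOR_THRESHOLD:
        thr = pd.Series(
            {name: global_k1_threshold(df[name].values) for name in names}
        )
    else:
        if with_thresholds:
            warnings.warn(
                f"fewer than {MIN_CELLS_FOR_THRESHOLD} cells; activity thresholds "
                "not fitted"
            )
        thr = pd.Series(np.inf, index=names)
    return ActivityMatrix(scores=df, thresholds=thr, top_frac=top_frac)


def global_k1_threshold(scores_one_program: np.ndarray) -> float:
    """Global activity cutoff: mean + 1·sd of a normal fit to all scores.

    With zero variance the threshold equals the mean, so no cell is
    strictly above it and none is called active.
    """
    scores = np.asarray(scores_one_program, dtype=float)
    if scores.size < MIN_CELLS_FOR_THRESHOLD:
        raise ValueError(
            f"need at least {MIN_CELLS_FOR_THRESHOLD} cells to fit a threshold"
        )
    mu, sd = norm.fit(scores)
    return float(mu + sd)
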