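"""Pipeline configuration.

All tuning constants of the discovery pipeline live in one frozen dataclass
so that a run is fully described by (input matrix, config, master seed).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Tuning constants for metaprogram discovery and validation.

    Defaults follow the published procedure: genes kept if expressed in at
    least 1% of pooled malignant cells, 30 NMF factors per cohort, loading
    z-score cutoff 1.5, co-expression edge threshold 0.4 (Spearman), at
    least 10 prioritized genes per retained factor, consensus membership in
    at least 25% of a metaprogram's factors, metaprograms active in at
    least 10% of cells, 100 stability repeats scored by five-fold CV
    logistic-regression auROC, k=30 Mahalanobis kNN with Louvain at
    resolution 0.4 (100 consensus runs), and a 0.2 correlation floor for
    cross-cohort sharing calls at alpha 0.05.
    """

    min_gene_cell_frac: float = 0.01
    n_factors: int = 30
    loading_z_threshold: float = 1.5
    coexpr_corr_threshold: float = 0.4
    min_prioritized_genes: int = 10
    auc_top_frac: float = 0.05
    consensus_gene_frac: float = 0.25
    min_active_cell_frac: float = 0.10
    n_stability_runs: int = 100
    cv_folds: int = 5
    knn_k: int = 30
    louvain_resolution: float = 0.4
    n_louvain_runs: int = 100
    cross_cohort_corr_floor: float = 0.2
    min_cells_per_tumor: int = 20
    alpha: float = 0.05
    master_seed: int = 0
    # "active in less than 10% of cells from each model" is read as
    # discard-only-if-inactive-everywhere; "any" gives the stricter reading.
    drop_inactive_mode: str = "all"

    _FRACTIONS = (
        "min_gene_cell_frac",
        "auc_top_frac",
        "consensus_gene_frac",
        "min_active_cell_frac",
        "alpha",
    )
    _COUNTS = (
        "n_factors",
        "min_prioritized_genes",
        "n_stability_runs",
        "cv_folds",
        "knn_k",
        "n_louvain_runs",
        "min_cells_per_tumor",
    )

    def __post_init__(self) -> None:
        for name in self._FRACTIONS:
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1); got {v!r}")
        for name in self._COUNTS:
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ValueError(f"{name} must be an integer >= 1; got {v!r}")
        for name in (
            "loading_z_threshold",
            "coexpr_corr_threshold",
            "louvain_resolution",
            "cross_cohort_corr_floor",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.drop_inactive_mode not in ("all", "any"):
            raise ValueError("drop_inactive_mode must be 'all' or 'any'")

    def replace(self, **changes) -> "PipelineConfig":
        return dataclasses.replace(self, **changes)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
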