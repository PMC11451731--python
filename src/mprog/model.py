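"""Model/Results front-end for the discovery pipeline.

``MetaprogramDiscovery`` is built from a count matrix and a config; its
``fit()`` runs the full stability-selected discovery and returns a
``DiscoveryResults`` carrying the selected run's metaprograms, the auROC
distribution over runs, and summary tables. ``CellStateModel`` clusters
cells in metaprogram-activity space the same way.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .config import PipelineConfig
from .datamodel import CountMatrix, GeneSetCollection, write_gmt
from .factorization import filter_genes
from .scoring import ActivityMatrix, score_programs
from .stability import RunResult, run_stability
from .states import CellStateClustering, cluster_cell_states

__all__ = ["MetaprogramDiscovery", "DiscoveryResults", "CellStateModel"]


class MetaprogramDiscovery:
    """Stability-selected NMF metaprogram discovery on two cohorts.

    Parameters
    ----------
    counts
        Gene × cell counts with cohort labels and malignant flags; only
        malignant cells are used.
    config
        Pipeline tuning constants (see :class:`PipelineConfig`).
    """

    def __init__(self, counts: CountMatrix, config: PipelineConfig | None = None):
        self.counts = counts
        self.config = config or PipelineConfig()
        cohorts = sorted(set(counts.cohort[counts.malignant]))
        if len(cohorts) != 2:
            raise ValueError(
                f"discovery expects exactly two cohorts of malignant cells, got {cohorts}"
            )
        self.cohorts = cohorts

    @classmethod
    def from_files(
        cls, mtx_path, genes_path, cells_path, config: PipelineConfig | None = None
    ) -> "MetaprogramDiscovery":
        from .datamodel import read_count_matrix

        return cls(read_count_matrix(mtx_path, genes_path, cells_path), config)

    def fit(self) -> "DiscoveryResults":
        selected, runs = run_stability(self.counts, self.config)
        return DiscoveryResults(self, selected, runs)


class DiscoveryResults:
    """Results of a fitted :class:`MetaprogramDiscovery`."""

    def __init__(
        self,
        model: MetaprogramDiscovery,
        selected: RunResult,
        runs: list[RunResult],
    ):
        self.model = model
        self.selected = selected
        self.runs = runs

    @property
    def metaprograms(self):
        return self.selected.metaprograms

    @property
    def auroc(self) -> float:
        """Cohort-separation auROC of the selected (median) run."""
        return self.selected.auroc

    @property
    def gene_sets(self) -> GeneSetCollection:
        return GeneSetCollection({mp.id: mp.genes for mp in self.metaprograms})

    def runs_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run_index": [r.run_index for r in self.runs],
                "seed": [r.seed for r in self.runs],
                "n_metaprograms": [len(r.metaprograms) for r in self.runs],
                "auroc": [r.auroc for r in self.runs],
                "selected": [r.run_index == self.selected.run_index for r in self.runs],
            }
        )

    def activities(self, counts: CountMatrix | None = None) -> ActivityMatrix:
        """Score the selected metaprograms on (malignant) cells."""
        cm = counts if counts is not None else self.model.counts.malignant_cells()
        cm = filter_genes(cm, self.model.config.min_gene_cell_frac)
        return score_programs(
            cm,
            self.gene_sets,
            top_frac=self.model.config.auc_top_frac,
            seed=derive_seed(self.model.config.master_seed, "results-activities"),
        )

    def summary(self) -> str:
        lines = [
            "Metaprogram discovery (stability-selected NMF)",
            "=" * 52,
            f"cohorts:            {self.model.cohorts[0]} vs {self.model.cohorts[1]}",
            f"stability runs:     {len(self.runs)} "
            f"({sum(1 for r in self.runs if r.auroc is None)} failed)",
            f"selected run:       #{self.selected.run_index} "
            f"(median auROC = {self.auroc:.3f})",
            f"metaprograms:       {len(self.metaprograms)}",
            "",
            f"{'MP':<6}{'genes':>6}{'factors':>9}  active fraction per cohort",
        ]
        for mp in self.metaprograms:
            frac = ", ".join(f"{c}: {f:.2f}" for c, f in sorted(mp.active_frac.items()))
            lines.append(
                f"{mp.id:<6}{len(mp.genes):>6}{len(mp.member_factors):>9}  {frac}"
            )
        return "\n".join(lines)

    def to_gmt(self, path) -> None:
        write_gmt(self.gene_sets, path)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_gmt(out / "metaprograms.gmt")
        self.runs_table().to_csv(out / "stability_runs.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {"metaprogram": mp.id, "cohort": c, "factor": f}
                for mp in self.metaprograms
                for c, f in mp.member_factors
            ]
        ).to_csv(out / "mp_membership.tsv", sep="\t", index=False)


class CellStateModel:
    """Cluster cells by metaprogram activity (Mahalanobis kNN + Louvain)."""

    def __init__(
        self,
        activities: ActivityMatrix,
        config: PipelineConfig | None = None,
    ):
        self.activities = activities
        self.config = config or PipelineConfig()

    def fit(self, compute_embedding: bool = False) -> "CellStateResults":
        clustering = cluster_cell_states(
            self.activities,
            k=self.config.knn_k,
            resolution=self.config.louvain_resolution,
            n_runs=self.config.n_louvain_runs,
            seed=derive_seed(self.config.master_seed, "cell-states"),
            compute_embedding=compute_embedding,
        )
        return CellStateResults(self, clustering)


class CellStateResults:
    def __init__(self, model: CellStateModel, clustering: CellStateClustering):
        self.model = model
        self.clustering = clustering

    @property
    def labels(self) -> pd.Series:
        return self.clustering.labels

    @property
    def silhouette(self) -> float:
        return self.clustering.silhouette

    @property
    def n_clusters(self) -> int:
        return self.clustering.n_clusters

    def summary(self) -> str:
        counts = self.labels.value_counts().sort_index()
        lines = [
            "Cell-state clustering (Mahalanobis kNN + consensus Louvain)",
            "=" * 58,
            f"cells:       {len(self.labels)}",
            f"clusters:    {self.n_clusters}",
            f"silhouette:  {self.silhouette:.3f}"
            if np.isfinite(self.silhouette)
            else "silhouette:  NA (single cluster)",
            "",
            "cluster sizes: " + ", ".join(f"{k}: {v}" for k, v in counts.items()),
        ]
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df = pd.DataFrame(
            {"cell_id": self.labels.index, "cluster": self.labels.values}
        )
        df["silhouette"] = self.silhouette
        df.to_csv(out / "cell_states.tsv", sep="\t", index=False)
        self.clustering.mean_activity_by_cluster().to_csv(
            out / "cluster_mean_activity.tsv", sep="\t"
        )
        if self.clustering.embedding is not None:
            self.clustering.embedding.to_csv(out / "umap.tsv", sep="\t")
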