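"""Synthetic single-cell cohorts with planted gene programs.

Two mouse-model-like cohorts ("A", "B") of malignant cells carry shared and
cohort-enriched expression programs; a multi-tumor human-like cohort carries
the homologous versions of the shared programs plus per-tumor
progression-free-survival times whose hazard is linked to program activity.
The generator is the ground-truth source for every recovery test: planted
gene sets, per-cell activities and the true survival linear predictor are
returned alongside the counts.

Counts are Poisson: each cell draws a library size (log-normal), per-gene
rates are a Gamma baseline multiplied by ``effect_size`` for every program
active in that cell, and the rate vector is renormalised to sum to one
before scaling by library size so planted programs do not inflate totals.
An optional Gamma mixing term adds negative-binomial overdispersion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._seeds import derive_seed
from .datamodel import CountMatrix, GeneSetCollection, HomologMap

__all__ = [
    "PlantedProgram",
    "SyntheticSpec",
    "SyntheticTruth",
    "default_programs",
    "default_spec",
    "null_spec",
    "default_homolog_map",
    "generate_mouse_cohorts",
    "generate_human_cohort",
]


@dataclass(frozen=True)
class PlantedProgram:
    """One planted gene program.

    ``effect_size`` multiplies the baseline rate of every program gene in
    cells where the program is active; activity is Bernoulli per cell with
    a cohort-specific probability (key "human" for the human cohort).
    ``hazard_coef`` is the log-hazard contribution of the standardized
    per-tumor program score to progression-free survival.
    """

    name: str
    gene_indices: tuple[int, ...]
    effect_size: float = 6.0
    activity_prob: dict = field(default_factory=dict)
    shared_with_human: bool = False
    hazard_coef: float = 0.0

    def __post_init__(self) -> None:
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        for c, p in self.activity_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"activity_prob[{c!r}]={p} outside [0,1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for cohort generation."""

    n_genes: int = 2000
    n_cells_per_cohort: int = 600
    programs: tuple[PlantedProgram, ...] = ()
    library_size_log_mean: float = float(np.log(2500.0))
    library_size_log_sd: float = 0.3
    baseline_rate_shape: float = 0.3
    baseline_rate_scale: float = 1.0
    n_tumors_human: int = 12
    n_cells_per_tumor: int = 50
    overdispersion: float = 0.0  # Gamma-mixing 1/size; 0 = pure Poisson
    dose_sd: float = 0.0  # jitter of the activity dose exponent in active cells
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_cells_per_cohort < 1:
            raise ValueError("n_genes and n_cells_per_cohort must be >= 1")
        for prog in self.programs:
            if any(i < 0 or i >= self.n_genes for i in prog.gene_indices):
                raise ValueError(f"program {prog.name} has gene indices outside range")

    def replace(self, **changes) -> "SyntheticSpec":
        return replace(self, **changes)


@dataclass
class SyntheticTruth:
    """Ground truth emitted next to a synthetic CountMatrix."""

    programs: GeneSetCollection
    activity: pd.DataFrame  # cells × programs, bool
    dose: pd.DataFrame  # cells × programs, float exponent of effect_size
    linear_predictor: pd.Series | None = None  # per sample, human cohort only

    def to_json(self, path: str | Path) -> None:
        payload = {
            "programs": {k: v for k, v in self.programs},
            "activity": {
                "index": list(self.activity.index),
                "columns": list(self.activity.columns),
                "values": self.activity.astype(int).values.tolist(),
            },
            "dose": self.dose.values.tolist(),
            "linear_predictor": (
                None
                if self.linear_predictor is None
                else {str(k): float(v) for k, v in self.linear_predictor.items()}
            ),
        }
        Path(path).write_text(json.dumps(payload) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        raw = json.loads(Path(path).read_text())
        act = pd.DataFrame(
            np.asarray(raw["activity"]["values"], dtype=bool),
            index=raw["activity"]["index"],
            columns=raw["activity"]["columns"],
        )
        dose = pd.DataFrame(
            np.asarray(raw["dose"], dtype=float), index=act.index, columns=act.columns
        )
        lp = raw["linear_predictor"]
        return cls(
            programs=GeneSetCollection(raw["programs"]),
            activity=act,
            dose=dose,
            linear_predictor=None if lp is None else pd.Series(lp, dtype=float),
        )


def default_programs(
    n_genes: int = 2000,
    n_programs: int = 5,
    genes_per_program: int = 40,
    effect_size: float = 6.0,
) -> tuple[PlantedProgram, ...]:
    """Five disjoint 40-gene programs: two cohort-exclusive, three shared.

    The shared programs are also planted in the human cohort; the first of
    them carries a positive survival hazard coefficient.
    """
    if n_programs * genes_per_program > n_genes:
        raise ValueError("programs do not fit in the gene universe")
    blocks = [
        tuple(range(i * genes_per_program, (i + 1) * genes_per_program))
        for i in range(n_programs)
    ]
    probs = [
        {"A": 0.7, "B": 0.0, "human": 0.0},
        {"A": 0.0, "B": 0.7, "human": 0.0},
        {"A": 0.4, "B": 0.4, "human": 0.4},
        {"A": 0.35, "B": 0.35, "human": 0.35},
        {"A": 0.3, "B": 0.3, "human": 0.3},
    ]
    shared = [False, False, True, True, True]
    hazard = [0.0, 0.0, 1.0, 0.0, 0.0]
    progs = []
    for i in range(n_programs):
        j = i % len(probs)
        progs.append(
            PlantedProgram(
                name=f"P{i + 1}",
                gene_indices=blocks[i],
                effect_size=effect_size,
                activity_prob=dict(probs[j]),
                shared_with_human=shared[j],
                hazard_coef=hazard[j],
            )
        )
    return tuple(progs)


def default_spec(seed: int = 0, **changes) -> SyntheticSpec:
    """The default study conditions: 2000 genes, 600 cells/cohort, 5 planted
    programs of 40 genes at effect 6, two of them cohort-exclusive."""
    spec = SyntheticSpec(programs=default_programs(), seed=seed)
    return spec.replace(**changes) if changes else spec


def null_spec(seed: int = 0, **changes) -> SyntheticSpec:
    """Same programs but with equal activity probability in both cohorts,
    so no program separates cohorts (classifier auROC should sit near 0.5)."""
    progs = tuple(
        replace(p, activity_prob={**p.activity_prob, "A": 0.35, "B": 0.35})
        for p in default_programs()
    )
    spec = SyntheticSpec(programs=progs, seed=seed)
    return spec.replace(**changes) if changes else spec


def _gene_ids(spec: SyntheticSpec) -> list[str]:
    width = max(4, len(str(spec.n_genes - 1)))
    return [f"G{i:0{width}d}" for i in range(spec.n_genes)]


def default_homolog_map(spec: SyntheticSpec) -> HomologMap:
    """A complete one-to-one mouse→human map (Gxxxx → HGxxxx)."""
    return HomologMap({g: "H" + g for g in _gene_ids(spec)})


def _truth_gene_sets(spec: SyntheticSpec, gene_ids: list[str]) -> GeneSetCollection:
    return GeneSetCollection(
        {p.name: [gene_ids[i] for i in p.gene_indices] for p in spec.programs}
    )


def _draw_counts(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    baseline: np.ndarray,
    dose: np.ndarray,  # cells × programs
) -> np.ndarray:
    """Poisson counts for one batch of cells given per-cell program doses."""
    n = dose.shape[0]
    log_rate = np.tile(np.log(baseline), (n, 1))
    for j, prog in enumerate(spec.programs):
        idx = np.asarray(prog.gene_indices, dtype=int)
        log_rate[:, idx] += np.log(prog.effect_size) * dose[:, [j]]
    rate = np.exp(log_rate)
    rate /= rate.sum(axis=1, keepdims=True)  # softnorm: totals track library size
    lib = rng.lognormal(spec.library_size_log_mean, spec.library_size_log_sd, size=n)
    mean = rate * lib[:, None]
    if spec.overdispersion > 0:
        size = 1.0 / spec.overdispersion
        mean = mean * rng.gamma(size, 1.0 / size, size=mean.shape)
    return rng.poisson(mean)


def _draw_activity(
    rng: np.random.Generator, spec: SyntheticSpec, cohort_key: str, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli activity and its continuous dose for ``n`` cells."""
    P = len(spec.programs)
    active = np.zeros((n, P), dtype=bool)
    for j, prog in enumerate(spec.programs):
        p = prog.activity_prob.get(cohort_key, 0.0)
        active[:, j] = rng.random(n) < p
    dose = active.astype(float)
    if spec.dose_sd > 0:
        jitter = rng.normal(1.0, spec.dose_sd, size=dose.shape)
        dose = np.where(active, np.clip(jitter, 0.0, None), 0.0)
    return active, dose


def generate_mouse_cohorts(spec: SyntheticSpec) -> tuple[CountMatrix, SyntheticTruth]:
    """Generate the two-cohort ("A"/"B") malignant-cell count matrix."""
    if not spec.programs:
        raise ValueError("spec.programs is empty")
    gene_ids = _gene_ids(spec)
    rng = np.random.default_rng(derive_seed(spec.seed, "mouse-cohorts"))
    baseline = rng.gamma(
        spec.baseline_rate_shape, spec.baseline_rate_scale, size=spec.n_genes
    )
    baseline = np.clip(baseline, 1e-8, None)  # keep every gene expressible

    blocks, cell_ids, cohorts, samples = [], [], [], []
    act_rows, dose_rows = [], []
    for cohort in ("A", "B"):
        n = spec.n_cells_per_cohort
        active, dose = _draw_activity(rng, spec, cohort, n)
        counts = _draw_counts(rng, spec, baseline, dose)
        blocks.append(counts)
        cell_ids += [f"{cohort}_{i:05d}" for i in range(n)]
        cohorts += [cohort] * n
        # two tumors per model: enough structure for per-sample operations
        samples += [f"{cohort}_T{1 + (i % 2)}" for i in range(n)]
        act_rows.append(active)
        dose_rows.append(dose)

    counts = np.vstack(blocks).T  # genes × cells
    prog_names = [p.name for p in spec.programs]
    truth = SyntheticTruth(
        programs=_truth_gene_sets(spec, gene_ids),
        activity=pd.DataFrame(np.vstack(act_rows), index=cell_ids, columns=prog_names),
        dose=pd.DataFrame(np.vstack(dose_rows), index=cell_ids, columns=prog_names),
    )
    cm = CountMatrix(
        values=sp.csr_matrix(counts),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cohort=np.array(cohorts, dtype=object),
        sample_id=np.array(samples, dtype=object),
        malignant=np.ones(len(cell_ids), dtype=bool),
    )
    return cm, truth


def generate_human_cohort(
    spec: SyntheticSpec,
    homolog_map: HomologMap | None = None,
    cohort_name: str = "human",
) -> tuple[CountMatrix, SyntheticTruth, pd.DataFrame]:
    """Generate a multi-tumor human-like cohort plus a survival table.

    Programs flagged ``shared_with_human`` are planted through their
    homolog ids. Per-tumor progression-free survival is exponential with
    rate ``exp(sum_p hazard_coef_p * z(score_p))`` where ``score_p`` is the
    tumor's mean activity dose of program p, standardized across tumors;
    censoring is Uniform(0, 2 × mean PFS).
    """
    if not spec.programs:
        raise ValueError("spec.programs is empty")
    if spec.n_tumors_human < 2:
        raise ValueError("need at least 2 human tumors")
    mouse_genes = _gene_ids(spec)
    if homolog_map is None:
        homolog_map = default_homolog_map(spec)
    for prog in spec.programs:
        if prog.shared_with_human:
            missing = [
                mouse_genes[i]
                for i in prog.gene_indices
                if mouse_genes[i] not in homolog_map.pairs
            ]
            if missing:
                raise ValueError(
                    f"homolog map misses {len(missing)} genes of shared program "
                    f"{prog.name} (e.g. {missing[0]})"
                )

    # Human gene universe mirrors the mouse one through the map; unmapped
    # mouse genes keep a human-only placeholder id so dimensions stay equal.
    human_genes = [homolog_map.pairs.get(g, f"HSONLY_{g}") for g in mouse_genes]

    human_spec = spec.replace(
        programs=tuple(p for p in spec.programs if p.shared_with_human)
    )
    rng = np.random.default_rng(derive_seed(spec.seed, "human-cohort"))
    baseline = rng.gamma(
        spec.baseline_rate_shape, spec.baseline_rate_scale, size=spec.n_genes
    )
    baseline = np.clip(baseline, 1e-8, None)

    blocks, cell_ids, samples = [], [], []
    act_rows, dose_rows = [], []
    tumor_ids = [f"T{t + 1:02d}" for t in range(spec.n_tumors_human)]
    for t_id in tumor_ids:
        n = spec.n_cells_per_tumor
        active, dose = _draw_activity(rng, human_spec, "human", n)
        counts = _draw_counts(rng, human_spec, baseline, dose)
        blocks.append(counts)
        cell_ids += [f"{t_id}_{i:04d}" for i in range(n)]
        samples += [t_id] * n
        act_rows.append(active)
        dose_rows.append(dose)

    prog_names = [p.name for p in human_spec.programs]
    activity = pd.DataFrame(np.vstack(act_rows), index=cell_ids, columns=prog_names)
    dose_df = pd.DataFrame(np.vstack(dose_rows), index=cell_ids, columns=prog_names)

    # Per-tumor standardized program scores drive the hazard.
    sample_arr = np.array(samples, dtype=object)
    eta = pd.Series(0.0, index=tumor_ids)
    for prog in human_spec.programs:
        per_tumor = dose_df[prog.name].groupby(sample_arr).mean().reindex(tumor_ids)
        sd = per_tumor.std(ddof=1)
        if sd > 0 and prog.hazard_coef != 0.0:
            eta += prog.hazard_coef * (per_tumor - per_tumor.mean()) / sd
    scale = np.exp(-eta.values)  # E[T] per tumor
    pfs = rng.exponential(scale)
    censor = rng.uniform(0.0, 2.0 * float(np.mean(scale)), size=len(tumor_ids))
    survival = pd.DataFrame(
        {
            "sample_id": tumor_ids,
            "time": np.minimum(pfs, censor),
            "event": pfs <= censor,
        }
    )

    # Truth gene sets in human ids.
    human_sets = GeneSetCollection(
        {
            p.name: [human_genes[i] for i in p.gene_indices]
            for p in human_spec.programs
        }
    )
    truth = SyntheticTruth(
        programs=human_sets,
        activity=activity,
        dose=dose_df,
        linear_predictor=eta,
    )
    cm = CountMatrix(
        values=sp.csr_matrix(np.vstack(blocks).T),
        gene_ids=human_genes,
        cell_ids=cell_ids,
        cohort=np.array([cohort_name] * len(cell_ids), dtype=object),
        sample_id=sample_arr,
        malignant=np.ones(len(cell_ids), dtype=bool),
    )
    return cm, truth, survival
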