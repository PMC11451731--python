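"""Core domain types and readers/writers for the on-disk formats.

Counts travel as Matrix Market (1-based coordinate, integer) with TSV
sidecars for gene and cell annotations; gene sets as GMT; homolog maps and
survival tables as TSV. Identifiers are case-sensitive and matched exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "GeneSetCollection",
    "HomologMap",
    "FormatError",
    "read_count_matrix",
    "write_count_matrix",
    "read_gmt",
    "write_gmt",
    "resolve_homologs",
    "read_homolog_table",
    "read_survival_table",
    "write_survival_table",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


_CELL_COLUMNS = ("cell_id", "cohort", "sample_id", "malignant")


@dataclass
class CountMatrix:
    """Sparse gene × cell count matrix with per-cell annotations.

    ``values`` holds nonnegative integer counts with genes on rows and
    cells on columns. ``cohort`` is the model/patient label used to split
    discovery runs, ``sample_id`` the tumor or biopsy of origin, and
    ``malignant`` flags tumor cells.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cohort: np.ndarray
    sample_id: np.ndarray
    malignant: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.cohort = np.asarray(self.cohort, dtype=object)
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.malignant = np.asarray(self.malignant, dtype=bool)
        g, n = self.values.shape
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {g} matrix rows")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} matrix columns")
        for name, arr in (("cohort", self.cohort), ("sample_id", self.sample_id)):
            if arr.shape != (n,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({n},)")
            if any(v is None or str(v) == "" for v in arr):
                raise ValueError(f"every cell needs a non-empty {name}")
        if self.malignant.shape != (n,):
            raise ValueError("malignant flag length mismatch")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene_ids")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell_ids")
        data = self.values.data
        if data.size:
            if np.any(data < 0):
                raise ValueError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise ValueError("non-integer counts")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            values=self.values[:, idx],
            gene_ids=self.gene_ids,
            cell_ids=[self.cell_ids[i] for i in idx],
            cohort=self.cohort[idx],
            sample_id=self.sample_id[idx],
            malignant=self.malignant[idx],
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return CountMatrix(
            values=self.values[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=self.cell_ids,
            cohort=self.cohort,
            sample_id=self.sample_id,
            malignant=self.malignant,
        )

    def malignant_cells(self) -> "CountMatrix":
        return self.subset_cells(self.malignant)


@dataclass
class GeneSetCollection:
    """Named, ordered gene lists (a GMT file in memory)."""

    sets: dict[str, list[str]]
    description: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")
        for name in self.sets:
            self.description.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class HomologMap:
    """One-to-one source → target gene mapping (partial; unmapped allowed)."""

    pairs: dict[str, str]

    def translate(self, genes: Iterable[str]) -> list[str]:
        """Map genes, silently dropping those without a homolog."""
        out = []
        for g in genes:
            t = self.pairs.get(g)
            if t is not None:
                out.append(t)
        return out

    def translate_collection(self, coll: GeneSetCollection) -> GeneSetCollection:
        """Translate every set, dropping unmapped genes and empty results."""
        sets, desc = {}, {}
        for name, genes in coll:
            mapped = list(dict.fromkeys(self.translate(genes)))
            if mapped:
                sets[name] = mapped
                desc[name] = coll.description.get(name, "")
            else:
                logger.warning("gene set %s empty after homolog mapping; dropped", name)
        return GeneSetCollection(sets, desc)


# ---------------------------------------------------------------------------
# Count matrix I/O


def read_count_matrix(
    mtx_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> CountMatrix:
    """Read counts from Matrix Market plus gene/cell TSV sidecars.

    The gene TSV needs a ``gene_id`` column; the cell TSV needs
    ``cell_id``, ``cohort``, ``sample_id`` and ``malignant`` columns. Row
    and column order must match the sidecars.
    """
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"cannot parse MTX file {mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)
    if mat.shape[0] == 0 or mat.shape[1] == 0:
        raise FormatError(f"MTX file {mtx_path} declares an empty matrix {mat.shape}")

    genes = pd.read_csv(genes_path, sep="\t", dtype=str)
    if "gene_id" not in genes.columns:
        raise ValueError(f"gene sidecar {genes_path} missing required column 'gene_id'")
    cells = pd.read_csv(cells_path, sep="\t", dtype=str)
    for col in _CELL_COLUMNS:
        if col not in cells.columns:
            raise ValueError(f"cell sidecar {cells_path} missing required column {col!r}")
    if len(genes) != mat.shape[0] or len(cells) != mat.shape[1]:
        raise FormatError(
            f"dimension mismatch: MTX is {mat.shape}, sidecars give "
            f"({len(genes)}, {len(cells)})"
        )
    malignant = cells["malignant"].map(
        {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}
    )
    if malignant.isna().any():
        raise ValueError("malignant column must be boolean (True/False or 0/1)")
    return CountMatrix(
        values=mat,
        gene_ids=genes["gene_id"].tolist(),
        cell_ids=cells["cell_id"].tolist(),
        cohort=cells["cohort"].to_numpy(),
        sample_id=cells["sample_id"].to_numpy(),
        malignant=malignant.to_numpy(),
    )


def write_count_matrix(
    cm: CountMatrix, mtx_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> None:
    """Write a CountMatrix as integer MTX plus TSV sidecars (round-trips)."""
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(cm.values), field="integer")
    pd.DataFrame({"gene_id": cm.gene_ids}).to_csv(genes_path, sep="\t", index=False)
    pd.DataFrame(
        {
            "cell_id": cm.cell_ids,
            "cohort": cm.cohort,
            "sample_id": cm.sample_id,
            "malignant": cm.malignant,
        }
    ).to_csv(cells_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB gene TAB gene ...).

    Duplicate genes within a set are dropped with a warning; order is
    otherwise preserved.
    """
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno} has {len(fields)} fields; GMT needs >= 3"
                )
            name, description, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise FormatError(f"{path}: duplicate set name {name!r} at line {lineno}")
            deduped = list(dict.fromkeys(g for g in genes if g))
            if len(deduped) < sum(1 for g in genes if g):
                logger.warning("set %s: duplicate genes dropped", name)
            sets[name] = deduped
            desc[name] = description
    return GeneSetCollection(sets, desc)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in coll:
            fh.write("\t".join([name, coll.description.get(name, "")] + genes) + "\n")


# ---------------------------------------------------------------------------
# Homolog resolution


def resolve_homologs(
    raw_pairs: Sequence[tuple[str, str]], genes_present: set[str]
) -> HomologMap:
    """Resolve a possibly one-to-many homolog table to a partial function.

    Targets absent from ``genes_present`` are dropped. A source with
    several surviving targets keeps the alphabetically first one — a
    deterministic tie-break; the choice of rule is ours, not inherited.
    """
    candidates: dict[str, list[str]] = {}
    for src, tgt in raw_pairs:
        candidates.setdefault(str(src), []).append(str(tgt))
    pairs: dict[str, str] = {}
    for src, targets in candidates.items():
        present = sorted(t for t in set(targets) if t in genes_present)
        if present:
            pairs[src] = present[0]
    if not pairs:
        warnings.warn("homolog map empty after resolution", stacklevel=2)
    return HomologMap(pairs)


def read_homolog_table(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column (source, target) TSV, with or without a header."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: homolog table needs two columns")
    first = df.iloc[0]
    if str(first[0]).lower() in ("source", "mouse", "gene", "source_gene"):
        df = df.iloc[1:]
    return [(r[0], r[1]) for r in df.itertuples(index=False)]


# ---------------------------------------------------------------------------
# Survival tables


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read (sample_id, time, event) TSV; event coded 0/1."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"survival table {path} missing column {col!r}")
    if (df["time"] < 0).any():
        raise ValueError("survival times must be nonnegative")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["event"] = df["event"].astype(int).astype(bool)
    return df


def write_survival_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df[["sample_id", "time", "event"]].copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, sep="\t", index=False)
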