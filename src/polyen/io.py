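"""Reading, writing and normalizing single-cell expression cohorts.

The central container is :class:`CellExpressionDataset`: a dense cells × genes
matrix of (log-normalized) expression together with per-cell annotations
(donor, cell type) and per-donor annotations (age, group, study). Datasets can
be read from a MatrixMarket directory (``matrix.mtx`` + ``barcodes.tsv`` +
``features.tsv`` + annotation TSVs) or from a dense CSV, and written back in
either format losslessly.

Normalization follows the standard single-cell recipe: per-cell counts are
scaled to a common size factor (default 10 000) and log1p-transformed
(natural log).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix, issparse

__all__ = [
    "CellExpressionDataset",
    "GeneSet",
    "SchemaError",
    "IntegrityError",
    "read_expression",
    "write_expression",
    "log_normalize",
    "read_gene_sets",
    "union_gene_sets",
    "intersect_genes",
]

CELL_COLUMNS = ("cell_id", "donor_id", "cell_type")
DONOR_COLUMNS = ("donor_id", "age")


class SchemaError(ValueError):
    """An annotation table is missing a required column."""


class IntegrityError(ValueError):
    """Cross-references between tables are inconsistent."""


@dataclass
class GeneSet:
    """A named list of gene symbols (e.g. a senescence marker panel)."""

    name: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)


@dataclass
class CellExpressionDataset:
    """Cells × genes expression with donor and cell-type annotations.

    Parameters
    ----------
    values
        Dense ``(n_cells, n_genes)`` float matrix. Raw counts if
        ``normalized`` is False, log-normalized expression otherwise.
    cell_annotations
        One row per cell with at least ``cell_id``, ``donor_id`` and
        ``cell_type`` columns; rows align with ``values``. ``cell_type`` may
        be empty/NaN for unannotated cells (excluded from cell-type-specific
        analyses, retained in pseudo-bulk).
    donor_annotations
        One row per donor with at least ``donor_id`` and ``age`` (years);
        optional ``group`` (e.g. smoking status) and ``study`` columns.
    gene_ids
        Unique gene symbols, one per matrix column.
    normalized
        Whether ``values`` are log-normalized.
    """

    values: np.ndarray
    cell_annotations: pd.DataFrame
    donor_annotations: pd.DataFrame
    gene_ids: list[str]
    normalized: bool = True
    name: str = "dataset"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_annotations = self.cell_annotations.reset_index(drop=True)
        self.donor_annotations = self.donor_annotations.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        for col in CELL_COLUMNS:
            if col not in self.cell_annotations.columns:
                raise SchemaError(f"cell annotation table is missing column {col!r}")
        for col in DONOR_COLUMNS:
            if col not in self.donor_annotations.columns:
                raise SchemaError(f"donor annotation table is missing column {col!r}")
        n_cells, n_genes = self.values.shape
        if len(self.cell_annotations) != n_cells:
            raise IntegrityError(
                f"{n_cells} matrix rows but {len(self.cell_annotations)} cell annotations"
            )
        if len(self.gene_ids) != n_genes:
            raise IntegrityError(
                f"{n_genes} matrix columns but {len(self.gene_ids)} gene ids"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise IntegrityError("gene_ids contains duplicates")
        donors = self.donor_annotations["donor_id"].astype(str)
        if donors.duplicated().any():
            raise IntegrityError("duplicate donor_id in donor annotations")
        known = set(donors)
        referenced = set(self.cell_annotations["donor_id"].astype(str))
        unknown = referenced - known
        if unknown:
            raise IntegrityError(
                f"cells reference donors absent from donor annotations: {sorted(unknown)}"
            )
        ages = pd.to_numeric(self.donor_annotations["age"], errors="coerce")
        if ages.isna().any() or not np.isfinite(ages.to_numpy()).all():
            raise IntegrityError("donor ages must be finite numbers")
        if (ages <= 0).any():
            raise IntegrityError("donor ages must be > 0")
        if np.isnan(self.values).any():
            raise IntegrityError("expression matrix contains NaN")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def donor_ids(self) -> list[str]:
        return [str(d) for d in self.donor_annotations["donor_id"]]

    def ages(self) -> pd.Series:
        """Donor ages indexed by donor_id."""
        return pd.Series(
            pd.to_numeric(self.donor_annotations["age"]).to_numpy(),
            index=self.donor_ids,
            name="age",
        )

    def cell_types(self) -> list[str]:
        labels = self.cell_annotations["cell_type"].dropna()
        return sorted({str(t) for t in labels if str(t) != ""})

    def subset_genes(self, genes: list[str]) -> "CellExpressionDataset":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:5]}")
        cols = [index[g] for g in genes]
        return replace(self, values=self.values[:, cols], gene_ids=list(genes))

    def subset_donors(self, donor_ids: list[str]) -> "CellExpressionDataset":
        keep = set(map(str, donor_ids))
        cmask = self.cell_annotations["donor_id"].astype(str).isin(keep).to_numpy()
        dmask = self.donor_annotations["donor_id"].astype(str).isin(keep).to_numpy()
        return replace(
            self,
            values=self.values[cmask],
            cell_annotations=self.cell_annotations.loc[cmask],
            donor_annotations=self.donor_annotations.loc[dmask],
        )


# -- readers / writers ---------------------------------------------------------


def _read_annotations(path: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    cells = pd.read_csv(os.path.join(path, "cells.tsv"), sep="\t", dtype=str)
    donors = pd.read_csv(os.path.join(path, "donors.tsv"), sep="\t")
    if "cell_id" not in cells.columns:
        raise SchemaError("cell annotation table is missing column 'cell_id'")
    if "donor_id" not in donors.columns:
        raise SchemaError("donor annotation table is missing column 'donor_id'")
    donors["donor_id"] = donors["donor_id"].astype(str)
    return cells, donors


def read_expression(path: str, format: str = "mtx_dir", *, normalized: bool = True,
                    name: str | None = None) -> CellExpressionDataset:
    """Read a dataset from disk.

    ``mtx_dir`` expects a directory with ``matrix.mtx`` (cells × genes),
    ``barcodes.tsv`` (cell ids), ``features.tsv`` (gene symbols), ``cells.tsv``
    and ``donors.tsv`` annotation tables. ``csv`` expects ``expression.csv``
    (first column ``cell_id``, remaining columns gene symbols) alongside the
    same annotation tables. ``h5ad-like`` reads an AnnData ``.h5ad`` file whose
    ``obs`` carries ``donor_id``/``cell_type`` cell columns and per-cell
    ``age`` (and optional ``group``/``study``) donor columns.
    """
    if format == "mtx_dir":
        matrix = mmread(os.path.join(path, "matrix.mtx"))
        if issparse(matrix):
            matrix = matrix.toarray()
        matrix = np.asarray(matrix, dtype=float)
        barcodes = pd.read_csv(os.path.join(path, "barcodes.tsv"), sep="\t", header=None)[0].astype(str)
        features = pd.read_csv(os.path.join(path, "features.tsv"), sep="\t", header=None)[0].astype(str)
        cells, donors = _read_annotations(path)
        cells = cells.set_index("cell_id").loc[barcodes].reset_index()
        gene_ids = list(features)
    elif format == "csv":
        table = pd.read_csv(os.path.join(path, "expression.csv"), index_col=0)
        matrix = table.to_numpy(dtype=float)
        gene_ids = [str(c) for c in table.columns]
        cells, donors = _read_annotations(path)
        cells = cells.set_index("cell_id").loc[table.index.astype(str)].reset_index()
    elif format == "h5ad-like":
        import anndata as ad

        adata = ad.read_h5ad(path)
        matrix = adata.X.toarray() if issparse(adata.X) else np.asarray(adata.X, dtype=float)
        gene_ids = [str(g) for g in adata.var_names]
        obs = adata.obs.reset_index().rename(columns={"index": "cell_id"})
        for col in ("donor_id", "cell_type"):
            if col not in obs.columns:
                raise SchemaError(f"h5ad obs is missing column {col!r}")
        if "age" not in obs.columns:
            raise SchemaError("h5ad obs is missing column 'age'")
        cells = obs[["cell_id", "donor_id", "cell_type"]].astype(str)
        donor_cols = ["donor_id", "age"] + [c for c in ("group", "study") if c in obs.columns]
        donors = obs[donor_cols].drop_duplicates("donor_id").reset_index(drop=True)
    else:
        raise ValueError(f"unknown format {format!r}")

    return CellExpressionDataset(
        values=matrix,
        cell_annotations=cells,
        donor_annotations=donors,
        gene_ids=gene_ids,
        normalized=normalized,
        name=name or os.path.basename(os.path.normpath(str(path))),
    )


def write_expression(dataset: CellExpressionDataset, path: str, format: str = "mtx_dir") -> None:
    """Write ``dataset`` so that :func:`read_expression` round-trips it."""
    os.makedirs(path, exist_ok=True)
    cell_ids = dataset.cell_annotations["cell_id"].astype(str)
    if format == "mtx_dir":
        mmwrite(os.path.join(path, "matrix.mtx"), csr_matrix(dataset.values))
        cell_ids.to_csv(os.path.join(path, "barcodes.tsv"), sep="\t", header=False, index=False)
        pd.Series(dataset.gene_ids).to_csv(
            os.path.join(path, "features.tsv"), sep="\t", header=False, index=False
        )
    elif format == "csv":
        table = pd.DataFrame(dataset.values, index=cell_ids, columns=dataset.gene_ids)
        table.index.name = "cell_id"
        table.to_csv(os.path.join(path, "expression.csv"))
    else:
        raise ValueError(f"unknown format {format!r}")
    dataset.cell_annotations.to_csv(os.path.join(path, "cells.tsv"), sep="\t", index=False)
    dataset.donor_annotations.to_csv(os.path.join(path, "donors.tsv"), sep="\t", index=False)


# -- normalization -------------------------------------------------------------


def log_normalize(counts: CellExpressionDataset, size_factor: float = 10_000.0) -> CellExpressionDataset:
    """Size-factor scale and log1p-transform raw counts.

    For cell ``c`` and gene ``g`` the result is
    ``log(1 + size_factor * count[c, g] / total_count[c])`` with the natural
    logarithm, matching the standard scanpy recipe. Refuses already-normalized
    input and cells with zero total counts (filter those upstream — they are
    never dropped silently).
    """
    if counts.normalized:
        raise ValueError("dataset is already log-normalized; refusing to normalize twice")
    if size_factor <= 0:
        raise ValueError("size_factor must be positive")
    if (counts.values < 0).any():
        raise ValueError("raw counts must be non-negative")
    totals = counts.values.sum(axis=1)
    if (totals <= 0).any():
        bad = counts.cell_annotations["cell_id"].astype(str)[totals <= 0].tolist()
        raise ValueError(f"cells with zero total counts: {bad}")
    scaled = counts.values * (size_factor / totals[:, None])
    return replace(counts, values=np.log1p(scaled), normalized=True)


# -- gene sets -----------------------------------------------------------------


def read_gene_sets(path: str) -> list[GeneSet]:
    """Read gene sets from a CSV/TSV with columns ``set_name`` and ``gene``."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(path, sep=sep)
    for col in ("set_name", "gene"):
        if col not in table.columns:
            raise SchemaError(f"gene-set table is missing column {col!r}")
    sets = []
    for name, sub in table.groupby("set_name", sort=False):
        members = list(dict.fromkeys(sub["gene"].astype(str)))
        sets.append(GeneSet(name=str(name), members=members))
    if not sets:
        raise ValueError("gene-set table contains no sets")
    return sets


def union_gene_sets(sets: list[GeneSet], name: str = "Union") -> GeneSet:
    """Union of several marker lists, each symbol kept once (first occurrence)."""
    if not sets:
        raise ValueError("no gene sets to union")
    members = list(dict.fromkeys(g for s in sets for g in s.members))
    return GeneSet(name=name, members=members)


def intersect_genes(
    train: CellExpressionDataset, test: CellExpressionDataset
) -> tuple[CellExpressionDataset, CellExpressionDataset]:
    """Restrict both datasets to their shared genes, in a canonical order.

    Cross-dataset evaluation only uses genes expressed in both the training
    and test sets; the shared genes are ordered as in the training dataset.
    """
    if not (train.normalized and test.normalized):
        raise ValueError("both datasets must be log-normalized before intersection")
    shared = [g for g in train.gene_ids if g in set(test.gene_ids)]
    if not shared:
        raise ValueError("train and test datasets share no genes")
    return train.subset_genes(shared), test.subset_genes(shared)
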