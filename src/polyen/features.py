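"""Donor-level polynomial feature construction.

Each donor's cells of a given type are collapsed into per-gene summary
statistics: the mean u_g and the sample variance v_g of log-normalized
expression. The regression design is the column-wise concatenation

    X = [u_1..u_n, v_1..v_n, u_1^2..u_n^2, v_1^2..v_n^2]

i.e. first- and second-degree polynomial features of both the mean and the
variance, 4n columns for n genes. Variants: the same construction on the top-k
principal components of cell-level expression (k = 10 by default), a
meta-regressor design concatenating every cell type's features before a
donor-level PCA (k = 20), and a pseudo-bulk design pooling all cells
regardless of type.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CellExpressionDataset, GeneSet

__all__ = [
    "FEATURE_KINDS",
    "DonorFeatureMatrix",
    "CellPCATransform",
    "aggregate_donor_stats",
    "polynomial_expand",
    "pca_features",
    "meta_features",
    "pseudo_bulk_features",
    "gene_space_features",
]

#: Feature kinds in the canonical column order of the design matrix.
FEATURE_KINDS = ("mean1", "var1", "mean2", "var2")


@dataclass
class DonorFeatureMatrix:
    """Donors × polynomial-features design matrix with column provenance.

    ``column_meta`` has one row per column with ``source`` (gene symbol, PC
    label, or gene|cell-type pair) and ``kind`` in :data:`FEATURE_KINDS`;
    ``is_gene`` records whether sources are gene symbols (needed for gene-level
    attribution aggregation).
    """

    X: np.ndarray
    y: np.ndarray
    donor_ids: list[str]
    column_meta: pd.DataFrame
    cell_type: str | None = None
    n_cells_per_donor: dict[str, int] = field(default_factory=dict)
    is_gene: bool = True

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.donor_ids = [str(d) for d in self.donor_ids]
        if self.X.shape[0] != len(self.y) or self.X.shape[0] != len(self.donor_ids):
            raise ValueError("rows of X, y and donor_ids must align")
        if self.X.shape[1] != len(self.column_meta):
            raise ValueError("column_meta must have one row per column of X")

    @property
    def n_donors(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def column_names(self) -> list[str]:
        return [
            f"{s}|{k}" for s, k in zip(self.column_meta["source"], self.column_meta["kind"])
        ]

    def sources(self) -> list[str]:
        """Unique feature sources (genes or PCs) in column order."""
        return list(dict.fromkeys(self.column_meta["source"]))

    def select_kinds(self, kinds: tuple[str, ...]) -> "DonorFeatureMatrix":
        """Restrict to columns of the given feature kinds (e.g. mean-only baselines)."""
        mask = self.column_meta["kind"].isin(kinds).to_numpy()
        return replace(
            self,
            X=self.X[:, mask],
            column_meta=self.column_meta.loc[mask].reset_index(drop=True),
        )

    def subset_donors(self, donor_ids: list[str]) -> "DonorFeatureMatrix":
        index = {d: i for i, d in enumerate(self.donor_ids)}
        rows = [index[str(d)] for d in donor_ids]
        return replace(
            self,
            X=self.X[rows],
            y=self.y[rows],
            donor_ids=[str(d) for d in donor_ids],
            n_cells_per_donor={d: self.n_cells_per_donor[d] for d in map(str, donor_ids)
                               if d in self.n_cells_per_donor},
        )

    # -- serialization ---------------------------------------------------------

    def to_csv(self, path: str) -> None:
        """Write the matrix as CSV plus a JSON metadata sidecar."""
        table = pd.DataFrame(self.X, index=pd.Index(self.donor_ids, name="donor_id"),
                             columns=self.column_names)
        table.insert(0, "age", self.y)
        table.to_csv(path)
        meta = {
            "cell_type": self.cell_type,
            "is_gene": self.is_gene,
            "n_cells_per_donor": self.n_cells_per_donor,
            "columns": self.column_meta.to_dict(orient="list"),
        }
        with open(_sidecar(path), "w") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def from_csv(cls, path: str) -> "DonorFeatureMatrix":
        table = pd.read_csv(path, index_col=0)
        with open(_sidecar(path)) as fh:
            meta = json.load(fh)
        y = table.pop("age").to_numpy()
        return cls(
            X=table.to_numpy(),
            y=y,
            donor_ids=[str(d) for d in table.index],
            column_meta=pd.DataFrame(meta["columns"]),
            cell_type=meta["cell_type"],
            n_cells_per_donor={str(k): int(v) for k, v in meta["n_cells_per_donor"].items()},
            is_gene=bool(meta["is_gene"]),
        )


def _sidecar(path: str) -> str:
    base, _ = os.path.splitext(path)
    return base + ".meta.json"


# -- aggregation ---------------------------------------------------------------


def _cells_of_type(dataset: CellExpressionDataset, cell_type: str | None) -> np.ndarray:
    labels = dataset.cell_annotations["cell_type"].astype("string")
    if cell_type is None:  # pseudo-bulk: every cell, annotated or not
        return np.ones(len(labels), dtype=bool)
    return (labels == cell_type).fillna(False).to_numpy()


def aggregate_donor_stats(
    dataset: CellExpressionDataset,
    cell_type: str | None,
    genes: GeneSet | list[str] | None = None,
    min_cells: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], list[str]]:
    """Per-donor mean and sample variance of expression for one cell type.

    Returns ``(U, V, retained, dropped)`` where ``U``/``V`` are donors × genes
    DataFrames of means and (n−1)-denominator sample variances over each
    donor's cells of ``cell_type`` (all cells when ``cell_type`` is None), and
    ``dropped`` lists donors with fewer than ``min_cells`` such cells.
    """
    if not dataset.normalized:
        raise ValueError("dataset must be log-normalized before aggregation")
    if min_cells < 2:
        raise ValueError("min_cells must be >= 2 so variances are defined")

    if genes is not None:
        members = genes.members if isinstance(genes, GeneSet) else list(genes)
        dataset = dataset.subset_genes(members)
    mask = _cells_of_type(dataset, cell_type)
    if cell_type is not None and not mask.any():
        raise ValueError(f"no cells with cell type {cell_type!r}")

    donor_of_cell = dataset.cell_annotations["donor_id"].astype(str).to_numpy()
    rows_u, rows_v, retained, dropped = [], [], [], []
    for donor in dataset.donor_ids:
        sel = mask & (donor_of_cell == donor)
        n = int(sel.sum())
        if n < min_cells:
            dropped.append(donor)
            continue
        block = dataset.values[sel]
        rows_u.append(block.mean(axis=0))
        rows_v.append(block.var(axis=0, ddof=1))
        retained.append(donor)
    if not retained:
        raise ValueError(
            f"no donor has >= {min_cells} cells of type {cell_type!r}"
        )
    U = pd.DataFrame(np.vstack(rows_u), index=retained, columns=dataset.gene_ids)
    V = pd.DataFrame(np.vstack(rows_v), index=retained, columns=dataset.gene_ids)
    return U, V, retained, dropped


def polynomial_expand(
    U: pd.DataFrame | np.ndarray,
    V: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    *,
    sources: list[str] | None = None,
    donor_ids: list[str] | None = None,
    cell_type: str | None = None,
    n_cells_per_donor: dict[str, int] | None = None,
    is_gene: bool = True,
) -> DonorFeatureMatrix:
    """Build the 4n-column polynomial design from mean and variance blocks.

    Column order is fixed — all means, all variances, all squared means, all
    squared variances, sources in input order — so downstream models and
    attributions are reproducible bit-for-bit.
    """
    if isinstance(U, pd.DataFrame):
        sources = sources or [str(c) for c in U.columns]
        donor_ids = donor_ids or [str(i) for i in U.index]
        U = U.to_numpy()
    if isinstance(V, pd.DataFrame):
        V = V.to_numpy()
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    if U.shape != V.shape:
        raise ValueError(f"U and V shapes differ: {U.shape} vs {V.shape}")
    if isinstance(y, pd.Series):
        y = y.to_numpy()
    y = np.asarray(y, dtype=float)
    if len(y) != U.shape[0]:
        raise ValueError("y must align with the rows of U and V")
    n = U.shape[1]
    if sources is None:
        sources = [f"f{i}" for i in range(n)]
    if donor_ids is None:
        donor_ids = [f"d{i}" for i in range(U.shape[0])]

    X = np.hstack([U, V, U**2, V**2])
    meta = pd.DataFrame(
        {
            "source": sources * 4,
            "kind": [k for k in FEATURE_KINDS for _ in range(n)],
        }
    )
    return DonorFeatureMatrix(
        X=X, y=y, donor_ids=donor_ids, column_meta=meta, cell_type=cell_type,
        n_cells_per_donor=n_cells_per_donor or {}, is_gene=is_gene,
    )


# -- PCA variants --------------------------------------------------------------


@dataclass
class CellPCATransform:
    """Mean-centered PCA loadings fitted on training cells, reusable on held-out cells."""

    center: np.ndarray
    components: np.ndarray  # (k, n_genes)
    gene_ids: list[str]

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def project(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.center) @ self.components.T


def _fit_cell_pca(values: np.ndarray, k: int) -> CellPCATransform:
    center = values.mean(axis=0)
    centered = values - center
    # deterministic full SVD; cell panels here are small enough
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank ({rank}) of the centered expression matrix")
    components = vt[:k]
    # sign convention: largest-magnitude loading positive
    for i in range(k):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
    return CellPCATransform(center=center, components=components, gene_ids=[])


def pca_features(
    dataset: CellExpressionDataset,
    cell_type: str | None,
    genes: GeneSet | list[str] | None = None,
    k: int = 10,
    min_cells: int = 10,
    fit_donors: list[str] | None = None,
    transform: CellPCATransform | None = None,
) -> tuple[DonorFeatureMatrix, CellPCATransform]:
    """Polynomial features computed on the top-k PCs of cell-level expression.

    The PCA is fitted on cells of ``fit_donors`` only (all retained donors by
    default); pass ``fit_donors`` restricted to training donors, then reuse the
    returned ``transform`` for held-out donors so test cells are projected with
    training loadings.
    """
    if genes is not None:
        members = genes.members if isinstance(genes, GeneSet) else list(genes)
        dataset = dataset.subset_genes(members)
    mask = _cells_of_type(dataset, cell_type)
    donor_of_cell = dataset.cell_annotations["donor_id"].astype(str).to_numpy()

    if transform is None:
        fit_set = set(map(str, fit_donors)) if fit_donors is not None else None
        fit_mask = mask if fit_set is None else mask & np.isin(donor_of_cell, list(fit_set))
        if not fit_mask.any():
            raise ValueError("no cells available to fit the PCA")
        transform = _fit_cell_pca(dataset.values[fit_mask], k)
        transform.gene_ids = list(dataset.gene_ids)
    elif transform.gene_ids and transform.gene_ids != dataset.gene_ids:
        raise ValueError("PCA transform was fitted on a different gene panel")

    scores = transform.project(dataset.values)
    pc_names = [f"PC{i + 1}" for i in range(transform.k)]
    projected = CellExpressionDataset(
        values=scores,
        cell_annotations=dataset.cell_annotations,
        donor_annotations=dataset.donor_annotations,
        gene_ids=pc_names,
        normalized=True,
        name=dataset.name,
    )
    U, V, retained, _ = aggregate_donor_stats(projected, cell_type, None, min_cells)
    ages = dataset.ages().loc[retained]
    counts = {d: int((mask & (donor_of_cell == d)).sum()) for d in retained}
    fm = polynomial_expand(
        U, V, ages, cell_type=cell_type, n_cells_per_donor=counts, is_gene=False
    )
    return fm, transform


def meta_features(
    dataset: CellExpressionDataset,
    cell_types: list[str],
    genes: GeneSet | list[str] | None = None,
    k: int = 20,
    min_cells: int = 10,
) -> tuple[DonorFeatureMatrix, list[str]]:
    """Meta-regressor design: all cell types' features concatenated, then 20 PCs.

    Per-donor polynomial features are computed for every listed cell type and
    concatenated column-wise (each gene × cell-type pair a potential feature);
    the donor-level concatenated matrix is mean-centered and projected onto its
    top-k principal components. Donors missing any listed cell type are
    dropped and reported.
    """
    if not cell_types:
        raise ValueError("cell_types must be non-empty")
    blocks: dict[str, DonorFeatureMatrix] = {}
    retained: set[str] | None = None
    for ct in cell_types:
        U, V, kept, _ = aggregate_donor_stats(dataset, ct, genes, min_cells)
        ages = dataset.ages().loc[kept]
        blocks[ct] = polynomial_expand(U, V, ages, cell_type=ct)
        retained = set(kept) if retained is None else retained & set(kept)
    if not retained:
        raise ValueError("no donor has enough cells of every listed cell type")
    donors = [d for d in dataset.donor_ids if d in retained]
    dropped = [d for d in dataset.donor_ids if d not in retained]

    parts, meta_parts = [], []
    for ct in cell_types:
        fm = blocks[ct].subset_donors(donors)
        parts.append(fm.X)
        m = fm.column_meta.copy()
        m["source"] = [f"{s}@{ct}" for s in m["source"]]
        meta_parts.append(m)
    concat = np.hstack(parts)
    ages = dataset.ages().loc[donors].to_numpy()

    if k >= min(concat.shape):
        rank_limit = min(concat.shape[0] - 1, concat.shape[1])
        if k > rank_limit:
            raise ValueError(f"k={k} exceeds what {concat.shape[0]} donors support")
    center = concat.mean(axis=0)
    _, s, vt = np.linalg.svd(concat - center, full_matrices=False)
    rank = int((s > (s[0] if s.size else 0) * 1e-12).sum())
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank ({rank}) of the concatenated feature matrix")
    scores = (concat - center) @ vt[:k].T
    meta = pd.DataFrame({"source": [f"metaPC{i + 1}" for i in range(k)], "kind": ["meta"] * k})
    fm = DonorFeatureMatrix(
        X=scores, y=ages, donor_ids=donors, column_meta=meta,
        cell_type="+".join(cell_types), is_gene=False,
    )
    return fm, dropped


def pseudo_bulk_features(
    dataset: CellExpressionDataset,
    genes: GeneSet | list[str] | None = None,
    min_cells: int = 10,
) -> DonorFeatureMatrix:
    """Polynomial features over ALL of a donor's cells, regardless of type."""
    U, V, retained, _ = aggregate_donor_stats(dataset, None, genes, min_cells)
    ages = dataset.ages().loc[retained]
    donor_of_cell = dataset.cell_annotations["donor_id"].astype(str).to_numpy()
    counts = {d: int((donor_of_cell == d).sum()) for d in retained}
    return polynomial_expand(U, V, ages, cell_type=None, n_cells_per_donor=counts)


def gene_space_features(
    dataset: CellExpressionDataset,
    cell_type: str | None,
    genes: GeneSet | list[str] | None = None,
    min_cells: int = 10,
) -> DonorFeatureMatrix:
    """Convenience: aggregate + polynomial_expand in gene space."""
    U, V, retained, _ = aggregate_donor_stats(dataset, cell_type, genes, min_cells)
    ages = dataset.ages().loc[retained]
    mask = _cells_of_type(dataset, cell_type)
    donor_of_cell = dataset.cell_annotations["donor_id"].astype(str).to_numpy()
    counts = {d: int((mask & (donor_of_cell == d)).sum()) for d in retained}
    return polynomial_expand(
        U, V, ages, cell_type=cell_type, n_cells_per_donor=counts
    )
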