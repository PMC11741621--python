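"""Leave-one-out and cross-dataset evaluation of age-prediction pipelines.

Both schemes score with the coefficient of determination R^2 over donors.
Leave-one-out (LOO) holds out one donor at a time: features, any PCA
transform, and hyperparameters are all rebuilt/re-tuned without the held-out
donor, so no information leaks from the test donor into training. The
cross-dataset (CD) scheme trains one model on pooled training-cohort donors
and predicts every donor of held-out cohorts, after restricting both sides to
their shared genes.

Evaluations are repeated (five runs in the reference protocol); run-to-run
variability comes from tuning randomness (search sampling and inner-CV fold
shuffling), with per-run seeds derived deterministically from a master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from ._seeds import derive_seed
from .features import (
    CellPCATransform,
    DonorFeatureMatrix,
    gene_space_features,
    pca_features,
    pseudo_bulk_features,
)
from .io import CellExpressionDataset, GeneSet, IntegrityError, intersect_genes
from .model import MODEL_KINDS, SearchSpace

__all__ = [
    "PipelineConfig",
    "EvaluationResult",
    "r2_score",
    "loo_evaluate",
    "cross_dataset_evaluate",
    "compare_methods",
    "top_k_results",
    "summarize_runs",
]


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot.

    SS_tot is taken about the mean of ``y_true``; the score is 1 only for
    exact predictions and can be arbitrarily negative for poor predictors.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-d arrays of equal length")
    if len(y_true) < 2:
        raise ValueError("need at least 2 observations")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("y_true is constant; R^2 is undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class PipelineConfig:
    """What to featurize and which model to fit.

    ``cell_type`` None selects pseudo-bulk aggregation over all cells.
    ``pca_k`` None keeps gene-space features; an integer projects cell-level
    expression onto that many training-fitted principal components first.
    """

    cell_type: str | None = None
    gene_set: GeneSet | None = None
    pca_k: int | None = None
    model_kind: str = "polyen"
    min_cells: int = 10
    search: SearchSpace = field(default_factory=SearchSpace)
    pseudo_bulk: bool = False
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(
                f"unknown model kind {self.model_kind!r}; choose from {sorted(MODEL_KINDS)}"
            )

    def describe(self) -> dict:
        return {
            "cell_type": self.cell_type,
            "gene_set": self.gene_set.name if self.gene_set else None,
            "pca_k": self.pca_k,
            "model_kind": self.model_kind,
            "min_cells": self.min_cells,
            "pseudo_bulk": self.pseudo_bulk,
        }


@dataclass
class EvaluationResult:
    """Predicted vs true ages and per-run R^2 for one pipeline evaluation."""

    scheme: str  # "LOO" or "CD"
    predictions: pd.DataFrame  # columns: run, donor_id, true_age, predicted_age
    r2_per_run: list[float]
    pipeline: dict
    n_runs: int
    dropped_donors: list[str] = field(default_factory=list)
    fold_train_donors: dict = field(default_factory=dict)  # (run, held-out donor) -> train donors

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2_per_run))

    @property
    def sd_r2(self) -> float:
        return float(np.std(self.r2_per_run, ddof=1)) if self.n_runs > 1 else 0.0

    def __post_init__(self) -> None:
        if len(self.r2_per_run) != self.n_runs:
            raise ValueError("r2_per_run must have one entry per run")
        per_run = self.predictions.groupby("run")["donor_id"].nunique()
        counts = self.predictions.groupby("run")["donor_id"].size()
        if not (per_run == counts).all():
            raise IntegrityError("a donor was predicted more than once in a run")


def _build_features(
    dataset: CellExpressionDataset,
    config: PipelineConfig,
    fit_donors: list[str] | None = None,
    transform: CellPCATransform | None = None,
) -> tuple[DonorFeatureMatrix, CellPCATransform | None]:
    if config.pseudo_bulk or config.cell_type is None:
        return pseudo_bulk_features(dataset, config.gene_set, config.min_cells), None
    if config.pca_k is None:
        return (
            gene_space_features(dataset, config.cell_type, config.gene_set, config.min_cells),
            None,
        )
    fm, tf = pca_features(
        dataset,
        config.cell_type,
        config.gene_set,
        k=config.pca_k,
        min_cells=config.min_cells,
        fit_donors=fit_donors,
        transform=transform,
    )
    return fm, tf


def _fit(fm: DonorFeatureMatrix, config: PipelineConfig, seed: int):
    fitter = MODEL_KINDS[config.model_kind]
    return fitter(fm, config.search, seed, standardize=config.standardize)


def _predict_for_kind(model, fm: DonorFeatureMatrix, config: PipelineConfig) -> np.ndarray:
    if config.model_kind in ("baseline_lasso", "baseline_en"):
        fm = fm.select_kinds(("mean1",))
    return model.predict(fm)


def loo_evaluate(
    dataset: CellExpressionDataset,
    config: PipelineConfig,
    n_runs: int = 5,
    seed: int = 0,
) -> EvaluationResult:
    """Leave-one-out evaluation with per-fold feature building and tuning.

    Donors failing the ``min_cells`` filter are excluded from both training and
    scoring and reported in ``dropped_donors``. Each run differs only through
    the derived tuning seed.
    """
    full_fm, _ = _build_features(dataset, config)
    donors = full_fm.donor_ids
    if len(donors) < 3:
        raise ValueError(f"need >= 3 donors after filtering, got {len(donors)}")
    dropped = [d for d in dataset.donor_ids if d not in set(donors)]

    rows = []
    r2s = []
    fold_train: dict = {}
    for run in range(n_runs):
        preds = {}
        for i, held_out in enumerate(donors):
            train_donors = [d for d in donors if d != held_out]
            fold_seed = derive_seed(seed, "loo", run, i)
            if config.pca_k is None:
                train_fm = full_fm.subset_donors(train_donors)
                test_fm = full_fm.subset_donors([held_out])
            else:
                # PCA refit on training cells only; held-out cells projected
                # with the training loadings.
                train_fm, tf = _build_features(
                    dataset.subset_donors(train_donors), config, fit_donors=train_donors
                )
                test_fm, _ = _build_features(
                    dataset.subset_donors([held_out]), config, transform=tf
                )
            model = _fit(train_fm, config, fold_seed)
            preds[held_out] = float(_predict_for_kind(model, test_fm, config)[0])
            fold_train[(run, held_out)] = list(train_fm.donor_ids)
        truth = {d: a for d, a in zip(full_fm.donor_ids, full_fm.y)}
        y_true = np.array([truth[d] for d in donors])
        y_pred = np.array([preds[d] for d in donors])
        r2s.append(r2_score(y_true, y_pred))
        rows += [
            {"run": run, "donor_id": d, "true_age": truth[d], "predicted_age": preds[d]}
            for d in donors
        ]
    return EvaluationResult(
        scheme="LOO",
        predictions=pd.DataFrame(rows),
        r2_per_run=r2s,
        pipeline=config.describe(),
        n_runs=n_runs,
        dropped_donors=dropped,
        fold_train_donors=fold_train,
    )


def _pool_feature_matrices(parts: list[DonorFeatureMatrix]) -> DonorFeatureMatrix:
    base = parts[0]
    for p in parts[1:]:
        if p.column_names != base.column_names:
            raise ValueError("feature columns differ across datasets; intersect genes first")
    X = np.vstack([p.X for p in parts])
    y = np.concatenate([p.y for p in parts])
    donors = [d for p in parts for d in p.donor_ids]
    counts = {d: c for p in parts for d, c in p.n_cells_per_donor.items()}
    return DonorFeatureMatrix(
        X=X, y=y, donor_ids=donors, column_meta=base.column_meta,
        cell_type=base.cell_type, n_cells_per_donor=counts, is_gene=base.is_gene,
    )


def cross_dataset_evaluate(
    train_datasets: list[CellExpressionDataset],
    test_datasets: list[CellExpressionDataset],
    config: PipelineConfig,
    n_runs: int = 5,
    seed: int = 0,
    allow_overlap: bool = False,
) -> EvaluationResult:
    """Train on pooled training cohorts, predict donors of held-out cohorts.

    All datasets are first restricted to the genes shared by every cohort;
    train and test donor sets must be disjoint (asserted, not assumed).
    ``allow_overlap`` disables that integrity check for deliberate harness
    self-checks (scoring the training set itself); never use it for reported
    evaluations.
    """
    if not train_datasets or not test_datasets:
        raise ValueError("need at least one training and one test dataset")
    train_ids = {d for ds in train_datasets for d in ds.donor_ids}
    test_ids = {d for ds in test_datasets for d in ds.donor_ids}
    overlap = train_ids & test_ids
    if overlap and not allow_overlap:
        raise IntegrityError(f"donors present in both partitions: {sorted(overlap)}")

    # shared gene panel across every cohort, in the first training cohort's order
    reference = train_datasets[0]
    for other in train_datasets[1:] + test_datasets:
        reference, _ = intersect_genes(reference, other)
    shared = reference.gene_ids
    train_datasets = [ds.subset_genes(shared) for ds in train_datasets]
    test_datasets = [ds.subset_genes(shared) for ds in test_datasets]

    rows, r2s = [], []
    fold_train: dict = {}
    for run in range(n_runs):
        run_seed = derive_seed(seed, "cd", run)
        train_parts = []
        transform = None
        if config.pca_k is not None:
            pooled_cells = _concat_datasets(train_datasets)
            train_fm, transform = _build_features(pooled_cells, config)
        else:
            for ds in train_datasets:
                fm, _ = _build_features(ds, config)
                train_parts.append(fm)
            train_fm = _pool_feature_matrices(train_parts)
        model = _fit(train_fm, config, run_seed)

        preds, truth = {}, {}
        for ds in test_datasets:
            fm, _ = _build_features(ds, config, transform=transform)
            p = _predict_for_kind(model, fm, config)
            for d, t, v in zip(fm.donor_ids, fm.y, p):
                preds[d], truth[d] = float(v), float(t)
        donors = sorted(preds)
        y_true = np.array([truth[d] for d in donors])
        y_pred = np.array([preds[d] for d in donors])
        r2s.append(r2_score(y_true, y_pred))
        rows += [
            {"run": run, "donor_id": d, "true_age": truth[d], "predicted_age": preds[d]}
            for d in donors
        ]
        fold_train[(run, "*")] = list(train_fm.donor_ids)
    return EvaluationResult(
        scheme="CD",
        predictions=pd.DataFrame(rows),
        r2_per_run=r2s,
        pipeline=config.describe(),
        n_runs=n_runs,
        fold_train_donors=fold_train,
    )


def _concat_datasets(datasets: list[CellExpressionDataset]) -> CellExpressionDataset:
    values = np.vstack([ds.values for ds in datasets])
    cells = pd.concat([ds.cell_annotations for ds in datasets], ignore_index=True)
    donors = pd.concat([ds.donor_annotations for ds in datasets], ignore_index=True)
    donors = donors.drop_duplicates("donor_id").reset_index(drop=True)
    return CellExpressionDataset(
        values=values, cell_annotations=cells, donor_annotations=donors,
        gene_ids=list(datasets[0].gene_ids), normalized=True, name="pooled",
    )


def top_k_results(mean_r2_by_cell_type: dict[str, float], k: int = 10) -> list[float]:
    """The k highest per-cell-type mean R^2 values for one method."""
    return sorted(mean_r2_by_cell_type.values(), reverse=True)[:k]


def compare_methods(results_a: list[float], results_b: list[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two methods' per-cell-type R^2 samples.

    Returns the U statistic of the first sample and the two-sided p-value.
    """
    if not results_a or not results_b:
        raise ValueError("both R^2 samples must be non-empty")
    res = mannwhitneyu(results_a, results_b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def summarize_runs(results: list[EvaluationResult]) -> pd.DataFrame:
    """Summary table sorted by mean R^2; non-positive means are flagged.

    One row per evaluated pipeline (cell type x gene set), mirroring the
    bar-chart presentation where rows with mean R^2 <= 0 are rendered barless.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "scheme": r.scheme,
                "cell_type": r.pipeline.get("cell_type"),
                "gene_set": r.pipeline.get("gene_set"),
                "model_kind": r.pipeline.get("model_kind"),
                "pca_k": r.pipeline.get("pca_k"),
                "mean_r2": r.mean_r2,
                "sd_r2": r.sd_r2,
                "n_runs": r.n_runs,
                "flagged_nonpositive": r.mean_r2 <= 0,
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values("mean_r2", ascending=False).reset_index(drop=True)
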