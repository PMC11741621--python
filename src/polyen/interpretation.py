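"""Shapley-value feature attribution, gene importance and empirical p-values.

For a linear model the Shapley attribution under feature independence has an
exact closed form: the attribution of feature j for donor d is

    phi_dj = w_j * (x_dj - E_ref[x_j])

where the expectation runs over a reference (background) population, by
default the training donors themselves. The baseline value is the expected
prediction over the reference, and local accuracy holds exactly:
baseline + sum_j phi_dj = prediction(d).

Gene-level importance aggregates a gene's four polynomial columns (mean,
variance, and their squares) as the sum of mean absolute attributions.
Empirical p-values come from a label permutation scheme: donor ages are
shuffled, the full pipeline (tune, fit, attribute, aggregate) is re-run, and
p(g) = (1 + #{null >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .features import FEATURE_KINDS, DonorFeatureMatrix
from .model import MODEL_KINDS, ElasticNetModel, SearchSpace

__all__ = [
    "ImportanceReport",
    "compute_shap",
    "aggregate_gene_scores",
    "permutation_pvalues",
    "explain",
    "export_preranked",
]


def compute_shap(
    model: ElasticNetModel,
    features: DonorFeatureMatrix | np.ndarray,
    reference: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Exact linear Shapley attributions and the reference baseline value.

    ``reference`` defaults to the rows of ``features`` (training donors as
    their own background). Returns ``(shap, baseline)`` with ``shap`` of shape
    (donors, features).
    """
    X = features.X if isinstance(features, DonorFeatureMatrix) else np.asarray(features, float)
    if X.shape[1] != len(model.coef_):
        raise ValueError(
            f"model has {len(model.coef_)} coefficients but X has {X.shape[1]} columns"
        )
    ref = X if reference is None else np.asarray(reference, dtype=float)
    if ref.shape[1] != X.shape[1]:
        raise ValueError("reference must have the same columns as X")
    ref_mean = ref.mean(axis=0)
    shap = (X - ref_mean) * model.coef_
    baseline = float(ref_mean @ model.coef_ + model.intercept_)
    return shap, baseline


def aggregate_gene_scores(shap: np.ndarray, column_meta: pd.DataFrame) -> pd.Series:
    """Per-source importance: sum over feature kinds of mean |attribution|.

    Sources are genes in gene space; for PC-space models the scores aggregate
    to PCs instead (callers should check ``DonorFeatureMatrix.is_gene``).
    """
    if shap.shape[1] != len(column_meta):
        raise ValueError("column_meta must describe every column of the attribution matrix")
    mean_abs = np.abs(shap).mean(axis=0)
    scores = (
        pd.DataFrame({"source": column_meta["source"].to_numpy(), "score": mean_abs})
        .groupby("source", sort=False)["score"]
        .sum()
    )
    return scores


def per_kind_scores(shap: np.ndarray, column_meta: pd.DataFrame) -> pd.DataFrame:
    """Mean |attribution| per (source, kind) — first- vs second-order comparison.

    Supports examining whether a gene's importance is carried by its mean, its
    variance, or their second-degree terms.
    """
    table = pd.DataFrame(
        {
            "source": column_meta["source"].to_numpy(),
            "kind": column_meta["kind"].to_numpy(),
            "score": np.abs(shap).mean(axis=0),
        }
    )
    wide = table.pivot_table(index="source", columns="kind", values="score", sort=False)
    order = [k for k in FEATURE_KINDS if k in wide.columns]
    return wide[order] if order else wide


def empirical_pvalues(observed: pd.Series, null_scores: np.ndarray) -> pd.Series:
    """Add-one permutation p-values: (1 + #{null >= observed}) / (n_perm + 1).

    ``null_scores`` has one row per permutation, columns aligned with
    ``observed``. Monotone rescaling of both observed and null scores leaves
    the p-values unchanged (only exceedance counts matter).
    """
    null_scores = np.asarray(null_scores, dtype=float)
    if null_scores.ndim != 2 or null_scores.shape[1] != len(observed):
        raise ValueError("null_scores must be (n_perm, n_sources) aligned with observed")
    n_perm = null_scores.shape[0]
    exceed = (null_scores >= observed.to_numpy()).sum(axis=0)
    return pd.Series((1 + exceed) / (n_perm + 1), index=observed.index, name="p_value")


@dataclass
class ImportanceReport:
    """SHAP attributions with gene-level scores, ranks and empirical p-values."""

    shap: np.ndarray
    baseline_value: float
    gene_scores: pd.Series
    column_meta: pd.DataFrame
    donor_ids: list[str]
    p_values: pd.Series | None = None
    n_permutations: int = 0
    kind_scores: pd.DataFrame | None = None
    coef_scores: pd.Series | None = None  # alternate ranking: aggregated |coefficient|
    is_gene: bool = True

    @property
    def ranks(self) -> pd.Series:
        """Dense 1..n ranking, largest score first (ties broken by source order)."""
        order = np.lexsort((np.arange(len(self.gene_scores)), -self.gene_scores.to_numpy()))
        ranks = np.empty(len(order), dtype=int)
        ranks[order] = np.arange(1, len(order) + 1)
        return pd.Series(ranks, index=self.gene_scores.index, name="rank")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"score": self.gene_scores, "rank": self.ranks})
        if self.coef_scores is not None:
            out["coef_score"] = self.coef_scores
        if self.p_values is not None:
            out["p_value"] = self.p_values
        return out.sort_values("rank")


def explain(
    model: ElasticNetModel,
    features: DonorFeatureMatrix,
    reference: np.ndarray | None = None,
) -> ImportanceReport:
    """Attribute a fitted model's predictions and aggregate to gene scores."""
    fm = features
    if len(model.coef_) != fm.n_features:
        # baselines are fitted on the mean-expression columns only
        fm = features.select_kinds(("mean1",))
        if len(model.coef_) != fm.n_features:
            raise ValueError("model and feature matrix have incompatible columns")
    shap, baseline = compute_shap(model, fm, reference)
    coef_scores = (
        pd.DataFrame({"source": fm.column_meta["source"].to_numpy(),
                      "score": np.abs(model.coef_)})
        .groupby("source", sort=False)["score"]
        .sum()
    )
    return ImportanceReport(
        shap=shap,
        baseline_value=baseline,
        gene_scores=aggregate_gene_scores(shap, fm.column_meta),
        column_meta=fm.column_meta,
        donor_ids=fm.donor_ids,
        kind_scores=per_kind_scores(shap, fm.column_meta),
        coef_scores=coef_scores,
        is_gene=fm.is_gene,
    )


def permutation_pvalues(
    features: DonorFeatureMatrix,
    observed_scores: pd.Series,
    n_perm: int = 200,
    seed: int = 0,
    model_kind: str = "polyen",
    space: SearchSpace | None = None,
) -> tuple[pd.Series, np.ndarray]:
    """Empirical gene p-values from an age-permutation null.

    For each permutation the donor ages are shuffled (the feature matrix is
    untouched), hyperparameters are re-tuned, the model refit, attributions
    recomputed and aggregated. Returns the p-values and the (n_perm, n_genes)
    matrix of null scores.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    fitter = MODEL_KINDS[model_kind]
    rng = np.random.default_rng(derive_seed(seed, "perm"))
    nulls = np.empty((n_perm, len(observed_scores)))
    sources = list(observed_scores.index)
    for b in range(n_perm):
        shuffled = DonorFeatureMatrix(
            X=features.X,
            y=rng.permutation(features.y),
            donor_ids=features.donor_ids,
            column_meta=features.column_meta,
            cell_type=features.cell_type,
            n_cells_per_donor=features.n_cells_per_donor,
            is_gene=features.is_gene,
        )
        model = fitter(shuffled, space, derive_seed(seed, "perm-fit", b))
        report = explain(model, shuffled)
        nulls[b] = report.gene_scores.reindex(sources).to_numpy()
    return empirical_pvalues(observed_scores, nulls), nulls


def export_preranked(gene_scores: pd.Series, path: str, *, is_gene: bool = True) -> None:
    """Write a GSEA pre-ranked ``.rnk`` file (gene TAB score, descending).

    Only gene-space scores may be exported; PC-space importances have no gene
    identity and preranked enrichment would be meaningless.
    """
    if not is_gene:
        raise ValueError(
            "scores are in PC space; re-featurize in gene space before exporting .rnk"
        )
    if gene_scores.index.duplicated().any():
        dupes = gene_scores.index[gene_scores.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene symbols in scores: {dupes}")
    ordered = gene_scores.sort_values(ascending=False)
    ordered.to_csv(path, sep="\t", header=False)


def read_preranked(path: str) -> pd.Series:
    """Read back a ``.rnk`` file written by :func:`export_preranked`."""
    table = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return pd.Series(table[1].to_numpy(), index=table.index.astype(str), name="score")
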