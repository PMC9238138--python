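"""Feature engineering: the exact representations the classifiers train on.

Pipeline order is fixed: variability (mean-absolute-deviation) selection on
unstandardized values, then per-column z-scoring, then (optionally) PCA.
Covariates — one-hot cancer type plus log10(mutation count + 1) — form a
block appended after all predictor columns.

Transformers follow the scikit-learn fit/transform contract and operate on
pandas DataFrames, preserving sample index and column names. Two fit scopes
are supported: ``paper_faithful`` (statistics fitted on the whole matrix, as
in whole-dataset preprocessing) and ``leakage_safe`` (fit on training
samples only), selected by which samples the caller passes as
``fit_samples``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .synthetic import OmicsDataset

__all__ = [
    "FeatureMatrix",
    "ColumnStandardizer",
    "MeanDeviationSelector",
    "MethylationImputer",
    "PCACompressor",
    "standardize",
    "select_top_mad",
    "impute_methylation",
    "pca_compress",
    "build_covariates",
    "assemble_feature_matrix",
]

#: Default raw-mode feature budgets per modality kind (None = keep all).
DEFAULT_RAW_K = {
    "expression": 8000,
    "methylation_27k": None,
    "methylation_450k": 100_000,
    "rppa": None,
    "mirna": None,
    "mutational_signatures": None,
}


@dataclass
class FeatureMatrix:
    """Assembled design matrix: predictors then covariates, with provenance."""

    values: pd.DataFrame
    column_provenance: dict[str, str] = field(default_factory=dict)
    n_covariates: int = 0

    @property
    def predictor_columns(self) -> list[str]:
        cols = list(self.values.columns)
        return cols[: len(cols) - self.n_covariates]

    @property
    def covariate_columns(self) -> list[str]:
        cols = list(self.values.columns)
        return cols[len(cols) - self.n_covariates :]


class ColumnStandardizer(BaseEstimator, TransformerMixin):
    """Per-column z-scoring; zero-variance columns map to all-zeros.

    ``ddof=0`` (population SD) by default; set ``ddof=1`` for the sample
    estimator.
    """

    def __init__(self, ddof: int = 0):
        self.ddof = ddof

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        if X.shape[0] == 0:
            raise ValueError("cannot fit standardizer on zero samples")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=self.ddof)
        self.scale_ = sd.where(sd > 0, 1.0)
        self.zero_variance_ = sd == 0
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        out = (X - self.mean_) / self.scale_
        if self.zero_variance_.any():
            out.loc[:, self.zero_variance_[self.zero_variance_].index] = 0.0
        return out


class MeanDeviationSelector(BaseEstimator, TransformerMixin):
    """Keep the k columns with largest mean absolute deviation about the mean.

    Applied before standardization (z-scoring equalizes spread and would make
    the ranking meaningless). Ties broken by column order; k > p keeps all
    columns. ``statistic="median"`` switches to the median-based deviation.
    """

    def __init__(self, k: int, statistic: str = "mean"):
        self.k = k
        self.statistic = statistic

    def fit(self, X: pd.DataFrame, y=None):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        X = pd.DataFrame(X)
        if self.statistic == "mean":
            dev = (X - X.mean(axis=0)).abs().mean(axis=0)
        elif self.statistic == "median":
            dev = (X - X.median(axis=0)).abs().median(axis=0)
        else:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        k = min(self.k, X.shape[1])
        # stable sort on negated deviation -> ties keep original column order
        order = np.argsort(-dev.to_numpy(), kind="stable")[:k]
        keep = np.zeros(X.shape[1], dtype=bool)
        keep[order] = True
        self.selected_columns_ = list(X.columns[keep])  # original order
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.selected_columns_]


class MethylationImputer(BaseEstimator, TransformerMixin):
    """Missing-value policy for methylation-style matrices.

    fit_transform: (1) drop the ``n_drop`` samples with the most missing
    values (skipped when nothing is missing, unless ``always_drop``);
    (2) mean-impute columns with at most ``max_impute`` missing values;
    (3) drop columns that still have missing values. Output is guaranteed
    complete. Sample dropping only happens at fit time; transform on new
    data reuses the fitted column set and means.
    """

    def __init__(self, n_drop: int = 10, max_impute: int = 2, always_drop: bool = False):
        self.n_drop = n_drop
        self.max_impute = max_impute
        self.always_drop = always_drop

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        X = pd.DataFrame(X)
        n_missing = X.isna().sum(axis=1)
        if self.always_drop or int(n_missing.max() or 0) > 0:
            n_drop = min(self.n_drop, len(X))
            # stable sort: ties broken by sample order
            order = np.argsort(-n_missing.to_numpy(), kind="stable")[:n_drop]
            X = X.drop(index=X.index[order])
        col_missing = X.isna().sum(axis=0)
        impute = col_missing[(col_missing >= 1) & (col_missing <= self.max_impute)].index
        drop = col_missing[col_missing > self.max_impute].index
        X = X.drop(columns=drop)
        self.column_means_ = X.mean(axis=0)
        X = X.fillna(self.column_means_)
        self.kept_columns_ = list(X.columns)
        self.n_imputed_columns_ = len(impute)
        self.n_dropped_columns_ = len(drop)
        assert not X.isna().any().any(), "imputer output contains missing values"
        return X

    def fit(self, X: pd.DataFrame, y=None):
        self.fit_transform(X)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)[self.kept_columns_]
        return X.fillna(self.column_means_)


class PCACompressor(BaseEstimator, TransformerMixin):
    """Top-k principal-component scores with a fixed sign convention.

    Retains min(p, k, n_fit - 1) components ordered by decreasing explained
    variance. Each component's sign is fixed so its largest-magnitude loading
    is positive, making scores deterministic across runs and platforms.
    Input is expected standardized.
    """

    def __init__(self, k: int):
        self.k = k

    def fit(self, X: pd.DataFrame, y=None):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        X = pd.DataFrame(X)
        n, p = X.shape
        n_comp = min(p, self.k, n - 1)
        pca = PCA(n_components=n_comp, svd_solver="full" if max(n, p) <= 2000 else "randomized",
                  random_state=0)
        pca.fit(X.to_numpy())
        comp = pca.components_
        flip = np.sign(comp[np.arange(comp.shape[0]), np.abs(comp).argmax(axis=1)])
        flip[flip == 0] = 1.0
        self.components_ = comp * flip[:, None]
        self.mean_ = pca.mean_
        self.explained_variance_ = pca.explained_variance_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        self.n_components_ = n_comp
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        scores = (X.to_numpy() - self.mean_) @ self.components_.T
        cols = [f"pc{j+1}" for j in range(self.n_components_)]
        return pd.DataFrame(scores, index=X.index, columns=cols)


def standardize(
    matrix: pd.DataFrame, fit_samples: pd.Index | None = None, ddof: int = 0
) -> tuple[pd.DataFrame, ColumnStandardizer]:
    """z-score each column using statistics from ``fit_samples`` (default:
    all samples, the whole-dataset mode), applied to all samples."""
    scaler = ColumnStandardizer(ddof=ddof)
    fit_on = matrix if fit_samples is None else matrix.loc[fit_samples]
    scaler.fit(fit_on)
    return scaler.transform(matrix), scaler


def select_top_mad(matrix: pd.DataFrame, k: int, statistic: str = "mean") -> pd.DataFrame:
    sel = MeanDeviationSelector(k=k, statistic=statistic)
    return sel.fit_transform(matrix)


def impute_methylation(
    matrix: pd.DataFrame, n_drop: int = 10, max_impute: int = 2
) -> pd.DataFrame:
    return MethylationImputer(n_drop=n_drop, max_impute=max_impute).fit_transform(matrix)


def pca_compress(
    matrix: pd.DataFrame, k: int, fit_samples: pd.Index | None = None
) -> tuple[pd.DataFrame, PCACompressor]:
    pca = PCACompressor(k=k)
    pca.fit(matrix if fit_samples is None else matrix.loc[fit_samples])
    return pca.transform(matrix), pca


def build_covariates(
    cohort_samples: pd.DataFrame, included_samples: pd.Index
) -> pd.DataFrame:
    """One-hot cancer type (types present among included samples) plus
    log10(mutation count + 1); the +1 offset admits zero-burden samples."""
    sub = cohort_samples.loc[included_samples]
    onehot = pd.get_dummies(sub["cancer_type"], prefix="cancer_type", dtype=float)
    onehot = onehot[sorted(onehot.columns)]
    burden = np.log10(sub["n_mutations"].astype(float) + 1.0)
    out = onehot.copy()
    out["log10_mut_burden"] = burden
    return out


def assemble_feature_matrix(
    datasets: list[OmicsDataset],
    covariates: pd.DataFrame,
    mode: str = "raw",
    per_dataset_k: dict[str, int] | int | None = None,
    fit_samples: pd.Index | None = None,
) -> FeatureMatrix:
    """Concatenate processed modalities column-wise and append covariates.

    mode="raw": deviation-selection (if a k is given for the modality) then
    standardize. mode="pca": standardize then top-k PC scores. All datasets
    must share the sample axis exactly (intersection is the caller's job,
    via io_reporting).
    """
    if mode not in {"raw", "pca"}:
        raise ValueError(f"unknown mode {mode!r}")
    ref = datasets[0].matrix.index
    for ds in datasets[1:]:
        if not ds.matrix.index.equals(ref):
            diff = ref.symmetric_difference(ds.matrix.index)
            raise ValueError(
                f"sample axis mismatch between {datasets[0].name} and {ds.name}: "
                f"{len(diff)} differing samples, e.g. {list(diff[:5])}"
            )
    if not covariates.index.equals(ref):
        diff = ref.symmetric_difference(covariates.index)
        raise ValueError(f"covariate sample axis mismatch: {len(diff)} differing samples")

    def k_for(name: str) -> int | None:
        if per_dataset_k is None:
            return None
        if isinstance(per_dataset_k, int):
            return per_dataset_k
        return per_dataset_k.get(name)

    blocks: list[pd.DataFrame] = []
    provenance: dict[str, str] = {}
    for ds in datasets:
        m = ds.matrix
        k = k_for(ds.name)
        if mode == "raw":
            if k is not None and k < m.shape[1]:
                m = select_top_mad(m, k)
            m, _ = standardize(m, fit_samples)
        else:
            m, _ = standardize(m, fit_samples)
            m, _ = pca_compress(m, k if k is not None else m.shape[1], fit_samples)
            m = m.add_prefix(f"{ds.name}_")
        blocks.append(m)
        provenance.update({c: ds.name for c in m.columns})

    blocks.append(covariates)
    provenance.update({c: "covariate" for c in covariates.columns})
    values = pd.concat(blocks, axis=1)
    return FeatureMatrix(
        values=values, column_provenance=provenance, n_covariates=covariates.shape[1]
    )
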