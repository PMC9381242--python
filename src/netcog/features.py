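"""PCA-based weighting and selection of the seven topology AUC features.

The feature matrix A stacks one row per subject and one column per metric
AUC, in the fixed order (gamma, lambda, sigma, Cp, Lp, Eglobal, Elocal).
Columns are standardized (mean 0, sample SD 1), the 7x7 covariance matrix R
of the standardized columns (equal to the correlation matrix of A) is
eigendecomposed, and each feature receives a weight w_i = lambda_i / sum(lambda)
from the eigenvalue attributed to it. Features whose weight exceeds a
threshold (0.6 by default) are selected; on the clinical cohort this singles
out the local-efficiency AUC.

Attributing eigenvalues of R to *original* features is not well defined
(eigenvalues belong to principal components, not variables). The default
rule matches eigenvalues to features one-to-one: each eigenvalue, largest
first, goes to the still-unclaimed feature its eigenvector loads on most
strongly; ``attribution="by_rank"`` instead pairs the sorted eigenvalues
with the feature columns positionally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .graphmetrics import METRIC_NAMES

__all__ = [
    "FEATURE_COLUMNS",
    "FeatureTable",
    "PCAResult",
    "standardize",
    "covariance_matrix",
    "feature_weights",
    "select_features",
    "project",
    "pca_feature_selection",
]

#: fixed feature-column order (AUC of each metric)
FEATURE_COLUMNS = tuple(f"auc_{m}" for m in METRIC_NAMES)


@dataclass
class FeatureTable:
    """n_subjects x n_features AUC matrix with subject bookkeeping."""

    A: np.ndarray
    column_names: tuple[str, ...] = FEATURE_COLUMNS
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2:
            raise ValueError("A must be 2-D (subjects x features)")
        if self.A.shape[1] != len(self.column_names):
            raise ValueError("column count does not match column_names")
        if not np.isfinite(self.A).all():
            raise ValueError("feature table contains missing values")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.A, columns=list(self.column_names))
        if self.subject_ids is not None:
            df.insert(0, "subject_id", self.subject_ids)
        return df


@dataclass
class PCAResult:
    B: np.ndarray
    R: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    weights: np.ndarray
    selected_indices: np.ndarray
    projected_features: np.ndarray | None = None


def standardize(A: np.ndarray) -> np.ndarray:
    """Column-standardize to mean 0, sample (n-1) SD 1."""
    A = np.asarray(A, dtype=float)
    sd = A.std(axis=0, ddof=1)
    const = np.flatnonzero(sd == 0)
    if const.size:
        raise ValueError(
            f"feature column(s) {const.tolist()} are constant and cannot be "
            "standardized"
        )
    return (A - A.mean(axis=0)) / sd


def covariance_matrix(B: np.ndarray) -> np.ndarray:
    """Sample covariance (n-1 denominator) of the standardized columns.

    On standardized data this equals the correlation matrix of the raw
    features, with unit diagonal.
    """
    B = np.asarray(B, dtype=float)
    n = B.shape[0]
    R = B.T @ B / (n - 1)
    return (R + R.T) / 2.0


def _eigh_sorted(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of symmetric R, descending; signs fixed so each vector's
    largest-magnitude component is positive."""
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(vecs.shape[1]):
        k = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vals, vecs


def feature_weights(R: np.ndarray, attribution: str = "by_loading") -> np.ndarray:
    """Per-feature weights w_i = lambda_i / sum(lambda), summing to 1.

    ``by_loading`` (default) matches eigenvalues to features one-to-one by
    descending eigenvalue, each taking the unclaimed feature its eigenvector
    loads on most strongly; ``by_rank`` attributes the j-th largest
    eigenvalue to the j-th feature column positionally.
    """
    R = np.asarray(R, dtype=float)
    vals, vecs = _eigh_sorted(R)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite eigenvalue in covariance matrix")
    total = vals.sum()
    if attribution == "by_rank":
        attributed = vals
    elif attribution == "by_loading":
        # greedy one-to-one matching: each eigenvalue, largest first, is
        # attributed to the still-unclaimed feature on which its eigenvector
        # loads most strongly (ties broken by feature index), so the weights
        # are a permutation of lambda_i / sum(lambda) and sum to 1
        m = vals.shape[0]
        attributed = np.empty(m)
        unclaimed = np.ones(m, dtype=bool)
        for j in range(m):
            loadings = np.where(unclaimed, np.abs(vecs[:, j]), -1.0)
            i = int(np.argmax(loadings))
            attributed[i] = vals[j]
            unclaimed[i] = False
    else:
        raise ValueError(f"unknown attribution rule {attribution!r}")
    return attributed / total


def select_features(w: np.ndarray, threshold: float = 0.6) -> np.ndarray:
    """Indices of features whose weight exceeds the threshold.

    With weights summing to 1 a threshold above 0.5 admits at most one
    feature; if none clears it, the argmax feature is returned with a
    warning so downstream stages always have a predictor.
    """
    w = np.asarray(w, dtype=float)
    selected = np.flatnonzero(w > threshold)
    if selected.size == 0:
        warnings.warn(
            f"no feature weight exceeds {threshold}; falling back to the "
            "highest-weight feature",
            stacklevel=2,
        )
        selected = np.array([int(np.argmax(w))])
    return selected


def project(B: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Project standardized data onto one eigenvector: c = B @ v."""
    B = np.asarray(B, dtype=float)
    v = np.asarray(v, dtype=float)
    if B.shape[1] != v.shape[0]:
        raise ValueError("eigenvector length does not match feature count")
    return B @ v


def pca_feature_selection(
    table: FeatureTable,
    threshold: float = 0.6,
    attribution: str = "by_loading",
    with_projection: bool = False,
) -> PCAResult:
    """Full weighting/selection pass over a feature table."""
    B = standardize(table.A)
    R = covariance_matrix(B)
    vals, vecs = _eigh_sorted(R)
    w = feature_weights(R, attribution=attribution)
    selected = select_features(w, threshold=threshold)
    projected = None
    if with_projection:
        projected = np.column_stack([project(B, vecs[:, j])
                                     for j in range(vecs.shape[1])])
    return PCAResult(B=B, R=R, eigenvalues=vals, eigenvectors=vecs,
                     weights=w, selected_indices=selected,
                     projected_features=projected)


def weights_report(weights: np.ndarray,
                   column_names: tuple[str, ...] = FEATURE_COLUMNS) -> pd.DataFrame:
    """Weights as a (feature, weight_percent) table."""
    return pd.DataFrame({"feature": list(column_names),
                         "weight_percent": 100.0 * np.asarray(weights)})
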