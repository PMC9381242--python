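"""End-to-end prediction frameworks and group-level statistics.

Four variants are assembled from the same graph-theory + PCA (GP) feature
front end:

* ``GPSV``    — eps-insensitive SVR baseline (stock implementation),
* ``GPLSV``   — LSSVR with fixed default kernel hyperparameters,
* ``GPWLSV``  — LSSVR tuned by the standard whale optimization algorithm,
* ``GPLWLSV`` — LSSVR tuned by the Levy-flight whale optimizer.

Evaluation is stratified k-fold cross-validation (default ten-fold) on the
patient group's scores, reporting RMSE, MAE and MAPE per fold and their
averages. Stratification bins the continuous score into quantile bins so
every fold sees the full score range. Feature extraction (graph metrics)
uses no labels, so it is computed once per subject before the folds; feature
selection and hyperparameter tuning are fitted inside each training fold.

Group-level operations compare the metric AUCs between patients and
controls (two-sample t) and associate regional node efficiency with the
cognition score (per-region Pearson r, p).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import lssvr as _lssvr
from . import lwoa as _lwoa
from .connectome import correlation_matrix, fisher_z, sparsity_grid
from .features import (FEATURE_COLUMNS, FeatureTable, pca_feature_selection)
from .graphmetrics import (METRIC_NAMES, NullConfig, auc, metric_curves,
                           node_efficiency)
from .connectome import binarize_at_sparsity
from .synthetic_cohort import Cohort

__all__ = [
    "VARIANTS",
    "FrameworkVariant",
    "PipelineConfig",
    "CVReport",
    "stratified_kfold",
    "evaluate_metrics",
    "aggregate_folds",
    "compute_feature_table",
    "run_framework",
    "group_compare_metric",
    "group_compare_table",
    "compute_node_efficiency_auc",
    "efficiency_score_association",
]


@dataclass(frozen=True)
class FrameworkVariant:
    name: str
    regressor: str  # "svr" | "lssvr"
    tuner: str      # "none" | "woa" | "lwoa"


VARIANTS = {
    "GPSV": FrameworkVariant("GPSV", "svr", "none"),
    "GPLSV": FrameworkVariant("GPLSV", "lssvr", "none"),
    "GPWLSV": FrameworkVariant("GPWLSV", "lssvr", "woa"),
    "GPLWLSV": FrameworkVariant("GPLWLSV", "lssvr", "lwoa"),
}


@dataclass
class PipelineConfig:
    """All knobs of the cross-validated prediction pipeline."""

    k_folds: int = 10
    n_score_bins: int = 5
    feature_mode: str = "elocal"      # "elocal" (default predictor) or "pca"
    pca_threshold: float = 0.6
    grid: np.ndarray = field(default_factory=sparsity_grid)
    null_config: NullConfig = field(default_factory=NullConfig)
    # fixed LSSVR hyperparameters for the untuned GPLSV variant
    default_J: float = 10.0
    default_sigma2: float = 1.0
    # stock SVR baseline settings
    svr_C: float = 1.0
    svr_epsilon: float = 0.1
    # tuner settings: search in log10 space over (J, sigma2)
    tuner_population: int = 20
    tuner_iters: int = 100
    tuner_bounds_log10: tuple = ((-2.0, 4.0), (-3.0, 3.0))
    tuner_inner_folds: int = 5
    seed: int = 0


@dataclass
class CVReport:
    variant: str
    seed: int
    per_fold: list[tuple[float, float, float]]
    averages: tuple[float, float, float]
    fold_predictions: list[np.ndarray]
    fold_actuals: list[np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"fold": i + 1, "rmse": r, "mae": m, "mape": p}
                for i, (r, m, p) in enumerate(self.per_fold)]
        rows.append({"fold": "average", "rmse": self.averages[0],
                     "mae": self.averages[1], "mape": self.averages[2]})
        return pd.DataFrame(rows)


def stratified_kfold(
    scores: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold assignment stratified by the score's rank order.

    Subjects are ordered by score (ties shuffled), then consecutive blocks
    of k are dealt one subject to each fold in shuffled order. Folds are
    mutually exclusive, cover all subjects, differ in size by at most one,
    and each spans the whole score distribution.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    jitter = rng.random(n)  # random tie-break within equal scores
    order = np.lexsort((jitter, scores))
    folds = np.empty(n, dtype=int)
    for start in range(0, n, k):
        block = order[start:start + k]
        assignment = rng.permutation(k)[: block.size]
        folds[block] = assignment
    return folds


def evaluate_metrics(
    actual: np.ndarray, predicted: np.ndarray
) -> tuple[float, float, float]:
    """(RMSE, MAE, MAPE); MAPE is a fraction and needs nonzero actuals."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.size == 0:
        raise ValueError("actual and predicted must be equal-length, nonempty")
    err = actual - predicted
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    if np.any(actual == 0):
        raise ValueError("MAPE undefined: actual contains zero")
    mape = float(np.mean(np.abs(err) / np.abs(actual)))
    return rmse, mae, mape


def aggregate_folds(per_fold) -> tuple[float, float, float]:
    """Arithmetic mean of per-fold (RMSE, MAE, MAPE) triples."""
    arr = np.asarray(per_fold, dtype=float)
    if arr.size == 0:
        raise ValueError("no folds to aggregate")
    mean = arr.mean(axis=0)
    return float(mean[0]), float(mean[1]), float(mean[2])


# ---------------------------------------------------------------------------
# feature extraction

def compute_feature_table(
    cohort: Cohort, config: PipelineConfig
) -> pd.DataFrame:
    """Per-subject metric-AUC table: subject_id, group, score, auc_*.

    In ``elocal`` mode only the local-efficiency column is computed (the
    default predictor needs nothing else and the normalized-metric null
    models dominate the cost); ``pca`` mode computes all seven.
    """
    if config.feature_mode == "elocal":
        metrics = ("elocal",)
    elif config.feature_mode == "pca":
        metrics = METRIC_NAMES
    else:
        raise ValueError(f"unknown feature_mode {config.feature_mode!r}")
    rows = []
    for s in cohort.subjects:
        zm = fisher_z(correlation_matrix(s.timeseries))
        curves = metric_curves(zm, config.grid, null_config=config.null_config,
                               metrics=metrics)
        row = {"subject_id": s.subject_id, "group": s.group, "score": s.score}
        for m in metrics:
            row[f"auc_{m}"] = curves.aucs[m]
        rows.append(row)
    return pd.DataFrame(rows)


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# regressors and tuning

def _inner_cv_rmse(X, y, params, n_splits, seed) -> float:
    """Mean RMSE of an LSSVR over a seeded inner k-fold split."""
    n = len(y)
    n_splits = max(2, min(n_splits, n))
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    folds = np.array_split(idx, n_splits)
    errs = []
    for i in range(n_splits):
        te = folds[i]
        tr = np.concatenate([folds[j] for j in range(n_splits) if j != i])
        try:
            model = _lssvr.fit(X[tr], y[tr], params)
            pred = _lssvr.predict(model, X[te])
        except np.linalg.LinAlgError:
            return 1.0e9  # degenerate hyperparameters: heavily penalized
        errs.append(np.sqrt(np.mean((y[te] - pred) ** 2)))
    return float(np.mean(errs))


def _tune_lssvr(X, y, variant: str, config: PipelineConfig,
                seed: int) -> _lssvr.KernelParams:
    def objective(pos):
        params = _lssvr.KernelParams(J=10.0 ** pos[0], sigma2=10.0 ** pos[1])
        return _inner_cv_rmse(X, y, params, config.tuner_inner_folds, seed)

    opt_config = _lwoa.OptimizerConfig(
        population_size=config.tuner_population,
        max_iters=config.tuner_iters,
        bounds=config.tuner_bounds_log10,
        variant="levy" if variant == "lwoa" else "standard",
        seed=seed,
    )
    result = _lwoa.optimize(objective, opt_config)
    return _lssvr.KernelParams(J=10.0 ** result.best_position[0],
                               sigma2=10.0 ** result.best_position[1])


def _fit_predict(variant: FrameworkVariant, config: PipelineConfig,
                 X_tr, y_tr, X_te, seed: int) -> np.ndarray:
    if variant.regressor == "svr":
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVR
        model = make_pipeline(
            StandardScaler(),
            SVR(C=config.svr_C, epsilon=config.svr_epsilon))
        model.fit(X_tr, y_tr)
        return model.predict(X_te)
    if variant.tuner == "none":
        params = _lssvr.KernelParams(J=config.default_J,
                                     sigma2=config.default_sigma2)
    else:
        params = _tune_lssvr(X_tr, y_tr, variant.tuner, config, seed)
    model = _lssvr.fit(X_tr, y_tr, params)
    return _lssvr.predict(model, X_te)


def run_framework(
    cohort: Cohort,
    variant: FrameworkVariant | str,
    config: PipelineConfig | None = None,
    feature_table: pd.DataFrame | None = None,
) -> CVReport:
    """Cross-validate one framework variant on the cohort's patient group.

    ``feature_table`` (from :func:`compute_feature_table`) may be supplied
    to reuse label-free feature extraction across variants; otherwise it is
    computed here. Fold assignment, tuner seeds and any selection are all
    derived from ``config.seed``, so identical inputs give identical
    reports.
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant.upper()]
    if config is None:
        config = PipelineConfig()
    if feature_table is None:
        feature_table = compute_feature_table(cohort, config)
    patients = feature_table[feature_table["group"] == "patient"].reset_index(
        drop=True)
    if patients.empty:
        raise ValueError("cohort has no patient subjects to cross-validate")
    y = patients["score"].to_numpy(dtype=float)
    folds = stratified_kfold(y, config.k_folds,
                             np.random.default_rng([config.seed, 1]))

    per_fold, preds, actuals = [], [], []
    for fold in range(config.k_folds):
        te = np.flatnonzero(folds == fold)
        tr = np.flatnonzero(folds != fold)
        cols = _select_columns(patients, tr, config)
        X = patients[cols].to_numpy(dtype=float)
        fold_seed = int(np.random.SeedSequence([config.seed, 2, fold])
                        .generate_state(1)[0] % (2 ** 31))
        pred = _fit_predict(variant, config, X[tr], y[tr], X[te], fold_seed)
        per_fold.append(evaluate_metrics(y[te], pred))
        preds.append(np.asarray(pred))
        actuals.append(y[te])
    return CVReport(variant=variant.name, seed=config.seed, per_fold=per_fold,
                    averages=aggregate_folds(per_fold),
                    fold_predictions=preds, fold_actuals=actuals)


def _select_columns(patients: pd.DataFrame, train_idx, config: PipelineConfig):
    """Feature columns for this fold (PCA selection fitted on training rows)."""
    if config.feature_mode == "elocal":
        return ["auc_elocal"]
    A = patients.loc[train_idx, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    result = pca_feature_selection(FeatureTable(A=A),
                                   threshold=config.pca_threshold)
    return [FEATURE_COLUMNS[i] for i in result.selected_indices]


# ---------------------------------------------------------------------------
# group-level statistics

def group_compare_metric(
    patients: np.ndarray, controls: np.ndarray, welch: bool = False
) -> tuple[float, float]:
    """Two-sample t comparison (patients vs controls), pooled variance by
    default, Welch optional."""
    patients = np.asarray(patients, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if patients.size < 2 or controls.size < 2:
        raise ValueError("need at least two values per group")
    if patients.std(ddof=1) == 0 and controls.std(ddof=1) == 0:
        if np.allclose(patients.mean(), controls.mean()):
            return 0.0, 1.0
        raise ValueError("degenerate zero-variance groups")
    t, p = stats.ttest_ind(patients, controls, equal_var=not welch)
    return float(t), float(p)


def group_compare_table(
    feature_table: pd.DataFrame, welch: bool = False
) -> pd.DataFrame:
    """Patients-vs-controls t test for every metric AUC column present."""
    rows = []
    cols = [c for c in feature_table.columns if c.startswith("auc_")]
    pat = feature_table[feature_table["group"] == "patient"]
    con = feature_table[feature_table["group"] == "control"]
    for c in cols:
        t, p = group_compare_metric(pat[c].to_numpy(), con[c].to_numpy(),
                                    welch=welch)
        rows.append({
            "metric": c, "patient_mean": pat[c].mean(),
            "control_mean": con[c].mean(), "t": t, "p": p,
        })
    return pd.DataFrame(rows)


def compute_node_efficiency_auc(
    cohort: Cohort, grid: np.ndarray | None = None
) -> np.ndarray:
    """Per-subject, per-region node-efficiency AUC over the sparsity grid."""
    if grid is None:
        grid = sparsity_grid()
    out = []
    for s in cohort.subjects:
        zm = fisher_z(correlation_matrix(s.timeseries))
        eff = np.stack([node_efficiency(binarize_at_sparsity(zm, sp))
                        for sp in grid])
        out.append(np.array([auc(eff[:, r], grid)
                             for r in range(eff.shape[1])]))
    return np.stack(out)


def efficiency_score_association(
    node_eff: np.ndarray,
    scores: np.ndarray,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-region Pearson association between node efficiency and score.

    Returns one row per region with (r, p, significant). Significance is
    uncorrected p < alpha by default, mirroring the original analysis;
    ``fdr=True`` applies Benjamini-Hochberg instead. Constant regions are
    skipped with NaN entries.
    """
    node_eff = np.asarray(node_eff, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if node_eff.shape[0] != scores.shape[0] or node_eff.shape[0] < 3:
        raise ValueError("need >= 3 subjects with matching rows")
    rows = []
    for r in range(node_eff.shape[1]):
        col = node_eff[:, r]
        if col.std() == 0 or scores.std() == 0:
            rows.append({"region": r, "r": np.nan, "p": np.nan})
            continue
        rr, pp = stats.pearsonr(col, scores)
        rows.append({"region": r, "r": float(rr), "p": float(pp)})
    df = pd.DataFrame(rows)
    pvals = df["p"].to_numpy()
    ok = np.isfinite(pvals)
    sig = np.zeros(len(df), dtype=bool)
    if fdr and ok.any():
        from statsmodels.stats.multitest import multipletests
        sig[ok] = multipletests(pvals[ok], alpha=alpha, method="fdr_bh")[0]
    else:
        sig[ok] = pvals[ok] < alpha
    df["significant"] = sig
    return df


def with_config_overrides(config: PipelineConfig, **overrides) -> PipelineConfig:
    return replace(config, **overrides)
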