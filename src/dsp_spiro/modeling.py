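"""Spirometric index estimation and evaluation.

Per index (FVC, FEV1, PEF) and breathing mode, models are fit on breath-level
features plus demographic covariates and evaluated by leave-one-subject-out
cross-validation (LOSO-CV): all rows of one subject are held out per fold,
and z-score standardization plus hyperparameter tuning happen strictly inside
each training fold. The elastic net minimizes

    (1/2n) * sum (y_i - b0 - x_i b)^2 + lam * [a*||b||_1 + (1-a)/2*||b||_2^2]

with mixing a in [0,1] and strength lam tuned by inner
leave-one-training-subject-out grid search on subject-level RMSE (ties prefer
the sparser model: larger lam, then larger a). Errors are aggregated per
subject (RMSE/MAE) and averaged, unweighted, across subjects. Breathing modes
are compared with a random-intercept linear mixed model on subject-level
RMSE, tested by a likelihood-ratio test on the mode fixed effect.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.linear_model import ElasticNet

from .errors import DataError, ParameterError
from .features import COVARIATE_COLUMNS, INDEX_TO_TARGET

logger = logging.getLogger(__name__)

#: repeatability benchmarks: acceptable within-subject differences (L, L/s)
REPEATABILITY_THRESHOLDS = {"fvc": 0.15, "fev1": 0.15, "pef": 0.67}


@dataclass(frozen=True)
class ElasticNetConfig:
    alpha_grid: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 11))
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-4
    lambda_grid: Optional[tuple[float, ...]] = None  # overrides the data-driven grid
    tol: float = 1e-7
    max_iter: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.alpha_grid or (self.lambda_grid is not None and not self.lambda_grid):
            raise ParameterError("grids must be nonempty")
        if self.tol <= 0:
            raise ParameterError("tol must be positive")
        if any(not (0 < a <= 1) for a in self.alpha_grid):
            raise ParameterError("mixing values must lie in (0, 1]")


@dataclass(frozen=True)
class FitResult:
    intercept: float
    coefficients: Mapping[str, float]  # original (de-standardized) scale
    chosen_alpha: Optional[float] = None
    chosen_lambda: Optional[float] = None
    feature_means: Optional[Mapping[str, float]] = None
    feature_sds: Optional[Mapping[str, float]] = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        cols = list(self.coefficients.keys())
        beta = np.array([self.coefficients[c] for c in cols])
        if cols:
            return self.intercept + X[cols].to_numpy(dtype=float) @ beta
        return np.full(len(X), self.intercept)


@dataclass(frozen=True)
class ErrorSummary:
    per_subject: pd.DataFrame   # columns: subject_id, rmse, mae
    mean_rmse: float
    mean_mae: float
    se_rmse: float
    se_mae: float
    index: str
    mode: str
    stage: str                  # {"training", "loso"}


@dataclass(frozen=True)
class MixedModelResult:
    estimate: float             # fixed effect of breathing mode
    se: float
    p_value: float              # likelihood-ratio test vs. the no-mode model
    var_subject: float
    var_resid: float
    index: str


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column z-scores; constant columns get SD surrogate 1 (=> zero column,
    coefficient forced 0 by the fit)."""
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)
    return (X - means) / sds, means, sds


def fit_ols(X: pd.DataFrame, y: Sequence[float]) -> FitResult:
    """Least-squares baseline; minimum-norm solution (with a warning) when
    the design is rank deficient."""
    yv = np.asarray(y, dtype=float)
    cols = list(X.columns)
    Xs, means, sds = _standardize(X.to_numpy(dtype=float))
    yc = yv - yv.mean()
    beta_std, _, rank, _ = np.linalg.lstsq(Xs, yc, rcond=None)
    if rank < Xs.shape[1]:
        logger.warning("rank-deficient design (rank %d < %d): minimum-norm fit",
                       rank, Xs.shape[1])
    beta = beta_std / sds
    intercept = float(yv.mean() - means @ beta)
    return FitResult(intercept=intercept,
                     coefficients=dict(zip(cols, beta)),
                     feature_means=dict(zip(cols, means)),
                     feature_sds=dict(zip(cols, sds)))


def fit_elastic_net(X: pd.DataFrame, y: Sequence[float], alpha: float,
                    lam: float, config: ElasticNetConfig | None = None) -> FitResult:
    """Elastic net at fixed (mixing alpha, strength lam); predictors are
    standardized and y centered internally, coefficients de-standardized."""
    config = config or ElasticNetConfig()
    yv = np.asarray(y, dtype=float)
    cols = list(X.columns)
    Xs, means, sds = _standardize(X.to_numpy(dtype=float))
    yc = yv - yv.mean()
    if lam == 0:
        beta_std = np.linalg.lstsq(Xs, yc, rcond=None)[0]
    else:
        model = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                           tol=config.tol, max_iter=config.max_iter)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xs, yc)
        if model.n_iter_ >= config.max_iter:
            raise DataError(f"elastic net did not converge in {config.max_iter} "
                            f"iterations (alpha={alpha}, lambda={lam})")
        beta_std = model.coef_
    beta = beta_std / sds
    intercept = float(yv.mean() - means @ beta)
    return FitResult(intercept=intercept, coefficients=dict(zip(cols, beta)),
                     chosen_alpha=alpha, chosen_lambda=lam,
                     feature_means=dict(zip(cols, means)),
                     feature_sds=dict(zip(cols, sds)))


def lambda_max(X: pd.DataFrame, y: Sequence[float], alpha: float) -> float:
    """Smallest penalty that zeroes every coefficient on standardized data."""
    yv = np.asarray(y, dtype=float)
    Xs, _, _ = _standardize(X.to_numpy(dtype=float))
    yc = yv - yv.mean()
    return float(np.max(np.abs(Xs.T @ yc)) / (len(yv) * alpha))


def _lambda_grid(X: pd.DataFrame, y: Sequence[float], alpha: float,
                 config: ElasticNetConfig) -> np.ndarray:
    if config.lambda_grid is not None:
        return np.sort(np.asarray(config.lambda_grid, dtype=float))[::-1]
    lmax = max(lambda_max(X, y, alpha), 1e-12)
    return np.geomspace(lmax, lmax * config.lambda_min_ratio, config.n_lambda)


def _path_predict(X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray,
                  alpha: float, lambdas: np.ndarray,
                  config: ElasticNetConfig) -> np.ndarray:
    """Predictions of the λ path (descending) on held-out rows; warm-started
    coordinate descent. Returns (len(lambdas), n_test)."""
    Xs, means, sds = _standardize(X_tr)
    ybar = y_tr.mean()
    yc = y_tr - ybar
    Xte_s = (X_te - means) / sds
    model = ElasticNet(alpha=lambdas[0], l1_ratio=alpha, fit_intercept=False,
                       warm_start=True, tol=config.tol, max_iter=config.max_iter)
    out = np.empty((len(lambdas), len(X_te)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, lam in enumerate(lambdas):
            model.set_params(alpha=lam)
            model.fit(Xs, yc)
            out[i] = ybar + Xte_s @ model.coef_
    return out


def tune_in_fold(train: pd.DataFrame, feature_cols: Sequence[str],
                 target_col: str, config: ElasticNetConfig | None = None,
                 subject_col: str = "subject_id"
                 ) -> tuple[float, float, FitResult]:
    """Inner leave-one-training-subject-out grid search over (alpha, lambda),
    minimizing mean subject-level RMSE; ties prefer larger lambda, then
    larger alpha. The winner is refit on all training rows."""
    config = config or ElasticNetConfig()
    subjects = train[subject_col].unique()
    if len(subjects) < 3:
        raise DataError("inner CV undefined with fewer than 3 training subjects")
    feature_cols = list(feature_cols)
    X_all = train[feature_cols]
    y_all = train[target_col].to_numpy(dtype=float)
    if not feature_cols:
        fit = FitResult(intercept=float(y_all.mean()), coefficients={})
        return (config.alpha_grid[-1], 0.0, fit)
    grids = {a: _lambda_grid(X_all, y_all, a, config) for a in config.alpha_grid}
    # sq_err[a][j] accumulates per-subject RMSE over inner folds
    rmse_acc = {a: np.zeros(len(grids[a])) for a in config.alpha_grid}
    Xmat = X_all.to_numpy(dtype=float)
    for s in subjects:
        mask = (train[subject_col] == s).to_numpy()
        X_tr, y_tr = Xmat[~mask], y_all[~mask]
        X_te, y_te = Xmat[mask], y_all[mask]
        for a in config.alpha_grid:
            preds = _path_predict(X_tr, y_tr, X_te, a, grids[a], config)
            rmse_acc[a] += np.sqrt(np.mean((preds - y_te) ** 2, axis=1))
    n_s = len(subjects)
    best = None  # (score, lam, alpha)
    for a in config.alpha_grid:
        scores = rmse_acc[a] / n_s
        for j, lam in enumerate(grids[a]):
            cand = (scores[j], lam, a)
            if best is None or cand[0] < best[0] or (
                    cand[0] == best[0] and (cand[1], cand[2]) > (best[1], best[2])):
                best = cand
    _, lam_star, alpha_star = best
    fit = fit_elastic_net(X_all, y_all, alpha_star, lam_star, config)
    return alpha_star, lam_star, fit


def summarize_errors(preds: pd.DataFrame, stage: str = "loso") -> ErrorSummary:
    """Subject-level RMSE and MAE, averaged (unweighted) across subjects."""
    if len(preds) == 0:
        raise DataError("no predictions to summarize")
    err = preds["y_pred"] - preds["y_true"]
    per = (preds.assign(sq=err ** 2, ab=err.abs())
           .groupby("subject_id", sort=True)
           .agg(rmse=("sq", lambda v: float(np.sqrt(v.mean()))),
                mae=("ab", "mean"))
           .reset_index())
    n = len(per)
    se = lambda v: float(v.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return ErrorSummary(per_subject=per,
                        mean_rmse=float(per["rmse"].mean()),
                        mean_mae=float(per["mae"].mean()),
                        se_rmse=se(per["rmse"]), se_mae=se(per["mae"]),
                        index=str(preds["index"].iloc[0]),
                        mode=str(preds["mode"].iloc[0]), stage=stage)


def run_loso_cv(table: pd.DataFrame, index: str, mode: Optional[str],
                model: str = "enet", config: ElasticNetConfig | None = None,
                feature_cols: Optional[Sequence[str]] = None,
                include_covariates: bool = True
                ) -> tuple[pd.DataFrame, ErrorSummary, ErrorSummary]:
    """Outer LOSO-CV for one index and mode.

    Returns (held-out predictions, LOSO error summary, training error
    summary). The training summary refits the selected procedure on all rows
    and predicts all rows.
    """
    config = config or ElasticNetConfig()
    if model not in ("ols", "enet"):
        raise ParameterError(f"unknown model {model!r}")
    target_col = INDEX_TO_TARGET.get(index, index)
    data = table if mode is None else table[table["mode"] == mode]
    data = data.reset_index(drop=True)
    if data[target_col].isna().any():
        raise DataError("missing reference targets")
    subjects = data["subject_id"].unique()
    if len(subjects) < 3:
        raise DataError("LOSO-CV needs at least 3 subjects")
    cols = list(feature_cols) if feature_cols is not None else []
    if include_covariates:
        cols = cols + [c for c in COVARIATE_COLUMNS if c in data.columns]

    def _fit(train_rows: pd.DataFrame) -> FitResult:
        y_tr = train_rows[target_col].to_numpy(dtype=float)
        if not cols:
            return FitResult(intercept=float(y_tr.mean()), coefficients={})
        if model == "ols":
            return fit_ols(train_rows[cols], y_tr)
        _, _, fit = tune_in_fold(train_rows, cols, target_col, config)
        return fit

    pred_rows = []
    for s in subjects:
        train_rows = data[data["subject_id"] != s]
        test_rows = data[data["subject_id"] == s]
        fit = _fit(train_rows)
        y_hat = fit.predict(test_rows[cols]) if cols else fit.predict(test_rows)
        for (_, row), yp in zip(test_rows.iterrows(), y_hat):
            pred_rows.append({"subject_id": row["subject_id"],
                              "cycle_id": row.get("cycle_id", ""),
                              "index": index, "mode": mode if mode is not None
                              else row.get("mode", ""),
                              "y_true": float(row[target_col]),
                              "y_pred": float(yp)})
    preds = pd.DataFrame(pred_rows)
    loso = summarize_errors(preds, stage="loso")
    full_fit = _fit(data)
    y_hat_all = full_fit.predict(data[cols]) if cols else full_fit.predict(data)
    train_preds = pd.DataFrame({
        "subject_id": data["subject_id"],
        "cycle_id": data.get("cycle_id", ""),
        "index": index,
        "mode": preds["mode"].iloc[0],
        "y_true": data[target_col].astype(float),
        "y_pred": y_hat_all,
    })
    training = summarize_errors(train_preds, stage="training")
    return preds, loso, training


def compare_modes(per_subject_rmse: pd.DataFrame, index: str) -> MixedModelResult:
    """Random-intercept mixed model of subject-level RMSE on breathing mode.

    ``per_subject_rmse`` needs columns subject_id, mode, rmse and may be
    partially crossed (subjects present in one or both modes). The mode
    effect is tested by a likelihood-ratio test (ML fits) against the
    intercept-only model.
    """
    import statsmodels.api as sm

    modes = sorted(per_subject_rmse["mode"].unique())
    if len(modes) < 2:
        raise DataError("mode contrast undefined with a single mode")
    df = per_subject_rmse.reset_index(drop=True)
    endog = df["rmse"].to_numpy(dtype=float)
    mode_ind = (df["mode"] == modes[1]).astype(float).to_numpy()
    exog_full = np.column_stack([np.ones(len(df)), mode_ind])
    exog_null = np.ones((len(df), 1))
    groups = df["subject_id"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.MixedLM(endog, exog_full, groups=groups).fit(reml=False)
        null = sm.MixedLM(endog, exog_null, groups=groups).fit(reml=False)
    lrt = max(0.0, 2.0 * (full.llf - null.llf))
    p = float(chi2.sf(lrt, df=1))
    return MixedModelResult(estimate=float(full.fe_params[1]),
                            se=float(full.bse_fe[1]), p_value=p,
                            var_subject=float(np.asarray(full.cov_re)[0, 0]),
                            var_resid=float(full.scale), index=index)


def report(summaries: Sequence[ErrorSummary],
           mixed_results: Sequence[MixedModelResult] = (),
           out_png: Optional[str] = None) -> dict:
    """Error table with repeatability-benchmark flags (0.15 L for FVC/FEV1,
    0.67 L/s for PEF) and an optional RMSE/MAE bar chart."""
    rows = []
    for s in summaries:
        thr = REPEATABILITY_THRESHOLDS.get(s.index.lower())
        rows.append({"index": s.index, "mode": s.mode, "stage": s.stage,
                     "rmse": s.mean_rmse, "mae": s.mean_mae,
                     "rmse_se": s.se_rmse, "mae_se": s.se_mae,
                     "threshold": thr,
                     "meets_threshold": (bool(s.mean_rmse <= thr)
                                         if thr is not None else None)})
    doc = {"errors": rows,
           "mode_comparison": [{"index": m.index, "estimate": m.estimate,
                                "se": m.se, "p_value": m.p_value,
                                "var_subject": m.var_subject,
                                "var_resid": m.var_resid,
                                "significant": bool(m.p_value < 0.05)}
                               for m in mixed_results]}
    if out_png is not None:
        _plot_report(rows, out_png)
    return doc


def _plot_report(rows: Sequence[dict], out_png: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    loso_rows = [r for r in rows if r["stage"] == "loso"] or list(rows)
    labels = [f"{r['index'].upper()}\n{r['mode']}" for r in loso_rows]
    x = np.arange(len(loso_rows))
    fig, ax = plt.subplots(figsize=(1.8 * max(len(loso_rows), 2), 3.2))
    ax.bar(x - 0.2, [r["rmse"] for r in loso_rows], width=0.4,
           yerr=[r["rmse_se"] for r in loso_rows], capsize=3,
           color="#1f4e79", label="RMSE")
    ax.bar(x + 0.2, [r["mae"] for r in loso_rows], width=0.4,
           yerr=[r["mae_se"] for r in loso_rows], capsize=3,
           color="#9dc3e6", label="MAE")
    ax.set_xticks(x, labels)
    ax.set_ylabel("error (L or L/s)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
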