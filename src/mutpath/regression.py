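"""Per-pathway LASSO regression of activity scores on somatic alterations.

For each pathway the score vector y (one value per tumor) is regressed on
the alteration feature matrix X with an L1 penalty,

    minimise (1/2n) * sum_j (y_j - b0 - x_j . b)^2 + lambda * ||b||_1 ,

on internally standardised columns (coefficients are reported back on the
original scale). The penalty is chosen by K-fold cross-validation over a
log-spaced grid descending from lambda_max (the smallest penalty that zeros
every slope). Predictive performance is the predicted coefficient of
determination R2_pred: per test fold, 1 - SSE/SST where both the model and
the null mean are estimated on the training fold only, averaged over folds.
Because the null mean is strictly out-of-sample, R2_pred can be negative
and is deliberately not clamped.

The penalised fit selects predictors; an unpenalised least-squares refit on
the selected columns then provides non-shrunken coefficients, per-predictor
t-test p-values, and the machinery (residual variance, Gram inverse) for
approximate prediction intervals used in personalised prediction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from joblib import Parallel, delayed
from scipy import stats
from sklearn.linear_model import lasso_path

from .errors import ValidationError
from .features import AlterationMatrix
from .scoring import PathwayScoreMatrix

logger = logging.getLogger(__name__)

INTERCEPT = "(Intercept)"


@dataclass
class RegressionConfig:
    """Cross-validation and refit settings.

    lambda_rule
        "min": penalty maximising mean cross-validated R2_pred.
        "one_se": largest penalty within one standard error of that maximum.
    pooled_r2
        If set, R2_pred pools squared errors across folds instead of
        averaging per-fold R2 values.
    """

    n_folds: int = 10
    lambda_rule: str = "min"
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    standardize: bool = True
    seed: int = 0
    alpha_level: float = 0.05
    pooled_r2: bool = False
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.lambda_rule not in ("min", "one_se"):
            raise ValidationError(f"unknown lambda_rule {self.lambda_rule!r}")
        if not (0 < self.alpha_level < 1):
            raise ValidationError("alpha_level must be in (0, 1)")


@dataclass
class LassoCVResult:
    lambda_chosen: float
    intercept: float
    coefficients: np.ndarray  # original scale, one per column of X
    r2_pred: float
    lambda_grid: np.ndarray
    cv_r2_mean: np.ndarray  # mean CV R2 per grid point


@dataclass
class RefitResult:
    feature_names: list[str]  # refit columns, post collinearity drop
    coefficients: dict[str, float]  # includes INTERCEPT
    pvalues: dict[str, float]  # includes INTERCEPT
    sigma2: float
    gram_inverse: np.ndarray  # (k+1) x (k+1), intercept first
    dof: int


@dataclass
class PathwayModel:
    """Everything retained about one fitted pathway model."""

    pathway_id: str
    predictor_set_label: str
    lambda_chosen: float
    r2_pred: float
    selected: list[str]
    refit_coefficients: dict[str, float]
    refit_pvalues: dict[str, float]
    refit_sigma2: float
    refit_gram_inverse: list[list[float]] = field(repr=False)
    refit_dof: int = 0
    n_samples: int = 0

    def to_dict(self) -> dict:
        return {
            "pathway_id": self.pathway_id,
            "predictor_set_label": self.predictor_set_label,
            "lambda_chosen": self.lambda_chosen,
            "r2_pred": self.r2_pred,
            "selected": self.selected,
            "refit_coefficients": self.refit_coefficients,
            "refit_pvalues": self.refit_pvalues,
            "refit_sigma2": self.refit_sigma2,
            "refit_gram_inverse": self.refit_gram_inverse,
            "refit_dof": self.refit_dof,
            "n_samples": self.n_samples,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PathwayModel":
        return cls(**d)


def save_models(models: Sequence[PathwayModel], path: str | Path) -> None:
    """One JSON record per line; stable field order."""
    with open(path, "w") as fh:
        for m in models:
            fh.write(json.dumps(m.to_dict()) + "\n")


def load_models(path: str | Path) -> list[PathwayModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                models.append(PathwayModel.from_dict(json.loads(line)))
    return models


# ---------------------------------------------------------------------------
# Cross-validated LASSO
# ---------------------------------------------------------------------------


def make_fold_assignment(n: int, n_folds: int, seed: int) -> np.ndarray:
    """Balanced random fold labels 0..n_folds-1, deterministic for a seed.

    Computed once per run and shared across pathways so that R2_pred values
    are comparable between pathway models.
    """
    if n_folds > n:
        raise ValidationError(f"n_folds={n_folds} exceeds n={n}")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % n_folds
    return labels[rng.permutation(n)]


def _standardize(X: np.ndarray, standardize: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
    else:
        sd = np.ones(X.shape[1])
    return (X - mean) / sd, mean, sd


def lambda_max(y: np.ndarray, X: np.ndarray, standardize: bool = True) -> float:
    """Smallest penalty at which all slope coefficients are zero."""
    Xs, _, _ = _standardize(X, standardize)
    n = len(y)
    return float(np.max(np.abs(Xs.T @ (y - y.mean()))) / n)


def fit_lasso_cv(
    y: np.ndarray,
    X: np.ndarray,
    config: RegressionConfig | None = None,
    fold_assignment: np.ndarray | None = None,
    lambdas: Sequence[float] | None = None,
) -> LassoCVResult:
    """Cross-validate the penalty and fit the final penalised model.

    ``lambdas`` overrides the automatic grid (values are sorted descending);
    passing a single value pins the penalty while still reporting its
    cross-validated R2_pred.
    """
    config = config or RegressionConfig()
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, _ = X.shape
    if len(y) != n:
        raise ValidationError("y and X have different numbers of samples")
    if np.var(y) == 0:
        raise ValidationError("response vector is constant")
    if fold_assignment is None:
        fold_assignment = make_fold_assignment(n, config.n_folds, config.seed)
    folds = np.unique(fold_assignment)

    if lambdas is None:
        lmax = lambda_max(y, X, config.standardize)
        if lmax == 0:
            raise ValidationError("lambda_max is zero; X carries no signal axis")
        grid = np.geomspace(lmax, lmax * config.lambda_min_ratio, config.n_lambda)
    else:
        grid = np.sort(np.asarray(lambdas, dtype=float))[::-1]

    sse = np.zeros((len(folds), len(grid)))
    sst = np.zeros(len(folds))
    for i, k in enumerate(folds):
        te = fold_assignment == k
        tr = ~te
        Xtr, mean, sd = _standardize(X[tr], config.standardize)
        ytr_mean = y[tr].mean()
        _, coefs, _ = lasso_path(Xtr, y[tr] - ytr_mean, alphas=grid)
        Xte = (X[te] - mean) / sd
        pred = Xte @ coefs + ytr_mean  # n_te x n_grid
        sse[i] = ((y[te][:, None] - pred) ** 2).sum(axis=0)
        sst[i] = ((y[te] - ytr_mean) ** 2).sum()
    r2_folds = 1.0 - sse / sst[:, None]
    cv_mean = r2_folds.mean(axis=0)

    best = int(np.argmax(cv_mean))
    if config.lambda_rule == "one_se" and len(folds) > 1:
        se = r2_folds[:, best].std(ddof=1) / np.sqrt(len(folds))
        ok = np.nonzero(cv_mean >= cv_mean[best] - se)[0]
        best = int(ok[0])  # grid descends: first qualifying index = largest lambda
    lam = float(grid[best])

    if config.pooled_r2:
        r2_pred = float(1.0 - sse[:, best].sum() / sst.sum())
    else:
        r2_pred = float(cv_mean[best])

    Xs, mean, sd = _standardize(X, config.standardize)
    _, coefs, _ = lasso_path(Xs, y - y.mean(), alphas=[lam])
    beta_std = coefs[:, 0]
    beta = beta_std / sd
    intercept = float(y.mean() - mean @ beta)
    return LassoCVResult(lam, intercept, beta, r2_pred, grid, cv_mean)


# ---------------------------------------------------------------------------
# Unpenalised refit and prediction intervals
# ---------------------------------------------------------------------------


def refit_unpenalized(
    y: np.ndarray,
    X_selected: np.ndarray,
    feature_names: Sequence[str],
) -> RefitResult:
    """Ordinary least squares on the selected columns with an intercept.

    Collinear columns are dropped greedily in input order (later duplicates
    lose, with a logged warning). Requires n > k + 1 so the residual
    variance has at least one degree of freedom.
    """
    y = np.asarray(y, dtype=float).ravel()
    X_selected = np.asarray(X_selected, dtype=float)
    if X_selected.ndim == 1:
        X_selected = X_selected[:, None]
    n = len(y)
    names = list(feature_names)
    if X_selected.shape[1] != len(names):
        raise ValidationError("feature_names length must match X_selected columns")

    # greedy rank filter: keep a column only if it adds rank
    kept: list[int] = []
    Xa = np.ones((n, 1))
    for j in range(X_selected.shape[1]):
        trial = np.column_stack([Xa, X_selected[:, j]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            Xa = trial
            kept.append(j)
        else:
            logger.warning("dropping collinear predictor %s from refit", names[j])
    names = [names[j] for j in kept]
    k = len(kept)
    if n <= k + 1:
        raise ValidationError(f"refit needs n > k + 1 (n={n}, k={k})")

    gram = Xa.T @ Xa
    gram_inv = np.linalg.inv(gram)
    beta = gram_inv @ (Xa.T @ y)
    resid = y - Xa @ beta
    dof = n - k - 1
    sigma2 = float(resid @ resid / dof)
    se = np.sqrt(np.maximum(sigma2 * np.diag(gram_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    all_names = [INTERCEPT, *names]
    return RefitResult(
        feature_names=names,
        coefficients=dict(zip(all_names, map(float, beta))),
        pvalues=dict(zip(all_names, map(float, pvals))),
        sigma2=sigma2,
        gram_inverse=gram_inv,
        dof=dof,
    )


def predict_with_interval(
    model: PathwayModel,
    x0: Mapping[str, float],
    alpha: float | None = None,
) -> tuple[float, float, float]:
    """Point prediction and approximate prediction interval for one tumor.

    x0 maps each of the model's refit features to its alteration value. The
    interval is the classical OLS prediction interval
    yhat +- t_{1-alpha/2, dof} * sigma * sqrt(1 + x0' G x0) with G the
    stored (intercept-augmented) Gram inverse.
    """
    alpha = 0.05 if alpha is None else alpha
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    names = [nm for nm in model.refit_coefficients if nm != INTERCEPT]
    missing = [nm for nm in names if nm not in x0]
    if missing:
        raise ValidationError(f"x0 missing required features: {missing}")
    xvec = np.array([1.0, *[float(x0[nm]) for nm in names]])
    beta = np.array([model.refit_coefficients[INTERCEPT],
                     *[model.refit_coefficients[nm] for nm in names]])
    yhat = float(xvec @ beta)
    if model.refit_dof < 1:
        raise ValidationError("model has no residual degrees of freedom")
    G = np.asarray(model.refit_gram_inverse, dtype=float)
    half = float(
        stats.t.ppf(1 - alpha / 2, model.refit_dof)
        * np.sqrt(model.refit_sigma2)
        * np.sqrt(1.0 + xvec @ G @ xvec)
    )
    return yhat, yhat - half, yhat + half


# ---------------------------------------------------------------------------
# Fitting a whole collection of pathway models
# ---------------------------------------------------------------------------


def _fit_one(
    pathway_id: str,
    y: np.ndarray,
    X: np.ndarray,
    feature_names: list[str],
    label: str,
    config: RegressionConfig,
    fold_assignment: np.ndarray,
) -> PathwayModel | None:
    try:
        cv = fit_lasso_cv(y, X, config, fold_assignment=fold_assignment)
        sel = np.nonzero(cv.coefficients != 0)[0]
        n = len(y)
        if len(sel) >= n - 1:
            # guard small cohorts: refit only the strongest |coefficient|s
            keep = min(len(sel), n - 2)
            strength = np.abs(cv.coefficients[sel])
            sel = sel[np.argsort(-strength, kind="stable")[:keep]]
            sel = np.sort(sel)
            logger.warning(
                "%s: %d selected predictors with n=%d; refitting top %d by |coef|",
                pathway_id, len(strength), n, keep,
            )
        sel_names = [feature_names[j] for j in sel]
        if len(sel) == 0:
            ybar = float(np.mean(y))
            dof = n - 1
            sigma2 = float(np.var(y, ddof=1))
            refit = RefitResult(
                feature_names=[],
                coefficients={INTERCEPT: ybar},
                pvalues={},
                sigma2=sigma2,
                gram_inverse=np.array([[1.0 / n]]),
                dof=dof,
            )
        else:
            refit = refit_unpenalized(y, X[:, sel], sel_names)
        return PathwayModel(
            pathway_id=pathway_id,
            predictor_set_label=label,
            lambda_chosen=cv.lambda_chosen,
            r2_pred=cv.r2_pred,
            selected=refit.feature_names,
            refit_coefficients=refit.coefficients,
            refit_pvalues={k: v for k, v in refit.pvalues.items() if k != INTERCEPT},
            refit_sigma2=refit.sigma2,
            refit_gram_inverse=np.asarray(refit.gram_inverse).tolist(),
            refit_dof=refit.dof,
            n_samples=n,
        )
    except ValidationError as exc:
        logger.warning("skipping pathway %s: %s", pathway_id, exc)
        return None


def fit_all_pathways(
    scores: PathwayScoreMatrix,
    X: AlterationMatrix,
    config: RegressionConfig | None = None,
    predictor_set_label: str = "census",
) -> list[PathwayModel]:
    """Fit one model per pathway with a shared fold assignment.

    Samples are aligned by identifier (the two inputs must cover the same
    sample set). Pathways with a degenerate (constant) score vector or other
    per-pathway failures are logged and skipped rather than aborting the run.
    Results are independent of ``config.n_jobs``.
    """
    config = config or RegressionConfig()
    score_samples = scores.sample_ids
    if set(score_samples) != set(X.sample_ids):
        raise ValidationError("score and alteration matrices cover different samples")
    Xdf = X.data.loc[score_samples]
    Xmat = Xdf.to_numpy(dtype=float)
    feature_names = X.feature_names
    n = len(score_samples)
    fold_assignment = make_fold_assignment(n, config.n_folds, config.seed)

    tasks = (
        delayed(_fit_one)(
            pid,
            scores.data.loc[pid].to_numpy(dtype=float),
            Xmat,
            feature_names,
            predictor_set_label,
            config,
            fold_assignment,
        )
        for pid in scores.pathway_ids
    )
    fitted = Parallel(n_jobs=config.n_jobs)(tasks)
    models = [m for m in fitted if m is not None]
    if not models:
        raise ValidationError("no pathway model could be fitted")
    return models
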