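"""OLS prediction under stratified, quantile-binned cross-validation.

The continuous trait is quantile-binned (default 8 equal-frequency bins) and
subjects are dealt into folds (default 10) stratified on those bins, so each
fold sees a representative slice of the score distribution. Each fold's model
is plain OLS with intercept, no regularization; feature importance is the
coefficient t-statistic ``t = beta / SE(beta)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DomainError, ValidationError

_PERFECT_FIT_TOL = 1e-12  # relative RSS below which the fit counts as exact


@dataclass
class BinAssignment:
    n_bins: int
    bin_of: np.ndarray  # per-subject label 0..n_bins-1
    bin_counts: np.ndarray


@dataclass
class FoldPlan:
    n_folds: int
    fold_of: np.ndarray  # per-subject fold label 0..n_folds-1
    seed: int

    def split(self):
        """Yield (train_idx, test_idx) per fold."""
        for k in range(self.n_folds):
            test = np.flatnonzero(self.fold_of == k)
            train = np.flatnonzero(self.fold_of != k)
            yield train, test


@dataclass
class FoldFit:
    fold: int
    feature_ids: np.ndarray
    beta: np.ndarray  # intercept first
    se: np.ndarray
    t: np.ndarray
    train_ids: np.ndarray
    test_ids: np.ndarray
    test_predictions: np.ndarray


@dataclass
class CVResult:
    fold_fits: list[FoldFit] = field(repr=False)
    fold_metrics: pd.DataFrame = field(repr=False)  # columns mae, rmse, r2 per fold
    metric_means: dict = field(default_factory=dict)
    metric_sds: dict = field(default_factory=dict)
    predictions: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)
    pooled_r: float = float("nan")
    pooled_r2: float = float("nan")


def metric_mae(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute error ``(1/n) sum |y_i - x_i|``."""
    y_obs, y_pred = _check_pair(y_obs, y_pred, min_n=1)
    return float(np.mean(np.abs(y_obs - y_pred)))


def metric_rmse(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean squared error ``sqrt((1/n) sum (y_i - x_i)^2)``."""
    y_obs, y_pred = _check_pair(y_obs, y_pred, min_n=1)
    return float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))


def metric_r2(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination ``1 - SSE/SST`` (SST about the observed mean).

    Can be negative for models worse than the mean predictor.
    """
    y_obs, y_pred = _check_pair(y_obs, y_pred, min_n=2)
    sst = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if sst == 0:
        raise ValidationError("R^2 undefined: observed values have zero variance")
    sse = float(np.sum((y_obs - y_pred) ** 2))
    return 1.0 - sse / sst


def _check_pair(y_obs, y_pred, min_n):
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.shape != y_pred.shape:
        raise DomainError("observed and predicted lengths differ")
    if y_obs.shape[0] < min_n:
        raise DomainError(f"need at least {min_n} observations")
    return y_obs, y_pred


def quantile_bins(y: np.ndarray, n_bins: int = 8) -> BinAssignment:
    """Equal-frequency bins of a continuous target by average rank.

    With all-distinct scores bin sizes differ by at most one. Heavy ties can
    empty a bin, in which case the bin count is reduced (with a warning)
    until every bin is populated.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if n_bins < 1:
        raise DomainError("n_bins must be >= 1")
    if n < n_bins:
        raise DomainError(f"n_bins={n_bins} exceeds number of subjects n={n}")
    if np.unique(y).size < 2:
        raise ValidationError("all scores identical; quantile binning undefined")
    ranks = stats.rankdata(y, method="average")
    nb = n_bins
    while nb > 1:
        labels = np.clip(np.ceil(ranks * nb / n).astype(int) - 1, 0, nb - 1)
        counts = np.bincount(labels, minlength=nb)
        if np.all(counts > 0):
            break
        nb -= 1
    else:
        labels = np.zeros(n, dtype=int)
        counts = np.array([n])
    if nb < n_bins:
        warnings.warn(
            f"ties emptied quantile bins; reduced n_bins from {n_bins} to {nb}",
            RuntimeWarning,
        )
    return BinAssignment(n_bins=nb, bin_of=labels, bin_counts=counts)


def stratified_folds(bins: BinAssignment, n_folds: int = 10, seed: int = 0) -> FoldPlan:
    """Deal subjects into folds stratified on quantile bins.

    Within each bin the members are shuffled (seeded) and dealt round-robin,
    so per-bin fold counts differ by at most one.
    """
    n = bins.bin_of.shape[0]
    if n_folds < 2:
        raise DomainError("n_folds must be >= 2")
    if n_folds > n:
        raise DomainError(f"n_folds={n_folds} exceeds number of subjects n={n}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    offset = 0  # carried across bins so overall fold sizes stay within 1
    for b in range(bins.n_bins):
        members = np.flatnonzero(bins.bin_of == b)
        rng.shuffle(members)
        fold_of[members] = (offset + np.arange(members.size)) % n_folds
        offset = (offset + members.size) % n_folds
    return FoldPlan(n_folds=n_folds, fold_of=fold_of, seed=seed)


def ols_fit(x_train: np.ndarray, y_train: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ordinary least squares with intercept; returns (beta, se, t).

    ``beta[0]`` is the intercept. Standard errors follow the textbook form
    ``sqrt(diag(sigma^2 (X'X)^-1))`` with ``sigma^2 = RSS/(n-k-1)``. An exact
    fit (RSS ~ 0) yields ``se = 0`` and a signed infinite t sentinel with a
    warning. A rank-deficient design raises, instructing to tighten feature
    selection.
    """
    x = np.atleast_2d(np.asarray(x_train, dtype=float))
    if x.shape[0] == 1 and np.asarray(y_train).size != 1:
        x = x.T
    y = np.asarray(y_train, dtype=float).ravel()
    n, k = x.shape
    if n != y.shape[0]:
        raise DomainError("X and y row counts differ")
    if n <= k + 1:
        raise DomainError(
            f"need more training rows than parameters: n={n}, k+1={k + 1}; "
            "tighten feature selection"
        )
    design = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(design) < k + 1:
        raise DomainError(
            "rank-deficient design matrix; tighten feature selection "
            "(selected features approach or exceed training size)"
        )
    res = sm.OLS(y, design).fit()
    beta = np.asarray(res.params, dtype=float)
    rss = float(res.ssr)
    scale = float(np.sum(y**2)) or 1.0
    if rss / scale < _PERFECT_FIT_TOL:
        warnings.warn("exact fit: zero residual variance, t set to signed inf", RuntimeWarning)
        se = np.zeros_like(beta)
        t = np.where(beta != 0, np.sign(beta) * np.inf, 0.0)
    else:
        se = np.asarray(res.bse, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.where(beta != 0, np.sign(beta) * np.inf, 0.0))
    return beta, se, t


def _predict(beta: np.ndarray, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return beta[0] + x @ beta[1:]


def run_cv(
    x: np.ndarray,
    y: np.ndarray,
    plan: FoldPlan,
    feature_ids: np.ndarray | None = None,
    subjects: list[str] | None = None,
) -> CVResult:
    """Cross-validated OLS: per-fold fits, metrics, and pooled predictions.

    Every subject is predicted exactly once out-of-fold. Reports per-fold
    MAE/RMSE/R^2 with their across-fold mean and SD (the fold-averaged view)
    and, separately, the pooled out-of-fold Pearson r and ``R^2 = 1 -
    SSE/SST`` (the pooled-scatter view); the two R^2 definitions differ.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x.reshape(-1, 1)
    y = np.asarray(y, dtype=float).ravel()
    n = y.shape[0]
    if feature_ids is None:
        feature_ids = np.arange(x.shape[1])
    if subjects is None:
        subjects = [f"s{i}" for i in range(n)]
    fold_fits: list[FoldFit] = []
    rows = []
    metrics = {"mae": [], "rmse": [], "r2": []}
    for k, (train, test) in enumerate(plan.split()):
        beta, se, t = ols_fit(x[train], y[train])
        pred = _predict(beta, x[test])
        fold_fits.append(
            FoldFit(
                fold=k,
                feature_ids=np.asarray(feature_ids, dtype=int),
                beta=beta,
                se=se,
                t=t,
                train_ids=train,
                test_ids=test,
                test_predictions=pred,
            )
        )
        metrics["mae"].append(metric_mae(y[test], pred))
        metrics["rmse"].append(metric_rmse(y[test], pred))
        metrics["r2"].append(metric_r2(y[test], pred))
        for idx, p in zip(test, pred):
            rows.append((subjects[idx], k, y[idx], float(p)))
    fold_metrics = pd.DataFrame(metrics)
    preds = pd.DataFrame(rows, columns=["subject_id", "fold", "observed", "predicted"])
    preds = preds.sort_values("subject_id", kind="stable").reset_index(drop=True)
    if preds["subject_id"].duplicated().any() or len(preds) != n:
        raise ValidationError("folds do not partition subjects")
    obs = preds["observed"].to_numpy()
    pre = preds["predicted"].to_numpy()
    if np.std(pre) > 0:
        pooled_r = float(stats.pearsonr(obs, pre)[0])
    else:
        pooled_r = float("nan")
    pooled_r2 = metric_r2(obs, pre)
    return CVResult(
        fold_fits=fold_fits,
        fold_metrics=fold_metrics,
        metric_means={m: float(fold_metrics[m].mean()) for m in metrics},
        metric_sds={m: float(fold_metrics[m].std(ddof=1)) for m in metrics},
        predictions=preds,
        pooled_r=pooled_r,
        pooled_r2=pooled_r2,
    )
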