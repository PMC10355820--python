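"""Cross-validated elastic net on a descending log-spaced lambda grid.

Conventions mirror glmnet: predictors are standardized inside each training
fold, the penalty path starts at the smallest lambda that zeroes every
coefficient (at the given L1 mixing) and descends log-uniformly, and the
chosen lambda minimizes mean cross-validated squared error.  Coefficients are
reported on the original predictor scale.  sklearn's coordinate-descent
ElasticNet is the per-lambda solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet as _SkElasticNet
from sklearn.model_selection import KFold

import warnings

LAMBDA_EPS = 1e-4
N_LAMBDA = 100
_VAR_TINY = 1e-12


@dataclass
class ElasticNetFit:
    """A fitted elastic net with its cross-validation record.

    Attributes
    ----------
    alpha : float
        L1/L2 mixing parameter in [0, 1] (1 = lasso).
    lam : float
        Selected penalty strength (argmin of the CV curve).
    coefficients : ndarray, (n_features,)
        Sparse coefficient vector on the original predictor scale.
    intercept : float
    cv_folds, cv_seed : int
        Fold count and the seed fixing the deterministic fold assignment.
    cv_curve : ndarray, (n_lambda, 2)
        (lambda, mean CV MSE) pairs along the path.
    """

    alpha: float
    lam: float
    coefficients: np.ndarray
    intercept: float
    cv_folds: int
    cv_seed: int
    cv_curve: np.ndarray = field(repr=False)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, float) @ self.coefficients


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    active = sd > np.sqrt(_VAR_TINY)
    Xs = np.zeros_like(X)
    Xs[:, active] = (X[:, active] - mean[active]) / sd[active]
    return Xs, mean, sd, active

def _fit_at(Xs, yc, lam, alpha):
    # sklearn objective: (1/2n)||y-Xb||^2 + alpha*l1_ratio*|b|_1 + ...
    if alpha == 0:
        model = _SkElasticNet(alpha=lam, l1_ratio=0.0, fit_intercept=False, max_iter=10000)
    else:
        model = _SkElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False, max_iter=10000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)  # l1_ratio=0 advisory
        model.fit(Xs, yc)
    return model.coef_


def lambda_grid(Xs: np.ndarray, yc: np.ndarray, alpha: float) -> np.ndarray:
    """Descending log-spaced path from the all-zero lambda down by LAMBDA_EPS."""
    n = Xs.shape[0]
    # at l1_ratio=0 there is no finite zeroing lambda; use the lasso pivot
    denom = max(alpha, 1e-3)
    lam_max = np.max(np.abs(Xs.T @ yc)) / (n * denom)
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max, lam_max * LAMBDA_EPS, N_LAMBDA)


def fit_cv_enet(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.5,
    folds: int = 10,
    seed: int = 0,
) -> ElasticNetFit:
    """Fit an elastic net with K-fold CV selection of the penalty.

    Raises on constant targets and on folds > n_samples.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise ValueError("target contains non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("constant target: nothing to fit")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n = X.shape[0]
    if folds > n:
        raise ValueError(f"folds ({folds}) exceeds sample count ({n})")

    Xs_full, mean, sd, active = _standardize(X)
    yc_full = y - y.mean()
    grid = lambda_grid(Xs_full, yc_full, alpha)

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sse = np.zeros(len(grid))
    for tr, te in kf.split(X):
        Xs_tr, m_tr, s_tr, act_tr = _standardize(X[tr])
        y_mean = y[tr].mean()
        yc_tr = y[tr] - y_mean
        Xs_te = np.zeros_like(X[te])
        Xs_te[:, act_tr] = (X[te][:, act_tr] - m_tr[act_tr]) / s_tr[act_tr]
        for j, lam in enumerate(grid):
            coef = _fit_at(Xs_tr, yc_tr, lam, alpha)
            pred = y_mean + Xs_te @ coef
            sse[j] += np.sum((y[te] - pred) ** 2)
    mse = sse / n
    best = int(np.argmin(mse))
    lam = float(grid[best])

    coef_std = _fit_at(Xs_full, yc_full, lam, alpha)
    coefficients = np.zeros(X.shape[1])
    coefficients[active] = coef_std[active] / sd[active]
    intercept = float(y.mean() - mean @ coefficients)
    return ElasticNetFit(
        alpha=float(alpha),
        lam=lam,
        coefficients=coefficients,
        intercept=intercept,
        cv_folds=int(folds),
        cv_seed=int(seed),
        cv_curve=np.column_stack([grid, mse]),
    )
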