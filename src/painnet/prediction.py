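"""LOOCV linear prediction of the normalized pain slope, and its scoring.

The selected edges feed an ordinary least-squares model (with intercept)
predicting each subject's normalized VAS slope (VAS/day) under
leave-one-out cross-validation — the edge set is frozen; only the linear
coefficients are re-fitted per fold.  The predicted slope extrapolates to
any visit n by

    predicted dVAS_1n = predicted slope * dt_1n            (single-rate linearity)
    predicted VAS_n   = VAS_1 + predicted dVAS_1n

Model quality is scored by Pearson r between actual and predicted values
(per target), RMSE on the normalized-slope scale, and a permutation test
that shuffles subjects' outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._utils import check_finite_2d, derive_seed

__all__ = [
    "loocv_predict",
    "extrapolate",
    "score_prediction",
    "permutation_pvalue",
]


def _design(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(x.shape[0]), x])


def loocv_predict(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Leave-one-out OLS predictions via the exact hat-matrix identity.

    For OLS, the prediction for subject i from a model fitted without
    subject i is y_i - e_i / (1 - h_ii), where e is the full-fit residual
    and h_ii the leverage — algebraically identical to refitting per fold,
    at one matrix factorization instead of M.

    ``x`` is M x k (k may be 0: intercept-only model predicting each
    fold's training mean).  Requires k + 1 < M and a full-rank design.
    """
    x = check_finite_2d(x, "x") if np.size(x) else np.empty((len(y), 0))
    y = np.asarray(y, float).ravel()
    m, k = x.shape[0], x.shape[1]
    if y.size != m:
        raise ValueError("x and y disagree on the number of subjects")
    if k + 1 >= m:
        raise ValueError(
            f"{k} predictors with {m} subjects leaves no room for LOOCV"
        )
    d = _design(x)
    q, r = np.linalg.qr(d)
    rank = np.sum(np.abs(np.diag(r)) > 1e-10 * np.abs(r[0, 0]))
    if rank < d.shape[1]:
        raise np.linalg.LinAlgError(
            "design matrix is rank-deficient: selected edges are collinear"
        )
    h = np.sum(q * q, axis=1)  # leverages
    if np.any(h >= 1 - 1e-12):
        raise np.linalg.LinAlgError(
            "a LOOCV fold is rank-deficient (leverage ~ 1); reduce the edge set"
        )
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - d @ beta
    return y - resid / (1 - h)


def extrapolate(rate, dt_1n):
    """Predicted dVAS_1n = predicted slope * dt_1n (Eq.-1-style scaling)."""
    rate = np.asarray(rate, float)
    dt = np.asarray(dt_1n, float)
    if np.any(dt < 0):
        raise ValueError("visit intervals must be non-negative")
    out = rate * dt
    return float(out) if out.ndim == 0 else out


@dataclass
class PredictionScore:
    pearson_r: float
    p_value: float          # parametric p from the correlation test
    rmse: float


def score_prediction(actual: np.ndarray, predicted: np.ndarray) -> PredictionScore:
    """Pearson r (with parametric p) and RMSE between actual and predicted.

    A constant vector makes the correlation undefined; r and p are
    reported as NaN in that case, RMSE is always computed.
    """
    a = np.asarray(actual, float).ravel()
    p = np.asarray(predicted, float).ravel()
    if a.size != p.size or a.size < 3:
        raise ValueError("need at least 3 paired observations")
    rmse = float(np.sqrt(np.mean((a - p) ** 2)))
    if np.ptp(a) == 0 or np.ptp(p) == 0:
        return PredictionScore(np.nan, np.nan, rmse)
    r, pval = stats.pearsonr(a, p)
    return PredictionScore(float(r), float(pval), rmse)


def permutation_pvalue(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    two_sided: bool = True,
) -> tuple[float, np.ndarray]:
    """Permutation significance of the LOOCV prediction correlation.

    Shuffles the outcome vector across subjects ``n_perm`` times, re-runs
    the LOOCV linear prediction with the edge set held fixed, and builds
    the null distribution of Pearson r.  The p-value uses the add-one
    rule, p = (1 + #{null >= observed}) / (n_perm + 1), so it can never be
    zero; the comparison is on |r| when ``two_sided`` (default) else on r.

    Returns (p, null_r).
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    y = np.asarray(y, float).ravel()
    obs = score_prediction(y, loocv_predict(x, y)).pearson_r
    rng = np.random.default_rng(derive_seed(seed, "perm"))
    null = np.empty(n_perm)
    for b in range(n_perm):
        yp = y[rng.permutation(y.size)]
        null[b] = score_prediction(yp, loocv_predict(x, yp)).pearson_r
    if two_sided:
        exceed = np.sum(np.abs(null) >= abs(obs))
    else:
        exceed = np.sum(null >= obs)
    return (1 + int(exceed)) / (n_perm + 1), null
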