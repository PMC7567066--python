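"""Stable predictive-edge identification: LASSO inside LOOCV.

The target is each subject's time-normalized pain change,
(VAS_4 - VAS_1) / dt_14 in VAS/day.  For each of M leave-one-out folds a
LASSO is fitted on the remaining M-1 subjects, with its penalty chosen by
inner 10-fold cross-validation under the minimum mean-squared-error rule.
Edges whose coefficient is nonzero in strictly more than 75% of the M
fits form the final feature set (stability-selection rule).

Choices the procedure pins down explicitly (scale-sensitivity of LASSO):
features are standardized on each fold's training set; the penalty path is
100 log-spaced values from the data-driven maximum down to 1e-4 of it;
inner-CV ties resolve toward the larger penalty (sparser model); inner
folds are seeded from the held-out subject's ID, not its position, so
reordering subjects cannot change the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from ._utils import check_finite_2d, derive_seed
from .connectivity import EdgeTable
from .synthetic import SubjectRecord

__all__ = [
    "SelectionResult",
    "normalized_target",
    "lasso_fold_fit",
    "stability_select",
]


def normalized_target(record: SubjectRecord) -> float:
    """Normalized VAS change: (VAS_4 - VAS_1) / dt_14, in VAS/day."""
    dt = record.delta_t(4)
    if dt <= 0:
        raise ValueError(
            f"subject {record.subject_id}: visit days must be increasing "
            f"(dt_14 = {dt})"
        )
    return (record.vas[3] - record.vas[0]) / dt


@dataclass
class SelectionResult:
    """Per-edge LOOCV selection frequencies and the final stable set."""

    fold_frequency: np.ndarray       # fraction of folds with nonzero coef
    threshold: float
    per_fold_lambda: np.ndarray      # chosen penalty per LOOCV fold
    edge_names: list[str] = field(default_factory=list)

    @property
    def selected(self) -> np.ndarray:
        """Edge indices with fold_frequency strictly above the threshold."""
        return np.flatnonzero(self.fold_frequency > self.threshold)

    @property
    def n_selected(self) -> int:
        return self.selected.size

    def to_frame(self) -> pd.DataFrame:
        names = self.edge_names or [
            f"edge{k}" for k in range(self.fold_frequency.size)
        ]
        sel = np.zeros(self.fold_frequency.size, dtype=bool)
        sel[self.selected] = True
        return pd.DataFrame(
            {"edge": names, "fold_frequency": self.fold_frequency, "selected": sel}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _lambda_path(x_std: np.ndarray, y: np.ndarray, n_lambdas: int) -> np.ndarray:
    n = x_std.shape[0]
    lam_max = np.max(np.abs(x_std.T @ (y - y.mean()))) / n
    if lam_max <= 0:
        lam_max = 1e-3
    return np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-4), n_lambdas)


def lasso_fold_fit(
    x: np.ndarray,
    y: np.ndarray,
    inner_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 100,
) -> tuple[np.ndarray, float]:
    """LASSO with inner-CV penalty choice on one training fold.

    Returns (support, lambda): indices of nonzero-coefficient features at
    the minimum-mean-squared-error penalty, and that penalty.  Features
    are standardized internally; the support refers to original columns.
    Deterministic given ``seed`` (inner-fold shuffling).
    """
    x = check_finite_2d(x, "x")
    y = np.asarray(y, float).ravel()
    if x.shape[0] != y.size:
        raise ValueError("x and y disagree on the number of subjects")
    if x.shape[0] < inner_folds:
        raise ValueError(
            f"{x.shape[0]} subjects cannot support {inner_folds}-fold inner "
            "CV; reduce inner_folds"
        )
    mu, sd = x.mean(axis=0), x.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    xs = (x - mu) / sd
    alphas = _lambda_path(xs, y, n_lambdas)
    cv = KFold(n_splits=inner_folds, shuffle=True, random_state=seed % (2**31))
    model = LassoCV(alphas=alphas, cv=cv, max_iter=20_000, tol=1e-4)
    with warnings.catch_warnings():
        # near-exact fits at the small end of the path trip sklearn's
        # duality-gap warning at gaps ~1e-8; harmless for support recovery
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(xs, y)
    # LassoCV's argmin over the descending path already lands on the
    # largest (sparsest) penalty among exact ties
    support = np.flatnonzero(model.coef_ != 0)
    return support, float(model.alpha_)


def stability_select(
    edges: EdgeTable,
    targets: np.ndarray,
    threshold: float = 0.75,
    seed: int = 0,
    inner_folds: int = 10,
    n_lambdas: int = 100,
) -> SelectionResult:
    """LOOCV stability selection over all edges.

    Runs ``lasso_fold_fit`` M times, each omitting one subject, tallies the
    per-edge nonzero frequency, and applies the strict > threshold rule
    (default 0.75).  Inner-fold seeds are derived from the omitted
    subject's ID so the result is invariant to subject order.
    """
    y = np.asarray(targets, float).ravel()
    m = edges.n_subjects
    if y.size != m:
        raise ValueError("targets length must equal the number of subjects")
    if m < inner_folds + 2:
        raise ValueError(
            f"need at least {inner_folds + 2} subjects for LOOCV with "
            f"{inner_folds}-fold inner CV"
        )
    counts = np.zeros(edges.n_edges)
    lambdas = np.empty(m)
    # canonical subject order inside each training fold, so that permuting
    # the table's row order cannot change inner-fold composition
    canon = sorted(range(m), key=lambda k: edges.subject_ids[k])
    for i in range(m):
        keep = np.array([k for k in canon if k != i])
        fold_seed = derive_seed(seed, "fold", edges.subject_ids[i])
        support, lam = lasso_fold_fit(
            edges.matrix[keep],
            y[keep],
            inner_folds=inner_folds,
            seed=fold_seed,
            n_lambdas=n_lambdas,
        )
        counts[support] += 1
        lambdas[i] = lam
    return SelectionResult(
        fold_frequency=counts / m,
        threshold=float(threshold),
        per_fold_lambda=lambdas,
        edge_names=edges.edge_names,
    )
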