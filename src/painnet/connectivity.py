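"""Per-subject network connectivity.

Builds the subject-level connectome used throughout the package: a
ridge-regularized partial-correlation matrix among component time series,
its Fisher r-to-z transform, and the canonical subjects x edges table that
the predictive model consumes.

Partial correlation between two components is the correlation of their
time series after regressing out every other component.  Rather than the
O(N^2) residual regressions, it is computed from the precision matrix of
the sample correlation matrix C, regularized as inv(C + rho * I) with
rho >= 0 (rho = 0.01 by default, following common FSLNets "ridgep"
practice), so the estimate is stable even when T is not much larger
than N:

    partial_r[i, j] = -P[i, j] / sqrt(P[i, i] * P[j, j]),   P = inv(C + rho I)

Regularization is applied to the *correlation* (not covariance) matrix so
that rho is scale-free across components; an alternate covariance dialect
can be obtained by passing pre-scaled data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import check_finite_2d

__all__ = [
    "ConnectivityMatrix",
    "EdgeTable",
    "partial_correlation",
    "fisher_z",
    "vectorize_edges",
    "residualize_covariate",
]


@dataclass
class ConnectivityMatrix:
    """N x N partial-correlation matrix for one subject.

    ``values`` holds raw partial correlations (``is_z=False``) or their
    Fisher z-transform (``is_z=True``); the diagonal is 1 (raw) and is
    never transformed.
    """

    values: np.ndarray
    rho: float
    subject_id: str = ""
    is_z: bool = False

    @property
    def n_components(self) -> int:
        return self.values.shape[0]

    def to_z(self) -> "ConnectivityMatrix":
        """Fisher-transform the off-diagonal entries; diagonal left at 1."""
        if self.is_z:
            return self
        z = self.values.copy()
        off = ~np.eye(z.shape[0], dtype=bool)
        z[off] = fisher_z(z[off])
        return ConnectivityMatrix(z, self.rho, self.subject_id, is_z=True)

    def to_frame(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        labels = list(labels) if labels is not None else [
            f"IC{i + 1}" for i in range(self.n_components)
        ]
        return pd.DataFrame(self.values, index=labels, columns=labels)


def partial_correlation(
    timeseries: np.ndarray, rho: float = 0.01, subject_id: str = ""
) -> ConnectivityMatrix:
    """Ridge-regularized partial correlation of a T x N time-series matrix.

    Parameters
    ----------
    timeseries
        T x N array, one column per component; T must exceed N.
    rho
        Ridge penalty added to the diagonal of the sample correlation
        matrix before inversion.  ``rho=0`` gives the plain partial
        correlation and requires full-rank data.

    Returns
    -------
    ConnectivityMatrix with exactly symmetric values, unit diagonal, and
    off-diagonal entries in (-1, 1).
    """
    ts = check_finite_2d(timeseries, "timeseries")
    t, n = ts.shape
    if t <= n:
        raise ValueError(f"need more time points than components (T={t}, N={n})")
    if rho < 0:
        raise ValueError("rho must be non-negative")
    sd = ts.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance component column(s): {dead.tolist()}")
    corr = np.corrcoef(ts, rowvar=False)
    reg = corr + rho * np.eye(n)
    # cond check catches the rho=0 rank-deficient case with a usable message
    if np.linalg.cond(reg) > 1e12:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; use rho > 0 (ridge regularization)"
        )
    prec = np.linalg.inv(reg)
    d = np.sqrt(np.diag(prec))
    pr = -prec / np.outer(d, d)
    pr = (pr + pr.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(pr, 1.0)
    return ConnectivityMatrix(pr, rho=float(rho), subject_id=subject_id)


def fisher_z(r):
    """Fisher r-to-z transform, z = atanh(r) = 0.5*ln((1+r)/(1-r)).

    Strictly increasing and odd; domain |r| < 1.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def edge_index(n_components: int) -> list[tuple[int, int]]:
    """Canonical edge ordering: row-major upper triangle, (i, j) with i < j."""
    iu, ju = np.triu_indices(n_components, k=1)
    return list(zip(iu.tolist(), ju.tolist()))


@dataclass
class EdgeTable:
    """Subjects x edges matrix of Fisher-z partial correlations.

    ``matrix`` is M x E with E = N(N-1)/2; ``edges`` is the canonical
    row-major upper-triangle index, a bijection onto matrix columns.
    """

    matrix: np.ndarray
    n_components: int
    subject_ids: list[str] = field(default_factory=list)
    component_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = check_finite_2d(self.matrix, "edge matrix")
        e = self.n_components * (self.n_components - 1) // 2
        if self.matrix.shape[1] != e:
            raise ValueError(
                f"edge matrix has {self.matrix.shape[1]} columns, expected "
                f"E = N(N-1)/2 = {e} for N = {self.n_components}"
            )
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i + 1:03d}" for i in range(len(self.matrix))]
        if not self.component_labels:
            self.component_labels = [f"IC{i + 1}" for i in range(self.n_components)]

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_edges(self) -> int:
        return self.matrix.shape[1]

    @property
    def edges(self) -> list[tuple[int, int]]:
        return edge_index(self.n_components)

    @property
    def edge_names(self) -> list[str]:
        lab = self.component_labels
        return [f"{lab[i]}-{lab[j]}" for i, j in self.edges]

    def to_matrix(self, row: int) -> np.ndarray:
        """Devectorize one subject's row back to a symmetric N x N matrix."""
        n = self.n_components
        m = np.zeros((n, n))
        iu, ju = np.triu_indices(n, k=1)
        m[iu, ju] = self.matrix[row]
        m = m + m.T
        np.fill_diagonal(m, 1.0)
        return m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=self.subject_ids, columns=self.edge_names
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="subject_id")

    @classmethod
    def from_csv(cls, path) -> "EdgeTable":
        df = pd.read_csv(path, index_col=0)
        e = df.shape[1]
        # invert E = N(N-1)/2
        n = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
        if n * (n - 1) // 2 != e:
            raise ValueError(f"{e} columns is not a valid edge count N(N-1)/2")
        # recover component labels in canonical order from the edge names
        labels: list[str] = []
        for name in df.columns:
            for part in name.split("-"):
                if part not in labels:
                    labels.append(part)
        return cls(
            df.to_numpy(float),
            n_components=n,
            subject_ids=[str(s) for s in df.index],
            component_labels=labels if len(labels) == n else [],
        )


def vectorize_edges(
    matrices: Sequence[ConnectivityMatrix],
    component_labels: Sequence[str] | None = None,
) -> EdgeTable:
    """Stack per-subject z-matrices into a subjects x edges table.

    Raw (non-z) matrices are Fisher-transformed first.  All subjects must
    share N and component ordering.
    """
    if not matrices:
        raise ValueError("no connectivity matrices given")
    n = matrices[0].n_components
    rows, ids = [], []
    iu, ju = np.triu_indices(n, k=1)
    for m in matrices:
        if m.n_components != n:
            raise ValueError(
                f"inconsistent component count: {m.n_components} vs {n} "
                f"(subject {m.subject_id!r})"
            )
        z = m.to_z()
        rows.append(z.values[iu, ju])
        ids.append(m.subject_id)
    return EdgeTable(
        np.vstack(rows),
        n_components=n,
        subject_ids=[s or f"sub-{k + 1:03d}" for k, s in enumerate(ids)],
        component_labels=list(component_labels) if component_labels else [],
    )


def residualize_covariate(edges: EdgeTable, covariate: np.ndarray) -> EdgeTable:
    """Replace each edge column by its residual after OLS on the covariate.

    Used for the sex-controlled sensitivity variant.  Idempotent: residuals
    are orthogonal to the covariate and mean-centred.
    """
    cov = np.asarray(covariate, dtype=float).ravel()
    if cov.size != edges.n_subjects:
        raise ValueError(
            f"covariate length {cov.size} != number of subjects {edges.n_subjects}"
        )
    if np.ptp(cov) == 0:
        raise ValueError("covariate is constant; cannot residualize")
    design = np.column_stack([np.ones_like(cov), cov])
    beta, *_ = np.linalg.lstsq(design, edges.matrix, rcond=None)
    resid = edges.matrix - design @ beta
    return EdgeTable(
        resid,
        n_components=edges.n_components,
        subject_ids=list(edges.subject_ids),
        component_labels=list(edges.component_labels),
    )
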