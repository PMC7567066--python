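"""Connectome-based longitudinal pain model (Model/Results interface).

`ConnectomePainModel` holds the data — a subjects x edges table of
baseline Fisher-z partial correlations and the subjects' VAS
trajectories — plus the procedure's tuning knobs.  `fit()` runs the full
predictive pipeline:

1. stability selection — LASSO inside leave-one-out CV, keeping edges
   with nonzero coefficients in > 75% of folds;
2. LOOCV ordinary least squares on the selected edges, predicting each
   subject's normalized VAS slope (VAS/day);
3. extrapolation of the slope to visits 2/3/4 (dVAS_1n = slope * dt_1n,
   VAS_n = VAS_1 + dVAS_1n);
4. scoring: Pearson r and RMSE per target, optional permutation p-values;
5. SBPp/SBPr classification per visit at the rescaled recovery thresholds.

The returned `ConnectomePainResults` carries everything, with a
`summary()` table in the spirit of statsmodels results objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classification as clf
from . import prediction as pred
from . import selection as sel
from ._utils import derive_seed
from .connectivity import EdgeTable, residualize_covariate
from .synthetic import SubjectRecord

__all__ = ["ConnectomePainModel", "ConnectomePainResults"]

VISITS = (2, 3, 4)


@dataclass
class ConnectomePainResults:
    """Fitted estimates, predictions and diagnostics of the pain model."""

    model: "ConnectomePainModel"
    selection: sel.SelectionResult
    coefficients: pd.Series            # final-model OLS coefs (full data)
    predicted_rate: np.ndarray         # per-subject LOOCV slope, VAS/day
    actual_rate: np.ndarray
    predictions: pd.DataFrame          # per subject x visit: dVAS & VAS
    scores: pd.DataFrame               # r, p, rmse per target
    classification: dict[int, clf.ClassificationResult]
    permutation_p: dict[str, float] = field(default_factory=dict)

    @property
    def selected_edges(self) -> list[str]:
        names = self.selection.edge_names
        return [names[k] for k in self.selection.selected]

    @property
    def rmse(self) -> float:
        """RMSE on the normalized-slope scale (VAS/day)."""
        return float(
            np.sqrt(np.mean((self.actual_rate - self.predicted_rate) ** 2))
        )

    def summary(self) -> str:
        lines = []
        w = 70
        lines.append("Connectome-based longitudinal pain model".center(w))
        lines.append("=" * w)
        m = self.model
        lines.append(
            f"Subjects: {len(m.records):>4}    Edges: {m.edges.n_edges:>5}    "
            f"Selected: {self.selection.n_selected}"
        )
        lines.append(
            f"Selection threshold: > {self.selection.threshold:.0%} of "
            f"{len(m.records)} LOOCV folds"
        )
        if self.selected_edges:
            lines.append("Selected edges (fold frequency):")
            for k in self.selection.selected:
                lines.append(
                    f"  {self.selection.edge_names[k]:<16}"
                    f"{self.selection.fold_frequency[k]:.2f}"
                    f"   coef {self.coefficients.get(self.selection.edge_names[k], np.nan):+.4f}"
                )
        else:
            lines.append("No edges passed the stability threshold.")
        lines.append("-" * w)
        lines.append(f"{'target':<14}{'r':>8}{'RMSE':>10}{'perm p':>10}")
        for t, row in self.scores.iterrows():
            p = self.permutation_p.get(t, np.nan)
            p_str = f"{p:.4f}" if np.isfinite(p) else "  --"
            lines.append(
                f"{t:<14}{row.pearson_r:>8.3f}{row.rmse:>10.4f}{p_str:>10}"
            )
        lines.append("-" * w)
        lines.append(
            f"{'visit':<8}{'thr %':>6}{'AUC':>8}{'acc':>8}{'sens':>8}{'spec':>8}"
        )
        for v in sorted(self.classification):
            c = self.classification[v]
            auc = f"{c.auc:.3f}" if np.isfinite(c.auc) else "  --"
            lines.append(
                f"{v:<8}{c.threshold_pct:>6.1f}{auc:>8}{c.accuracy:>8.3f}"
                f"{c.sensitivity:>8.3f}{c.specificity:>8.3f}"
            )
        lines.append("=" * w)
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        """Deterministic plain-type summary for manifests and reports."""
        out = {
            "n_subjects": len(self.model.records),
            "n_edges": int(self.model.edges.n_edges),
            "selected_edges": self.selected_edges,
            "fold_frequency": {
                self.selection.edge_names[k]: float(self.selection.fold_frequency[k])
                for k in self.selection.selected
            },
            "rmse_rate": self.rmse,
            "scores": {
                t: {
                    "pearson_r": None if not np.isfinite(r.pearson_r) else float(r.pearson_r),
                    "rmse": float(r.rmse),
                }
                for t, r in self.scores.iterrows()
            },
            "permutation_p": {k: float(v) for k, v in self.permutation_p.items()},
            "classification": {
                str(v): {
                    "threshold_pct": c.threshold_pct,
                    "auc": None if not np.isfinite(c.auc) else float(c.auc),
                    "accuracy": c.accuracy,
                    "sensitivity": None if not np.isfinite(c.sensitivity) else c.sensitivity,
                    "specificity": None if not np.isfinite(c.specificity) else c.specificity,
                }
                for v, c in self.classification.items()
            },
        }
        return out


class ConnectomePainModel:
    """Predicts longitudinal VAS change from baseline connectome edges.

    Parameters
    ----------
    edges
        Subjects x edges table of baseline Fisher-z partial correlations.
    records
        Matching subject records (VAS at four visits, visit days, sex).
    selection_threshold
        Stability-selection fold-frequency cutoff (strict >; default 0.75).
    inner_folds
        Inner CV folds for the LASSO penalty (default 10).
    recovery_thresholds
        Percent-decrease recovery criterion per visit.  Defaults to the
        published {4: 20, 3: 15, 2: 13}; pass ``"auto"`` to rescale the
        base-visit threshold from the cohort's own mean drops.
    sex_adjust
        Residualize edges on the sex covariate before fitting.
    """

    def __init__(
        self,
        edges: EdgeTable,
        records: Sequence[SubjectRecord],
        selection_threshold: float = 0.75,
        inner_folds: int = 10,
        n_lambdas: int = 100,
        recovery_thresholds: Mapping[int, float] | str = None,
        base_recovery_pct: float = 20.0,
        sex_adjust: bool = False,
        strict_recovery_boundary: bool = False,
    ):
        if edges.n_subjects != len(records):
            raise ValueError(
                f"edge table has {edges.n_subjects} subjects, records have "
                f"{len(records)}"
            )
        for r in records:
            r.validate()
        self.records = list(records)
        self.sex = np.array([r.sex for r in self.records])
        if sex_adjust:
            edges = residualize_covariate(edges, self.sex)
        self.edges = edges
        self.selection_threshold = selection_threshold
        self.inner_folds = inner_folds
        self.n_lambdas = n_lambdas
        self.base_recovery_pct = base_recovery_pct
        self.strict_recovery_boundary = strict_recovery_boundary
        self.sex_adjust = sex_adjust
        if recovery_thresholds is None:
            self.recovery_thresholds = dict(clf.DEFAULT_THRESHOLDS)
        elif recovery_thresholds == "auto":
            self.recovery_thresholds = self._auto_thresholds()
        else:
            self.recovery_thresholds = {
                int(k): float(v) for k, v in recovery_thresholds.items()
            }

    @classmethod
    def from_dataframes(
        cls, edges_df: pd.DataFrame, subjects_df: pd.DataFrame, **kwargs
    ) -> "ConnectomePainModel":
        """Build from an edge DataFrame (subjects x "ICi-ICj" columns) and a
        subject table with subject_id, sex, vas_v1..4, days_v1..4."""
        from .pipeline import records_from_frame

        e = edges_df.shape[1]
        n = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
        table = EdgeTable(
            edges_df.to_numpy(float),
            n_components=n,
            subject_ids=[str(s) for s in edges_df.index],
        )
        return cls(table, records_from_frame(subjects_df), **kwargs)

    def _auto_thresholds(self) -> dict[int, float]:
        v1 = np.array([r.vas[0] for r in self.records])
        drops = {
            n: float(np.mean(v1 - [r.vas[n - 1] for r in self.records]))
            for n in VISITS
        }
        out = {4: self.base_recovery_pct}
        for n in (2, 3):
            out[n] = clf.adjust_threshold(
                drops[n], drops[4], base=self.base_recovery_pct
            )
        return out

    # -- fitting ---------------------------------------------------------

    def fit(
        self,
        seed: int = 0,
        n_permutations: int = 0,
        selection: sel.SelectionResult | None = None,
    ) -> ConnectomePainResults:
        """Run selection, LOOCV prediction, scoring and classification.

        ``n_permutations`` > 0 adds permutation p-values (outcomes shuffled
        across subjects, edge set held fixed).  A precomputed
        ``selection`` skips stage 1 (used by the permutation machinery and
        the seed-ROI baseline).
        """
        y = np.array([sel.normalized_target(r) for r in self.records])
        if selection is None:
            selection = sel.stability_select(
                self.edges,
                y,
                threshold=self.selection_threshold,
                seed=derive_seed(seed, "select"),
                inner_folds=self.inner_folds,
                n_lambdas=self.n_lambdas,
            )
        x_sel = self.edges.matrix[:, selection.selected]
        rate_hat = pred.loocv_predict(x_sel, y)

        # final coefficients on the full cohort, for reporting
        d = np.column_stack([np.ones(len(y)), x_sel])
        beta, *_ = np.linalg.lstsq(d, y, rcond=None)
        names = ["intercept"] + [
            selection.edge_names[k] for k in selection.selected
        ]
        coefs = pd.Series(beta, index=names)

        v1 = np.array([r.vas[0] for r in self.records])
        rows, score_rows, cls_results = [], {}, {}
        score_rows["rate"] = pred.score_prediction(y, rate_hat)
        for n in VISITS:
            dt = np.array([r.delta_t(n) for r in self.records])
            dvas_hat = pred.extrapolate(rate_hat, dt)
            vas_hat = v1 + dvas_hat
            actual_vn = np.array([r.vas[n - 1] for r in self.records])
            actual_dvas = actual_vn - v1
            score_rows[f"dvas_v{n}"] = pred.score_prediction(actual_dvas, dvas_hat)
            score_rows[f"vas_v{n}"] = pred.score_prediction(actual_vn, vas_hat)
            thr = self.recovery_thresholds[n]
            labels = clf.label_groups(
                self.records, visit=n, threshold_pct=thr,
                strict=self.strict_recovery_boundary,
            )
            cls_results[n] = clf.roc_metrics(
                dvas_hat, labels, v1, visit=n, threshold_pct=thr,
                strict=self.strict_recovery_boundary,
            )
            for i, r in enumerate(self.records):
                rows.append(
                    {
                        "subject_id": r.subject_id,
                        "visit": n,
                        "dt_days": dt[i],
                        "predicted_rate": rate_hat[i],
                        "predicted_dvas": dvas_hat[i],
                        "predicted_vas": vas_hat[i],
                        "actual_dvas": actual_dvas[i],
                        "actual_vas": actual_vn[i],
                    }
                )
        scores = pd.DataFrame(
            {
                t: {"pearson_r": s.pearson_r, "p_value": s.p_value, "rmse": s.rmse}
                for t, s in score_rows.items()
            }
        ).T

        perm_p: dict[str, float] = {}
        if n_permutations:
            perm_p = self._permutation_pvalues(
                x_sel, y, n_permutations, derive_seed(seed, "permutation")
            )
        return ConnectomePainResults(
            model=self,
            selection=selection,
            coefficients=coefs,
            predicted_rate=rate_hat,
            actual_rate=y,
            predictions=pd.DataFrame(rows),
            scores=scores,
            classification=cls_results,
            permutation_p=perm_p,
        )

    def _permutation_pvalues(
        self, x_sel: np.ndarray, y: np.ndarray, n_perm: int, seed: int
    ) -> dict[str, float]:
        """Two-sided permutation p per target; outcomes shuffled jointly.

        Each permutation reassigns whole outcome records (slope, visit
        days, VAS) to subjects, reruns the LOOCV prediction on the
        permuted slopes and rescores every target, so the null respects
        the within-subject coupling between slope and trajectory.
        """
        rng = np.random.default_rng(seed)
        v1 = np.array([r.vas[0] for r in self.records])
        targets = ["rate"] + [
            f"{kind}_v{n}" for n in VISITS for kind in ("dvas", "vas")
        ]
        dt = {n: np.array([r.delta_t(n) for r in self.records]) for n in VISITS}
        actual_vn = {
            n: np.array([r.vas[n - 1] for r in self.records]) for n in VISITS
        }

        def _rs(yy, order):
            """Observed |r| per target for outcome order ``order``."""
            rate_hat = pred.loocv_predict(x_sel, yy)
            out = {"rate": pred.score_prediction(yy, rate_hat).pearson_r}
            for n in VISITS:
                dvas_hat = rate_hat * dt[n][order]
                adv = actual_vn[n][order] - v1[order]
                out[f"dvas_v{n}"] = pred.score_prediction(adv, dvas_hat).pearson_r
                out[f"vas_v{n}"] = pred.score_prediction(
                    actual_vn[n][order], v1[order] + dvas_hat
                ).pearson_r
            return out

        ident = np.arange(y.size)
        obs = _rs(y, ident)
        exceed = {t: 0 for t in targets}
        for _ in range(n_perm):
            order = rng.permutation(y.size)
            null = _rs(y[order], order)
            for t in targets:
                if np.isfinite(null[t]) and abs(null[t]) >= abs(obs[t]):
                    exceed[t] += 1
        return {t: (1 + exceed[t]) / (n_perm + 1) for t in targets}
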