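"""Group spatial ICA network definition and component labelling.

Subjects' 4-D volumes are temporally concatenated and decomposed by
spatial ICA (voxels are the statistical samples, so components are
spatially independent maps with shared mixing time courses — the standard
group-ICA formulation).  Components are labelled by spatial
cross-correlation against template resting-state-network maps, with
|r| < 0.1 flagged as noise, anatomically annotated by atlas-region
overlap (> 90% rule), and per-subject component time series are obtained
by stage-1 dual regression (multivariate spatial regression of the kept
maps onto each volume).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

__all__ = [
    "ComponentSet",
    "group_ica",
    "match_templates",
    "overlap_labels",
    "subject_timeseries",
]

NOISE_LABEL = "noise"


@dataclass
class ComponentSet:
    """ICA spatial maps with labels, template correlations and keep flags."""

    spatial_maps: np.ndarray                  # K x V
    grid_shape: tuple[int, int, int]
    labels: list[str] = field(default_factory=list)
    template_corr: np.ndarray | None = None   # best |r| per component
    kept: np.ndarray | None = None            # boolean per component

    def __post_init__(self):
        k = self.spatial_maps.shape[0]
        if not self.labels:
            self.labels = [f"IC{i + 1}" for i in range(k)]
        if self.kept is None:
            self.kept = np.ones(k, dtype=bool)

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]

    @property
    def n_kept(self) -> int:
        return int(np.sum(self.kept))

    def kept_maps(self) -> np.ndarray:
        return self.spatial_maps[self.kept]

    def kept_labels(self) -> list[str]:
        return [l for l, k in zip(self.labels, self.kept) if k]

    def apply_keep_list(
        self, keep: Sequence[int] = (), drop: Sequence[int] = ()
    ) -> "ComponentSet":
        """Manual keep/drop overrides (0-based indices) after template matching."""
        kept = self.kept.copy()
        kept[list(keep)] = True
        kept[list(drop)] = False
        return ComponentSet(
            self.spatial_maps, self.grid_shape, list(self.labels),
            self.template_corr, kept,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, self.n_components + 1),
                "label": self.labels,
                "template_corr": (
                    self.template_corr
                    if self.template_corr is not None
                    else np.full(self.n_components, np.nan)
                ),
                "kept": self.kept,
            }
        )


def group_ica(
    subject_volumes: Sequence[np.ndarray],
    n_components: int,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-5,
    n_restarts: int = 3,
) -> tuple[ComponentSet, np.ndarray]:
    """Temporally concatenated group spatial ICA.

    Parameters
    ----------
    subject_volumes
        List of (x, y, z, T) arrays on a shared grid.
    n_components
        Number of ICs to extract; total concatenated time points must
        exceed it.  Dimension reduction to this order happens inside the
        ICA whitening step (PCA on the concatenated data).

    Returns
    -------
    (components, mixing)
        Unlabelled ComponentSet (each map sign-fixed so its
        maximum-magnitude voxel is positive) and the total_T x K group
        mixing time courses.
    """
    if not subject_volumes:
        raise ValueError("no subject volumes given")
    grid_shape = subject_volumes[0].shape[:3]
    mats = []
    for i, vol in enumerate(subject_volumes):
        if vol.shape[:3] != grid_shape:
            raise ValueError(
                f"subject {i} grid {vol.shape[:3]} != {grid_shape}"
            )
        mats.append(vol.reshape(-1, vol.shape[3]).T)  # T x V
    data = np.vstack(mats)  # total_T x V
    total_t, n_vox = data.shape
    if total_t <= n_components:
        raise ValueError(
            f"{total_t} concatenated time points cannot support "
            f"{n_components} components"
        )
    if np.linalg.matrix_rank(data[: min(total_t, n_components + 5)]) < min(
        n_components, total_t
    ):
        raise ValueError("concatenated data are rank-deficient for this order")
    data = data - data.mean(axis=0, keepdims=True)
    # samples = voxels, features = time points -> spatially independent
    # sources; deterministic restarts guard the occasional non-converged
    # FastICA initialization
    sources = ica = None
    last_exc = None
    for attempt in range(n_restarts):
        ica = FastICA(
            n_components=n_components,
            random_state=(seed + 7919 * attempt) % 2**31,
            max_iter=max_iter,
            tol=tol,
            whiten="unit-variance",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                sources = ica.fit_transform(data.T)  # V x K
                break
            except ConvergenceWarning as exc:
                last_exc = exc
                sources = None
    if sources is None:
        raise RuntimeError(
            f"ICA did not converge within {max_iter} iterations in any of "
            f"{n_restarts} restarts (tol={tol}); last: {last_exc}"
        )
    maps = sources.T                        # K x V
    mixing = ica.mixing_                    # total_T x K
    # fix arbitrary ICA sign: peak-magnitude voxel positive
    for k in range(n_components):
        peak = np.argmax(np.abs(maps[k]))
        if maps[k, peak] < 0:
            maps[k] = -maps[k]
            mixing[:, k] = -mixing[:, k]
    return ComponentSet(maps, grid_shape), mixing


def _spatial_corr(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None) -> float:
    if mask is not None:
        a, b = a[mask], b[mask]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def match_templates(
    components: ComponentSet,
    templates: Mapping[str, np.ndarray],
    noise_cutoff: float = 0.1,
    mask: np.ndarray | None = None,
) -> ComponentSet:
    """Label components by best absolute spatial correlation with templates.

    Each component gets the label of its best-matching template; a
    component whose best |r| falls below ``noise_cutoff`` (strictly) is
    flagged as noise and excluded.  Correlations are computed over in-mask
    voxels after de-meaning both maps, so matching is invariant to
    positive rescaling; ICA sign ambiguity is handled by the absolute value.
    """
    names = list(templates)
    if not names:
        raise ValueError("no templates given")
    n_vox = components.spatial_maps.shape[1]
    for name, tpl in templates.items():
        tpl = np.asarray(tpl)
        if tpl.reshape(-1).size != n_vox:
            raise ValueError(
                f"template {name!r} has {tpl.reshape(-1).size} voxels, "
                f"components have {n_vox}"
            )
    if mask is not None:
        mask = np.asarray(mask).reshape(-1).astype(bool)
    tpl_flat = {n: np.asarray(t, float).reshape(-1) for n, t in templates.items()}
    labels, best_r, kept = [], [], []
    for k in range(components.n_components):
        comp = components.spatial_maps[k]
        rs = {n: abs(_spatial_corr(comp, t, mask)) for n, t in tpl_flat.items()}
        best = max(rs, key=rs.get)
        labels.append(best if rs[best] >= noise_cutoff else NOISE_LABEL)
        best_r.append(rs[best])
        kept.append(rs[best] >= noise_cutoff)
    return ComponentSet(
        components.spatial_maps,
        components.grid_shape,
        labels,
        np.array(best_r),
        np.array(kept, dtype=bool),
    )


def overlap_labels(
    component_mask: np.ndarray,
    region_masks: Mapping[str, np.ndarray],
    ratio_threshold: float = 0.9,
) -> pd.DataFrame:
    """Anatomical annotation by region-overlap ratio.

    ratio = |region AND component| / |region|; a region is "involved" when
    the ratio strictly exceeds ``ratio_threshold`` (default 0.9, i.e. the
    > 90% rule).  Empty regions get ratio NaN, not involved, with a warning.
    """
    comp = np.asarray(component_mask).astype(bool).reshape(-1)
    rows = []
    for name, region in region_masks.items():
        reg = np.asarray(region).astype(bool).reshape(-1)
        if reg.size != comp.size:
            raise ValueError(
                f"region {name!r} has {reg.size} voxels, component mask has "
                f"{comp.size}"
            )
        n_reg = int(reg.sum())
        if n_reg == 0:
            warnings.warn(f"region {name!r} is empty; overlap undefined")
            rows.append({"region": name, "overlap_ratio": np.nan, "involved": False})
            continue
        ratio = float(np.sum(reg & comp)) / n_reg
        rows.append(
            {"region": name, "overlap_ratio": ratio,
             "involved": bool(ratio > ratio_threshold)}
        )
    return pd.DataFrame(rows)


def component_mask(spatial_map: np.ndarray, z_threshold: float = 3.0) -> np.ndarray:
    """Binarize a spatial map at |z-scored weight| > z_threshold."""
    m = np.asarray(spatial_map, float).reshape(-1)
    z = (m - m.mean()) / m.std()
    return np.abs(z) > z_threshold


def subject_timeseries(
    components: ComponentSet,
    volume: np.ndarray,
    cond_max: float = 1e8,
) -> np.ndarray:
    """Stage-1 dual regression: per-volume spatial regression of kept maps.

    Solves, for each time point, the least-squares fit of all kept
    component maps jointly to the voxel vector, returning the T x N matrix
    of subject-specific component time courses (columns ordered by
    component index).
    """
    if volume.shape[:3] != components.grid_shape:
        raise ValueError(
            f"subject grid {volume.shape[:3]} != component grid "
            f"{components.grid_shape}"
        )
    maps = components.kept_maps()
    if maps.shape[0] == 0:
        raise ValueError("no kept components to regress")
    design = maps.T  # V x N
    if np.linalg.cond(design) > cond_max:
        raise ValueError(
            "kept spatial maps are nearly collinear; spatial regression is "
            f"ill-conditioned (cond > {cond_max:g})"
        )
    data = volume.reshape(-1, volume.shape[3])  # V x T
    coef, *_ = np.linalg.lstsq(design, data, rcond=None)  # N x T
    return coef.T
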