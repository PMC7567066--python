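"""Synthetic study generator with known ground truth.

Emulates the study design of a longitudinal subacute-back-pain cohort:
~49 subjects, 240 retained fMRI volumes at TR 2.5 s, pain intensity on a
0-100 visual analog scale (VAS) at four visits spaced roughly 7, 28 and
55 weeks after baseline, and a sparse linear relation planted between
baseline connectome edges and the time-normalized VAS change.

The generative model is deliberately simple so every downstream stage has
a closed-form oracle:

* K spatial sources are non-overlapping Gaussian blobs on a small voxel
  grid (desk-scale stand-in for ICA components).
* Component time courses are i.i.d. multivariate normal across time with
  covariance = inverse(latent_precision), so the true partial correlation
  between components i and j is exactly -Q_ij / sqrt(Q_ii * Q_jj) for the
  latent precision Q.  No hemodynamics, autocorrelation, motion or drift.
* Voxel series are the mixing source_maps^T @ timecourses plus white noise.
* Each subject's normalized VAS slope (VAS/day) is
  planted_weights . z_edges + N(0, noise_sd); VAS at later visits follows
  that single slope linearly (visits 2-3 with small jitter), clamped to
  [0, 100] with clamped subjects flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import connectivity as conn
from ._utils import derive_seed

__all__ = [
    "GroundTruth",
    "SubjectRecord",
    "SyntheticStudy",
    "generate_sources",
    "chain_precision",
    "make_ground_truth",
    "generate_subject_volumes",
    "generate_outcomes",
    "simulate_study",
]

#: Visit-interval means/SDs in weeks for visits 2, 3, 4 relative to baseline.
VISIT_WEEK_MEANS = (6.90, 27.92, 54.68)
VISIT_WEEK_SDS = (2.14, 3.69, 3.83)

DEFAULT_N_SUBJECTS = 49
DEFAULT_N_VOLUMES = 240  # 244 acquired minus 4 dummy volumes
DEFAULT_TR_S = 2.5


@dataclass
class GroundTruth:
    """Known generative parameters of a synthetic study."""

    source_maps: np.ndarray          # K x V, nonnegative
    grid_shape: tuple[int, int, int]
    latent_precision: np.ndarray     # K x K symmetric positive definite
    planted_weights: np.ndarray      # length E = K(K-1)/2, sparse
    noise_sd: float                  # outcome noise, VAS/day
    voxel_noise_sd: float            # additive voxel noise, signal units
    subject_jitter_sd: float         # per-subject time-course jitter
    seed: int

    @property
    def n_components(self) -> int:
        return self.source_maps.shape[0]

    @property
    def n_edges(self) -> int:
        k = self.n_components
        return k * (k - 1) // 2

    def validate(self) -> None:
        p = self.latent_precision
        if not np.allclose(p, p.T):
            raise ValueError("latent_precision must be symmetric")
        if np.any(np.diag(p) <= 0):
            raise ValueError("latent_precision diagonal must be positive")
        eig = np.linalg.eigvalsh(p)
        if eig.min() <= 0:
            raise ValueError("latent_precision must be positive definite")
        if self.planted_weights.size != self.n_edges:
            raise ValueError(
                f"planted_weights has length {self.planted_weights.size}, "
                f"expected {self.n_edges}"
            )
        nnz = np.count_nonzero(self.planted_weights)
        if nnz > 0.1 * self.n_edges:
            raise ValueError(
                f"planted_weights must be sparse (<= 10% nonzero); "
                f"{nnz}/{self.n_edges} are nonzero"
            )
        maps = self.source_maps
        if np.any(maps < 0):
            raise ValueError("source_maps must be nonnegative")
        live = maps[maps.std(axis=1) > 0]
        if len(live) > 1:
            c = np.corrcoef(live)
            off = c[~np.eye(len(c), dtype=bool)]
            if np.max(np.abs(off)) >= 0.3:
                raise ValueError(
                    "source maps must have pairwise spatial |r| < 0.3"
                )

    def true_partial_correlation(self) -> np.ndarray:
        """Closed-form partial correlation implied by the latent precision."""
        q = self.latent_precision
        d = np.sqrt(np.diag(q))
        pr = -q / np.outer(d, d)
        np.fill_diagonal(pr, 1.0)
        return pr

    def to_json(self, path) -> None:
        payload = {
            "grid_shape": list(self.grid_shape),
            "source_maps": self.source_maps.tolist(),
            "latent_precision": self.latent_precision.tolist(),
            "planted_weights": self.planted_weights.tolist(),
            "noise_sd": self.noise_sd,
            "voxel_noise_sd": self.voxel_noise_sd,
            "subject_jitter_sd": self.subject_jitter_sd,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            source_maps=np.asarray(d["source_maps"], float),
            grid_shape=tuple(d["grid_shape"]),
            latent_precision=np.asarray(d["latent_precision"], float),
            planted_weights=np.asarray(d["planted_weights"], float),
            noise_sd=d["noise_sd"],
            voxel_noise_sd=d["voxel_noise_sd"],
            subject_jitter_sd=d["subject_jitter_sd"],
            seed=d["seed"],
        )


@dataclass
class SubjectRecord:
    """One participant: VAS at four visits, visit days, sex, group label."""

    subject_id: str
    sex: int                       # 0 = male, 1 = female
    vas: tuple[float, float, float, float]
    visit_days: tuple[int, int, int, int]
    group: str = "unassigned"      # SBPp | SBPr | unassigned
    clamped: bool = False          # VAS hit the [0, 100] bounds

    def validate(self) -> None:
        if self.visit_days[0] != 0:
            raise ValueError("visit one must be day 0")
        if not all(a < b for a, b in zip(self.visit_days, self.visit_days[1:])):
            raise ValueError("visit_days must be strictly increasing")
        if any(v < 0 or v > 100 for v in self.vas):
            raise ValueError("VAS scores must lie in [0, 100]")
        if self.vas[0] <= 40:
            raise ValueError("baseline VAS must exceed 40 (eligibility)")

    def delta_t(self, visit: int) -> int:
        """Days between baseline and the given visit (2, 3 or 4)."""
        return self.visit_days[visit - 1] - self.visit_days[0]


def generate_sources(
    grid_shape: Sequence[int],
    n_components: int,
    seed: int,
    min_extent: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Place K disjoint Gaussian-blob sources on a voxel grid.

    The grid is partitioned into equal cells of at least ``min_extent``
    voxels per axis; each source peaks at the centre of a distinct cell,
    guaranteeing pairwise spatial correlation < 0.3.

    Returns (maps, peaks): maps is K x V (flattened row-major), peaks is
    K x 3 voxel coordinates.  Deterministic given the seed.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if len(grid_shape) != 3:
        raise ValueError("grid_shape must have three extents")
    if n_components < 2:
        raise ValueError("need at least two components")
    ndiv = [max(1, g // min_extent) for g in grid_shape]
    n_cells = int(np.prod(ndiv))
    if n_cells < n_components:
        raise ValueError(
            f"grid {grid_shape} too small to place {n_components} disjoint "
            f"sources (only {n_cells} cells of >= {min_extent} voxels)"
        )
    rng = np.random.default_rng(seed)
    cells = rng.choice(n_cells, size=n_components, replace=False)
    cell_sizes = [g / d for g, d in zip(grid_shape, ndiv)]
    sigma = min(cell_sizes) / 4.0
    coords = np.stack(
        np.meshgrid(*[np.arange(g) for g in grid_shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    maps = np.empty((n_components, coords.shape[0]))
    peaks = np.empty((n_components, 3))
    for k, cell in enumerate(cells):
        idx = np.unravel_index(cell, ndiv)
        peak = np.array([(i + 0.5) * s for i, s in zip(idx, cell_sizes)])
        d2 = np.sum((coords - peak) ** 2, axis=1)
        maps[k] = np.exp(-d2 / (2.0 * sigma**2))
        peaks[k] = peak
    c = np.corrcoef(maps)
    off = c[~np.eye(n_components, dtype=bool)]
    if off.size and np.max(np.abs(off)) >= 0.3:  # pragma: no cover - guard
        raise RuntimeError("source placement failed the disjointness check")
    return maps, peaks


def chain_precision(n_components: int, coupling: float = -0.35) -> np.ndarray:
    """Tridiagonal precision: neighbours conditionally coupled, others not.

    Diagonally dominant for |coupling| < 0.5, hence positive definite.
    """
    p = np.eye(n_components)
    for i in range(n_components - 1):
        p[i, i + 1] = p[i + 1, i] = coupling
    return p


def make_ground_truth(
    grid_shape: Sequence[int] = (12, 12, 10),
    n_components: int = 12,
    n_planted: int = 3,
    weight_scale: float = 1.0,
    noise_sd: float = 0.01,
    voxel_noise_sd: float = 0.5,
    subject_jitter_sd: float = 0.05,
    seed: int = 0,
) -> GroundTruth:
    """Assemble a full GroundTruth with defaults matching the study design.

    ``weight_scale`` is in (VAS/day) per z-unit of edge strength: with
    between-subject edge SD of roughly 1/sqrt(T-3) ~ 0.065 z at T = 240,
    three planted edges give a normalized-slope spread of ~0.1 VAS/day,
    i.e. changes of tens of VAS points over the ~55-week follow-up.
    """
    maps, _ = generate_sources(grid_shape, n_components, seed=derive_seed(seed, "src"))
    e = n_components * (n_components - 1) // 2
    weights = np.zeros(e)
    if n_planted:
        if n_planted > 0.1 * e:
            raise ValueError(
                f"{n_planted} planted edges exceeds the 10% sparsity cap for E={e}"
            )
        # plant only on conditionally independent (non-adjacent) pairs of
        # the chain precision: their edges fluctuate around zero, so the
        # planted slopes are centred and trajectories rarely clamp
        from .connectivity import edge_index

        null_edges = [
            k for k, (i, j) in enumerate(edge_index(n_components)) if j - i > 1
        ]
        if len(null_edges) < n_planted:
            raise ValueError("not enough conditionally independent edges to plant")
        rng = np.random.default_rng(derive_seed(seed, "weights"))
        chosen = rng.choice(null_edges, size=n_planted, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_planted)
        weights[chosen] = signs * weight_scale
    truth = GroundTruth(
        source_maps=maps,
        grid_shape=tuple(int(g) for g in grid_shape),
        latent_precision=chain_precision(n_components),
        planted_weights=weights,
        noise_sd=float(noise_sd),
        voxel_noise_sd=float(voxel_noise_sd),
        subject_jitter_sd=float(subject_jitter_sd),
        seed=int(seed),
    )
    truth.validate()
    return truth


def _sample_timecourses(
    truth: GroundTruth, n_volumes: int, rng: np.random.Generator
) -> np.ndarray:
    cov = np.linalg.inv(truth.latent_precision)
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_volumes, truth.n_components))
    tc = z @ chol.T
    if truth.subject_jitter_sd > 0:
        tc = tc + truth.subject_jitter_sd * rng.standard_normal(tc.shape)
    return tc


def generate_subject_volumes(
    truth: GroundTruth,
    n_subjects: int = DEFAULT_N_SUBJECTS,
    n_volumes: int = DEFAULT_N_VOLUMES,
    seed: int = 0,
    return_volumes: bool = True,
) -> tuple[list[np.ndarray] | None, list[np.ndarray]]:
    """Draw per-subject component time courses and (optionally) 4-D volumes.

    Returns (volumes, timecourses): volumes is a list of (x, y, z, T)
    arrays (or None when ``return_volumes=False``), timecourses a list of
    the true T x K component series, for oracle tests.
    """
    truth.validate()
    if n_volumes <= truth.n_components:
        raise ValueError("n_volumes must exceed n_components for full-rank data")
    vols = [] if return_volumes else None
    tcs = []
    for s in range(n_subjects):
        rng = np.random.default_rng(derive_seed(seed, "subject", s))
        tc = _sample_timecourses(truth, n_volumes, rng)
        tcs.append(tc)
        if return_volumes:
            flat = truth.source_maps.T @ tc.T  # V x T
            if truth.voxel_noise_sd > 0:
                flat = flat + truth.voxel_noise_sd * rng.standard_normal(flat.shape)
            vols.append(flat.reshape(*truth.grid_shape, n_volumes))
    return vols, tcs


def generate_outcomes(
    truth: GroundTruth,
    edge_table: np.ndarray,
    seed: int = 0,
    visit_week_means: Sequence[float] = VISIT_WEEK_MEANS,
    visit_week_sds: Sequence[float] = VISIT_WEEK_SDS,
    vas_jitter_sd: float = 1.0,
    female_fraction: float = 0.49,
) -> list[SubjectRecord]:
    """Generate VAS trajectories from baseline edges via the planted model.

    Per subject: normalized slope r = planted_weights . edges + N(0, noise_sd)
    in VAS/day; baseline VAS ~ Uniform(41, 100); VAS at visit n is
    VAS_1 + r * dt_1n (visits 2-3 with N(0, vas_jitter_sd) jitter), clamped
    to [0, 100] with the clamp flagged.  Visit days are drawn from the
    stated week-scale means/SDs, converted at 7 days/week, rounded, and
    forced strictly increasing; visit one is day 0.
    """
    x = np.asarray(edge_table, float)
    if x.ndim != 2 or x.shape[1] != truth.planted_weights.size:
        raise ValueError(
            f"edge_table must be subjects x {truth.planted_weights.size}"
        )
    records = []
    for s in range(x.shape[0]):
        rng = np.random.default_rng(derive_seed(seed, "outcome", s))
        rate = float(truth.planted_weights @ x[s])
        if truth.noise_sd > 0:
            rate += truth.noise_sd * rng.standard_normal()
        vas1 = rng.uniform(41.0, 100.0)
        weeks = []
        prev = 0.0
        for mu, sd in zip(visit_week_means, visit_week_sds):
            w = max(prev + 1.0, rng.normal(mu, sd))
            weeks.append(w)
            prev = w
        days = [0] + [int(round(7 * w)) for w in weeks]
        for i in range(1, 4):  # rounding can still collide
            if days[i] <= days[i - 1]:
                days[i] = days[i - 1] + 1
        vas = [vas1]
        clamped = False
        for visit, d in enumerate(days[1:], start=2):
            v = vas1 + rate * d
            if visit in (2, 3) and vas_jitter_sd > 0:
                v += vas_jitter_sd * rng.standard_normal()
            vc = min(100.0, max(0.0, v))
            clamped = clamped or (vc != v)
            vas.append(vc)
        records.append(
            SubjectRecord(
                subject_id=f"sub-{s + 1:03d}",
                sex=int(rng.uniform() < female_fraction),
                vas=tuple(vas),
                visit_days=tuple(days),
                clamped=clamped,
            )
        )
        records[-1].validate()
    return records


@dataclass
class SyntheticStudy:
    """A complete synthetic cohort: ground truth, data and outcomes."""

    truth: GroundTruth
    records: list[SubjectRecord]
    edge_table: conn.EdgeTable
    timecourses: list[np.ndarray]
    volumes: list[np.ndarray] | None = None

    @property
    def rates(self) -> np.ndarray:
        """Actual normalized VAS slopes (VAS/day), visit 1 -> 4."""
        return np.array(
            [(r.vas[3] - r.vas[0]) / r.delta_t(4) for r in self.records]
        )

    def subject_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "subject_id": r.subject_id,
                    "sex": r.sex,
                    **{f"vas_v{i + 1}": r.vas[i] for i in range(4)},
                    **{f"days_v{i + 1}": r.visit_days[i] for i in range(4)},
                }
            )
        return pd.DataFrame(rows)


def simulate_study(
    n_subjects: int = DEFAULT_N_SUBJECTS,
    n_volumes: int = DEFAULT_N_VOLUMES,
    grid_shape: Sequence[int] = (12, 12, 10),
    n_components: int = 12,
    n_planted: int = 3,
    noise_sd: float = 0.01,
    voxel_noise_sd: float = 0.5,
    rho: float = 0.01,
    seed: int = 0,
    include_volumes: bool = False,
    vas_jitter_sd: float = 1.0,
    **truth_kwargs,
) -> SyntheticStudy:
    """One-call cohort generator used by tests, the CLI and acceptance runs.

    Edges are computed from the *true* component time courses with the same
    ridge partial-correlation + Fisher-z pipeline applied downstream, then
    outcomes are planted on those edges.
    """
    truth = make_ground_truth(
        grid_shape=grid_shape,
        n_components=n_components,
        n_planted=n_planted,
        noise_sd=noise_sd,
        voxel_noise_sd=voxel_noise_sd,
        seed=seed,
        **truth_kwargs,
    )
    vols, tcs = generate_subject_volumes(
        truth,
        n_subjects=n_subjects,
        n_volumes=n_volumes,
        seed=derive_seed(seed, "vols"),
        return_volumes=include_volumes,
    )
    mats = [
        conn.partial_correlation(tc, rho=rho, subject_id=f"sub-{s + 1:03d}")
        for s, tc in enumerate(tcs)
    ]
    edges = conn.vectorize_edges(mats)
    records = generate_outcomes(
        truth, edges.matrix, seed=derive_seed(seed, "outcomes"),
        vas_jitter_sd=vas_jitter_sd,
    )
    return SyntheticStudy(
        truth=truth,
        records=records,
        edge_table=edges,
        timecourses=tcs,
        volumes=vols,
    )


def write_study(study: SyntheticStudy, out_dir) -> None:
    """Persist a study: 4-D NIfTI per subject, subject CSV, truth sidecar."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study.subject_frame().to_csv(out / "subjects.csv", index=False)
    study.truth.to_json(out / "ground_truth.json")
    if study.volumes is not None:
        for rec, vol in zip(study.records, study.volumes):
            img = nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4))
            nib.save(img, out / f"{rec.subject_id}_bold.nii")
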