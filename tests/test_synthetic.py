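"""Generator tests: determinism, mixing fidelity, outcome identifiability."""

import numpy as np
import pytest

from painnet import synthetic as syn


class TestSources:
    def test_disjoint_peaks_and_low_overlap(self):
        maps, peaks = syn.generate_sources((8, 8, 8), 2, seed=1)
        assert maps.shape == (2, 512)
        assert np.all(maps >= 0)
        r = np.corrcoef(maps)[0, 1]
        assert abs(r) < 0.3
        assert not np.allclose(peaks[0], peaks[1])

    def test_deterministic(self):
        a, _ = syn.generate_sources((8, 8, 8), 2, seed=1)
        b, _ = syn.generate_sources((8, 8, 8), 2, seed=1)
        np.testing.assert_array_equal(a, b)

    def test_grid_too_small(self):
        with pytest.raises(ValueError, match="too small"):
            syn.generate_sources((2, 2, 2), 50, seed=0)

    def test_many_sources_stay_dissimilar(self):
        maps, _ = syn.generate_sources((12, 12, 10), 12, seed=4)
        c = np.corrcoef(maps)
        off = c[~np.eye(12, dtype=bool)]
        assert np.max(np.abs(off)) < 0.3


class TestGroundTruth:
    def test_validate_catches_dense_weights(self):
        truth = syn.make_ground_truth(seed=0)
        truth.planted_weights = np.ones(truth.n_edges)
        with pytest.raises(ValueError, match="sparse"):
            truth.validate()

    def test_validate_requires_spd_precision(self):
        truth = syn.make_ground_truth(seed=0)
        truth.latent_precision = syn.chain_precision(12, coupling=-0.9)
        with pytest.raises(ValueError, match="positive definite"):
            truth.validate()

    def test_json_round_trip(self, tmp_path):
        truth = syn.make_ground_truth(grid_shape=(8, 8, 6), n_components=6,
                                      n_planted=1, seed=2)
        truth.to_json(tmp_path / "gt.json")
        back = syn.GroundTruth.from_json(tmp_path / "gt.json")
        np.testing.assert_array_equal(back.source_maps, truth.source_maps)
        np.testing.assert_array_equal(back.planted_weights, truth.planted_weights)
        assert back.grid_shape == truth.grid_shape


class TestVolumes:
    def test_deterministic(self):
        truth = syn.make_ground_truth(grid_shape=(8, 8, 6), n_components=4,
                                      n_planted=0, seed=2)
        v1, t1 = syn.generate_subject_volumes(truth, n_subjects=2, n_volumes=30, seed=9)
        v2, t2 = syn.generate_subject_volumes(truth, n_subjects=2, n_volumes=30, seed=9)
        np.testing.assert_array_equal(v1[0], v2[0])
        np.testing.assert_array_equal(t1[1], t2[1])

    def test_pure_mixing_is_scalar_multiple_in_blob(self):
        # one-component limit: with zero voxel noise every in-blob voxel
        # series is proportional to the component time course
        truth = syn.make_ground_truth(grid_shape=(8, 8, 6), n_components=2,
                                      n_planted=0, voxel_noise_sd=0.0,
                                      subject_jitter_sd=0.0, seed=2)
        # silence the second component so single-source mixing is exact
        truth.source_maps[1] = 0.0
        vols, tcs = syn.generate_subject_volumes(truth, 1, n_volumes=40, seed=1)
        flat = vols[0].reshape(-1, 40)
        voxel = np.argmax(truth.source_maps[0])
        expected = truth.source_maps[0][voxel] * tcs[0][:, 0]
        np.testing.assert_allclose(flat[voxel], expected, atol=1e-12)

    def test_mixing_fidelity_regression_recovery(self):
        # regressing the true maps onto noiseless volumes returns the true
        # time courses essentially exactly
        truth = syn.make_ground_truth(grid_shape=(10, 10, 8), n_components=4,
                                      n_planted=0, voxel_noise_sd=0.0, seed=3)
        vols, tcs = syn.generate_subject_volumes(truth, 1, n_volumes=60, seed=4)
        flat = vols[0].reshape(-1, 60)
        rec, *_ = np.linalg.lstsq(truth.source_maps.T, flat, rcond=None)
        for k in range(4):
            r = np.corrcoef(rec[k], tcs[0][:, k])[0, 1]
            assert r > 0.999

    def test_chain_precision_conditional_independence(self):
        # components 1 and 3 of a chain are conditionally independent given
        # 2; the residual-regression partial correlation on the true time
        # courses must be ~0 at large T
        truth = syn.make_ground_truth(grid_shape=(8, 8, 6), n_components=3,
                                      n_planted=0, subject_jitter_sd=0.0, seed=6)
        _, tcs = syn.generate_subject_volumes(
            truth, 1, n_volumes=5000, seed=8, return_volumes=False
        )
        tc = tcs[0]
        # residual-regression oracle
        def resid(a, b):
            bb = np.column_stack([np.ones(len(b)), b])
            beta, *_ = np.linalg.lstsq(bb, a, rcond=None)
            return a - bb @ beta
        r13_2 = np.corrcoef(resid(tc[:, 0], tc[:, 1]), resid(tc[:, 2], tc[:, 1]))[0, 1]
        assert abs(r13_2) < 0.05

    def test_rejects_bad_precision(self):
        truth = syn.make_ground_truth(grid_shape=(8, 8, 6), n_components=4,
                                      n_planted=0, seed=2)
        truth.latent_precision = -np.eye(4)
        with pytest.raises(ValueError):
            syn.generate_subject_volumes(truth, 1, n_volumes=30, seed=0)


class TestOutcomes:
    @staticmethod
    def _truth_and_edges(noise_sd, n_subjects=12, n_planted=1, seed=0):
        truth = syn.make_ground_truth(grid_shape=(8, 8, 6), n_components=6,
                                      n_planted=n_planted, noise_sd=noise_sd, seed=seed)
        rng = np.random.default_rng(42)
        edges = 0.1 * rng.standard_normal((n_subjects, truth.n_edges))
        return truth, edges

    def test_zero_rate_means_flat_trajectory(self):
        truth, edges = self._truth_and_edges(noise_sd=0.0, n_planted=0)
        recs = syn.generate_outcomes(truth, edges, seed=1, vas_jitter_sd=0.0)
        for r in recs:
            assert r.vas[3] == r.vas[0]

    def test_noiseless_rates_reconstruct_exactly(self):
        truth, edges = self._truth_and_edges(noise_sd=0.0)
        recs = syn.generate_outcomes(truth, edges, seed=1, vas_jitter_sd=0.0)
        for i, r in enumerate(recs):
            if r.clamped:
                continue
            rate = (r.vas[3] - r.vas[0]) / r.delta_t(4)
            assert rate == pytest.approx(truth.planted_weights @ edges[i], abs=1e-12)

    def test_cohort_invariants_at_study_scale(self, study49):
        assert len(study49.records) == 49
        for r in study49.records:
            r.validate()  # days increasing, VAS in range, baseline > 40
        days = np.array([r.visit_days for r in study49.records])
        assert np.all(days[:, 0] == 0)
        # mean intervals should sit near the design's 6.9 / 27.9 / 54.7 weeks
        weeks = days[:, 1:].mean(axis=0) / 7.0
        assert abs(weeks[0] - 6.9) < 2
        assert abs(weeks[1] - 27.9) < 3
        assert abs(weeks[2] - 54.7) < 3

    def test_noiseless_ols_identifiability(self, study_noiseless):
        # with no outcome noise the planted weights are exactly recoverable
        # by OLS on the true edges (unclamped subjects)
        s = study_noiseless
        keep = np.array([not r.clamped for r in s.records])
        planted = np.flatnonzero(s.truth.planted_weights)
        x = s.edge_table.matrix[np.ix_(keep, planted)]
        y = s.rates[keep]
        d = np.column_stack([np.ones(keep.sum()), x])
        beta, *_ = np.linalg.lstsq(d, y, rcond=None)
        np.testing.assert_allclose(
            beta[1:], s.truth.planted_weights[planted], atol=1e-8
        )
        assert abs(beta[0]) < 1e-8

    def test_deterministic(self):
        truth, edges = self._truth_and_edges(noise_sd=0.01)
        a = syn.generate_outcomes(truth, edges, seed=5)
        b = syn.generate_outcomes(truth, edges, seed=5)
        assert [r.vas for r in a] == [r.vas for r in b]
        assert [r.visit_days for r in a] == [r.visit_days for r in b]
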