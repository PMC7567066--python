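"""Connectivity tests against independent residual-regression oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from painnet import connectivity as conn


def partial_corr_oracle(ts):
    """Independent oracle: correlation of residuals after regressing out
    all other columns (two-pass OLS, no precision matrix)."""
    t, n = ts.shape
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            others = np.delete(np.arange(n), [i, j])
            d = np.column_stack([np.ones(t), ts[:, others]])
            ri = ts[:, i] - d @ np.linalg.lstsq(d, ts[:, i], rcond=None)[0]
            rj = ts[:, j] - d @ np.linalg.lstsq(d, ts[:, j], rcond=None)[0]
            out[i, j] = out[j, i] = np.corrcoef(ri, rj)[0, 1]
    return out


def data_with_exact_correlation(c, t, seed=0):
    """T x N data whose *sample* correlation matrix equals c exactly."""
    n = c.shape[0]
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((t, n))
    x -= x.mean(axis=0)
    q, _ = np.linalg.qr(x)          # orthonormal, mean ~0 columns
    q -= q.mean(axis=0)
    q, _ = np.linalg.qr(q)          # re-orthonormalize after centring
    y = q @ np.linalg.cholesky(c).T
    y /= y.std(axis=0, ddof=1)
    return y


class TestPartialCorrelation:
    def test_conditional_independence_identity(self):
        # r13 = r12 * r23  =>  partial r13 = 0 (numerator r13 - r12 r23)
        c = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.5], [0.3, 0.5, 1.0]])
        ts = data_with_exact_correlation(c, t=50, seed=1)
        pc = conn.partial_correlation(ts, rho=0.0)
        assert abs(pc.values[0, 2]) < 1e-10

    def test_matches_residual_regression_oracle(self, rng):
        for rep in range(5):
            ts = rng.standard_normal((120, 6))
            pc = conn.partial_correlation(ts, rho=0.0)
            np.testing.assert_allclose(pc.values, partial_corr_oracle(ts), atol=1e-6)

    def test_independent_columns_near_zero(self, rng):
        ts = rng.standard_normal((10_000, 5))
        pc = conn.partial_correlation(ts, rho=0.01)
        off = pc.values[~np.eye(5, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_exact_symmetry_and_unit_diagonal(self, rng):
        pc = conn.partial_correlation(rng.standard_normal((60, 7)), rho=0.01)
        np.testing.assert_array_equal(pc.values, pc.values.T)
        np.testing.assert_array_equal(np.diag(pc.values), np.ones(7))
        off = pc.values[~np.eye(7, dtype=bool)]
        assert np.all(np.abs(off) < 1)

    def test_monotone_shrinkage_in_rho(self, rng):
        ts = rng.standard_normal((80, 6)) @ np.linalg.cholesky(
            0.5 * np.eye(6) + 0.5
        )
        prev = np.inf
        for rho in [0.0, 0.01, 0.1, 1.0, 10.0]:
            pc = conn.partial_correlation(ts, rho=rho)
            peak = np.max(np.abs(pc.values[~np.eye(6, dtype=bool)]))
            assert peak <= prev + 1e-12
            prev = peak

    def test_zero_variance_column_named(self, rng):
        ts = rng.standard_normal((50, 4))
        ts[:, 2] = 3.0
        with pytest.raises(ValueError, match=r"\[2\]"):
            conn.partial_correlation(ts)

    def test_too_few_timepoints(self, rng):
        with pytest.raises(ValueError, match="time points"):
            conn.partial_correlation(rng.standard_normal((5, 8)))

    def test_rank_deficient_needs_ridge(self, rng):
        ts = rng.standard_normal((50, 4))
        ts[:, 3] = ts[:, 0] + ts[:, 1]  # exact collinearity
        with pytest.raises(np.linalg.LinAlgError, match="rho > 0"):
            conn.partial_correlation(ts, rho=0.0)
        conn.partial_correlation(ts, rho=0.01)  # regularized version works


class TestFisherZ:
    def test_reference_values(self):
        assert conn.fisher_z(0.0) == 0.0
        assert conn.fisher_z(0.5) == pytest.approx(0.5 * np.log(3), abs=1e-12)
        assert conn.fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    @settings(deadline=None)
    @given(st.floats(min_value=-0.999, max_value=0.999))
    def test_odd_and_monotone(self, r):
        assert conn.fisher_z(-r) == pytest.approx(-conn.fisher_z(r), abs=1e-12)
        if abs(r) < 0.99:
            assert conn.fisher_z(r + 0.001) > conn.fisher_z(r)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            conn.fisher_z(1.0)

    def test_matrix_z_variant_is_atanh(self, rng):
        pc = conn.partial_correlation(rng.standard_normal((60, 5)), rho=0.01)
        z = pc.to_z()
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(z.values[off], np.arctanh(pc.values[off]))
        assert z.is_z and not pc.is_z


class TestEdgeTable:
    @pytest.mark.parametrize("n,e", [(4, 6), (12, 66), (43, 903)])
    def test_edge_count(self, n, e):
        assert len(conn.edge_index(n)) == e

    def test_vectorize_round_trip(self, rng):
        mats = [
            conn.partial_correlation(rng.standard_normal((60, 5)),
                                     subject_id=f"s{i}")
            for i in range(3)
        ]
        table = conn.vectorize_edges(mats)
        assert table.matrix.shape == (3, 10)
        # devectorize reproduces the z-matrix exactly
        for i, m in enumerate(mats):
            z = m.to_z().values
            np.testing.assert_allclose(table.to_matrix(i), z, atol=1e-12)

    def test_inconsistent_n_rejected(self, rng):
        mats = [
            conn.partial_correlation(rng.standard_normal((60, 5))),
            conn.partial_correlation(rng.standard_normal((60, 4))),
        ]
        with pytest.raises(ValueError, match="inconsistent"):
            conn.vectorize_edges(mats)

    def test_csv_round_trip(self, tmp_path, rng):
        mats = [conn.partial_correlation(rng.standard_normal((50, 4)),
                                         subject_id=f"s{i}") for i in range(3)]
        table = conn.vectorize_edges(mats)
        table.to_csv(tmp_path / "edges.csv")
        back = conn.EdgeTable.from_csv(tmp_path / "edges.csv")
        np.testing.assert_allclose(back.matrix, table.matrix, atol=1e-12)
        assert back.subject_ids == table.subject_ids
        assert back.edge_names == table.edge_names


class TestResidualize:
    def _table(self, matrix):
        n = 4  # any N with matching E works for these column-wise tests
        e = n * (n - 1) // 2
        assert matrix.shape[1] == e
        return conn.EdgeTable(matrix, n_components=n)

    def test_orthogonal_covariate_only_centres(self, rng):
        cov = np.array([1.0, -1.0, 1.0, -1.0])
        col = np.array([2.0, 2.0, 5.0, 5.0])  # zero sample covariance with cov
        m = np.tile(col[:, None], (1, 6))
        out = conn.residualize_covariate(self._table(m), cov)
        np.testing.assert_allclose(out.matrix, m - col.mean(), atol=1e-12)

    def test_proportional_column_zeroed(self):
        cov = np.array([1.0, 2.0, 3.0, 4.0])
        m = np.tile((3 * cov)[:, None], (1, 6))
        out = conn.residualize_covariate(self._table(m), cov)
        np.testing.assert_allclose(out.matrix, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        m = rng.standard_normal((8, 6))
        cov = rng.standard_normal(8)
        out = conn.residualize_covariate(self._table(m), cov)
        d = np.column_stack([np.ones(8), cov])
        beta = np.linalg.solve(d.T @ d, d.T @ m)  # normal equations
        np.testing.assert_allclose(out.matrix, m - d @ beta, atol=1e-10)

    def test_idempotent(self, rng):
        m = rng.standard_normal((10, 6))
        cov = rng.standard_normal(10)
        once = conn.residualize_covariate(self._table(m), cov)
        twice = conn.residualize_covariate(once, cov)
        np.testing.assert_allclose(twice.matrix, once.matrix, atol=1e-10)

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            conn.residualize_covariate(
                self._table(rng.standard_normal((5, 6))), np.ones(5)
            )
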