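import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gmchaos import errors
from gmchaos.chaos import (
    EmbeddingConfig,
    LambdaMap,
    LambdaSeries,
    divergence_curve,
    embed,
    lambda_global,
    lambda_local,
    lambda_map,
    lyapunov_from_series,
    nearest_neighbors,
    smooth_map,
)
from tests.conftest import logistic_series


def brute_force_neighbors(X, theiler):
    m_rows = len(X)
    out = np.full(m_rows, -1)
    for k in range(m_rows):
        best, best_d = -1, np.inf
        for j in range(m_rows):
            if abs(k - j) <= theiler:
                continue
            d = np.linalg.norm(X[k] - X[j])
            if d < best_d:
                best, best_d = j, d
        out[k] = best
    return out


class TestEmbed:
    def test_row_count_and_first_row(self):
        traj = embed(np.arange(5.0), EmbeddingConfig(m=2, tau=1, fit_range=(1, 2), max_steps=2))
        assert traj.n_states == 4
        np.testing.assert_array_equal(traj.states[0], [0, 1])

    def test_identity_embedding(self):
        x = np.arange(7.0)
        traj = embed(x, EmbeddingConfig(m=1, tau=1, fit_range=(1, 2), max_steps=2))
        assert traj.states.shape == (7, 1)
        np.testing.assert_array_equal(traj.states[:, 0], x)

    def test_index_arithmetic(self):
        x = np.arange(10.0) ** 2
        cfg = EmbeddingConfig(m=3, tau=2, fit_range=(1, 2), max_steps=2)
        traj = embed(x, cfg)
        assert traj.n_states == 6
        for k in range(6):
            np.testing.assert_array_equal(traj.states[k], [x[k], x[k + 2], x[k + 4]])

    def test_too_short_rejected(self):
        with pytest.raises(errors.SeriesTooShortError):
            embed(np.arange(5.0), EmbeddingConfig(m=3, tau=2, fit_range=(1, 2), max_steps=2))

    @settings(deadline=None, max_examples=60)
    @given(
        n=st.integers(min_value=3, max_value=200),
        m=st.integers(min_value=1, max_value=6),
        tau=st.integers(min_value=1, max_value=5),
    )
    def test_row_count_property(self, n, m, tau):
        if n <= (m - 1) * tau + 1:
            return
        x = np.sin(np.arange(n, dtype=float))
        traj = embed(x, EmbeddingConfig(m=m, tau=tau, fit_range=(0, 1), max_steps=1))
        assert traj.n_states == n - (m - 1) * tau


class TestNearestNeighbors:
    def test_tie_break_smaller_index(self):
        x = np.array([0.0, 1.0, 2.0])
        traj = embed(x, EmbeddingConfig(m=1, fit_range=(0, 1), max_steps=1))
        nbrs = nearest_neighbors(traj, theiler=0)
        assert nbrs[1] == 0  # equidistant to 0 and 2; smaller index wins

    def test_theiler_exhausts_candidates(self):
        traj = embed(np.arange(5.0), EmbeddingConfig(m=1, fit_range=(0, 1), max_steps=1))
        assert np.all(nearest_neighbors(traj, theiler=4) == -1)

    def test_matches_brute_force(self, rng):
        for theiler in (0, 1, 3):
            X = rng.random((50, 2))
            traj = type("T", (), {"states": X})()
            np.testing.assert_array_equal(
                nearest_neighbors(traj, theiler), brute_force_neighbors(X, theiler)
            )


class TestDivergenceCurve:
    def test_geometric_series_exact_slope(self):
        # x_i = c * r^i gives pair distances proportional to r^(k+s), so
        # every reference's log-divergence advances by exactly ln r per
        # step (the step-wise mean is only linear over a fixed pair set,
        # which shrinks as pairs run off the trajectory end)
        r = 1.1
        x = 0.01 * r ** np.arange(60)
        cfg = EmbeddingConfig(m=2, tau=1, theiler=1, fit_range=(0, 10), max_steps=10)
        traj = embed(x, cfg)
        nbrs = nearest_neighbors(traj, 1)
        curve = divergence_curve(traj, nbrs, cfg)
        per_ref_steps = np.diff(curve.per_reference, axis=1)
        valid = np.isfinite(per_ref_steps)
        assert valid.any()
        np.testing.assert_allclose(per_ref_steps[valid], np.log(r), atol=1e-9)
        # surviving-pair restriction: refs valid through the horizon give a
        # mean curve with the exact slope
        full = np.isfinite(curve.per_reference).all(axis=1)
        mean_fixed = curve.per_reference[full].mean(axis=0)
        np.testing.assert_allclose(np.diff(mean_fixed), np.log(r), atol=1e-9)

    def test_zero_distance_pairs_excluded(self):
        x = np.array([1.0, 2.0, 1.0, 2.0, 5.0, 9.0])
        cfg = EmbeddingConfig(m=2, tau=1, theiler=0, fit_range=(0, 1), max_steps=2)
        traj = embed(x, cfg)
        # rows 0 and 2 are identical -> their pair distance is 0 at step 0
        nbrs = nearest_neighbors(traj, 0)
        curve = divergence_curve(traj, nbrs, cfg)
        assert curve.n_zero_excluded > 0
        assert np.all(np.isfinite(curve.mean_log_div[curve.counts > 0]))

    def test_matches_brute_force(self, rng):
        x = rng.random(40)
        cfg = EmbeddingConfig(m=3, tau=1, theiler=2, fit_range=(0, 5), max_steps=8)
        traj = embed(x, cfg)
        nbrs = nearest_neighbors(traj, 2)
        curve = divergence_curve(traj, nbrs, cfg)
        X = traj.states
        m_rows = len(X)
        for s in range(9):
            logs = []
            for k in range(m_rows):
                j = nbrs[k]
                if j < 0 or k + s >= m_rows or j + s >= m_rows:
                    continue
                d = np.linalg.norm(X[k + s] - X[j + s])
                if d > 0:
                    logs.append(np.log(d))
            if logs:
                np.testing.assert_allclose(curve.mean_log_div[s], np.mean(logs), atol=1e-12)
                assert curve.counts[s] == len(logs)

    def test_constant_series_degenerate(self):
        x = np.ones(30)
        cfg = EmbeddingConfig(m=2, tau=1, theiler=1, fit_range=(0, 2), max_steps=4)
        traj = embed(x, cfg)
        nbrs = nearest_neighbors(traj, 1)
        with pytest.raises(errors.DegenerateSeriesError):
            divergence_curve(traj, nbrs, cfg)


class TestLambdaGlobal:
    def test_exact_line(self):
        cfg = EmbeddingConfig(m=2, tau=1, fit_range=(0, 8), max_steps=10)
        from gmchaos.chaos import DivergenceCurve

        steps = np.arange(11)
        curve = DivergenceCurve(
            steps=steps,
            mean_log_div=0.25 * steps - 3.0,
            counts=np.full(11, 5),
            per_reference=np.zeros((5, 11)),
        )
        est = lambda_global(curve, cfg)
        assert est.lambda_global == pytest.approx(0.25)
        assert est.fit_r2 == pytest.approx(1.0)

    def test_logistic_map_recovers_ln2(self):
        """Rosenstein estimate on the r=4 logistic map vs the orbit-average oracle."""
        x = logistic_series(5000)
        analytic = np.mean(np.log(np.abs(4.0 - 8.0 * x)))  # = ln 2 in the limit
        cfg = EmbeddingConfig(m=2, tau=1, fit_range=(0, 6), max_steps=20)
        est, _ = lyapunov_from_series(x, cfg)
        assert abs(est.lambda_global - analytic) / analytic < 0.05
        assert abs(est.lambda_global - np.log(2.0)) / np.log(2.0) < 0.05

    def test_periodic_series_near_zero_slope(self):
        n = np.arange(5000)
        x = np.sin(2.0 * np.pi * n / (10.0 * np.sqrt(2.0)))
        cfg = EmbeddingConfig(m=2, tau=1, fit_range=(0, 6), max_steps=20)
        est, _ = lyapunov_from_series(x, cfg)
        assert abs(est.lambda_global) < 0.02


class TestLambdaLocal:
    def _linear_curve(self, m_rows, slope, n_steps=6):
        from gmchaos.chaos import DivergenceCurve

        steps = np.arange(n_steps)
        per_ref = np.tile(slope * steps, (m_rows, 1)) - 2.0
        return DivergenceCurve(
            steps=steps,
            mean_log_div=per_ref.mean(axis=0),
            counts=np.full(n_steps, m_rows),
            per_reference=per_ref,
        )

    def test_constant_slope_everywhere(self):
        cfg = EmbeddingConfig(fit_range=(0, 3), max_steps=5)
        curve = self._linear_curve(10, 0.4)
        ls = lambda_local(curve, cfg)
        np.testing.assert_allclose(ls.values, 0.4)

    def test_t_step_scaling(self):
        curve = self._linear_curve(10, 0.4)
        cfg1 = EmbeddingConfig(T_step=1.0, fit_range=(0, 3), max_steps=5)
        cfg2 = EmbeddingConfig(T_step=2.0, fit_range=(0, 3), max_steps=5)
        np.testing.assert_allclose(
            lambda_local(curve, cfg2).values, lambda_local(curve, cfg1).values / 2.0
        )

    def test_matches_brute_force_finite_difference(self, rng):
        x = rng.random(30)
        cfg = EmbeddingConfig(m=2, tau=1, theiler=1, fit_range=(0, 3), max_steps=5)
        traj = embed(x, cfg)
        nbrs = nearest_neighbors(traj, 1)
        curve = divergence_curve(traj, nbrs, cfg)
        ls = lambda_local(curve, cfg)
        X = traj.states
        for k in range(traj.n_states):
            j = nbrs[k]
            if j < 0 or k + 1 >= traj.n_states or j + 1 >= traj.n_states:
                continue
            d0 = np.linalg.norm(X[k] - X[j])
            d1 = np.linalg.norm(X[k + 1] - X[j + 1])
            if d0 > 0 and d1 > 0:
                assert ls.values[k] == pytest.approx(np.log(d1) - np.log(d0))

    def test_mean_local_matches_global_for_linear_curve(self):
        cfg = EmbeddingConfig(fit_range=(0, 4), max_steps=5)
        curve = self._linear_curve(20, 0.31)
        est = lambda_global(curve, cfg)
        ls = lambda_local(curve, cfg)
        assert np.nanmean(ls.values) == pytest.approx(est.lambda_global)


class TestLambdaInvariances:
    @pytest.mark.parametrize("transform", ["shift", "scale"])
    def test_series_affine_invariance(self, rng, transform):
        x = rng.random(400)
        cfg = EmbeddingConfig(m=3, tau=1, fit_range=(1, 8), max_steps=12)
        est0, _ = lyapunov_from_series(x, cfg)
        y = x + 7.3 if transform == "shift" else x * 4.2
        est1, _ = lyapunov_from_series(y, cfg)
        assert est1.lambda_global == pytest.approx(est0.lambda_global, abs=1e-10)


class TestLambdaMap:
    def test_three_selected_voxels(self, iso_affine):
        ls = LambdaSeries(
            values=np.array([0.1, -0.2, 0.3]),
            voxel_indices=np.array([[0, 0, 0], [3, 3, 3], [7, 7, 7]]),
        )
        lmap = lambda_map(ls, (8, 8, 8), iso_affine)
        assert np.count_nonzero(lmap.data) == 3
        assert lmap.data[3, 3, 3] == -0.2

    def test_empty_series_all_zero(self, iso_affine):
        ls = LambdaSeries(values=np.zeros(0), voxel_indices=np.zeros((0, 3), dtype=int))
        lmap = lambda_map(ls, (4, 4, 4), iso_affine)
        assert not lmap.data.any()

    def test_gather_scatter_identity(self, rng, iso_affine):
        idx = rng.choice(6 * 6 * 6, size=20, replace=False)
        voxels = np.column_stack(np.unravel_index(idx, (6, 6, 6)))
        values = rng.standard_normal(20)
        ls = LambdaSeries(values=values, voxel_indices=voxels)
        lmap = lambda_map(ls, (6, 6, 6), iso_affine)
        np.testing.assert_allclose(lmap.data[tuple(voxels.T)], values)

    def test_flagged_missing_written_as_zero(self, iso_affine):
        ls = LambdaSeries(
            values=np.array([0.5, np.nan]),
            voxel_indices=np.array([[1, 1, 1], [2, 2, 2]]),
        )
        lmap = lambda_map(ls, (4, 4, 4), iso_affine)
        assert lmap.data[2, 2, 2] == 0.0
        assert lmap.data[1, 1, 1] == 0.5

    def test_out_of_bounds_rejected(self, iso_affine):
        ls = LambdaSeries(values=np.array([1.0]), voxel_indices=np.array([[9, 0, 0]]))
        with pytest.raises(errors.ShapeMismatchError):
            lambda_map(ls, (4, 4, 4), iso_affine)


class TestSmoothMap:
    def test_delta_gives_analytic_gaussian_peak(self, iso_affine):
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 1.0
        lmap = LambdaMap(data, iso_affine)
        out = smooth_map(lmap, fwhm_mm=8.0)
        sigma_vox = 8.0 / (1.5 * np.sqrt(8 * np.log(2)))
        peak = (1.0 / (sigma_vox * np.sqrt(2 * np.pi))) ** 3
        assert out.data[10, 10, 10] == pytest.approx(peak, rel=1e-3)

    def test_sub_voxel_fwhm_is_identity(self, rng, iso_affine):
        lmap = LambdaMap(rng.random((10, 10, 10)), iso_affine)
        out = smooth_map(lmap, fwhm_mm=1e-4)
        np.testing.assert_allclose(out.data, lmap.data, atol=1e-6)

    def test_constant_map_interior_unchanged(self, iso_affine):
        lmap = LambdaMap(np.ones((30, 30, 30)), iso_affine)
        out = smooth_map(lmap, fwhm_mm=8.0)
        assert out.data[15, 15, 15] == pytest.approx(1.0, abs=1e-9)

    def test_non_positive_fwhm_rejected(self, iso_affine):
        with pytest.raises(ValueError):
            smooth_map(LambdaMap(np.ones((4, 4, 4)), iso_affine), fwhm_mm=0.0)
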