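"""Pointwise SDs, statistical shape models, and the growth-curve builder."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from facegrowth import (
    GenerativeSpec,
    build_growth_curves,
    default_age_grid,
    fit_ssm,
    mahalanobis_sq,
    pointwise_sd,
    simulate_cohort,
    ssm_project,
)
from facegrowth.errors import (
    InsufficientDataError,
    InvalidModelError,
    ValidationError,
)
from facegrowth.mesh import AxisConvention
from facegrowth.regression import KernelConfig
from facegrowth.simulate import base_topology
from facegrowth.variation import SSM


def _unit_normals(rng, k):
    n = rng.standard_normal((k, 3))
    return n / np.linalg.norm(n, axis=1, keepdims=True)


class TestPointwiseSD:
    def test_two_point_axis_displacement(self):
        """Two subjects displaced +/- d along one axis: sd on that axis = d."""
        k, d = 5, 1.7
        residuals = np.zeros((2, 3 * k))
        D = residuals.reshape(2, k, 3)
        D[0, 2, 0] = d
        D[1, 2, 0] = -d
        normals = np.tile([0.0, 0.0, 1.0], (k, 1))
        sd = pointwise_sd(residuals, np.ones(2), normals)
        assert sd.sd_ml[2] == pytest.approx(d)
        assert sd.sd_ml[[0, 1, 3, 4]] == pytest.approx(0.0)
        assert sd.sd_magnitude[2] == pytest.approx(d)

    def test_zero_residuals_give_zero_sds(self, rng):
        sd = pointwise_sd(np.zeros((4, 12)), np.ones(4), _unit_normals(rng, 4))
        for name in ("sd_ml", "sd_si", "sd_ap", "sd_normal", "sd_magnitude"):
            assert (getattr(sd, name) == 0).all()

    def test_matches_brute_force_weighted_rms_loop(self, rng):
        """Vectorized SDs vs an explicit per-vertex, per-subject loop."""
        n, k = 17, 50
        residuals = rng.standard_normal((n, 3 * k))
        weights = rng.uniform(0.01, 1.0, n)
        normals = _unit_normals(rng, k)
        sd = pointwise_sd(residuals, weights, normals)
        D = residuals.reshape(n, k, 3)
        for v in rng.choice(k, size=10, replace=False):
            acc_axis, acc_norm, acc_mag = np.zeros(3), 0.0, 0.0
            for i in range(n):
                acc_axis += weights[i] * D[i, v] ** 2
                acc_norm += weights[i] * float(D[i, v] @ normals[v]) ** 2
                acc_mag += weights[i] * float(D[i, v] @ D[i, v])
            wsum = weights.sum()
            assert sd.sd_ml[v] == pytest.approx(np.sqrt(acc_axis[0] / wsum), abs=1e-12)
            assert sd.sd_si[v] == pytest.approx(np.sqrt(acc_axis[1] / wsum), abs=1e-12)
            assert sd.sd_ap[v] == pytest.approx(np.sqrt(acc_axis[2] / wsum), abs=1e-12)
            assert sd.sd_normal[v] == pytest.approx(np.sqrt(acc_norm / wsum), abs=1e-12)
            assert sd.sd_magnitude[v] == pytest.approx(np.sqrt(acc_mag / wsum), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_pythagorean_identity(self, seed):
        rng = np.random.default_rng(seed)
        n, k = 9, 8
        sd = pointwise_sd(
            rng.standard_normal((n, 3 * k)), rng.uniform(0.1, 1, n),
            _unit_normals(rng, k),
        )
        np.testing.assert_allclose(
            sd.sd_magnitude**2, sd.sd_ml**2 + sd.sd_si**2 + sd.sd_ap**2, atol=1e-9
        )

    def test_weight_rescaling_invariance(self, rng):
        n, k = 12, 6
        residuals = rng.standard_normal((n, 3 * k))
        w = rng.uniform(0.1, 1, n)
        normals = _unit_normals(rng, k)
        a = pointwise_sd(residuals, w, normals)
        b = pointwise_sd(residuals, 2.0 * w, normals)
        np.testing.assert_allclose(a.sd_magnitude, b.sd_magnitude, rtol=1e-12)

    def test_empty_kernel_raises(self, rng):
        with pytest.raises(ValidationError):
            pointwise_sd(np.ones((3, 6)), np.zeros(3), _unit_normals(rng, 2))

    def test_axis_convention_is_respected(self, rng):
        n, k = 6, 4
        residuals = rng.standard_normal((n, 3 * k))
        normals = _unit_normals(rng, k)
        swapped = AxisConvention(medial_lateral=2, superior_inferior=1,
                                 anterior_posterior=0)
        a = pointwise_sd(residuals, np.ones(n), normals)
        b = pointwise_sd(residuals, np.ones(n), normals, axis_convention=swapped)
        np.testing.assert_allclose(a.sd_ml, b.sd_ap)


class TestSSM:
    def test_rank_one_residuals_yield_single_full_variance_mode(self, rng):
        direction = rng.standard_normal(30)
        direction /= np.linalg.norm(direction)
        scores = rng.standard_normal(20)
        residuals = np.outer(scores, direction)
        ssm = fit_ssm(residuals, np.ones(20), retained_fraction=0.98)
        assert ssm.n_modes == 1
        assert ssm.mode_variances.sum() == pytest.approx(ssm.total_variance)
        assert abs(abs(ssm.modes[0] @ direction) - 1.0) < 1e-10

    def test_modes_orthonormal_and_variances_sorted(self, rng):
        residuals = rng.standard_normal((40, 60))
        ssm = fit_ssm(residuals, rng.uniform(0.1, 1, 40))
        gram = ssm.modes @ ssm.modes.T
        np.testing.assert_allclose(gram, np.eye(ssm.n_modes), atol=1e-8)
        assert (np.diff(ssm.mode_variances) <= 1e-12).all()

    def test_variance_conservation_with_full_retention(self, rng):
        """All modes together carry exactly the total weighted variance."""
        n, p = 25, 15  # p well below n_eff - 1 so the cap keeps every mode
        residuals = rng.standard_normal((n, p))
        w = rng.uniform(0.1, 1, n)
        ssm = fit_ssm(residuals, w, retained_fraction=1.0)
        total = float(np.sum((w / w.sum())[:, None] * residuals**2))
        assert ssm.total_variance == pytest.approx(total, rel=1e-10)
        assert ssm.mode_variances.sum() == pytest.approx(total, rel=1e-8)

    def test_retention_rule_is_minimal(self, rng):
        """Retained set reaches 98%; dropping its last mode falls below."""
        residuals = rng.standard_normal((60, 40)) * np.linspace(3, 0.2, 40)
        ssm = fit_ssm(residuals, np.ones(60), retained_fraction=0.98)
        got = ssm.mode_variances.sum() / ssm.total_variance
        assert got >= 0.98
        assert ssm.mode_variances[:-1].sum() / ssm.total_variance < 0.98

    def test_weight_rescaling_invariance(self, rng):
        residuals = rng.standard_normal((20, 30))
        w = rng.uniform(0.1, 1, 20)
        a = fit_ssm(residuals, w)
        b = fit_ssm(residuals, 3.0 * w)
        np.testing.assert_allclose(a.mode_variances, b.mode_variances, rtol=1e-10)
        np.testing.assert_allclose(np.abs(a.modes), np.abs(b.modes), atol=1e-10)

    def test_full_reconstruction_no_worse_than_retained(self, rng):
        residuals = rng.standard_normal((30, 45))
        w = np.ones(30)
        retained = fit_ssm(residuals, w, retained_fraction=0.90)
        full = fit_ssm(residuals, w, retained_fraction=1.0)
        r = residuals[3]
        err_ret = np.linalg.norm(r - retained.modes.T @ (retained.modes @ r))
        err_full = np.linalg.norm(r - full.modes.T @ (full.modes @ r))
        assert err_full <= err_ret + 1e-12


class TestProjection:
    def _ssm(self, rng, k=30, m=5):
        modes, _ = np.linalg.qr(rng.standard_normal((3 * k, m)))
        lam = np.sort(rng.uniform(0.5, 5.0, m))[::-1]
        return SSM(modes=modes.T, mode_variances=lam, retained_fraction=0.98,
                   n_effective=100.0, total_variance=lam.sum() / 0.9)

    def test_in_span_displacement_reconstructs_exactly(self, rng):
        ssm = self._ssm(rng)
        c_true = rng.standard_normal(ssm.n_modes)
        d = ssm.modes.T @ c_true
        c = ssm_project(ssm, d)
        np.testing.assert_allclose(ssm.modes.T @ c, d, atol=1e-9)

    def test_orthogonal_displacement_projects_to_zero(self, rng):
        ssm = self._ssm(rng)
        d = rng.standard_normal(ssm.modes.shape[1])
        d -= ssm.modes.T @ (ssm.modes @ d)
        np.testing.assert_allclose(ssm_project(ssm, d), 0.0, atol=1e-9)

    def test_weighted_projection_matches_normal_equations_oracle(self, rng):
        ssm = self._ssm(rng, k=30, m=5)
        d = rng.standard_normal(90)
        vw = rng.uniform(0.05, 1.0, 30)
        c = ssm_project(ssm, d, vertex_weights=vw)
        W = np.repeat(vw, 3)
        # generic dense weighted-least-squares solve
        A = ssm.modes.T * np.sqrt(W)[:, None]
        oracle, *_ = np.linalg.lstsq(A, d * np.sqrt(W), rcond=None)
        np.testing.assert_allclose(c, oracle, atol=1e-9)


class TestMahalanobis:
    def test_zero_coefficients(self, rng):
        ssm = TestProjection()._ssm(rng)
        d2, p = mahalanobis_sq(ssm, np.zeros(ssm.n_modes))
        assert d2 == 0.0 and p == 1.0

    def test_unit_standardized_deviation(self, rng):
        ssm = TestProjection()._ssm(rng, m=1)
        d2, _ = mahalanobis_sq(ssm, np.array([np.sqrt(ssm.mode_variances[0])]))
        assert d2 == pytest.approx(1.0)

    def test_tail_probability_matches_monte_carlo(self, rng):
        """m=3, c_j = sqrt(lambda_j): D^2 = 3; tail vs 10^6 chi-square draws."""
        ssm = TestProjection()._ssm(rng, m=3)
        d2, p = mahalanobis_sq(ssm, np.sqrt(ssm.mode_variances))
        assert d2 == pytest.approx(3.0)
        draws = np.random.default_rng(123).chisquare(df=3, size=10**6)
        assert p == pytest.approx(float(np.mean(draws > 3.0)), abs=0.005)

    def test_invalid_variances_raise(self, rng):
        ssm = TestProjection()._ssm(rng)
        object.__setattr__(ssm, "mode_variances", ssm.mode_variances * 0.0)
        with pytest.raises(InvalidModelError):
            mahalanobis_sq(ssm, np.zeros(ssm.n_modes))


class TestGrowthCurves:
    def test_toy_cohort_builds_complete_model(self, small_spec):
        shapes, _ = simulate_cohort(small_spec, 60, seed=9, sex="male")
        model = build_growth_curves(
            shapes, base_topology(small_spec), sex="male",
            age_grid=np.array([5.0, 10.0, 15.0]),
            kernel=KernelConfig(sigma_floor=1.0, min_effective_n=20),
        )
        assert len(model.entries) == 3
        for entry in model.entries:
            assert entry.expected.shape == (small_spec.n_vertices, 3)
            assert entry.ssm.n_modes >= 1
            assert (entry.sd.sd_magnitude > 0).all()

    def test_default_female_grid_spacing(self):
        grid = default_age_grid("female")
        assert grid[0] == pytest.approx(0.5)
        assert grid[-1] == pytest.approx(68.9)
        assert np.ptp(np.diff(grid)) < 1e-9
        assert np.diff(grid)[0] == pytest.approx(0.3, abs=1e-9)

    def test_default_male_grid_range(self):
        grid = default_age_grid("male")
        assert grid[-1] == pytest.approx(51.8)
        assert np.diff(grid)[0] == pytest.approx(0.3, abs=1e-9)

    def test_variation_increases_with_age(self, full_model):
        """Mean pointwise SD magnitude is non-decreasing over grid ages,
        mirroring the generative age-growing variance."""
        means = [e.sd.sd_magnitude.mean() for e in full_model.entries]
        assert all(b >= a * 0.98 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0]

    def test_insufficient_data_lists_failing_ages(self, small_spec):
        shapes, _ = simulate_cohort(small_spec, 30, seed=2, sex="female")
        with pytest.raises(InsufficientDataError):
            build_growth_curves(
                shapes, base_topology(small_spec), sex="female",
                age_grid=np.array([10.0, 20.0]),
                kernel=KernelConfig(sigma_floor=1.0, min_effective_n=31),
            )
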