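"""Kurihara mesh, Gaussian kernels, detector matrices and harmonics."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from tensaxs import sphharm
from tensaxs.geometry import (
    SampleOrientation,
    default_segment_boundaries,
    probed_circle,
)
from tensaxs.rsm_basis import (
    KuriharaMesh,
    detector_projection_matrix,
    evaluate_rsm,
    funk_radon_sh,
    kernel_weight,
    kurihara_mesh,
    normalization_factors,
    sh_transform_matrix,
    to_spherical_harmonics,
)
from tensaxs.sampling_quality import circle_points

RNG = np.random.default_rng(7)


def _friedel_nn_spacing(modes):
    tree = cKDTree(np.vstack([modes, -modes]))
    dist, _ = tree.query(modes, k=2)
    return 2 * np.arcsin(np.clip(dist[:, 1] / 2, 0, 1))


class TestKuriharaMesh:
    @pytest.mark.parametrize("s,expected", [(1, 2), (3, 18), (9, 162)])
    def test_mode_count_is_two_s_squared(self, s, expected):
        assert kurihara_mesh(s).n_modes == expected

    def test_ring_populations_for_s3(self):
        mesh = kurihara_mesh(3)
        theta = np.arccos(mesh.modes[:, 2])
        rings = np.unique(np.round(theta, 9))
        sizes = [np.sum(np.isclose(theta, r)) for r in rings]
        assert sizes == [2, 6, 10]

    def test_modes_on_upper_hemisphere_and_unit_norm(self):
        mesh = kurihara_mesh(8)
        assert np.all(mesh.modes[:, 2] >= 0)
        assert np.allclose(np.linalg.norm(mesh.modes, axis=1), 1, atol=1e-12)

    @pytest.mark.parametrize("s", [2, 5, 9, 13, 20])
    def test_quasi_uniform_spacing(self, s):
        spacing = _friedel_nn_spacing(kurihara_mesh(s).modes)
        assert spacing.min() > 0
        assert spacing.max() / spacing.min() < 2.0

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            kurihara_mesh(0)


class TestKernel:
    def test_peak_width_and_friedel_symmetry(self):
        mode = np.array([0.0, 0, 1])
        sigma = 0.2
        assert kernel_weight(mode, mode, sigma) == 1.0
        at_sigma = np.array([np.sin(sigma), 0, np.cos(sigma)])
        assert kernel_weight(at_sigma, mode, sigma) == pytest.approx(
            np.exp(-0.5), rel=1e-12
        )
        v = np.array([0.3, 0.5, np.sqrt(1 - 0.34)])
        assert kernel_weight(-v, mode, sigma) == kernel_weight(v, mode, sigma)

    def test_normalization_factors_match_double_loop(self):
        mesh = kurihara_mesh(3)
        factors = normalization_factors(mesh)
        brute = np.array(
            [
                sum(
                    kernel_weight(u, v, mesh.sigma)
                    for v in mesh.modes
                )
                for u in mesh.modes
            ]
        )
        assert np.allclose(factors, brute, atol=1e-12)
        assert np.all(factors >= 1.0)


class TestDetectorMatrix:
    def test_single_segment_matches_dense_quadrature(self):
        mesh = kurihara_mesh(4)
        orientation = SampleOrientation(0.9, -0.3)
        g = detector_projection_matrix(
            mesh, orientation, None, np.array([0.0, np.pi])
        )
        tau = np.linspace(0, np.pi, 10_000, endpoint=False)
        circle = probed_circle(tau, orientation)
        kernels = np.array(
            [kernel_weight(circle, m, mesh.sigma) for m in mesh.modes]
        )
        oracle = kernels.mean(axis=1) / mesh.normalization
        assert np.allclose(g[0], oracle, atol=1e-4)

    def test_linearity_under_left_multiplication(self):
        mesh = kurihara_mesh(3)
        g = detector_projection_matrix(
            mesh, SampleOrientation(0.2, 0.1), None, default_segment_boundaries(8)
        )
        c1, c2 = RNG.normal(size=(2, mesh.n_modes))
        assert np.allclose(g @ (2 * c1 - 3 * c2), 2 * g @ c1 - 3 * g @ c2)
        assert np.allclose(g @ np.zeros(mesh.n_modes), 0.0)

    def test_isotropic_function_gives_flat_segments(self):
        mesh = kurihara_mesh(9)
        # coefficients fitted to the constant function 1
        theta, phi, w = sphharm.quadrature_grid(12)
        v = np.column_stack(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi),
             np.cos(theta)]
        )
        from tensaxs.rsm_basis import _kernel_matrix

        design = _kernel_matrix(v, mesh) / mesh.normalization
        c, *_ = np.linalg.lstsq(design, np.ones(len(v)), rcond=None)
        g = detector_projection_matrix(
            mesh, SampleOrientation(0.5, 0.4), None, default_segment_boundaries(8)
        )
        segments = g @ c
        assert np.ptp(segments) / segments.mean() < 0.02

    def test_zero_width_segment_rejected(self):
        mesh = kurihara_mesh(2)
        with pytest.raises(ValueError):
            detector_projection_matrix(
                mesh, SampleOrientation(0, 0), None, np.array([0.3, 0.3, 1.0])
            )

    @pytest.mark.parametrize("s", [5, 9, 13])
    def test_normalization_evens_the_detector_response(self, s):
        # the all-ones coefficient vector represents the near-isotropic
        # partition sum k(v, n) / N_n; with the auto-projection
        # normalization its segment response is flatter than without
        mesh = kurihara_mesh(s)
        g = detector_projection_matrix(
            mesh, SampleOrientation(0.7, 0.2), None,
            default_segment_boundaries(8),
        )
        normalized = g @ np.ones(mesh.n_modes)
        raw = g @ mesh.normalization  # undoes the 1/N_n factor
        cov_norm = normalized.std() / normalized.mean()
        cov_raw = raw.std() / raw.mean()
        assert cov_norm < cov_raw


class TestEvaluateRsm:
    def test_zero_and_friedel_symmetry(self):
        mesh = kurihara_mesh(3)
        assert evaluate_rsm(mesh, np.zeros(mesh.n_modes), np.array([0.0, 0, 1])) == 0
        c = RNG.normal(size=mesh.n_modes)
        v = np.array([0.2, -0.5, np.sqrt(1 - 0.29)])
        assert evaluate_rsm(mesh, c, v) == evaluate_rsm(mesh, c, -v)

    def test_delta_coefficient_recovers_inverse_normalization(self):
        mesh = kurihara_mesh(3)
        k = 7
        c = np.zeros(mesh.n_modes)
        c[k] = 1.0
        value = evaluate_rsm(mesh, c, mesh.modes[k])
        assert value == pytest.approx(1.0 / mesh.normalization[k], rel=1e-12)

    def test_length_mismatch_rejected(self):
        mesh = kurihara_mesh(2)
        with pytest.raises(ValueError):
            evaluate_rsm(mesh, np.zeros(5), np.array([0.0, 0, 1]))


class TestSphericalHarmonics:
    def test_zero_coefficients_transform_to_zero(self):
        mesh = kurihara_mesh(3)
        f = to_spherical_harmonics(mesh, np.zeros(mesh.n_modes))
        assert np.allclose(f.values, 0.0)

    def test_isotropic_interpolant_is_pure_degree_zero(self):
        mesh = kurihara_mesh(9)
        from tensaxs.phantom import ring_rsm_coefficients

        c = ring_rsm_coefficients(mesh, np.array([0.0, 0, 1]), 0.0, 0.3, offset=1.0)
        f = to_spherical_harmonics(mesh, c)
        power = f.degree_power()
        higher = sum(v for ell, v in power.items() if ell > 0)
        assert np.sqrt(higher / power[0]) < 0.03

    def test_round_trip_evaluation_within_band_limit(self):
        mesh = kurihara_mesh(5)
        c = RNG.normal(size=mesh.n_modes)
        f = to_spherical_harmonics(mesh, c, lmax=16)
        v = RNG.normal(size=(200, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        direct = evaluate_rsm(mesh, c, v)
        via_sh = f.evaluate_directions(v)
        scale = np.abs(direct).max()
        assert np.abs(direct - via_sh).max() < 0.05 * scale

    def test_full_sphere_evaluation_is_even(self):
        mesh = kurihara_mesh(4)
        c = RNG.normal(size=mesh.n_modes)
        f = to_spherical_harmonics(mesh, c)
        v = RNG.normal(size=(50, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        assert np.allclose(
            f.evaluate_directions(v), f.evaluate_directions(-v), atol=1e-12
        )

    def test_batch_transform_matches_single(self):
        mesh = kurihara_mesh(4)
        transform = sh_transform_matrix(mesh, lmax=8)
        c = RNG.normal(size=(3, mesh.n_modes))
        batch = c @ transform.T
        for i in range(3):
            single = to_spherical_harmonics(mesh, c[i], lmax=8)
            assert np.allclose(batch[i], single.values, atol=1e-10)

    def test_odd_lmax_rejected(self):
        mesh = kurihara_mesh(2)
        with pytest.raises(ValueError):
            to_spherical_harmonics(mesh, np.zeros(mesh.n_modes), lmax=7)


class TestFunkRadon:
    def test_degree_multipliers_are_legendre_at_zero(self):
        for lmax, ell, expected in [(4, 0, 1.0), (4, 2, -0.5), (4, 4, 3 / 8)]:
            ls, ms = sphharm.even_degree_index(lmax)
            values = np.zeros(ls.size)
            values[(ls == ell) & (ms == 0)] = 1.0
            f = sphharm.SHCoefficients(lmax, values)
            g = funk_radon_sh(f)
            assert g.values[(ls == ell) & (ms == 0)][0] == pytest.approx(expected)

    def test_matches_great_circle_quadrature(self):
        lmax = 8
        ls, _ = sphharm.even_degree_index(lmax)
        f = sphharm.SHCoefficients(lmax, RNG.normal(size=ls.size))
        g = funk_radon_sh(f)
        for _ in range(50):
            d = RNG.normal(size=3)
            d /= np.linalg.norm(d)
            circle_mean = f.evaluate_directions(circle_points(d, 720)).mean()
            assert circle_mean == pytest.approx(
                float(g.evaluate_directions(d)), abs=1e-6
            )

    def test_self_adjoint_and_mean_preserving(self):
        lmax = 6
        ls, _ = sphharm.even_degree_index(lmax)
        a = sphharm.SHCoefficients(lmax, RNG.normal(size=ls.size))
        b = sphharm.SHCoefficients(lmax, RNG.normal(size=ls.size))
        fa, fb = funk_radon_sh(a), funk_radon_sh(b)
        assert np.dot(fa.values, b.values) == pytest.approx(
            np.dot(a.values, fb.values), rel=1e-12
        )
        assert fa.values[0] == a.values[0]
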