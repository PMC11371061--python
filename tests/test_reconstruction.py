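"""Solver building blocks: relaxed inverse, weights, gradient, SIRT limit."""

import numpy as np
import pytest

from tensaxs.geometry import (
    SampleOrientation,
    default_segment_boundaries,
    generate_tilt_scheme,
    scheme_views,
)
from tensaxs.john_transform import backproject, default_image_shape, project
from tensaxs.reconstruction import (
    ReconstructionConfig,
    huber,
    loss_and_gradient,
    preconditioner_matrix,
    projection_matrices,
    reconstruct,
    relaxed_elementwise_inverse,
    weight_matrix,
)
from tensaxs.rsm_basis import kurihara_mesh

RNG = np.random.default_rng(3)


class TestRelaxedInverse:
    def test_masking_rule(self):
        eps = 0.1
        a = np.array([1.0, 0.0, 2 * eps, 0.5 * eps])
        out = relaxed_elementwise_inverse(a, eps)
        assert np.allclose(out, [1.0, 0.0, 1 / (2 * eps), 0.0])

    def test_smooth_variant_never_masks(self):
        out = relaxed_elementwise_inverse(np.array([0.0, 1.0]), 0.5, smooth=True)
        assert np.allclose(out, [2.0, 1 / 1.5])

    def test_requires_positive_epsilon(self):
        with pytest.raises(ValueError):
            relaxed_elementwise_inverse(np.ones(2), 0.0)


class TestWeightsAndPreconditioner:
    def test_unit_fixture_weight_is_one(self):
        # single voxel, single pixel, unit detector response: forward of
        # the all-ones field is exactly 1
        g = np.array([[1.0]])
        w = weight_matrix(
            g, SampleOrientation(0, 0), None, (1, 1, 1), (1, 1)
        )
        assert w[0, 0, 0] == pytest.approx(1.0)

    def test_missed_rays_masked_to_zero(self):
        g = np.array([[1.0]])
        w = weight_matrix(
            g, SampleOrientation(0, 0), None, (2, 2, 2), (12, 12)
        )
        assert w[0, 0, 0] == 0.0  # corner ray misses the 2^3 volume
        assert w[6, 6, 0] > 0.0

    def test_sirt_row_and_column_sums_with_identity_g(self):
        """With G = I and one channel the weights and preconditioner are
        the classical SIRT inverse row/column sums of the ray matrix."""
        shape = (6, 6, 6)
        scheme = generate_tilt_scheme(
            2, 5, np.pi / 4, segment_boundaries=np.array([0.0, np.pi])
        )
        views = scheme_views(scheme)
        image_shape = default_image_shape(shape)
        gs = [np.eye(1)] * len(views)
        eps = 1e-8
        for g, (orientation, mount) in zip(gs, views):
            w = weight_matrix(g, orientation, mount, shape, image_shape, eps)
            rowsum = project(np.ones(shape + (1,)), orientation, mount,
                             image_shape)
            expected = np.where(rowsum >= eps * rowsum.max(), 1 / np.where(
                rowsum == 0, 1, rowsum), 0.0)
            assert np.allclose(w, expected)
        m = preconditioner_matrix(gs, views, shape, image_shape, eps)
        colsum = sum(
            backproject(np.ones(image_shape + (1,)), shape, o, mt)
            for o, mt in views
        )
        expected = np.where(
            colsum >= eps * colsum.max(), 1 / np.where(colsum == 0, 1, colsum), 0.0
        )
        assert np.allclose(m, expected)


class TestHuber:
    @pytest.mark.parametrize(
        "x,delta,value,deriv",
        [
            (0.0, 1.0, 0.0, 0.0),
            (1.0, 1.0, 0.5, 1.0),
            (3.0, 1.0, 1.0 * (3.0 - 0.5), 1.0),
            (-3.0, 1.0, 2.5, -1.0),
        ],
    )
    def test_branches_and_continuity(self, x, delta, value, deriv):
        v, d = huber(np.array(x), delta)
        assert v == pytest.approx(value)
        assert d == pytest.approx(deriv)

    def test_derivative_is_continuous_at_the_knee(self):
        delta = 0.3
        below = huber(np.array(delta - 1e-9), delta)[1]
        above = huber(np.array(delta + 1e-9), delta)[1]
        assert abs(below - above) < 1e-8


@pytest.fixture(scope="module")
def small_problem():
    mesh = kurihara_mesh(2)
    scheme = generate_tilt_scheme(
        2, 3, np.pi / 4, segment_boundaries=default_segment_boundaries(4)
    )
    views = scheme_views(scheme)
    shape = (3, 3, 3)
    image_shape = (5, 5)
    gs = projection_matrices(mesh, scheme)
    rng = np.random.default_rng(0)
    data = [
        rng.normal(size=image_shape + (scheme.n_segments,))
        for _ in range(len(views))
    ]
    weights = [
        weight_matrix(g, o, mt, shape, image_shape)
        for g, (o, mt) in zip(gs, views)
    ]
    x = rng.normal(size=shape + (mesh.n_modes,))
    return x, data, weights, gs, views


class TestGradient:
    @pytest.mark.parametrize("tv,l1", [(0.0, 0.0), (0.05, 0.02)])
    def test_gradient_matches_finite_differences(self, small_problem, tv, l1):
        x, data, weights, gs, views = small_problem
        config = ReconstructionConfig(tv_weight=tv, l1_weight=l1,
                                      huber_delta=0.05)
        loss, grad = loss_and_gradient(x, data, weights, gs, views, config)
        rng = np.random.default_rng(5)
        # large enough to clear floating-point cancellation in the loss,
        # small enough that Huber curvature changes are negligible
        h = 1e-4
        for _ in range(12):
            idx = tuple(rng.integers(s) for s in x.shape)
            xp = x.copy()
            xp[idx] += h
            xm = x.copy()
            xm[idx] -= h
            lp = loss_and_gradient(xp, data, weights, gs, views, config)[0]
            lm = loss_and_gradient(xm, data, weights, gs, views, config)[0]
            fd = (lp - lm) / (2 * h)
            assert grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)

    def test_zero_state_zero_data_has_zero_loss(self, small_problem):
        _, data, weights, gs, views = small_problem
        config = ReconstructionConfig()
        zeros = [np.zeros_like(d) for d in data]
        x0 = np.zeros((3, 3, 3, gs[0].shape[1]))
        loss, grad = loss_and_gradient(x0, zeros, weights, gs, views, config)
        assert loss == 0.0
        assert not grad.any()

    def test_tv_term_vanishes_on_constant_field(self, small_problem):
        x, data, weights, gs, views = small_problem
        const = np.ones_like(x)
        base = ReconstructionConfig()
        with_tv = ReconstructionConfig(tv_weight=1.0, huber_delta=0.05)
        l0 = loss_and_gradient(const, data, weights, gs, views, base)[0]
        l1 = loss_and_gradient(const, data, weights, gs, views, with_tv)[0]
        assert l1 == pytest.approx(l0)


class TestReconstruct:
    def test_reduces_to_independent_scalar_sirt(self):
        """With G = I, one channel, no momentum and no regularization the
        update must equal a hand-rolled weighted SIRT, iterate for iterate."""
        shape = (8, 8, 8)
        scheme = generate_tilt_scheme(
            3, 6, np.pi / 4, segment_boundaries=np.array([0.0, np.pi])
        )
        views = scheme_views(scheme)
        image_shape = default_image_shape(shape)
        gs = [np.eye(1)] * len(views)
        rng = np.random.default_rng(1)
        idx = np.indices(shape).astype(float) - 3.5
        truth = np.exp(-(idx**2).sum(axis=0) / 8.0)[..., None]
        data = [
            project(truth, o, mt, image_shape) for o, mt in views
        ]
        config = ReconstructionConfig(
            n_iterations=15, nesterov_momentum=0.0, step_size=1.0
        )
        iterates = []
        reconstruct(
            data, None, scheme, config, field_shape=shape, gs=gs,
            callback=lambda it, loss, x: iterates.append(x.copy()),
        )

        # independent scalar SIRT with explicit row/column-sum weights
        eps = config.epsilon_relaxation
        rowsums = [project(np.ones(shape + (1,)), o, mt, image_shape)
                   for o, mt in views]
        ws = [
            np.where(r >= eps * r.max(), 1.0 / np.where(r == 0, 1.0, r), 0.0)
            for r in rowsums
        ]
        colsum = sum(
            backproject(np.ones(image_shape + (1,)), shape, o, mt)
            for o, mt in views
        )
        m = np.where(
            colsum >= eps * colsum.max(),
            1.0 / np.where(colsum == 0, 1.0, colsum), 0.0,
        )
        x = np.zeros(shape + (1,))
        for it in range(config.n_iterations):
            update = np.zeros_like(x)
            for (o, mt), d, w in zip(views, data, ws):
                residual = project(x, o, mt, image_shape) - d
                update += backproject(w * residual, shape, o, mt)
            x = x - m * update
            scale = max(np.abs(x).max(), 1e-30)
            assert np.abs(iterates[it] - x).max() <= 1e-8 * scale

    def test_zero_data_with_l1_converges_to_zero_field(self):
        mesh = kurihara_mesh(2)
        scheme = generate_tilt_scheme(
            2, 4, np.pi / 4, segment_boundaries=default_segment_boundaries(4)
        )
        shape = (4, 4, 4)
        image_shape = default_image_shape(shape)
        data = [
            np.zeros(image_shape + (scheme.n_segments,))
            for _ in scheme.orientations
        ]
        config = ReconstructionConfig(n_iterations=20, l1_weight=0.1)
        x, trace = reconstruct(data, mesh, scheme, config, field_shape=shape)
        assert np.abs(x).max() < 1e-10
        assert trace[-1] == pytest.approx(0.0, abs=1e-12)

    def test_divergence_aborts_with_diagnostic(self):
        mesh = kurihara_mesh(2)
        scheme = generate_tilt_scheme(
            2, 4, np.pi / 4, segment_boundaries=default_segment_boundaries(4)
        )
        shape = (4, 4, 4)
        image_shape = default_image_shape(shape)
        rng = np.random.default_rng(0)
        data = [
            rng.normal(size=image_shape + (scheme.n_segments,))
            for _ in scheme.orientations
        ]
        config = ReconstructionConfig(n_iterations=100, step_size=50.0)
        with pytest.raises(RuntimeError, match="increased"):
            reconstruct(data, mesh, scheme, config, field_shape=shape)

    def test_loss_trace_decreases_after_burn_in(self, study):
        trace = study["trace_full"]
        assert np.all(np.diff(trace[5:]) <= 1e-6 * trace[0])
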