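"""Weighted, preconditioned, regularized solver for the per-projection systems.

For each projection ``i`` the forward model is ``P_i X G_i^T = D_i``: the
John transform ``P_i`` maps the coefficient field to projection space and
the detector matrix ``G_i`` maps basis coefficients to azimuthal detector
segments.  The solver minimizes the weighted least-squares objective

    sum_i 1/2 <W_i (.) r_i, r_i> + tv_weight * HuberTV(X)
                                 + l1_weight * HuberL1(X),
    r_i = P_i X G_i^T - D_i,

by Nesterov-accelerated, preconditioned gradient descent from a zero
start.  The weights ``W_i`` (relaxed elementwise inverse of the forward
projection of an all-ones field) and the preconditioner ``M`` (relaxed
inverse of the accumulated back-projection of all-ones data) generalize
the SIRT row- and column-sum normalizations to the multi-channel,
detector-mapped setting: with a single channel and ``G = I`` the update is
exactly weighted SIRT.

The relaxed inverse masks entries below a threshold to zero, so rays that
miss the volume and voxels never traversed are excluded rather than
amplified; a smooth ``1/(a + epsilon)`` variant is available.  Both
regularizers act on the basis-set coefficients (not on pointwise sphere
values) in the Huber approximation, which keeps the gradient Lipschitz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import AcquisitionScheme, SampleOrientation, scheme_views
from .john_transform import backproject, project
from .rsm_basis import KuriharaMesh, detector_projection_matrix

__all__ = [
    "ReconstructionConfig",
    "relaxed_elementwise_inverse",
    "weight_matrix",
    "preconditioner_matrix",
    "huber",
    "loss_and_gradient",
    "reconstruct",
    "projection_matrices",
]


@dataclass
class ReconstructionConfig:
    """Solver hyperparameters; defaults favor plainly converging iterations."""

    n_iterations: int = 200
    step_size: float = 1.0
    nesterov_momentum: float = 0.9
    tv_weight: float = 0.0
    l1_weight: float = 0.0
    huber_delta: float = 1e-3
    epsilon_relaxation: float = 1e-8
    seed: int = 0
    nonnegative: bool = False
    smooth_inverse: bool = False
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if not (0.0 <= self.nesterov_momentum < 1.0):
            raise ValueError("nesterov_momentum must lie in [0, 1)")
        for name in ("tv_weight", "l1_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("step_size", "huber_delta", "epsilon_relaxation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def relaxed_elementwise_inverse(
    a: np.ndarray, epsilon: float, smooth: bool = False
) -> np.ndarray:
    """Elementwise ``1/a`` with small entries masked (or damped) by ``epsilon``.

    Hard masking (default) returns ``1/a`` where ``a >= epsilon`` and 0
    elsewhere; the smooth variant returns ``1/(a + epsilon)`` everywhere.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    a = np.asarray(a, dtype=float)
    if smooth:
        return 1.0 / (a + epsilon)
    out = np.zeros_like(a)
    mask = a >= epsilon
    out[mask] = 1.0 / a[mask]
    return out


def projection_matrices(
    mesh: KuriharaMesh,
    scheme: AcquisitionScheme | list[AcquisitionScheme],
    rel_tol: float = 1e-5,
) -> list[np.ndarray]:
    """Detector matrices ``G_i`` for every view of the scheme(s)."""
    views = scheme_views(scheme)
    return [
        detector_projection_matrix(
            mesh, orientation, mount, views.segment_boundaries, rel_tol
        )
        for orientation, mount in views
    ]


def _forward_one(x, g, orientation, mount, image_shape, voxel_size):
    """``P_i X G_i^T``: contract channels first (cheap), then project."""
    return project(x @ g.T, orientation, mount, image_shape, voxel_size)


def _adjoint_one(r, g, shape, orientation, mount, voxel_size):
    """``P_i^T R G_i``: back-project segments, then expand to coefficients."""
    return backproject(r, shape, orientation, mount, voxel_size) @ g


def weight_matrix(
    g: np.ndarray,
    orientation: SampleOrientation,
    mount: np.ndarray | None,
    field_shape: tuple[int, int, int],
    image_shape: tuple[int, int],
    epsilon: float = 1e-8,
    voxel_size: float = 1.0,
    smooth: bool = False,
) -> np.ndarray:
    """Per-pixel, per-segment weights: relaxed inverse of ``P_i U G_i^T``.

    ``U`` is the all-ones coefficient field, so each entry counts (in path
    length and detector response) how much of the volume can feed a datum;
    pixels whose rays miss the volume get weight zero.  ``epsilon`` is
    relative to the largest entry.
    """
    ones = np.ones(tuple(field_shape) + (g.shape[1],))
    fwd = _forward_one(ones, g, orientation, mount, image_shape, voxel_size)
    eps = epsilon * max(fwd.max(), np.finfo(float).tiny)
    return relaxed_elementwise_inverse(fwd, eps, smooth)


def preconditioner_matrix(
    gs: list[np.ndarray],
    views,
    field_shape: tuple[int, int, int],
    image_shape: tuple[int, int],
    epsilon: float = 1e-8,
    voxel_size: float = 1.0,
    smooth: bool = False,
) -> np.ndarray:
    """Per-voxel, per-mode preconditioner: relaxed inverse of
    ``sum_i P_i^T V G_i`` with ``V`` the all-ones data stack.

    Normalizes the gradient by the measurement multiplicity of every
    (voxel, basis function) pair; voxels never traversed are masked.
    """
    if not gs:
        raise ValueError("need at least one projection")
    total = np.zeros(tuple(field_shape) + (gs[0].shape[1],))
    for g, (orientation, mount) in zip(gs, views):
        ones = np.ones(tuple(image_shape) + (g.shape[0],))
        total += _adjoint_one(
            ones, g, field_shape, orientation, mount, voxel_size
        )
    eps = epsilon * max(total.max(), np.finfo(float).tiny)
    return relaxed_elementwise_inverse(total, eps, smooth)


def huber(x: np.ndarray, delta: float) -> tuple[np.ndarray, np.ndarray]:
    """Huber value and derivative: quadratic inside ``|x| <= delta``,
    linear with slope ``delta * sign(x)`` outside."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    x = np.asarray(x, dtype=float)
    absx = np.abs(x)
    quad = absx <= delta
    value = np.where(quad, 0.5 * x**2, delta * (absx - 0.5 * delta))
    deriv = np.where(quad, x, delta * np.sign(x))
    return value, deriv


def _tv_value_grad(x: np.ndarray, delta: float) -> tuple[float, np.ndarray]:
    """Huber total variation over forward differences along the 3 voxel axes."""
    value = 0.0
    grad = np.zeros_like(x)
    for axis in range(3):
        d = np.diff(x, axis=axis)
        v, g = huber(d, delta)
        value += v.sum()
        lo = [slice(None)] * 4
        hi = [slice(None)] * 4
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        grad[tuple(lo)] -= g
        grad[tuple(hi)] += g
    return value, grad


def loss_and_gradient(
    x: np.ndarray,
    data: list[np.ndarray],
    weights: list[np.ndarray],
    gs: list[np.ndarray],
    views,
    config: ReconstructionConfig,
) -> tuple[float, np.ndarray]:
    """Objective value and its gradient with respect to the coefficients."""
    shape = x.shape[:3]
    image_shape = data[0].shape[:2]
    loss = 0.0
    grad = np.zeros_like(x)
    for i, (d, w, g, (orientation, mount)) in enumerate(
        zip(data, weights, gs, views)
    ):
        residual = (
            _forward_one(x, g, orientation, mount, image_shape, config.voxel_size)
            - d
        )
        wr = w * residual
        term = 0.5 * float(np.sum(wr * residual))
        if not np.isfinite(term):
            raise FloatingPointError(f"non-finite loss in projection {i}")
        loss += term
        grad += _adjoint_one(wr, g, shape, orientation, mount, config.voxel_size)
    if config.tv_weight > 0:
        v, gtv = _tv_value_grad(x, config.huber_delta)
        loss += config.tv_weight * v
        grad += config.tv_weight * gtv
    if config.l1_weight > 0:
        v, gl1 = huber(x, config.huber_delta)
        loss += config.l1_weight * float(v.sum())
        grad += config.l1_weight * gl1
    return loss, grad


def reconstruct(
    data: list[np.ndarray],
    mesh: KuriharaMesh | None,
    scheme: AcquisitionScheme | list[AcquisitionScheme],
    config: ReconstructionConfig | None = None,
    field_shape: tuple[int, int, int] | None = None,
    gs: list[np.ndarray] | None = None,
    callback=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct a coefficient field from segment-binned projection data.

    Parameters
    ----------
    data
        One ``(J, K, M)`` array per view of ``scheme`` (a single scheme or
        a multi-mount list), in view order.
    field_shape
        Voxel grid; defaults to a cube of the raster size minus margin.
    gs
        Precomputed detector matrices (recomputed from the mesh if absent).

    Returns the final coefficient field ``(X, Y, Z, N)`` and the
    per-iteration loss trace.  Deterministic: zero initialization, fixed
    iteration count.  Raises if the loss increases for 10 consecutive
    iterations.
    """
    if config is None:
        config = ReconstructionConfig()
    views = scheme_views(scheme)
    if len(data) != len(views) or not data:
        raise ValueError("need exactly one data image per scheme view")
    image_shape = data[0].shape[:2]
    if any(d.shape != data[0].shape for d in data):
        raise ValueError("all projection images must share a shape")
    if field_shape is None:
        side = max(2, image_shape[0] - 2)
        field_shape = (side, side, side)
    if gs is None:
        if mesh is None:
            raise ValueError("either a mesh or precomputed matrices required")
        gs = projection_matrices(mesh, scheme)

    weights = [
        weight_matrix(
            g,
            orientation,
            mount,
            field_shape,
            image_shape,
            config.epsilon_relaxation,
            config.voxel_size,
            config.smooth_inverse,
        )
        for g, (orientation, mount) in zip(gs, views)
    ]
    precond = preconditioner_matrix(
        gs,
        views,
        field_shape,
        image_shape,
        config.epsilon_relaxation,
        config.voxel_size,
        config.smooth_inverse,
    )

    x = np.zeros(tuple(field_shape) + (gs[0].shape[1],))
    x_prev = x.copy()
    trace = np.empty(config.n_iterations)
    n_increases = 0
    for it in range(config.n_iterations):
        y = x + config.nesterov_momentum * (x - x_prev)
        loss, grad = loss_and_gradient(y, data, weights, gs, views, config)
        x_prev = x
        x = y - config.step_size * precond * grad
        if config.nonnegative:
            np.maximum(x, 0.0, out=x)
        trace[it] = loss
        n_increases = n_increases + 1 if it > 0 and loss > trace[it - 1] else 0
        if n_increases >= 10:
            raise RuntimeError(
                f"loss increased for 10 consecutive iterations (it={it}); "
                "reduce step_size or momentum"
            )
        if callback is not None:
            callback(it, loss, x)
    return x, trace
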