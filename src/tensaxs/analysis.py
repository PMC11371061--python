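"""Figures of merit for reconstructed reciprocal-space maps.

All metrics operate on the even-degree spherical-harmonic expansion of a
voxel's RSM (see :func:`tensaxs.rsm_basis.to_spherical_harmonics`):

* spherical mean — average amplitude over the sphere;
* relative anisotropy — spherical standard deviation over the mean, a
  scale-free degree-of-orientation measure;
* orientation — the minimal eigenvector of the rank-2 second-moment
  tensor ``T = integral f(q) q q^T dOmega``, i.e. the axis the scattering
  ring wraps around (Friedel-equivalent to its negation);
* fiber symmetry factor — how closely the RSM resembles an ideal
  equatorial ring about its orientation, computed as the normalized
  excess of the Funk-Radon transform at the orientation;
* multi-orientation detection — local maxima of the Funk-Radon transform
  on a dense hemisphere grid, for voxels containing several fiber
  populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from . import sphharm
from .geometry import great_circle_distance_friedel
from .sphharm import SHCoefficients

__all__ = [
    "spherical_mean",
    "relative_anisotropy",
    "orientation",
    "fiber_symmetry_factor",
    "orientation_error",
    "detect_orientations",
    "analyze_field",
    "projection_fourier_anisotropy",
    "OrientationResult",
]

_Y00 = 1.0 / np.sqrt(4.0 * np.pi)


def spherical_mean(f: SHCoefficients) -> float:
    """Mean of the function over the sphere (the degree-0 term)."""
    return float(f.values[0] * _Y00)


def relative_anisotropy(f: SHCoefficients) -> float:
    """Spherical standard deviation normalized by the spherical mean.

    With orthonormal harmonics the variance is the summed squared power of
    all degrees above zero divided by ``4 pi``.
    """
    mean = spherical_mean(f)
    if mean <= 0:
        raise ValueError("relative anisotropy undefined for nonpositive mean")
    var = float(np.sum(f.values[1:] ** 2)) / (4.0 * np.pi)
    return np.sqrt(var) / mean


@dataclass
class OrientationResult:
    direction: np.ndarray
    valid: bool
    eigenvalues: np.ndarray


def second_moment_tensor(f: SHCoefficients) -> np.ndarray:
    """``T = integral f(q) q q^T dOmega`` by exact grid quadrature.

    The integrand components are degree-2 polynomials in ``q``, so the
    band-limited quadrature grid integrates them exactly.
    """
    theta, phi, w = sphharm.quadrature_grid(max(2, f.lmax))
    values = f.evaluate(theta, phi)
    st = np.sin(theta)
    q = np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])
    return np.einsum("i,ij,ik->jk", values * w, q, q)


def orientation(
    f: SHCoefficients, degeneracy_tol: float = 1e-3
) -> OrientationResult:
    """Minimal eigenvector of the rank-2 tensor representation.

    For equatorial (ring-like) scattering the smallest-eigenvalue axis of
    the second-moment tensor is the fiber orientation.  When the two
    smallest eigenvalues are closer than ``degeneracy_tol`` relative to
    the largest eigenvalue magnitude, the orientation is ill-defined and
    flagged invalid (isotropic maps, crossed rings of equal weight, ...).
    """
    t = second_moment_tensor(f)
    evals, evecs = np.linalg.eigh(t)
    scale = max(np.abs(evals).max(), np.finfo(float).tiny)
    valid = (evals[1] - evals[0]) / scale > degeneracy_tol and evals[-1] > 0
    direction = evecs[:, 0] / np.linalg.norm(evecs[:, 0])
    return OrientationResult(direction, bool(valid), evals)


def _dense_hemisphere(n: int = 4000) -> np.ndarray:
    """Deterministic quasi-uniform hemisphere grid (Fibonacci lattice)."""
    i = np.arange(n)
    z = (i + 0.5) / n  # upper hemisphere only
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def fiber_symmetry_factor(
    f: SHCoefficients, o: np.ndarray, tol: float = 1e-9
) -> float:
    """Normalized excess of the Funk-Radon transform at the orientation.

    With ``g = F[f]`` and ``mu`` its spherical mean,
    ``FSF = (g(o) - mu) / (max_sphere g - mu)``; 1 for an ideal
    equatorial ring about ``o`` (where ``o`` maximizes ``g``), 0 for an
    isotropic map (by the zero-denominator convention).
    """
    g = sphharm.funk_radon(f)
    mu = spherical_mean(g)
    grid = _dense_hemisphere()
    at_o = float(g.evaluate_directions(np.asarray(o, dtype=float)))
    gmax = max(float(g.evaluate_directions(grid).max()), at_o)
    denom = gmax - mu
    scale = max(abs(mu), abs(gmax), 1.0)
    if denom < tol * scale:
        return 0.0
    return float((at_o - mu) / denom)


def orientation_error(v: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Angle between two orientation axes, Friedel symmetric, in [0, pi/2]."""
    return great_circle_distance_friedel(v, u)


def _refine_peak(g: SHCoefficients, v0: np.ndarray) -> tuple[np.ndarray, float]:
    """Polish a peak by maximizing over the local tangent plane."""
    v0 = v0 / np.linalg.norm(v0)
    seed = np.zeros(3)
    seed[np.argmin(np.abs(v0))] = 1.0
    e1 = seed - np.dot(seed, v0) * v0
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v0, e1)

    def neg(ab):
        v = v0 + ab[0] * e1 + ab[1] * e2
        v /= np.linalg.norm(v)
        return -float(g.evaluate_directions(v))

    res = minimize(neg, np.zeros(2), method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 200})
    v = v0 + res.x[0] * e1 + res.x[1] * e2
    v /= np.linalg.norm(v)
    return v, -res.fun


def detect_orientations(
    f: SHCoefficients,
    min_separation: float = np.radians(20.0),
    min_prominence: float = 0.25,
    grid_size: int = 4000,
) -> list[tuple[np.ndarray, float]]:
    """Local maxima of the Funk-Radon transform: candidate orientations.

    Peaks are found on a dense hemisphere grid, merged by non-maximum
    suppression within ``min_separation`` (Friedel metric), kept when
    their excess over the spherical mean reaches ``min_prominence`` of the
    global maximum excess, and polished by a local continuous
    maximization.  Returned sorted by peak value, descending.
    """
    if min_separation <= 0 or min_prominence <= 0:
        raise ValueError("thresholds must be positive")
    g = sphharm.funk_radon(f)
    grid = _dense_hemisphere(grid_size)
    values = g.evaluate_directions(grid)
    mu = spherical_mean(g)
    gmax = float(values.max())
    if gmax - mu <= 1e-12 * max(abs(mu), 1.0):
        return []  # isotropic: no meaningful maxima

    # local-maximum candidates: best point within a grid-resolution ball
    tree = cKDTree(np.vstack([grid, -grid]))
    local_radius = 2.0 * np.sqrt(2.0 * np.pi / grid_size)  # ~2 grid spacings
    chord = 2.0 * np.sin(local_radius / 2.0)
    neighbors = tree.query_ball_point(grid, chord)
    n = len(grid)
    is_peak = np.array(
        [values[i] >= values[[j % n for j in nb]].max() for i, nb in enumerate(neighbors)]
    )
    candidates = np.flatnonzero(is_peak)
    candidates = candidates[np.argsort(values[candidates])[::-1]]

    selected: list[tuple[np.ndarray, float]] = []
    for idx in candidates:
        if (values[idx] - mu) < min_prominence * (gmax - mu):
            continue
        v = grid[idx]
        if any(
            great_circle_distance_friedel(v, u) < min_separation
            for u, _ in selected
        ):
            continue
        selected.append((v, float(values[idx])))

    refined = [_refine_peak(g, v) for v, _ in selected]
    refined.sort(key=lambda t: -t[1])
    return refined


def analyze_field(
    mesh, field: np.ndarray, lmax: int = 12, mean_floor: float = 1e-6
) -> dict[str, np.ndarray]:
    """Per-voxel scalar and orientational metrics for a coefficient field.

    Vectorized over voxels: one linear map takes every voxel to its
    harmonic expansion, then mean, relative anisotropy, orientation
    (batched eigendecomposition of the rank-2 tensors) and fiber symmetry
    factor are evaluated in bulk.  Voxels whose spherical mean falls below
    ``mean_floor`` times the field maximum are flagged invalid.
    """
    from scipy.special import eval_legendre

    from .rsm_basis import sh_transform_matrix

    field = np.asarray(field, dtype=float)
    shape = field.shape[:3]
    transform = sh_transform_matrix(mesh, lmax)
    sh = field.reshape(-1, field.shape[-1]) @ transform.T  # (nvox, ncoef)
    nvox = sh.shape[0]
    mean = sh[:, 0] * _Y00
    floor = mean_floor * max(mean.max(), np.finfo(float).tiny)
    ok = mean > floor
    var = np.sum(sh[:, 1:] ** 2, axis=1) / (4.0 * np.pi)
    ra = np.zeros(nvox)
    ra[ok] = np.sqrt(var[ok]) / mean[ok]

    # batched second-moment tensors: T_vox = sum_j sh_j * TB_j
    ls, ms = sphharm.even_degree_index(lmax)
    theta, phi, w = sphharm.quadrature_grid(lmax)
    st = np.sin(theta)
    q = np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])
    design = sphharm.real_sph_harm_matrix(ls, ms, theta, phi)
    tensor_basis = np.einsum("pj,p,pa,pb->jab", design, w, q, q)
    tensors = np.einsum("vj,jab->vab", sh, tensor_basis)
    evals, evecs = np.linalg.eigh(tensors)
    scale = np.maximum(np.abs(evals).max(axis=1), np.finfo(float).tiny)
    valid = ok & ((evals[:, 1] - evals[:, 0]) / scale > 1e-3)
    axes = evecs[:, :, 0]
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)

    # fiber symmetry factor from the Funk-Radon transform
    multipliers = eval_legendre(ls, 0.0)
    g = sh * multipliers
    grid = _dense_hemisphere()
    gtheta = np.arccos(np.clip(grid[:, 2], -1, 1))
    gphi = np.arctan2(grid[:, 1], grid[:, 0])
    grid_design = sphharm.real_sph_harm_matrix(ls, ms, gtheta, gphi)
    gmax = (g @ grid_design.T).max(axis=1)
    otheta = np.arccos(np.clip(axes[:, 2], -1, 1))
    ophi = np.arctan2(axes[:, 1], axes[:, 0])
    at_axis = np.einsum(
        "vj,vj->v", g, sphharm.real_sph_harm_matrix(ls, ms, otheta, ophi)
    )
    gmax = np.maximum(gmax, at_axis)
    mu = g[:, 0] * _Y00
    denom = gmax - mu
    fsf = np.zeros(nvox)
    good = valid & (denom > 1e-9 * np.maximum(np.abs(gmax), 1.0))
    fsf[good] = (at_axis[good] - mu[good]) / denom[good]

    return {
        "mean": mean.reshape(shape),
        "relative_anisotropy": ra.reshape(shape),
        "orientation": axes.reshape(shape + (3,)),
        "orientation_valid": valid.reshape(shape),
        "fiber_symmetry": fsf.reshape(shape),
        "sh_coefficients": sh.reshape(shape + (sh.shape[-1],)),
    }


def projection_fourier_anisotropy(image: np.ndarray) -> float:
    """Directional imbalance of a projection's Fourier amplitude.

    Missing-wedge smearing of a projection along one raster axis
    attenuates its discrete Fourier transform along that axis.  The
    statistic is ``|log(E0 / E1)|`` where ``E0`` and ``E1`` are the mean
    DFT amplitudes (normalized by the zero-frequency component) along the
    two frequency half-axes, DC excluded: near zero for an isotropically
    resolved projection, large when one direction is smeared.
    """
    image = np.asarray(image, dtype=float)
    spectrum = np.abs(np.fft.fft2(image))
    if spectrum[0, 0] == 0:
        raise ValueError("image has zero total intensity")
    spectrum = spectrum / spectrum[0, 0]
    n0, n1 = image.shape
    e0 = spectrum[1 : max(2, n0 // 2), 0].mean()
    e1 = spectrum[0, 1 : max(2, n1 // 2)].mean()
    return float(abs(np.log(e0 / e1)))
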