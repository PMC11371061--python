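"""Real spherical harmonics on quadrature grids, restricted to even degrees.

Friedel symmetry makes every reciprocal-space map an even function on the
sphere, so only even-degree harmonics carry weight.  Coefficients are
stored in the real orthonormal basis; expansion uses Gauss-Legendre nodes
in the polar angle crossed with a uniform azimuthal grid, which integrates
band-limited products exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre, sph_harm_y

__all__ = [
    "SHCoefficients",
    "even_degree_index",
    "real_sph_harm_matrix",
    "quadrature_grid",
    "expand",
    "funk_radon",
]


def even_degree_index(lmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Arrays of (degree, order) pairs for all even degrees up to ``lmax``."""
    if lmax < 0 or lmax % 2 != 0:
        raise ValueError("lmax must be even and nonnegative")
    ls, ms = [], []
    for ell in range(0, lmax + 1, 2):
        for m in range(-ell, ell + 1):
            ls.append(ell)
            ms.append(m)
    return np.array(ls), np.array(ms)


def real_sph_harm_matrix(
    ls: np.ndarray, ms: np.ndarray, theta: np.ndarray, phi: np.ndarray
) -> np.ndarray:
    """Design matrix of real orthonormal harmonics, shape ``(npts, ncoef)``.

    ``theta`` is the polar angle, ``phi`` the azimuth (both flat arrays).
    """
    theta = np.asarray(theta, dtype=float).ravel()
    phi = np.asarray(phi, dtype=float).ravel()
    out = np.empty((theta.size, len(ls)))
    for j, (ell, m) in enumerate(zip(ls, ms)):
        y = sph_harm_y(int(ell), abs(int(m)), theta, phi)
        if m == 0:
            out[:, j] = y.real
        elif m > 0:
            out[:, j] = np.sqrt(2.0) * (-1.0) ** m * y.real
        else:
            out[:, j] = np.sqrt(2.0) * (-1.0) ** m * y.imag
    return out


def quadrature_grid(
    lmax: int, oversample: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spherical quadrature grid exact for band limit ``2 * lmax``.

    Returns flat arrays ``(theta, phi, weights)`` with
    ``sum(weights) = 4 pi``.  ``oversample`` scales the node counts above
    the exactness minimum to reduce aliasing of slightly-off-band input.
    """
    n_theta = oversample * (lmax + 1)
    n_phi = 2 * oversample * (lmax + 1)
    x, wx = np.polynomial.legendre.leggauss(n_theta)
    theta = np.arccos(x)
    phi = np.arange(n_phi) * (2.0 * np.pi / n_phi)
    th, ph = np.meshgrid(theta, phi, indexing="ij")
    w = np.repeat(wx, n_phi) * (2.0 * np.pi / n_phi)
    return th.ravel(), ph.ravel(), w


def _vectors_to_angles(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    v = np.atleast_2d(np.asarray(v, dtype=float))
    theta = np.arccos(np.clip(v[:, 2], -1.0, 1.0))
    phi = np.arctan2(v[:, 1], v[:, 0])
    return theta, phi


@dataclass
class SHCoefficients:
    """Even-degree real spherical-harmonic coefficients up to ``lmax``."""

    lmax: int
    values: np.ndarray

    def __post_init__(self) -> None:
        ls, _ = even_degree_index(self.lmax)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != ls.shape:
            raise ValueError(
                f"expected {ls.size} coefficients for lmax={self.lmax}, "
                f"got {self.values.size}"
            )

    @property
    def index(self) -> tuple[np.ndarray, np.ndarray]:
        return even_degree_index(self.lmax)

    def evaluate(self, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        ls, ms = self.index
        return real_sph_harm_matrix(ls, ms, theta, phi) @ self.values

    def evaluate_directions(self, v: np.ndarray) -> np.ndarray:
        """Evaluate at unit vectors ``v`` of shape ``(..., 3)``."""
        v = np.asarray(v, dtype=float)
        theta, phi = _vectors_to_angles(v.reshape(-1, 3))
        return self.evaluate(theta, phi).reshape(v.shape[:-1])

    def degree_power(self) -> dict[int, float]:
        """Total squared coefficient weight per degree."""
        ls, _ = self.index
        return {
            int(ell): float(np.sum(self.values[ls == ell] ** 2))
            for ell in range(0, self.lmax + 1, 2)
        }


def expand(
    values: np.ndarray,
    theta: np.ndarray,
    phi: np.ndarray,
    weights: np.ndarray,
    lmax: int,
) -> SHCoefficients:
    """Quadrature projection of grid samples onto the even-degree basis."""
    ls, ms = even_degree_index(lmax)
    design = real_sph_harm_matrix(ls, ms, theta, phi)
    coeffs = design.T @ (np.asarray(values, dtype=float).ravel() * weights)
    return SHCoefficients(lmax, coeffs)


def funk_radon(f: SHCoefficients) -> SHCoefficients:
    """Funk-Radon transform in the normalized (great-circle mean) convention.

    Diagonal in the harmonic basis: degree ``ell`` is scaled by the
    Legendre polynomial value ``P_ell(0)`` (1, -1/2, 3/8, ... for even
    degrees; odd degrees are annihilated and absent here anyway).
    """
    ls, _ = f.index
    multipliers = eval_legendre(ls, 0.0)
    return SHCoefficients(f.lmax, f.values * multipliers)
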