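"""Sampling density on the sphere of projection and the Funk-Radon quality factor.

A tomographic acquisition realizes a set of beam directions on the unit
sphere (the *sphere of projection*).  By the projection-slice theorem, the
reconstruction at a reciprocal-space direction ``q`` draws on projections
whose beam directions lie on the great circle orthogonal to ``q``; gaps on
that circle produce missing-wedge artifacts.  The quality factor evaluates
the Funk-Radon transform (the normalized great-circle mean) of a
Friedel-symmetric coverage indicator, yielding a value in ``[0, 1]`` for
every reciprocal direction: 1 when the whole orthogonal semicircle is
within the angular threshold ``delta`` of some measured direction, down to
0 when none of it is.

The coverage indicator is binary by default (a direction is covered or it
is not); a soft Gaussian-kernel variant, capped at 1, is available for
smoother maps.  ``delta`` is a *relative* notion of sufficient sampling:
the default ties it to the scheme's own median nearest-neighbor spacing
rather than to an absolute Nyquist-style criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import great_circle_distance_friedel

__all__ = [
    "SamplingDensity",
    "default_delta",
    "quality_factor",
    "quality_map",
    "circle_points",
]


def _antipodal_tree(directions: np.ndarray) -> cKDTree:
    return cKDTree(np.vstack([directions, -directions]))


def _chord_to_angle(d: np.ndarray) -> np.ndarray:
    return 2.0 * np.arcsin(np.clip(d / 2.0, 0.0, 1.0))


def default_delta(directions: np.ndarray, factor: float = 1.5) -> float:
    """``factor`` times the median nearest-neighbor Friedel spacing.

    The nearest neighbor of each measured direction is found in the
    antipodally doubled point set, so the spacing is measured with the
    projective (Friedel) metric.
    """
    directions = np.asarray(directions, dtype=float)
    if len(directions) < 2:
        raise ValueError("need at least two directions to estimate spacing")
    tree = _antipodal_tree(directions)
    # k=2: the first hit is the query point itself at distance zero.
    dist, _ = tree.query(directions, k=2)
    spacing = _chord_to_angle(dist[:, 1])
    return factor * float(np.median(spacing))


@dataclass
class SamplingDensity:
    """Friedel-symmetric coverage of the sphere of projection.

    Parameters
    ----------
    directions
        Measured beam directions, shape ``(n, 3)``, unit vectors.
    delta
        Angular coverage threshold in radians; ``None`` selects the
        default (1.5x the median nearest-neighbor spacing).
    mode
        ``"binary"`` (indicator of being within ``delta`` of a
        measurement) or ``"soft"`` (sum of Gaussian kernels of width
        ``delta``, capped at 1).
    """

    directions: np.ndarray
    delta: float | None = None
    mode: str = "binary"
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.directions = np.atleast_2d(np.asarray(self.directions, dtype=float))
        if len(self.directions) == 0:
            raise ValueError("sampling density requires at least one direction")
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("directions must be unit vectors")
        if self.delta is None:
            self.delta = default_delta(self.directions)
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.mode not in ("binary", "soft"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = _antipodal_tree(self.directions)
        return self._tree

    def __call__(self, v: np.ndarray) -> np.ndarray:
        """Evaluate the density at unit direction(s) ``v``."""
        v = np.asarray(v, dtype=float)
        flat = np.atleast_2d(v.reshape(-1, 3))
        if self.mode == "binary":
            dist, _ = self.tree.query(flat, k=1)
            # small absolute slack so boundary cases (e.g. delta = pi/2)
            # are not lost to chord/angle rounding
            values = (_chord_to_angle(dist) <= self.delta + 1e-12).astype(float)
        else:
            # Gaussian kernel sum over all measurements, capped at 1.
            ang = great_circle_distance_friedel(
                flat[:, None, :], self.directions[None, :, :]
            )
            values = np.minimum(
                np.exp(-(ang**2) / (2.0 * self.delta**2)).sum(axis=1), 1.0
            )
        return values.reshape(v.shape[:-1])


def circle_points(direction: np.ndarray, n: int) -> np.ndarray:
    """``n`` equispaced points on the great circle orthogonal to ``direction``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    # Seed axis: the coordinate axis least aligned with d (deterministic).
    seed = np.zeros(3)
    seed[np.argmin(np.abs(d))] = 1.0
    e1 = seed - np.dot(seed, d) * d
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    tau = np.arange(n) * (2.0 * np.pi / n)
    return np.cos(tau)[:, None] * e1 + np.sin(tau)[:, None] * e2


def quality_factor(
    density: SamplingDensity, direction: np.ndarray, n_quadrature: int = 360
) -> float:
    """Funk-Radon transform of the sampling density at one reciprocal direction.

    The normalized mean of the coverage over the great circle orthogonal to
    ``direction``, computed by an ``n_quadrature``-point equispaced
    (trapezoidal, periodic) rule.  Lies in ``[0, 1]``.
    """
    if n_quadrature < 16:
        raise ValueError("n_quadrature must be at least 16")
    pts = circle_points(direction, n_quadrature)
    return float(density(pts).mean())


def quality_map(
    density: SamplingDensity, grid: np.ndarray, n_quadrature: int = 360
) -> np.ndarray:
    """Quality factor at every direction of ``grid`` (shape ``(m, 3)``).

    All circle points are batched into a single nearest-neighbor query, so
    dense maps stay fast.
    """
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    if len(grid) == 0:
        raise ValueError("empty evaluation grid")
    pts = np.concatenate([circle_points(g, n_quadrature) for g in grid])
    values = density(pts).reshape(len(grid), n_quadrature)
    return values.mean(axis=1)
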