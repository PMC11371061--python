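"""Multi-channel John (X-ray) transform and absorbance.

Line-integral forward projection of a voxel field with an arbitrary number
of channels per voxel, and its exact adjoint.  The projector is
voxel-driven: every voxel is mapped along the beam onto the raster plane
and deposits its value times the voxel size through a separable footprint
over the two raster axes.  The footprint along each axis is the unit
pixel box convolved with the voxel cube's projected edge extents (a box
spline, in the spirit of distance-driven and separable-footprint
projectors), which suppresses the lattice-aliasing ripple a plain
bilinear splat shows near 45-degree views.  Because the footprint is an
exact partition of unity on the pixel lattice, the projector conserves
mass to rounding for any orientation, and the adjoint (the matching
gather) satisfies ``<Px, y> = <x, P^T y>`` exactly — the property the
iterative solver depends on.

Geometry: raster axes are the detector 0/90-degree azimuth axes rotated
into the sample frame; pixel values model the pixel-area average of ray
integrals; the voxel grid is centered on the volume center, 0-based
indexing.  All channels share the ray geometry.
"""

from __future__ import annotations

import logging

import numba
import numpy as np

from .geometry import SampleOrientation, beam_direction, detector_axes

__all__ = ["project", "backproject", "absorbance", "default_image_shape"]

logger = logging.getLogger(__name__)


@numba.njit(cache=True)
def _box_spline(t, w, n):
    """Convolution of ``n`` unit-integral boxes of widths ``w[:n]`` at ``t``.

    Evaluated by the inclusion-exclusion formula over truncated powers.
    """
    total = 0.0
    for i in range(n):
        total += w[i]
    acc = 0.0
    for mask in range(1 << n):
        shift = t + 0.5 * total
        sign = 1.0
        for i in range(n):
            if mask & (1 << i):
                shift -= w[i]
                sign = -sign
        if shift > 0.0:
            power = 1.0
            for _ in range(n - 1):
                power *= shift
            acc += sign * power
    denom = 1.0
    for i in range(2, n):  # (n - 1)!
        denom *= i
    for i in range(n):
        denom *= w[i]
    return acc / denom


@numba.njit(cache=True)
def _axis_widths(v, w):
    """Footprint box widths along one raster axis: the unit pixel box plus
    the voxel cube's nonvanishing projected edge extents."""
    w[0] = 1.0
    n = 1
    for i in range(3):
        e = abs(v[i])
        if e > 1e-9:
            w[n] = e
            n += 1
    return n


@numba.njit(cache=True)
def _splat(field, image, jv, kv, h, adjoint):
    """Shared forward/adjoint kernel.

    Forward: scatter voxel values into ``image``.  Adjoint: gather pixel
    values into ``field`` with the same weights.  The footprint (pixel box
    convolved with the voxel shadow) is an exact partition of unity on the
    pixel lattice, so no normalization is needed and total mass is exact.
    Serial loops keep the accumulation order deterministic.
    """
    nx, ny, nz, nchan = field.shape
    nj, nk, _ = image.shape
    cx = (nx - 1) / 2.0
    cy = (ny - 1) / 2.0
    cz = (nz - 1) / 2.0
    cj = (nj - 1) / 2.0
    ck = (nk - 1) / 2.0

    wj = np.empty(4)
    wk = np.empty(4)
    n_j = _axis_widths(jv, wj)
    n_k = _axis_widths(kv, wk)
    hwj = 0.0
    for i in range(n_j):
        hwj += wj[i]
    hwk = 0.0
    for i in range(n_k):
        hwk += wk[i]
    hwj *= 0.5
    hwk *= 0.5
    # footprint support is at most 1 + sqrt(3) < 3 pixels wide, so it
    # touches at most 3 consecutive pixels per axis (plus one safety tap)
    max_taps = 4
    wj_buf = np.empty(max_taps)
    wk_buf = np.empty(max_taps)

    for ix in range(nx):
        px = (ix - cx) * h
        for iy in range(ny):
            py = (iy - cy) * h
            for iz in range(nz):
                pz = (iz - cz) * h
                jf = (px * jv[0] + py * jv[1] + pz * jv[2]) / h + cj
                kf = (px * kv[0] + py * kv[1] + pz * kv[2]) / h + ck
                j0 = int(np.floor(jf - hwj)) + 1
                k0 = int(np.floor(kf - hwk)) + 1
                for d in range(max_taps):
                    wj_buf[d] = _box_spline(j0 + d - jf, wj, n_j)
                    wk_buf[d] = _box_spline(k0 + d - kf, wk, n_k)
                for dj in range(max_taps):
                    j = j0 + dj
                    if j < 0 or j >= nj or wj_buf[dj] == 0.0:
                        continue
                    w1 = wj_buf[dj] * h
                    for dk in range(max_taps):
                        k = k0 + dk
                        if k < 0 or k >= nk or wk_buf[dk] == 0.0:
                            continue
                        w = w1 * wk_buf[dk]
                        if adjoint:
                            for ch in range(nchan):
                                field[ix, iy, iz, ch] += w * image[j, k, ch]
                        else:
                            for ch in range(nchan):
                                image[j, k, ch] += w * field[ix, iy, iz, ch]


def _raster_axes(
    orientation: SampleOrientation, mount_rotation: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    p = beam_direction(orientation, mount_rotation)
    if not np.isfinite(p).all() or np.linalg.norm(p) < 1e-12:
        raise ValueError("degenerate geometry: zero-norm beam direction")
    return detector_axes(orientation, mount_rotation)


def default_image_shape(field_shape: tuple[int, ...]) -> tuple[int, int]:
    """Square raster covering the voxel grid under any rotation.

    The margin keeps every voxel footprint (half-width up to about 1.4
    pixels) fully inside the image, which is what makes mass conservation
    exact.
    """
    n = int(np.ceil(np.linalg.norm(field_shape[:3]))) + 4
    return (n, n)


def project(
    field: np.ndarray,
    orientation: SampleOrientation,
    mount_rotation: np.ndarray | None = None,
    image_shape: tuple[int, int] | None = None,
    voxel_size: float = 1.0,
) -> np.ndarray:
    """Forward-project a (X, Y, Z, C) field to a (J, K, C) image.

    Output values are line integrals, i.e. channel units times length.
    """
    field = np.ascontiguousarray(np.asarray(field, dtype=float))
    if field.ndim != 4 or field.size == 0:
        raise ValueError("field must be a nonempty (X, Y, Z, C) array")
    if image_shape is None:
        image_shape = default_image_shape(field.shape)
    jv, kv = _raster_axes(orientation, mount_rotation)
    image = np.zeros(tuple(image_shape) + (field.shape[3],))
    _splat(field, image, jv, kv, float(voxel_size), False)
    return image


def backproject(
    image: np.ndarray,
    field_shape: tuple[int, int, int],
    orientation: SampleOrientation,
    mount_rotation: np.ndarray | None = None,
    voxel_size: float = 1.0,
) -> np.ndarray:
    """Exact adjoint of :func:`project` for the same geometry."""
    image = np.ascontiguousarray(np.asarray(image, dtype=float))
    if image.ndim != 3:
        raise ValueError("image must be a (J, K, C) array")
    jv, kv = _raster_axes(orientation, mount_rotation)
    field = np.zeros(tuple(field_shape) + (image.shape[2],))
    _splat(field, image, jv, kv, float(voxel_size), True)
    return field


def absorbance(
    transmitted: np.ndarray, incident: float | str = "auto"
) -> np.ndarray:
    """Per-pixel absorbance ``ln(I0 / I_T)``.

    With ``incident="auto"`` the incident intensity is approximated by the
    image maximum — valid whenever the raster includes some air, whose
    absorbance is negligible.  Nonpositive transmitted intensities are
    masked with NaN and logged rather than raised.
    """
    transmitted = np.asarray(transmitted, dtype=float)
    if incident == "auto":
        i0 = float(np.nanmax(transmitted))
    else:
        i0 = float(incident)
    if i0 <= 0:
        raise ValueError("incident intensity must be positive")
    bad = ~(transmitted > 0)
    if np.any(bad):
        logger.warning(
            "absorbance: masking %d pixel(s) with nonpositive transmission",
            int(bad.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(i0 / transmitted)
    out[bad] = np.nan
    return out
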