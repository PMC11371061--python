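"""Coordinate conventions, rotations and acquisition-scheme generation.

Conventions
-----------
The laboratory frame has the X-ray beam travelling along ``z``.  The sample
sits on a two-circle stage: the main tomographic rotation (angle ``alpha``)
is about the laboratory ``y`` axis, and the tilt (angle ``beta``) is about
the laboratory ``x`` axis.  The tilt stage carries the rotation stage, and
a remounted sample is rotated relative to its pin before either stage
acts, so a sample orientation corresponds to the active composite rotation
``R = R_x(beta) @ R_y(alpha) @ R_mount`` applied to the sample.  The
sample and laboratory frames coincide at ``alpha = beta = 0`` on the first
mount.

All directions handled here live in the *sample* frame: the beam direction
for a given orientation is ``R.T @ z``, and likewise for the detector
azimuth axes.  Angles are radians internally; file formats and the CLI use
degrees.

Because elastic scattering obeys Friedel symmetry (``q`` and ``-q`` are
equivalent), directions are compared with a projective metric,
``arccos(|v . u|)``, which identifies antipodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "SampleOrientation",
    "AcquisitionScheme",
    "rotation_y",
    "rotation_x",
    "rotation_z",
    "composite_rotation",
    "beam_direction",
    "detector_axes",
    "probed_circle",
    "great_circle_distance_friedel",
    "generate_tilt_scheme",
    "default_segment_boundaries",
    "SchemeViews",
    "scheme_views",
]

_UNIT_TOL = 1e-6


class SampleOrientation(NamedTuple):
    """Sample orientation as (rotation, tilt) angles in radians."""

    alpha: float
    beta: float


def rotation_y(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_x(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotation_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def composite_rotation(
    orientation: SampleOrientation, mount_rotation: np.ndarray | None = None
) -> np.ndarray:
    """Active rotation applied to the sample: ``R_x(beta) R_y(alpha) R_mount``.

    The mount rotation is innermost: a remounted sample is rotated on its
    pin before the stage angles act, so the beam directions of a
    remounted series are the first-mount directions carried through the
    (inverse) mount rotation.
    """
    alpha, beta = orientation
    rot = rotation_x(beta) @ rotation_y(alpha)
    if mount_rotation is not None:
        rot = rot @ np.asarray(mount_rotation, dtype=float)
    return rot


def beam_direction(
    orientation: SampleOrientation, mount_rotation: np.ndarray | None = None
) -> np.ndarray:
    """Unit beam direction in the sample frame for a given orientation."""
    rot = composite_rotation(orientation, mount_rotation)
    return rot.T @ np.array([0.0, 0.0, 1.0])


def detector_axes(
    orientation: SampleOrientation, mount_rotation: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Detector 0-degree and 90-degree azimuth axes in the sample frame.

    Together with the beam direction these form a right-handed orthonormal
    triad ``(q0, q90, p)``.
    """
    rot = composite_rotation(orientation, mount_rotation)
    q0 = rot.T @ np.array([1.0, 0.0, 0.0])
    q90 = rot.T @ np.array([0.0, 1.0, 0.0])
    return q0, q90


def probed_circle(
    tau: float | np.ndarray,
    orientation: SampleOrientation,
    mount_rotation: np.ndarray | None = None,
) -> np.ndarray:
    """Reciprocal directions probed at detector azimuth ``tau``.

    The probed set is the great circle orthogonal to the beam,
    ``cos(tau) q0 + sin(tau) q90``.  ``tau`` may be an array, in which case
    an array of shape ``tau.shape + (3,)`` is returned.
    """
    q0, q90 = detector_axes(orientation, mount_rotation)
    tau = np.asarray(tau, dtype=float)
    return np.cos(tau)[..., None] * q0 + np.sin(tau)[..., None] * q90


def great_circle_distance_friedel(v: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Friedel-symmetric great-circle distance ``arccos(|v . u|)``.

    Identifies each direction with its antipode, so the result lies in
    ``[0, pi/2]``.  Broadcasts over leading axes; the last axis must have
    length 3 and hold unit vectors.
    """
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    for name, w in (("v", v), ("u", u)):
        norms = np.linalg.norm(w, axis=-1)
        if not np.allclose(norms, 1.0, atol=_UNIT_TOL):
            raise ValueError(f"{name} must contain unit vectors (got norm {norms})")
    dots = np.abs(np.sum(v * u, axis=-1))
    return np.arccos(np.clip(dots, -1.0, 1.0))


def default_segment_boundaries(n_segments: int = 16) -> np.ndarray:
    """Evenly spaced detector-segment boundaries covering ``[0, pi)``."""
    return np.linspace(0.0, np.pi, n_segments + 1)


@dataclass
class AcquisitionScheme:
    """A set of sample orientations plus detector-segment boundaries.

    Parameters
    ----------
    orientations
        Ordered list of (alpha, beta) sample orientations, radians.
    mount_rotation
        Extra rotation of the sample frame for a remounted series
        (identity for the first mount).
    segment_boundaries
        Strictly increasing azimuthal bin edges spanning ``[0, pi)``;
        ``M + 1`` values delimit ``M`` detector segments.
    """

    orientations: list[SampleOrientation]
    mount_rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    segment_boundaries: np.ndarray = field(
        default_factory=lambda: default_segment_boundaries()
    )

    def __post_init__(self) -> None:
        self.orientations = [SampleOrientation(*o) for o in self.orientations]
        if len(self.orientations) == 0:
            raise ValueError("scheme must contain at least one orientation")
        self.mount_rotation = np.asarray(self.mount_rotation, dtype=float)
        b = np.asarray(self.segment_boundaries, dtype=float)
        if b.ndim != 1 or len(b) < 2 or np.any(np.diff(b) <= 0):
            raise ValueError("segment boundaries must be strictly increasing")
        if b[0] < -1e-12 or b[-1] > np.pi + 1e-12:
            raise ValueError("segment boundaries must lie within [0, pi]")
        self.segment_boundaries = b

    @property
    def n_segments(self) -> int:
        return len(self.segment_boundaries) - 1

    def beam_directions(self) -> np.ndarray:
        """Beam directions of every orientation, shape ``(n, 3)``."""
        return np.array(
            [beam_direction(o, self.mount_rotation) for o in self.orientations]
        )

    # -- JSON round trip (angles in degrees on disk) --------------------
    def to_json(self) -> str:
        payload = {
            "orientations": [
                [np.degrees(o.alpha), np.degrees(o.beta)] for o in self.orientations
            ],
            "mount_rotation": self.mount_rotation.ravel().tolist(),
            "segment_boundaries_deg": np.degrees(self.segment_boundaries).tolist(),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AcquisitionScheme":
        payload = json.loads(text)
        orientations = [
            SampleOrientation(np.radians(a), np.radians(b))
            for a, b in payload["orientations"]
        ]
        mount = np.array(payload["mount_rotation"], dtype=float).reshape(3, 3)
        boundaries = np.radians(payload["segment_boundaries_deg"])
        return cls(orientations, mount, boundaries)


@dataclass
class SchemeViews:
    """Flattened view list over one scheme or several (a multi-mount set).

    Iterating yields ``(orientation, mount_rotation)`` pairs in
    acquisition order; ``mount_index`` records which scheme each view
    came from.  All schemes must share their detector segmentation.
    """

    orientations: list[SampleOrientation]
    mounts: list[np.ndarray]
    mount_index: list[int]
    segment_boundaries: np.ndarray

    def __len__(self) -> int:
        return len(self.orientations)

    def __iter__(self):
        return iter(zip(self.orientations, self.mounts))


def scheme_views(
    scheme: "AcquisitionScheme | Sequence[AcquisitionScheme]",
) -> SchemeViews:
    """Flatten one scheme or a sequence of schemes into per-view geometry."""
    schemes = [scheme] if isinstance(scheme, AcquisitionScheme) else list(scheme)
    if not schemes:
        raise ValueError("need at least one scheme")
    boundaries = schemes[0].segment_boundaries
    for s in schemes[1:]:
        if not np.allclose(s.segment_boundaries, boundaries):
            raise ValueError("schemes must share detector segment boundaries")
    orientations: list[SampleOrientation] = []
    mounts: list[np.ndarray] = []
    mount_index: list[int] = []
    for si, s in enumerate(schemes):
        orientations.extend(s.orientations)
        mounts.extend([s.mount_rotation] * len(s.orientations))
        mount_index.extend([si] * len(s.orientations))
    return SchemeViews(orientations, mounts, mount_index, boundaries)


def generate_tilt_scheme(
    n_tilts: int,
    n_rotations: int,
    beta_max: float,
    mount_rotation: np.ndarray | None = None,
    segment_boundaries: np.ndarray | None = None,
    full_rotation: bool = False,
    single_mount: bool = True,
) -> AcquisitionScheme:
    """Regular tilt-series scheme: tilts crossed with rotations, tilt-major.

    Tilts are evenly spaced in ``[-beta_max, beta_max]`` (a single tilt sits
    at zero) and rotations evenly spaced over a half turn ``[0, pi)``; with
    ``full_rotation`` the rotations span ``[0, 2 pi)`` to mimic a real
    acquisition (the extra half-turn is Friedel-redundant).

    A mechanically realistic single-mount stage cannot tilt beyond 45
    degrees; pass ``single_mount=False`` to lift that check.
    """
    if n_tilts < 1 or n_rotations < 1:
        raise ValueError("need at least one tilt and one rotation")
    if beta_max < 0:
        raise ValueError("beta_max must be nonnegative")
    if single_mount and beta_max > np.pi / 4 + 1e-12:
        raise ValueError(
            "single-mount schemes are limited to tilts of 45 degrees; "
            "pass single_mount=False to override"
        )
    if n_tilts == 1:
        tilts = np.array([0.0])
    else:
        tilts = np.linspace(-beta_max, beta_max, n_tilts)
    span = 2.0 * np.pi if full_rotation else np.pi
    rotations = np.arange(n_rotations) * (span / n_rotations)
    orientations = [
        SampleOrientation(alpha, beta) for beta in tilts for alpha in rotations
    ]
    kwargs = {}
    if mount_rotation is not None:
        kwargs["mount_rotation"] = mount_rotation
    if segment_boundaries is not None:
        kwargs["segment_boundaries"] = segment_boundaries
    return AcquisitionScheme(orientations, **kwargs)
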