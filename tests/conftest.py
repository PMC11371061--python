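"""Shared fixtures: meshes and the standard dual-mount phantom study.

The "study" fixture bundle reproduces the package's reference experiment:
a 16^3 two-domain phantom with an interface band, measured noiselessly on
two 7-tilt x 16-rotation mounts (the second rotated 90 degrees about the
beam), reconstructed with default solver settings from the full data and
from mount 1 alone.  It is session-scoped because the two 200-iteration
reconstructions dominate the suite's runtime.
"""

import logging

import numpy as np
import pytest

from tensaxs.geometry import (
    default_segment_boundaries,
    generate_tilt_scheme,
    rotation_z,
)
from tensaxs.phantom import (
    default_phantom_spec,
    make_phantom,
    simulate_measurement,
)
from tensaxs.reconstruction import (
    ReconstructionConfig,
    projection_matrices,
    reconstruct,
)
from tensaxs.rsm_basis import kurihara_mesh

logging.getLogger("tensaxs").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def mesh7():
    return kurihara_mesh(7)


@pytest.fixture(scope="session")
def dual_schemes():
    seg = default_segment_boundaries(16)
    return [
        generate_tilt_scheme(7, 16, np.pi / 4, segment_boundaries=seg),
        generate_tilt_scheme(
            7, 16, np.pi / 4,
            mount_rotation=rotation_z(np.pi / 2), segment_boundaries=seg,
        ),
    ]


@pytest.fixture(scope="session")
def study(mesh7, dual_schemes):
    """Phantom truth, noiseless dual-mount data, full and mount-1 tomograms."""
    spec = default_phantom_spec((16, 16, 16))
    field, ground_truth = make_phantom(spec, mesh7)
    gs = projection_matrices(mesh7, dual_schemes)
    projections = simulate_measurement(field, mesh7, dual_schemes, gs=gs)
    config = ReconstructionConfig()
    rec_full, trace_full = reconstruct(
        projections.data, mesh7, dual_schemes, config,
        field_shape=(16, 16, 16), gs=gs,
    )
    n1 = len(dual_schemes[0].orientations)
    rec_mount1, trace_mount1 = reconstruct(
        projections.data[:n1], mesh7, dual_schemes[0], config,
        field_shape=(16, 16, 16), gs=gs[:n1],
    )
    return {
        "spec": spec,
        "field": field,
        "ground_truth": ground_truth,
        "schemes": dual_schemes,
        "gs": gs,
        "projections": projections,
        "rec_full": rec_full,
        "trace_full": trace_full,
        "rec_mount1": rec_mount1,
        "trace_mount1": trace_mount1,
        "mesh": mesh7,
    }
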