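"""Plain-text legacy VTK writers for inspection in standard 3D viewers.

Only the two shapes the pipeline produces are supported: voxel grids of
per-voxel metrics (structured points) and spherical point clouds
(polydata), both written in the human-readable legacy ASCII format so no
VTK library is required to produce or to parse them.
"""

from __future__ import annotations

import numpy as np

__all__ = ["export_vtk_image", "export_vtk_points"]


def _format_array(fh, name: str, array: np.ndarray) -> None:
    array = np.asarray(array, dtype=np.float32)
    if array.ndim == 4 and array.shape[3] == 3:
        fh.write(f"VECTORS {name} float\n")
        flat = array.transpose(2, 1, 0, 3).reshape(-1, 3)
        for row in flat:
            fh.write(f"{row[0]:.7g} {row[1]:.7g} {row[2]:.7g}\n")
    elif array.ndim == 3:
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        for value in array.transpose(2, 1, 0).ravel():
            fh.write(f"{value:.7g}\n")
    else:
        raise ValueError(f"array {name!r} must be (X,Y,Z) or (X,Y,Z,3)")


def export_vtk_image(
    path, arrays: dict[str, np.ndarray], voxel_size: float = 1.0
) -> None:
    """Write per-voxel arrays as a legacy-ASCII structured-points file.

    ``arrays`` maps names to ``(X, Y, Z)`` scalar or ``(X, Y, Z, 3)``
    vector fields, all on the same grid.
    """
    if not arrays:
        raise ValueError("no arrays to export")
    shapes = {np.asarray(a).shape[:3] for a in arrays.values()}
    if len(shapes) != 1:
        raise ValueError("all arrays must share the voxel grid")
    (shape,) = shapes
    if 0 in shape:
        raise ValueError("empty field")
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("tensaxs voxel metrics\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {shape[0]} {shape[1]} {shape[2]}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {voxel_size} {voxel_size} {voxel_size}\n")
        fh.write(f"POINT_DATA {shape[0] * shape[1] * shape[2]}\n")
        for name in sorted(arrays):
            _format_array(fh, name, arrays[name])


def export_vtk_points(
    path, points: np.ndarray, values: dict[str, np.ndarray]
) -> None:
    """Write a point cloud (e.g. a reciprocal-sphere quality map) as polydata."""
    points = np.asarray(points, dtype=np.float32)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) == 0:
        raise ValueError("points must be a nonempty (n, 3) array")
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("tensaxs sphere map\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(points)} float\n")
        for row in points:
            fh.write(f"{row[0]:.7g} {row[1]:.7g} {row[2]:.7g}\n")
        fh.write(f"POINT_DATA {len(points)}\n")
        for name in sorted(values):
            arr = np.asarray(values[name], dtype=np.float32).ravel()
            if len(arr) != len(points):
                raise ValueError(f"array {name!r} length mismatch")
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            for value in arr:
                fh.write(f"{value:.7g}\n")
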