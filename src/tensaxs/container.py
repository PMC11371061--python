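"""HDF5 container for projection stacks, meshes, tomograms and provenance.

Layout::

    /projections/<i>/data       (J, K, M) float32  segment-binned scattering
    /projections/<i>/diode      (J, K)    float32  transmitted intensity
    /projections/<i>/alpha_deg  ()        float64  rotation angle
    /projections/<i>/beta_deg   ()        float64  tilt angle
    /projections/<i>/mount      ()        int      index into /mounts
    /mounts                     (n, 3, 3) float64  mount rotations
    /segment_boundaries_deg     (M + 1,)  float64
    /mesh/{modes,sigma,s}                          basis grid (optional)
    /tomogram/coefficients      (X, Y, Z, N) float32 (optional)
    /ground_truth/*                                  (optional)
    /provenance/{config,version,seed}                always written

Angles are stored in degrees (human-readable); everything in memory is
radians.  Bulk arrays are float32 on disk, float64 in memory; geometry and
provenance stay float64.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np

from .geometry import AcquisitionScheme, SampleOrientation
from .rsm_basis import KuriharaMesh

__all__ = ["ProjectionData", "write_container", "read_container"]


@dataclass
class ProjectionData:
    """In-memory projection stacks with their complete geometry."""

    data: list[np.ndarray]
    diode: list[np.ndarray]
    orientations: list[SampleOrientation]
    mounts: list[np.ndarray]
    mount_index: list[int]
    segment_boundaries: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.data)
        if not (
            len(self.diode) == len(self.orientations) == len(self.mounts)
            == len(self.mount_index) == n
        ):
            raise ValueError("projection attribute lists must have equal length")
        n_seg = len(self.segment_boundaries) - 1
        for i, d in enumerate(self.data):
            if d.ndim != 3 or d.shape[2] != n_seg:
                raise ValueError(
                    f"projection {i}: data has {d.shape} but the scheme "
                    f"defines {n_seg} segments"
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_segments(self) -> int:
        return len(self.segment_boundaries) - 1

    def schemes(self) -> list[AcquisitionScheme]:
        """Rebuild one acquisition scheme per mount, in mount order."""
        out = []
        for mi in sorted(set(self.mount_index)):
            orientations = [
                o for o, m in zip(self.orientations, self.mount_index) if m == mi
            ]
            mount = self.mounts[self.mount_index.index(mi)]
            out.append(
                AcquisitionScheme(orientations, mount, self.segment_boundaries)
            )
        return out


def write_container(
    path,
    projections: ProjectionData | None = None,
    mesh: KuriharaMesh | None = None,
    tomogram: np.ndarray | None = None,
    ground_truth: dict | None = None,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write a deterministic container; provenance is always embedded."""
    from . import __version__

    with h5py.File(path, "w") as fh:
        if projections is not None:
            unique_mounts: list = []
            remap = []
            for mi, mount in zip(projections.mount_index, projections.mounts):
                while mi >= len(unique_mounts):
                    unique_mounts.append(None)
                unique_mounts[mi] = np.asarray(mount, dtype=float)
                remap.append(mi)
            fh.create_dataset("mounts", data=np.array(unique_mounts))
            fh.create_dataset(
                "segment_boundaries_deg",
                data=np.degrees(projections.segment_boundaries),
            )
            grp = fh.create_group("projections")
            for i in range(len(projections)):
                g = grp.create_group(str(i))
                g.create_dataset(
                    "data", data=projections.data[i].astype(np.float32)
                )
                g.create_dataset(
                    "diode", data=projections.diode[i].astype(np.float32)
                )
                g.create_dataset(
                    "alpha_deg", data=np.degrees(projections.orientations[i].alpha)
                )
                g.create_dataset(
                    "beta_deg", data=np.degrees(projections.orientations[i].beta)
                )
                g.create_dataset("mount", data=remap[i])
        if mesh is not None:
            g = fh.create_group("mesh")
            g.create_dataset("modes", data=mesh.modes)
            g.create_dataset("sigma", data=mesh.sigma)
            g.create_dataset("s", data=mesh.s)
        if tomogram is not None:
            fh.create_group("tomogram").create_dataset(
                "coefficients", data=np.asarray(tomogram).astype(np.float32)
            )
        if ground_truth is not None:
            g = fh.create_group("ground_truth")
            for key, value in sorted(ground_truth.items()):
                value = np.asarray(value)
                if value.dtype.kind == "f":
                    value = value.astype(np.float32)
                g.create_dataset(key, data=value)
        prov = fh.create_group("provenance")
        prov.create_dataset(
            "config", data=json.dumps(config or {}, sort_keys=True)
        )
        prov.create_dataset("version", data=__version__)
        prov.create_dataset("seed", data=-1 if seed is None else int(seed))


def _require(fh: h5py.File, path: str):
    if path not in fh:
        raise KeyError(f"malformed container: missing dataset {path!r}")
    return fh[path]


def read_container(path) -> dict:
    """Read and validate a container written by :func:`write_container`.

    Returns a dict with keys ``projections`` (:class:`ProjectionData` or
    None), ``mesh``, ``tomogram``, ``ground_truth`` and ``provenance``.
    Fails loudly, naming the first missing dataset.
    """
    out: dict = {
        "projections": None,
        "mesh": None,
        "tomogram": None,
        "ground_truth": None,
    }
    with h5py.File(path, "r") as fh:
        if "projections" in fh:
            mounts = np.asarray(_require(fh, "mounts"))
            boundaries = np.radians(
                np.asarray(_require(fh, "segment_boundaries_deg"))
            )
            keys = sorted(fh["projections"].keys(), key=int)
            data, diode, orientations, mount_rots, mount_idx = [], [], [], [], []
            n_seg = None
            for key in keys:
                base = f"projections/{key}"
                d = np.asarray(_require(fh, f"{base}/data"), dtype=float)
                if n_seg is None:
                    n_seg = d.shape[2]
                elif d.shape[2] != n_seg:
                    raise ValueError(
                        f"projection {key}: segment count {d.shape[2]} "
                        f"differs from {n_seg}"
                    )
                data.append(d)
                diode.append(
                    np.asarray(_require(fh, f"{base}/diode"), dtype=float)
                )
                alpha = float(np.asarray(_require(fh, f"{base}/alpha_deg")))
                beta = float(np.asarray(_require(fh, f"{base}/beta_deg")))
                orientations.append(
                    SampleOrientation(np.radians(alpha), np.radians(beta))
                )
                mi = int(np.asarray(_require(fh, f"{base}/mount")))
                mount_idx.append(mi)
                mount_rots.append(mounts[mi])
            out["projections"] = ProjectionData(
                data, diode, orientations, mount_rots, mount_idx, boundaries
            )
        if "mesh" in fh:
            out["mesh"] = KuriharaMesh(
                s=int(np.asarray(_require(fh, "mesh/s"))),
                modes=np.asarray(_require(fh, "mesh/modes"), dtype=float),
                sigma=float(np.asarray(_require(fh, "mesh/sigma"))),
            )
        if "tomogram" in fh:
            out["tomogram"] = np.asarray(
                _require(fh, "tomogram/coefficients"), dtype=float
            )
        if "ground_truth" in fh:
            out["ground_truth"] = {
                k: np.asarray(v) for k, v in fh["ground_truth"].items()
            }
        prov = _require(fh, "provenance")
        out["provenance"] = {
            "config": json.loads(prov["config"][()].decode()),
            "version": prov["version"][()].decode(),
            "seed": int(np.asarray(prov["seed"])),
        }
    return out
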