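# tensaxs

Small-angle X-ray scattering tensor tomography (SAXSTT) with local
Gaussian-kernel reciprocal-space maps, and a sampling-quality framework
for the missing-wedge problem.

## The problem

Scanning SAXS measures, at every raster point, the angular distribution
of nanoscale scattering — in bone, the diffuse equatorial ring of the
mineral platelets around collagen fibrils.  SAXSTT turns many such scans,
acquired while rotating and tilting the sample, into a volume where every
voxel carries its own reciprocal-space map (RSM) `f(q̂)`: a function on
the unit sphere, even under `q̂ → −q̂` (Friedel symmetry), from which mean
scattering, anisotropy and the local fiber orientation are read off.

Tilt stages cannot exceed ±45°, so a single mount leaves part of the
sphere of projection unmeasured — a *missing wedge* that blurs specific
reciprocal-space directions.  This package implements the full pipeline
around that problem, for users who design acquisition schemes or analyze
tensor-tomographic reconstructions:

* **geometry** — sample orientations `(α, β)`, dual-mount schemes,
  probed great circles, the Friedel metric `Δ(v, u) = arccos|v·u|`;
* **sampling_quality** — the quality factor `F[ρ](q̂)`: the Funk–Radon
  transform (normalized great-circle mean) of a coverage indicator on
  the sphere of projection.  `F = 1` where the orthogonal semicircle is
  fully measured; a ±45° single mount bottoms out at exactly `F = 0.5`;
* **rsm_basis** — `N = 2s²` Gaussian kernels on a hemispherical
  Kurihara-style mesh, detector projection matrices `G`, and conversion
  to even-degree spherical harmonics;
* **john_transform** — a multi-channel X-ray projector with exact mass
  conservation and an exact adjoint;
* **reconstruction** — the per-projection systems `Pᵢ X Gᵢᵀ = Dᵢ` solved
  by Nesterov-accelerated gradient descent with SIRT-style weights and
  preconditioner, optional Huber TV/L1 regularization;
* **analysis** — spherical mean, relative anisotropy, orientation (the
  minimal eigenvector of `∫ f q̂ q̂ᵀ dΩ`), a fiber-symmetry factor, and
  multi-orientation detection from Funk–Radon maxima;
* **phantom** — synthetic bone-like phantoms with oriented-ring RSMs,
  multi-orientation interface voxels, and Poisson counting noise with a
  low-transmission core.

See `docs/methods.md` for the model, defaults and numerical choices.

## Worked example

Predict the missing wedge of a dual-mount acquisition, then simulate and
reconstruct a small phantom:

```python
import numpy as np
from tensaxs.geometry import generate_tilt_scheme, rotation_z
from tensaxs.sampling_quality import SamplingDensity, quality_map
from tensaxs.rsm_basis import kurihara_mesh
from tensaxs.phantom import default_phantom_spec, make_phantom, simulate_measurement
from tensaxs.reconstruction import reconstruct, ReconstructionConfig
from tensaxs.analysis import analyze_field, orientation_error

# -- where will a single +-45 degree mount fail?
dense1 = generate_tilt_scheme(31, 60, np.pi / 4)
dense2 = generate_tilt_scheme(31, 60, np.pi / 4,
                              mount_rotation=rotation_z(np.pi / 2))
density = SamplingDensity(dense1.beam_directions())
grid = kurihara_mesh(12).modes            # 288 reciprocal directions
q1 = quality_map(density, grid)
both = np.vstack([dense1.beam_directions(), dense2.beam_directions()])
qb = quality_map(SamplingDensity(both, delta=density.delta), grid)
print(f"mount 1 quality: min {q1.min():.3f}, max {q1.max():.3f}")
print(f"both mounts:     min {qb.min():.3f}, max {qb.max():.3f}")

# -- simulate a noisy dual-mount measurement of an 8^3 two-domain phantom
mesh = kurihara_mesh(5)                   # 50 basis functions
mount1 = generate_tilt_scheme(5, 8, np.pi / 4)
mount2 = generate_tilt_scheme(5, 8, np.pi / 4,
                              mount_rotation=rotation_z(np.pi / 2))
truth, gt = make_phantom(default_phantom_spec((8, 8, 8)), mesh)
data = simulate_measurement(truth, mesh, [mount1, mount2], noise=1e5, seed=7)

tomogram, trace = reconstruct(data.data, mesh, [mount1, mount2],
                              ReconstructionConfig(n_iterations=100),
                              field_shape=(8, 8, 8))
mask = truth.any(axis=-1)
rmse = np.linalg.norm((tomogram - truth)[mask]) / np.linalg.norm(truth[mask])
print(f"final loss {trace[-1]:.3e}, coefficient RMSE {100 * rmse:.1f}%")

metrics = analyze_field(mesh, tomogram)
sel = (gt["n_orientations"] == 1) & metrics["orientation_valid"]
err = orientation_error(metrics["orientation"][sel],
                        gt["orientations"][sel][:, 0])
print(f"median orientation error {np.degrees(np.median(err)):.2f} deg "
      f"over {sel.sum()} single-domain voxels")
```

Output:

```
mount 1 quality: min 0.544, max 1.000
both mounts:     min 1.000, max 1.000
final loss 4.666e-01, coefficient RMSE 3.4%
median orientation error 0.22 deg over 64 single-domain voxels
```

Reading it: the single mount predicts degraded reconstruction (`F` down
to ~0.5) in the reciprocal-space band orthogonal to its rotation axis,
while the two mounts together cover every great circle (`F = 1`
everywhere).  Reconstructing from the combined, Poisson-noisy data
recovers the phantom's basis coefficients to a few percent and the
planted fiber orientations to a fraction of a degree.

The same pipeline is scriptable from the shell:

```sh
tensaxs simulate --shape 16 --mesh-scale 7 --out run.h5
tensaxs reconstruct --input run.h5 --field-shape 16 --output tomo.h5
tensaxs analyze --input tomo.h5 --output metrics.h5 --vtk glyphs.vtk
```

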