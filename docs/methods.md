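# Methods

`tensaxs` implements small-angle X-ray scattering tensor tomography
(SAXSTT) with reciprocal-space maps (RSMs) represented by local Gaussian
radial basis functions on a hemispherical grid, together with a
sampling-quality framework that predicts where in reciprocal space a given
acquisition geometry will produce missing-wedge artifacts.  This note
records the model, the parameters that matter, the numerical choices, and
what the synthetic test bed does and does not demonstrate.

## Model

Each voxel of the sample carries an RSM `f(q̂)`: the angular distribution
of small-angle scattering at fixed |q|, an even function on the unit
sphere (Friedel symmetry, `f(q̂) = f(−q̂)`).  The RSM is expanded in `N =
2s²` Gaussian kernels whose modes sit on a Kurihara-style latitude-ring
mesh covering the upper hemisphere:

    f(q̂) = Σₙ cₙ · exp(−Δ(q̂, q̂ₙ)² / 2σ²) / Nₙ ,

where `Δ(v, u) = arccos |v·u|` is the Friedel-symmetric great-circle
distance, and `Nₙ` (the row sums of the mode-vs-mode kernel matrix) even
out the slightly irregular mode distribution.  Because the metric itself
identifies antipodes, hemisphere modes represent full-sphere even
functions without duplicated points.

A measurement at sample orientation `(α, β)` (rotation about the main
tomographic axis `ŷ`, tilt about `x̂`; a remounted sample additionally
carries a fixed innermost rotation) probes the great circle orthogonal to
the beam direction, azimuthally binned into detector segments
`[φₘ, φₘ₊₁)`.  Two linear operators define the forward model
`Pᵢ X Gᵢᵀ = Dᵢ` for each projection `i`:

* `Gᵢ` (segments × modes): the kernel of each mode averaged along the
  probed circle over each segment, normalized by `Nₙ` and the segment
  width;
* `Pᵢ`: the John (X-ray) transform — line integrals of every basis
  channel through the voxel grid.

### Sampling quality

An acquisition realizes beam directions on the sphere of projection.  By
the projection-slice theorem the reconstruction at reciprocal direction
`q̂` draws on the great circle of beam directions orthogonal to `q̂`; the
quality factor is the Funk–Radon transform (normalized great-circle mean)
of a binary coverage indicator `ρ` (1 within an angular threshold `δ` of
some measured direction).  It is 1 where the whole orthogonal semicircle
is covered and exactly 0.5 at the worst direction of a single-mount ±45°
tilt series, since such a circle is still half covered by the tilt range.
`δ` defaults to 1.5× the scheme's median nearest-neighbor spacing — a
deliberately *relative* notion of sampling sufficiency; absolute
Nyquist-style thresholds are avoided because smoothness and sparsity
constraints in the solver change the required sampling in ways that a
single number would misrepresent.  A soft (kernel-sum, capped) indicator
is available behind a flag.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `s` | 7 (phantom studies), 9 supported | mesh scale; `N = 2s²` modes, ring spacing `(π/2)/s` |
| `σ` | `0.6·(π/2)/s` | kernel width (rad). 0.5 ring spacings leaves up to 7% RMS error when fitting 15°-wide equatorial rings (worst orientation); 0.6 brings the worst case under 3.5% while the kernel stays well below the inter-mode spacing, i.e. local |
| segments | 16 over `[0, π)` | azimuthal binning (11.25°), matching the basis resolution; 8 segments leave sub-bin reciprocal structure weakly constrained |
| `δ` | 1.5× median NN spacing | coverage threshold of the sampling density |
| `n_quadrature` | 360 | trapezoid points for great-circle means |
| `rel_tol` | 1e-5 | adaptive-Simpson termination for `G` entries (largest element change relative to the largest element) |
| `lmax` | 12 (even degrees only) | spherical-harmonic band limit for analysis |
| iterations / step / momentum | 200 / 1.0 / 0.9 | Nesterov-accelerated preconditioned descent; the preconditioner absorbs the problem scale so step 1 is stable |
| `tv_weight`, `l1_weight` | 0 | optional Huber-smoothed regularization on basis coefficients |
| `ε` (relaxed inverse) | 1e-8 × max entry | hard masking threshold |

## Solver

The objective is `Σᵢ ½⟨Wᵢ ⊙ rᵢ, rᵢ⟩ + λ_TV·HuberTV(X) + λ₁·HuberL1(X)`
with `rᵢ = Pᵢ X Gᵢᵀ − Dᵢ`.  `Wᵢ` is the relaxed elementwise inverse of
`Pᵢ U Gᵢᵀ` (U all ones) and the preconditioner `M` the relaxed inverse of
`Σᵢ Pᵢᵀ V Gᵢ` (V all ones): the multi-channel generalization of SIRT row-
and column-sum normalization.  The weighted quadratic form (W applied
once in the gradient) is chosen precisely so that with one channel and
`G = I` the iteration *is* classical weighted SIRT — a blocking test
asserts per-iteration agreement with an independently written scalar SIRT
to 1e-8.  The relaxed inverse hard-masks entries below `ε` so rays that
miss the volume and voxels never traversed are excluded rather than
amplified; a smooth `1/(a+ε)` variant exists behind a flag.
Initialization is zero, no nonnegativity constraint by default (an
optional clamp exists), and the solver aborts if the loss rises for 10
consecutive iterations.  Both regularizers act coefficient-wise (on the
basis coefficients, not pointwise sphere values).

## Projector

The John transform is voxel-driven with a separable footprint: each
voxel deposits `value × h` through the convolution of the unit pixel box
with the voxel cube's projected edge extents along each raster axis (a
box spline; the construction of distance-driven / separable-footprint
projectors).  Two properties are exact by construction and are the
projector's contract: mass conservation (the footprint is a partition of
unity on the pixel lattice) and adjointness of the back-projector (same
weights).  A plain bilinear splat satisfies both but aliases the
projected voxel lattice near 45° views (up to ~18% ripple); the matched
footprint nulls that alias, leaving ~0.7% worst-case deviation between
projections of a smooth spherically symmetric field at different
orientations.  Rays pass through pixel centers, the volume is centered,
and channel loops are ordered deterministically.

## Spherical-harmonic analysis

Interpolants are projected onto real even-degree spherical harmonics by
quadrature on a Gauss–Legendre × uniform-azimuth grid of size
`2(lmax+1) × 4(lmax+1)` (exact for band-limited integrands; odd degrees
vanish identically because the kernel metric is Friedel symmetric).  The
Funk–Radon transform is diagonal in this basis with multipliers `P_ℓ(0)`
(1, −½, 3/8, …) — the normalized (mean over circle) convention, used
consistently everywhere.  Derived metrics per voxel:

* **mean** — the ℓ=0 term (`a₀₀/√4π`);
* **relative anisotropy** — spherical standard deviation over the mean,
  from the ℓ>0 power;
* **orientation** — minimal eigenvector of the second-moment tensor
  `T = ∫ f q̂ q̂ᵀ dΩ`; flagged invalid when the two smallest eigenvalues
  differ by less than 1e-3 of the spread (isotropic or perfectly crossed
  maps);
* **fiber symmetry factor** — `(F[f](ô) − μ) / (max F[f] − μ)` with `μ`
  the spherical mean: 1 for an ideal equatorial ring about `ô`, 0 for an
  isotropic map (zero-denominator convention).  The ratio form makes it
  scale-free.  This is a documented interpretation: it is built from the
  Funk–Radon transform of the harmonic representation and the rank-2
  orientation, is maximal for ring functions, and quantifies equatorial
  symmetry — the stated properties of the figure of merit — but the
  exact published formula was not recoverable;
* **multi-orientation detection** — local maxima of `F[f]` on a ~4000
  point Fibonacci hemisphere, non-maximum-suppressed within a minimum
  separation (default 20°), kept above a prominence fraction of the
  global maximum excess (default 0.25), and polished by Nelder–Mead on
  the local tangent plane.

## Synthetic test bed

The phantom module generates what the pipeline is tested against: voxel
fields of equatorial-ring RSMs
(`offset + amplitude·exp(−(π/2 − Δ(q̂, ô))²/2w²)`, fitted to the basis by
weighted least squares), the signature of diffuse mineral scattering
around collagen fibrils in bone.  The default phantom is a 16³ sphere
split into two domains with orthogonal orientations (`ẑ` and `x̂`) whose
masks overlap in a two-voxel interface band where coefficients add —
multi-orientation voxels.  Ring width is 15°, isotropic offset 10% of the
amplitude.  The reference acquisition is two mounts of 7 tilts
(±45°) × 16 rotations (half turn), the second mount rotated 90° about
the beam axis, with 16 detector segments — 112 views per mount, the
desk-scale analog of the dual-mount scheme with 224 views per mount used
on real bone.  These sizes keep the two 200-iteration reconstructions in
the test suite to a few minutes each.

Noise, when enabled, is Poisson on photon counts *before* transmission
normalization: scattered counts `Poisson(D·I_T·scale)` divided by
transmitted counts `Poisson(I_T·scale)`, so low-transmission pixels show
the amplified noise seen behind thick sample regions.  The companion
absorption field has a core transmitting ~4% (against 20–50% in the
periphery).  Real-data effects that are *not* emulated: glue
contamination at particular q-ranges, detector point spread, beam
hardening, alignment errors between mounts (synthetic geometry is exact,
so no registration step exists).  Consequently the phantom tests
demonstrate correctness and conditioning of the method — not robustness
to the full instrumental error budget of a beamline experiment.

Reference results under these conditions (recomputed by the test suite):
complete dual-mount data reconstruct the phantom coefficients to ~3–5%
RMSE over sample voxels and orientations to a fraction of a degree in
strongly anisotropic voxels; the mount-1-only reconstruction degrades to
~13% with per-basis-function errors that rank-correlate strongly with
the predicted sampling deficit `1 − F[ρ]`, and its x/z-aligned RSM
components acquire directional Fourier smearing in projections along the
unmeasured axis while the y-aligned component does not.

## Numerical choices and degenerate inputs

* `G` integrals: composite Simpson, uniformly refined (doubling) until
  the largest element change is below 1e-5 of the largest element;
  kernels are smooth so this converges in a few refinements.
* Coverage queries use a KD-tree on the antipodally doubled direction
  set; chord distances are converted to angles, with a 1e-12 slack so
  boundary thresholds (e.g. `δ = π/2`) are not lost to rounding.
* Zero or negative transmitted intensities are masked (NaN) with a
  logged warning, not raised — they occur legitimately in noisy
  simulations.
* Orientation of an isotropic voxel: validity flag false, direction
  still returned (the eigenvector is arbitrary).
* Ring widths well below `σ` are not representable; the fit proceeds and
  the residual is logged.
* Angles are radians in memory and degrees in all files and CLI
  boundaries; bulk arrays are float32 on disk, float64 in memory.

## Known limitations

* The mesh layout (staggered latitude rings with `4i − 2` points) meets
  the published constraints (hemispheric, `N = 2s²`, quasi-uniform:
  nearest-neighbor spacing ratio < 1.25 for `s ≤ 20`) but is a
  reimplementation, not a byte-level clone of any reference mesh.
* The projector trades sub-pixel resolution (pixel-box smoothing) for
  exact mass/adjointness and low angular ripple.
* Quality factors are relative: they rank directions within a scheme and
  saturate at the documented bounds, but do not predict absolute
  reconstruction error without calibration.
* The solver uses a fixed step and momentum; no line search.  With the
  provided preconditioner this is stable for step sizes near 1, and the
  divergence guard catches misconfiguration.
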