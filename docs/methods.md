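# Methods

## Forward model

The model is `g_m = T H f + b` on a grid of `nx × ny` lateral pixels and
`nz` axial slices with step `dz` (default 20 slices of 20 nm spanning
0–400 nm; slice centers at `z_j = z0 + (j−1)·dz`, z = 0 at the
glass/sample interface, z increasing away from the coverslip).

**Excitation.** `p(α) = (4π/λ)·sqrt(n1² sin²α − n2²)` — the standard
evanescent-wave result.  `I0(α)` defaults to 1 for all angles (`unit`
mode): the reconstruction recovers `f` in arbitrary units, so any
angle-independent scale is absorbed; an s-polarized Fresnel factor
`4cos²α/(1 − (n2/n1)²)` is available as `fresnel_s` for instruments whose
per-angle intensity is not equalized.  Default indices n1 = 1.515
(glass/immersion oil), n2 = 1.33 (aqueous medium), λ = 491 nm, NA = 1.49,
107 nm lateral pixels — conventional values, all overridable.

**Default angle set.** Ten angles evenly spaced from 0.5° above the
critical angle (61.39° for 1.515/1.33) to 0.5° below the aperture limit
asin(NA/n1).  The small lower margin matters: it is the near-critical
angles, with penetration depths up to ~300 nm, that carry depth
information beyond ~200 nm.  A Fisher-information (Cramér–Rao) analysis
of the slab fit shows that starting 1.5° above critical (penetration
≤ 175 nm) leaves essentially no thickness sensitivity at 400 nm at any
realistic photon budget.

**T.** Depth and angle decouple from the lateral coordinates, so T is a
dense (M, nz) matrix shared by all pixels.  The within-slice integral of
the exponential uses the midpoint rule (`value at slice center × dz`);
the relative error is `(p·dz)²/24 < 0.5%` for 20 nm slices, and an exact
per-slab analytic integral is available as `quadrature="exact"`.

**H.** One in-focus 2D kernel convolves every slice: the evanescent layer
is thin enough that the PSF is effectively constant over it.  Boundary
handling is periodic convolution on a grid zero-padded by the kernel
half-width, cropped afterward; since the wrap only touches the pad this
equals zero-boundary linear convolution while keeping the operator
diagonal in the padded Fourier basis.  The default kernel is an isotropic
Gaussian with σ = 0.21·λ/NA (the standard in-focus approximation,
≈ 0.65 px at the default optics); an Airy pattern and user-supplied
kernels are supported.  The PSF is a model choice, not a contribution of
the method, and should be overridden when a measured kernel exists.

**Background.** Spatially constant, one scalar per angle (laser power and
interface intensity vary with angle), estimated as the mean over a
structure-free region and subtracted from the data before solving.
Negative residual pixels are kept unclipped to avoid bias.

## Regularization

Both penalties act on periodic finite differences with the axial
differences divided by the voxel aspect ratio `dz / pixel size`, making
the penalty isotropic in physical units (with 20 nm slices and ~100 nm
pixels, unscaled axial differences would be over-penalized five-fold).

* **TV**: μ · Σ_voxels ‖∇f‖₂ (isotropic, one ℓ2 group over the three
  first differences).  Prox: per-voxel group soft-thresholding.
* **Hessian–Schatten (order 1)**: μ · Σ_voxels ‖Hess f‖_* , the nuclear
  norm of the symmetric 3×3 second-difference matrix.  Prox: per-voxel
  eigendecomposition and eigenvalue soft-thresholding.  The six unique
  second differences are stored once; off-diagonal components carry
  weight 2 in every inner product (Frobenius metric of the symmetric
  matrix), which is exactly the metric in which the eigenvalue shrinkage
  is the true prox.  The solver's normal equations use the same weights.

μ has no default: it balances fidelity against regularity and depends on
noise level and content.  With max-normalized data, 1e−4 to 1e−1 is the
useful range (the tests use ~5e−3 for TV at moderate noise).

## ADMM solver

Splitting `u1 = Hf`, `u2 = Lf`, `u3 = f` with scaled duals and penalties
ρ1, ρ2, ρ3 (defaults all 1; the background-subtracted data are normalized
to unit maximum so unit penalties are serviceable).  Per iteration:

1. **u1** — per-pixel axial solve `(TᵀT + ρ1 I) u1 = Tᵀg + ρ1(Hf + d1)`,
   one (nz, nz) Cholesky factorization computed once and shared by all
   pixels and iterations; pad pixels carry no data and copy `Hf + d1`.
2. **u2** — exact prox of (μ/ρ2)·R at `Lf + d2`.
3. **u3** — projection `max(0, f + d3)`.
4. **f** — Fourier-diagonal solve of
   `(ρ1 HᵀH + ρ2 LᵀL + ρ3 I) f = ρ1 Hᵀ(u1−d1) + ρ2 Lᵀ(u2−d2) + ρ3(u3−d3)`;
   ρ3 > 0 keeps the denominator strictly positive.
5. Dual ascent on d1, d2, d3.

The update order (u-blocks, f, duals) is one valid ordering of the
splitting; on small TV instances the converged objective matches an
independent long-run primal-dual (Chambolle–Pock) solver to well below
0.1%, and the μ→0 limit matches nonnegative least squares.  The returned
estimate is the u3 iterate — exactly nonnegative by construction, and
within the primal feasibility tolerance of f.  Default 50 iterations, the
budget at which reconstructions are run in practice; an optional relative
primal-residual tolerance enables early stopping.  The solver contains no
randomness: identical inputs give bit-identical results.

With `deconvolve=False` (or a delta kernel) H is the identity and the
algorithm reduces to pure depth reconstruction; the two paths produce
bit-identical iterates for a delta PSF.

## Calibration slab fitting

Each pixel's angle curve is fitted with a uniform slab [z0, z0 + t] of
density A:

`s_m = A·I0(α_m)/p(α_m) · e^{−z0·p(α_m)} · (1 − e^{−t·p(α_m)})`,

the exact integral of the excitation over the slab (computed with expm1;
the p → 0 widefield limit A·I0·t is continuous).  For the lens phantom
z0 is fixed at 0 (the liquid wets the coverslip).  The fit is bounded
trust-region least squares (t ∈ [0, 1000] nm, A ≥ 0, z0 ∈ [0, 500] nm
when free) from three deterministic thickness starts {50, 150, 300} nm,
keeping the lowest residual — reproducible without randomness.  The fit
uses the pure T model (no lateral PSF): the phantom varies laterally over
micrometres, far above the diffraction scale.  All-zero curves and fits
that hit the thickness bound are flagged.

The lens radius is recovered by least squares of `t = r²/(2R̂) + c` over
pixels with fitted thickness in a 100–400 nm window (the range over which
the profile is expected to track the gap linearly); flat maps are flagged
as unbounded radius.

## Synthetic phantoms and noise

The generator emulates: the lens-gap phantom (uniform density below
`t(r) = R − sqrt(R² − r²)`, partial-volume weighting at the gap surface),
laterally uniform or disjoint fluorescent sheets with linear axial
interpolation, and piecewise-linear filament tubes with Gaussian lateral
profile.  Acquisition noise is `none`, additive Gaussian, or
Poisson–Gaussian (EMCCD-like: Poisson shot noise at a photon scale plus
Gaussian read noise), seeded and bit-reproducible.
`NoiseSpec.for_peak_snr(peak, 30)` sets the photon scale so the brightest
pixel has shot-noise SNR 30, with 1% read noise.

The default lens-phantom grid is a 600 × 100 µm strip through the contact
point at 6.25 µm lateral sampling and 32 slices of 20 nm.  With
R = 288 mm the gap reaches ~625 nm at the strip end, covering the
100–400 nm validation window with margin, and the strip width gives a few
dozen pixels per 20 nm thickness bin.  (A strip only 200 µm long would
cap the gap at ~17 nm — too shallow to exercise the model at all.)  The
coarse pixels are legitimate because the gap varies laterally on the
millimetre scale.

What the phantoms do **not** emulate: lens bevel effects at the phantom
rim, interface scattering, depth-varying PSFs, spatially varying
background, fixed-pattern sensor noise, or refractive-index heterogeneity
inside cells.  Passing the phantom suite therefore validates the solver
and estimators against their own forward physics (plus noise), not
against every real-instrument imperfection.

## Validation statistics

The **radius recovery** check simulates the phantom noiselessly, fits
thickness per pixel and the radius from the 100–400 nm window; agreement
within a few tenths of a percent of the nominal 288 mm is typical, the
residual coming from the axial voxelization.

The **linear tracking range** check adds Poisson–Gaussian noise at peak
SNR ≈ 30, bins pixels by true gap thickness in 20 nm steps from 100 nm,
and finds the largest thickness up to which the *median* fitted thickness
per bin deviates from the bin's true thickness by less than one axial
step.  The statistic deliberately aggregates within bins — it measures
whether the estimated thickness **profile** tracks the true slope, which
is what a thickness-versus-radius calibration curve shows.  Per-pixel
errors are governed by the Cramér–Rao bound, which at t = 400 nm, 10
angles and peak SNR 30 is ≥ ~41 nm for any angle placement; no estimator
can beat that pixelwise, while the bin-median profile remains accurate
well past 400 nm (typically to ~450–520 nm depending on the noise seed).

## Depth statistics and rendering

Mean depth per pixel: `D_i = round(Σ_j j·R_ij / Σ_j R_ij)·dz` with
1-based slice index and rounding half away from zero (a .5 centroid goes
to the deeper slice; banker's rounding would change bin assignment at
exact midpoints).  Zero-mass pixels are masked.  The two-channel relative
depth histogram accumulates `sqrt(mass1 · mass2)` at bin (D¹_i, D²_i)
over pixels valid in both channels — pixels empty in either channel are
excluded — and is normalized so its maximum equals exactly 1.  Renders
tint each slice with an entry of a built-in approximately isoluminant
blue→orange colormap (user-replaceable via CSV) and average along z.
Channel drift is measured by Fourier cross-correlation with 1/100-pixel
upsampled peak refinement.

## Numerical choices and limitations

* Periodic differences everywhere, consistent with the FFT f-update;
  operator identities are exact, not approximate.
* The u1 Cholesky solve is numerically safe for any ρ1 > 0 because
  TᵀT ⪰ 0.
* Degenerate inputs: empty background masks, flat drift images, all-zero
  slab curves, sub-critical angles, and non-normalizable PSF kernels all
  raise named errors; the solver raises a divergence error naming the
  iteration if iterates become non-finite.
* GPU execution and depth-varying PSFs are out of scope; the solver is
  single-threaded numpy/scipy.
* Reconstruction quality beyond ~400 nm degrades intrinsically — the
  deepest evanescent excitation decays with 1/e depth ≈ 300 nm, so the
  data carry little signal from deeper structures.
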