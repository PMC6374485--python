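# matirf

Multi-angle total internal reflection fluorescence (MA-TIRF) microscopy
turns a stack of 2D TIRF images, acquired at several supercritical
incident angles, into a nanometric-resolution axial reconstruction of the
fluorophore density near the coverslip.  `matirf` is a complete numerical
toolkit for this modality: the physical forward model, a fast ADMM solver
for joint deconvolution and depth reconstruction, the calibration-phantom
analysis used to validate axial accuracy, and the depth statistics and
renderings used to interpret reconstructions.  It is aimed at microscopists
running MA-TIRF instruments and at method developers who need a tested
reference implementation.

## Model

Beyond the critical angle, excitation is evanescent:
`I(z, α) = I0(α) · exp(−z·p(α))` with inverse penetration depth
`p(α) = (4π/λ)·sqrt(n1²·sin²α − n2²)`.  A stack of acquisitions at angles
`α_1 < … < α_M` follows the discrete model

```
g_m = T H f + b,        m = 1 … M
```

where `f ≥ 0` is the unknown density on an (nx, ny, nz) grid, `H` blurs
each z-slice with the in-focus 2D PSF, `T` weights depth by the per-angle
exponential excitation (a dense M × nz matrix shared by all pixels), and
`b` is a constant per-angle background.  The reconstruction solves

```
f̂ = argmin_{f ≥ 0}  ½‖T H f − g‖² + μ R(L f)
```

with `R(L·)` either isotropic total variation (gradient operator, ℓ2,1
norm) or the Hessian–Schatten penalty (second differences, per-voxel
nuclear norm).  An ADMM splitting `u1 = Hf`, `u2 = Lf`, `u3 = f` makes
every subproblem exact and direct — one shared Cholesky factorization for
the data step, closed-form proximal operators, a pointwise projection,
and one FFT-diagonal solve — so there are no inner iterative loops.

The calibration phantom is a uniform fluorescent liquid filling the gap
between the coverslip and a divergent spherical lens (radius of curvature
R = 288 mm): the gap `t(r) = R − sqrt(R² − r²) ≈ r²/2R` sweeps the whole
0–600 nm range within a fraction of a millimetre.  Fitting each pixel's
multi-angle curve with a uniform-slab ("top-hat") model yields a thickness
map whose quadratic radial profile returns the lens radius — an absolute,
end-to-end test of axial accuracy.

## Worked example

Simulate the lens calibration phantom, fit per-pixel slab thickness, and
recover the lens radius:

```python
import numpy as np
from matirf import (OpticalConfig, default_angle_set, build_excitation,
                    lens_strip_grid, LensPhantomSpec, lens_phantom_volume,
                    make_psf, BackgroundModel, NoiseSpec,
                    simulate_acquisition, fit_slab_per_pixel, fit_lens_radius)

config = OpticalConfig()                       # 491 nm, n1=1.515, n2=1.33, NA 1.49
excitation = build_excitation(config, default_angle_set(config, 10))
grid = lens_strip_grid()                       # 600 x 100 um strip, 32 slices of 20 nm
volume = lens_phantom_volume(LensPhantomSpec(), grid)
stack = simulate_acquisition(volume, excitation, make_psf(config, "delta"),
                             BackgroundModel.zero(10), NoiseSpec(model="none"))
fit = fit_slab_per_pixel(stack.images, excitation, fix_z0=True)
radius = fit_lens_radius(fit.thickness_map, grid.pixel_size_nm)
print(f"recovered radius of curvature: {radius:.1f} mm")
```

This prints

```
recovered radius of curvature: 286.9 mm
```

within 0.4% of the 288 mm ground truth: the forward model, the slab
integral and the profile fit agree end to end.  The residual deviation
comes from the 20 nm axial voxelization of the phantom.

A shell workflow is available through the `matirf` command
(`simulate`, `reconstruct`, `fit-thickness`, `fit-lens`, `depthmap`,
`hist2d`, `render`, `drift`); every command takes a YAML config and
reproduces its outputs bit-identically for fixed inputs and seeds.

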