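"""Synthetic ground-truth volumes and simulated MA-TIRF acquisitions.

Every phantom produces a :class:`FluorophoreVolume` on a caller-supplied
grid; :func:`simulate_acquisition` pushes a volume through the forward
model and adds seeded sensor noise.  The default noise model is
Poisson–Gaussian (shot noise at a chosen photon scale plus Gaussian read
noise), the behaviour of an EMCCD camera.

The lens phantom reproduces the calibration sample — a uniform fluorescent
liquid in the gap between the coverslip and a divergent spherical lens
(R = 288 mm) — on a narrow strip through the contact point.  Because the
gap grows like r^2/2R, a strip a few hundred micrometres long covers the
whole 0–600 nm depth range at a coarse lateral sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_model import (
    AcquisitionStack,
    BackgroundModel,
    FluorophoreVolume,
    GridSpec,
    PSFModel,
    forward,
)
from .optics import ConfigurationError, ExcitationModel
from .thickness_fit import LensPhantomSpec, lens_gap_profile

__all__ = [
    "NoiseSpec",
    "lens_phantom_volume",
    "sheet_phantom",
    "filament_phantom",
    "simulate_acquisition",
    "lens_strip_grid",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Sensor noise: none, additive Gaussian, or Poisson–Gaussian.

    ``photon_scale`` converts arbitrary intensity units to expected photon
    counts for the Poisson branch (SNR at a pixel of clean intensity I is
    sqrt(photon_scale * I)); ``gaussian_sigma`` is the read-noise standard
    deviation in intensity units.  A fixed seed makes output bit-reproducible.
    """

    model: str = "poisson_gaussian"
    gaussian_sigma: float = 0.0
    photon_scale: float = 900.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("none", "gaussian", "poisson_gaussian"):
            raise ConfigurationError(f"unknown noise model {self.model!r}")
        if self.gaussian_sigma < 0:
            raise ConfigurationError("gaussian_sigma must be >= 0")
        if self.photon_scale <= 0:
            raise ConfigurationError("photon_scale must be > 0")

    @classmethod
    def for_peak_snr(cls, peak_intensity: float, peak_snr: float = 30.0,
                     seed: int = 0) -> "NoiseSpec":
        """Poisson–Gaussian noise whose shot-noise SNR at the brightest
        pixel equals ``peak_snr``, with 1% read noise."""
        return cls(model="poisson_gaussian",
                   gaussian_sigma=0.01 * peak_intensity,
                   photon_scale=peak_snr**2 / peak_intensity,
                   seed=seed)


def lens_strip_grid(strip_length_um: float = 600.0,
                    strip_width_um: float = 100.0,
                    pixel_size_um: float = 6.25,
                    nz: int = 32, dz_nm: float = 20.0) -> GridSpec:
    """Coarse strip grid through the lens contact point.

    The gap varies slowly laterally, so micrometre-scale pixels suffice; a
    600 um strip reaches gaps of ~625 nm with R = 288 mm, covering the
    100–400 nm validation window with margin, and the 100 um width gives
    a few dozen pixels per 20 nm thickness bin.  The first slice center
    sits at dz/2 so slice j spans [(j-1) dz, j dz].
    """
    nx = int(round(strip_length_um / pixel_size_um))
    ny = int(round(strip_width_um / pixel_size_um))
    return GridSpec(nx=nx, ny=max(ny, 1), nz=nz, dz_nm=dz_nm,
                    pixel_size_nm=pixel_size_um * 1e3, z0_nm=dz_nm / 2.0)


def lens_phantom_volume(spec: LensPhantomSpec, grid: GridSpec) -> FluorophoreVolume:
    """Voxelized lens-gap phantom.

    A voxel holds ``fluor_density`` when it lies fully below the local gap
    thickness t(r); the slice straddling the gap surface gets the partial
    volume fraction.  Pixel (iy, ix) sits at lateral position
    (ix, iy) * pixel size in the frame where ``spec.contact_mm`` locates
    the contact point (default: the grid origin).
    """
    px_mm = grid.pixel_size_nm * 1e-6
    x_mm = px_mm * np.arange(grid.nx)
    y_mm = px_mm * np.arange(grid.ny)
    xx, yy = np.meshgrid(x_mm, y_mm)
    r = np.hypot(xx - spec.contact_mm[0], yy - spec.contact_mm[1])
    t = lens_gap_profile(spec, r)  # (ny, nx) nm
    z_lo = np.maximum(grid.z_centers_nm - grid.dz_nm / 2.0, 0.0)
    z_hi = grid.z_centers_nm + grid.dz_nm / 2.0
    # occupied fraction of each slab below the gap surface
    frac = (np.minimum(t[None], z_hi[:, None, None]) - z_lo[:, None, None])
    frac = np.clip(frac / grid.dz_nm, 0.0, 1.0)
    return FluorophoreVolume(grid=grid, values=spec.fluor_density * frac)


def sheet_phantom(depths_nm, masses, grid: GridSpec,
                  laterally_disjoint: bool = False) -> FluorophoreVolume:
    """Laterally uniform fluorescent sheets at given depths.

    Each sheet deposits ``mass`` per pixel column, split linearly between
    the two slices bracketing its depth (a depth on a slice center is a
    single-slice sheet).  With ``laterally_disjoint`` the x-range is split
    into one block per sheet so the sheets do not overlap laterally.
    """
    depths = np.atleast_1d(np.asarray(depths_nm, dtype=float))
    masses = np.atleast_1d(np.asarray(masses, dtype=float))
    if depths.shape != masses.shape:
        raise ConfigurationError("depths and masses must have equal length")
    z = grid.z_centers_nm
    vol = np.zeros(grid.shape)
    n_sheets = depths.size
    for k, (d, m) in enumerate(zip(depths, masses)):
        if d < z[0] or d > z[-1]:
            raise ConfigurationError(
                f"depth {d} nm outside grid range [{z[0]}, {z[-1]}] nm"
            )
        jf = (d - grid.z0_nm) / grid.dz_nm
        j0 = int(np.floor(jf))
        w1 = jf - j0
        if laterally_disjoint:
            x0 = k * grid.nx // n_sheets
            x1 = (k + 1) * grid.nx // n_sheets
            xs = slice(x0, x1)
        else:
            xs = slice(None)
        vol[j0, :, xs] += m * (1.0 - w1)
        if w1 > 0:
            vol[j0 + 1, :, xs] += m * w1
    return FluorophoreVolume(grid=grid, values=vol)


def filament_phantom(control_points_3d, intensity: float, grid: GridSpec,
                     lateral_width_px: float = 1.0) -> FluorophoreVolume:
    """Piecewise-linear fluorescent tube (an actin-fiber-like test scene).

    Control points are (x_px, y_px, z_nm).  The polyline is sampled densely;
    each sample splats a lateral Gaussian of the given width and is split
    linearly between the two bracketing z-slices.  Deterministic.
    """
    pts = np.asarray(control_points_3d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ConfigurationError("control points must be (n, 3): x, y, z_nm")
    if np.any(pts[:, 2] < grid.z_centers_nm[0]) or np.any(pts[:, 2] > grid.z_centers_nm[-1]):
        raise ConfigurationError("control point depth outside the grid")
    vol = np.zeros(grid.shape)
    if intensity == 0:
        return FluorophoreVolume(grid=grid, values=vol)
    half = max(1, int(np.ceil(3 * lateral_width_px)))
    yg, xg = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    for a, b in zip(pts[:-1], pts[1:]):
        seg_len = np.hypot(b[0] - a[0], b[1] - a[1])
        n_samp = max(2, int(np.ceil(seg_len / 0.25)))
        for s in np.linspace(0.0, 1.0, n_samp, endpoint=False):
            x, y, zn = a + s * (b - a)
            jf = (zn - grid.z0_nm) / grid.dz_nm
            j0 = int(np.clip(np.floor(jf), 0, grid.nz - 1))
            w1 = np.clip(jf - j0, 0.0, 1.0)
            cy, cx = int(round(y)), int(round(x))
            spot = np.exp(-((yg + cy - y) ** 2 + (xg + cx - x) ** 2)
                          / (2 * lateral_width_px**2)) * (intensity / n_samp)
            ys = slice(max(cy - half, 0), min(cy + half + 1, grid.ny))
            xs = slice(max(cx - half, 0), min(cx + half + 1, grid.nx))
            ky = slice(ys.start - (cy - half), ys.stop - (cy - half))
            kx = slice(xs.start - (cx - half), xs.stop - (cx - half))
            vol[j0, ys, xs] += (1 - w1) * spot[ky, kx]
            if w1 > 0 and j0 + 1 < grid.nz:
                vol[j0 + 1, ys, xs] += w1 * spot[ky, kx]
    return FluorophoreVolume(grid=grid, values=vol)


def simulate_acquisition(volume: FluorophoreVolume, excitation: ExcitationModel,
                         psf: PSFModel, background: BackgroundModel,
                         noise: NoiseSpec,
                         tz: np.ndarray | None = None) -> AcquisitionStack:
    """Simulate an MA-TIRF stack: forward model plus seeded sensor noise.

    ``noise='none'`` reproduces the clean forward output exactly; the
    Gaussian branch adds N(0, sigma^2); the Poisson–Gaussian branch draws
    Poisson(photon_scale * clean) / photon_scale then adds the Gaussian
    term.  Output is clamped at zero.
    """
    from .forward_model import build_tirf_matrix  # local to avoid cycle noise

    if tz is None:
        tz = build_tirf_matrix(excitation, volume.grid)
    clean = forward(volume, tz, psf, background)
    if noise.model == "none":
        noisy = clean
    else:
        rng = np.random.default_rng(noise.seed)
        if noise.model == "gaussian":
            noisy = clean + rng.normal(0.0, noise.gaussian_sigma, clean.shape)
        else:
            counts = rng.poisson(np.maximum(noise.photon_scale * clean, 0.0))
            noisy = counts / noise.photon_scale
            if noise.gaussian_sigma > 0:
                noisy = noisy + rng.normal(0.0, noise.gaussian_sigma, clean.shape)
        noisy = np.maximum(noisy, 0.0)
    return AcquisitionStack(images=noisy, angle_set=excitation.angle_set,
                            pixel_size_nm=volume.grid.pixel_size_nm)
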