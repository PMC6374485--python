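"""Discrete MA-TIRF image formation.

A stack of TIRF acquisitions at M supercritical angles is modelled as

    g_m = T H f + b_m,

where ``f`` is the fluorophore density on an (nz, ny, nx) grid, ``H``
convolves each z-slice with the same in-focus 2D PSF (the evanescent layer
is thin enough for the PSF to be treated as axially constant), ``T``
integrates each pixel's axial profile against the per-angle exponential
excitation, and ``b_m`` is a spatially constant per-angle background.

Because the excitation depends only on depth and angle, T factorizes into a
dense (M, nz) matrix shared by all pixels; that matrix is what
:func:`build_tirf_matrix` produces.

Array conventions: volumes are ``(nz, ny, nx)`` with z ascending away from
the coverslip (z = 0 at the glass/sample interface); stacks are
``(M, ny, nx)`` with pages in ascending-angle order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, special

from .optics import AngleSet, ConfigurationError, ExcitationModel, OpticalConfig

__all__ = [
    "DimensionError",
    "GridSpec",
    "FluorophoreVolume",
    "AcquisitionStack",
    "PSFModel",
    "BackgroundModel",
    "build_tirf_matrix",
    "apply_T",
    "apply_T_adjoint",
    "apply_H",
    "apply_H_adjoint",
    "forward",
    "estimate_background",
    "make_psf",
]


class DimensionError(ValueError):
    """Raised when operator and operand grids are incompatible."""


@dataclass(frozen=True)
class GridSpec:
    """Reconstruction grid: lateral sampling and axial slicing.

    Slice centers sit at ``z_j = z0_nm + (j - 1) * dz_nm`` for j = 1..nz.
    The default axial grid (20 slices of 20 nm) spans the 0–400 nm range a
    MA-TIRF stack can resolve.
    """

    nx: int
    ny: int
    nz: int = 20
    dz_nm: float = 20.0
    pixel_size_nm: float = 107.0
    z0_nm: float = 0.0

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ConfigurationError("grid sizes must be >= 1")
        if self.dz_nm <= 0 or self.pixel_size_nm <= 0:
            raise ConfigurationError("grid steps must be > 0")
        if self.z0_nm < 0:
            raise ConfigurationError("z0_nm must be >= 0 (coverslip at z=0)")

    @property
    def z_centers_nm(self) -> np.ndarray:
        return self.z0_nm + self.dz_nm * np.arange(self.nz, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nz, self.ny, self.nx)

    @property
    def voxel_aspect(self) -> float:
        """Axial-to-lateral step ratio dz / pixel size."""
        return self.dz_nm / self.pixel_size_nm


@dataclass
class FluorophoreVolume:
    """Nonnegative fluorophore density on a grid (arbitrary units)."""

    grid: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise DimensionError(
                f"volume shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if np.any(self.values < 0):
            raise ConfigurationError("fluorophore density must be nonnegative")

    def total_mass(self) -> float:
        return float(self.values.sum())


@dataclass
class AcquisitionStack:
    """M co-registered TIRF images with their incident angles."""

    images: np.ndarray            # (M, ny, nx)
    angle_set: AngleSet
    pixel_size_nm: float = 107.0
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise DimensionError("stack images must be (M, ny, nx)")
        if self.images.shape[0] != len(self.angle_set):
            raise DimensionError(
                f"{self.images.shape[0]} pages for {len(self.angle_set)} angles"
            )
        if not np.all(np.isfinite(self.images)):
            raise ConfigurationError("stack intensities must be finite")

    @property
    def n_angles(self) -> int:
        return self.images.shape[0]


@dataclass
class PSFModel:
    """Single in-focus 2D blur kernel applied to every z-slice.

    The kernel is sum-normalized and centered (centroid within half a pixel
    of the central pixel); ``focal_plane_z_nm`` is metadata only.
    """

    kernel: np.ndarray
    provenance: str = "user_supplied"
    focal_plane_z_nm: float = 0.0

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 2 or k.shape[0] % 2 == 0 or k.shape[1] % 2 == 0:
            raise ConfigurationError("PSF kernel must be 2D with odd sizes")
        if np.any(k < 0):
            raise ConfigurationError("PSF kernel must be nonnegative")
        s = k.sum()
        if s <= 0:
            raise ConfigurationError("PSF kernel is not normalizable (sum <= 0)")
        k = k / s
        iy, ix = np.indices(k.shape)
        cy = float((iy * k).sum())
        cx = float((ix * k).sum())
        if abs(cy - (k.shape[0] - 1) / 2) > 0.5 or abs(cx - (k.shape[1] - 1) / 2) > 0.5:
            raise ConfigurationError("PSF kernel centroid is off-center")
        self.kernel = k

    @property
    def is_delta(self) -> bool:
        return self.kernel.shape == (1, 1)

    @property
    def half_width(self) -> tuple[int, int]:
        return (self.kernel.shape[0] // 2, self.kernel.shape[1] // 2)


@dataclass
class BackgroundModel:
    """Spatially constant background, one level per angle (a.u.)."""

    level_per_angle: np.ndarray

    def __post_init__(self) -> None:
        lv = np.atleast_1d(np.asarray(self.level_per_angle, dtype=float))
        if np.any(lv < 0):
            raise ConfigurationError("background levels must be >= 0")
        self.level_per_angle = lv

    @classmethod
    def zero(cls, m: int) -> "BackgroundModel":
        return cls(np.zeros(m))


def build_tirf_matrix(excitation: ExcitationModel, grid: GridSpec,
                      quadrature: str = "midpoint") -> np.ndarray:
    """Depth-weighting matrix Tz of shape (M, nz).

    Tz[m, j] approximates the within-slice integral of the excitation
    I0(alpha_m) * exp(-z * p(alpha_m)).  With ``midpoint`` quadrature each
    entry is the slice-center value times dz; ``exact`` integrates the
    exponential analytically over each slab (difference negligible when
    dz * p << 1, which holds for 20 nm slices).
    """
    z = grid.z_centers_nm
    p = excitation.p[:, None]
    i0 = excitation.i0[:, None]
    if quadrature == "midpoint":
        tz = i0 * np.exp(-z[None, :] * p) * grid.dz_nm
    elif quadrature == "exact":
        z_lo = np.maximum(z - grid.dz_nm / 2.0, 0.0)
        z_hi = z + grid.dz_nm / 2.0
        tz = i0 * (np.exp(-z_lo[None, :] * p) - np.exp(-z_hi[None, :] * p)) / p
    else:
        raise ConfigurationError(f"unknown quadrature {quadrature!r}")
    return tz


def apply_T(tz: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Depth-weighted axial projection: out[m] = sum_j Tz[m, j] * f[j]."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 3 or values.shape[0] != tz.shape[1]:
        raise DimensionError(
            f"volume has {values.shape[0] if values.ndim == 3 else '?'} slices, "
            f"Tz expects {tz.shape[1]}"
        )
    return np.einsum("mj,jyx->myx", tz, values)


def apply_T_adjoint(tz: np.ndarray, images: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`apply_T`: out[j] = sum_m Tz[m, j] * g[m]."""
    images = np.asarray(images, dtype=float)
    if images.ndim != 3 or images.shape[0] != tz.shape[0]:
        raise DimensionError(
            f"stack has {images.shape[0] if images.ndim == 3 else '?'} pages, "
            f"Tz expects {tz.shape[0]}"
        )
    return np.einsum("mj,myx->jyx", tz, images)


def _check_kernel_fits(kernel: np.ndarray, shape: tuple[int, ...]) -> None:
    ky, kx = kernel.shape
    ny, nx = shape[-2:]
    # padded grid has ny + 2*(ky//2) rows; the kernel always fits there
    # unless it exceeds the padded extent
    if ky > ny + 2 * (ky // 2) or kx > nx + 2 * (kx // 2):
        raise DimensionError("PSF kernel larger than the padded lateral grid")


def apply_H(values: np.ndarray, psf: PSFModel) -> np.ndarray:
    """Slice-wise 2D blur.

    Each z-slice is convolved with the PSF kernel on a grid zero-padded by
    the kernel half-width with periodic wrap, then cropped back — i.e. the
    wrap only ever touches the zero pad, so no signal wraps around.
    """
    values = np.asarray(values, dtype=float)
    _check_kernel_fits(psf.kernel, values.shape)
    if psf.is_delta:
        return values.copy()
    single = values.ndim == 2
    if single:
        values = values[None]
    out = signal.fftconvolve(values, psf.kernel[None], mode="same", axes=(1, 2))
    return out[0] if single else out


def apply_H_adjoint(values: np.ndarray, psf: PSFModel) -> np.ndarray:
    """Adjoint of :func:`apply_H`: slice-wise correlation with the kernel."""
    values = np.asarray(values, dtype=float)
    _check_kernel_fits(psf.kernel, values.shape)
    if psf.is_delta:
        return values.copy()
    single = values.ndim == 2
    if single:
        values = values[None]
    flipped = psf.kernel[::-1, ::-1]
    out = signal.fftconvolve(values, flipped[None], mode="same", axes=(1, 2))
    return out[0] if single else out


def forward(volume: FluorophoreVolume | np.ndarray, tz: np.ndarray,
            psf: PSFModel, background: BackgroundModel) -> np.ndarray:
    """Full image formation: T H f + b, returned as an (M, ny, nx) array."""
    values = volume.values if isinstance(volume, FluorophoreVolume) else np.asarray(volume, float)
    blurred = apply_H(values, psf)
    imgs = apply_T(tz, blurred)
    b = background.level_per_angle
    if b.shape[0] != imgs.shape[0]:
        raise DimensionError(
            f"{b.shape[0]} background levels for {imgs.shape[0]} angles"
        )
    return imgs + b[:, None, None]


def estimate_background(stack: AcquisitionStack,
                        roi_mask: np.ndarray) -> BackgroundModel:
    """Per-angle background from a structure-free region.

    The level for angle m is the mean of image m over ``roi_mask`` — the
    region must not contain any fluorescent structures.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != stack.images.shape[1:]:
        raise DimensionError(
            f"mask shape {mask.shape} != image shape {stack.images.shape[1:]}"
        )
    if not mask.any():
        raise ConfigurationError("background ROI mask is empty")
    levels = stack.images[:, mask].mean(axis=1)
    return BackgroundModel(levels)


def make_psf(config: OpticalConfig, provenance: str = "gaussian",
             size: int | None = None,
             kernel: np.ndarray | None = None) -> PSFModel:
    """Construct the in-focus 2D PSF.

    ``gaussian``: isotropic Gaussian with sigma = 0.21 * lambda / NA (the
    standard in-focus widefield approximation), expressed in pixels through
    the lateral pixel size.  ``airy``: normalized (2 J1(v)/v)^2 pattern with
    v = (2 pi / lambda) * NA * r.  ``user_supplied``: validates and
    normalizes the provided kernel.
    """
    if provenance == "user_supplied":
        if kernel is None:
            raise ConfigurationError("user_supplied PSF requires a kernel")
        return PSFModel(kernel=np.asarray(kernel, float), provenance=provenance)

    if provenance == "delta":
        return PSFModel(kernel=np.ones((1, 1)), provenance="delta")

    sigma_px = 0.21 * config.wavelength_nm / config.numerical_aperture / config.pixel_size_nm
    if size is None:
        size = max(3, int(2 * np.ceil(4 * sigma_px) + 1))
    if size % 2 == 0:
        raise ConfigurationError("PSF size must be odd")
    half = size // 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    r_px = np.hypot(yy, xx)
    if provenance == "gaussian":
        k = np.exp(-(r_px**2) / (2.0 * sigma_px**2))
    elif provenance == "airy":
        v = (2.0 * np.pi / config.wavelength_nm) * config.numerical_aperture \
            * r_px * config.pixel_size_nm
        with np.errstate(invalid="ignore", divide="ignore"):
            k = (2.0 * special.j1(v) / v) ** 2
        k[r_px == 0] = 1.0
    else:
        raise ConfigurationError(f"unknown PSF provenance {provenance!r}")
    return PSFModel(kernel=k, provenance=provenance)
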