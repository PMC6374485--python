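"""Depth statistics and visualization of reconstructed volumes.

Given a reconstructed volume R (nz slices, axial step dz), the per-pixel
mean depth is

    D_i = round( sum_j j * R_ij / sum_j R_ij ) * dz,    j = 1..nz,

with round half away from zero.  Two channels are compared through a 2D
relative-depth histogram: for each pixel valid in both channels the bin
(D_i^1, D_i^2) accumulates the geometric mean of the two axial masses,
sqrt(sum_j R_ij^1 * sum_j R_ij^2), and the histogram is normalized so its
maximum equals 1.  Volumes are rendered as color-coded depth maps: each
slice is tinted by an isoluminant colormap entry and the tinted stack
averaged along z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.registration import phase_cross_correlation

from .forward_model import DimensionError, FluorophoreVolume
from .optics import ConfigurationError

__all__ = [
    "DepthMap",
    "RelativeDepthHistogram",
    "RenderOptions",
    "isolum_colormap",
    "mean_depth_map",
    "relative_depth_histogram",
    "depth_render",
    "channel_drift",
]


@dataclass
class DepthMap:
    """Per-pixel mean depth (nm, integer multiple of dz) with validity mask."""

    values: np.ndarray
    valid_mask: np.ndarray
    dz_nm: float


@dataclass
class RelativeDepthHistogram:
    """2D histogram of paired mean depths, weighted by geometric-mean mass."""

    bins_nm: np.ndarray
    counts: np.ndarray
    normalized: bool


@dataclass
class RenderOptions:
    """Depth-render settings: one RGB triplet per slice, intensity scaling."""

    colormap: np.ndarray
    intensity_scaling: str = "linear"  # or "percentile-clip"
    clip_percentile: float = 99.5

    def __post_init__(self) -> None:
        cm = np.asarray(self.colormap, dtype=float)
        if cm.ndim != 2 or cm.shape[1] != 3:
            raise ConfigurationError("colormap must be (nz, 3)")
        if np.any(cm < 0) or np.any(cm > 1):
            raise ConfigurationError("colormap entries must lie in [0, 1]")
        self.colormap = cm


def isolum_colormap(n: int) -> np.ndarray:
    """Approximately isoluminant blue-to-orange colormap with n entries."""
    c0 = np.array([0.20, 0.50, 1.00])
    c1 = np.array([1.00, 0.55, 0.05])
    t = np.linspace(0.0, 1.0, n)[:, None]
    rgb = (1 - t) * c0 + t * c1
    lum = rgb @ np.array([0.299, 0.587, 0.114])
    rgb = rgb * (0.5 / lum)[:, None]
    return np.clip(rgb, 0.0, 1.0)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def mean_depth_map(volume: FluorophoreVolume) -> DepthMap:
    """Mean depth D_i = round(sum_j j R_ij / sum_j R_ij) * dz (1-based j).

    Pixels with zero axial mass are masked invalid.  Rounding is half away
    from zero (a .5 centroid moves to the deeper slice), so values are
    exact multiples of dz in [dz, nz * dz].
    """
    r = volume.values
    nz = r.shape[0]
    j = np.arange(1, nz + 1, dtype=float)[:, None, None]
    mass = r.sum(axis=0)
    valid = mass > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        centroid = (j * r).sum(axis=0) / mass
    d = np.zeros_like(mass)
    d[valid] = _round_half_away(centroid[valid]) * volume.grid.dz_nm
    return DepthMap(values=d, valid_mask=valid, dz_nm=volume.grid.dz_nm)


def relative_depth_histogram(vol1: FluorophoreVolume, vol2: FluorophoreVolume,
                             normalize: bool = True) -> RelativeDepthHistogram:
    """Relative-depth 2D histogram between two co-registered channels.

    For each pixel with nonzero mass in both volumes, the bin addressed by
    the two mean depths accumulates sqrt(mass1 * mass2); identical
    channels put all weight on the diagonal.  When normalized, the maximum
    count is exactly 1.
    """
    if vol1.grid != vol2.grid:
        raise DimensionError("volumes must share the same grid")
    nz = vol1.grid.nz
    dz = vol1.grid.dz_nm
    d1 = mean_depth_map(vol1)
    d2 = mean_depth_map(vol2)
    both = d1.valid_mask & d2.valid_mask
    if not both.any():
        raise ConfigurationError("no pixel has mass in both channels")
    m1 = vol1.values.sum(axis=0)[both]
    m2 = vol2.values.sum(axis=0)[both]
    i1 = (d1.values[both] / dz).astype(int) - 1
    i2 = (d2.values[both] / dz).astype(int) - 1
    counts = np.zeros((nz, nz))
    np.add.at(counts, (i1, i2), np.sqrt(m1 * m2))
    if normalize:
        counts = counts / counts.max()
    bins = dz * np.arange(1, nz + 1, dtype=float)
    return RelativeDepthHistogram(bins_nm=bins, counts=counts,
                                  normalized=normalize)


def depth_render(volume: FluorophoreVolume,
                 options: RenderOptions | None = None) -> np.ndarray:
    """Color-coded depth map: slice intensities tinted then averaged over z.

    RGB_i = (1/nz) sum_j R_ij * colormap[j]; optional intensity scaling
    (linear max or percentile clip) is applied after the average.  Returns
    an (ny, nx, 3) float image in [0, 1] after scaling.
    """
    nz = volume.grid.nz
    if options is None:
        options = RenderOptions(colormap=isolum_colormap(nz))
    if options.colormap.shape[0] != nz:
        raise ConfigurationError(
            f"colormap has {options.colormap.shape[0]} entries for {nz} slices"
        )
    rgb = np.einsum("jyx,jc->yxc", volume.values, options.colormap) / nz
    if options.intensity_scaling == "linear":
        peak = rgb.max()
    elif options.intensity_scaling == "percentile-clip":
        peak = np.percentile(rgb, options.clip_percentile)
    else:
        raise ConfigurationError(
            f"unknown intensity scaling {options.intensity_scaling!r}"
        )
    if peak > 0:
        rgb = np.clip(rgb / peak, 0.0, 1.0)
    return rgb


def channel_drift(image1: np.ndarray, image2: np.ndarray,
                  pixel_size_nm: float) -> tuple[float, float]:
    """Sub-pixel lateral drift between two channels, in nm (dy, dx).

    Estimated from the cross-correlation peak with Fourier-upsampled
    sub-pixel refinement.  Flat images have no correlation peak and raise.
    """
    a = np.asarray(image1, dtype=float)
    b = np.asarray(image2, dtype=float)
    if a.shape != b.shape:
        raise DimensionError("images must share a grid")
    if a.std() == 0 or b.std() == 0:
        raise ConfigurationError("flat image: cross-correlation peak undefined")
    shift, _, _ = phase_cross_correlation(a, b, upsample_factor=100)
    return (float(shift[0] * pixel_size_nm), float(shift[1] * pixel_size_nm))
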