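"""Top-hat slab fitting for calibration phantoms.

The calibration sample is a uniform fluorescent liquid filling the gap
between the coverslip and a divergent spherical lens (radius of curvature
R = 288 mm, diameter 25.1 mm).  The gap thickness grows quadratically with
distance r from the contact point, t(r) = R - sqrt(R^2 - r^2) ~ r^2 / 2R,
sweeping the 0–500 nm depth range over well under a millimetre — a known
nanometric phantom.

Each pixel's multi-angle intensity curve is modelled by a uniform slab
("top hat") of density A between depths z0 and z0 + t.  Integrating the
evanescent excitation over the slab gives the closed form

    s_m = A * I0(a_m) / p(a_m) * exp(-z0 p(a_m)) * (1 - exp(-t p(a_m))),

fitted per pixel by bounded nonlinear least squares.  Fitted thickness
maps recover the lens profile, whose quadratic fit returns the radius of
curvature — the end-to-end accuracy check of the whole model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .optics import ConfigurationError, ExcitationModel

__all__ = [
    "SlabFitResult",
    "LensPhantomSpec",
    "slab_intensity",
    "fit_slab_per_pixel",
    "lens_gap_profile",
    "fit_lens_radius",
    "linear_tracking_range",
]

# deterministic thickness multi-starts (nm): shallow / mid / deep basin
_T_STARTS = (50.0, 150.0, 300.0)
_T_MAX = 1000.0
_Z0_MAX = 500.0


@dataclass
class SlabFitResult:
    """Per-pixel slab fit: thickness t, density A, start depth z0, residual RMS.

    ``boundary_mask`` flags pixels whose best fit hit the thickness bound
    or had an all-zero curve — their thickness is not trustworthy.
    """

    thickness_map: np.ndarray
    amplitude_map: np.ndarray
    start_depth_map: np.ndarray
    residual_map: np.ndarray
    boundary_mask: np.ndarray


@dataclass(frozen=True)
class LensPhantomSpec:
    """Divergent spherical lens resting on the coverslip.

    Defaults are the calibration lens: R = 288 mm, diameter 25.1 mm.
    ``contact_mm`` is the lateral (x, y) position of the contact point in
    the grid's physical frame; ``fluor_density`` the uniform density of
    the fluorescent liquid filling the gap.
    """

    radius_mm: float = 288.0
    diameter_mm: float = 25.1
    contact_mm: tuple[float, float] = (0.0, 0.0)
    fluor_density: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.diameter_mm <= 0:
            raise ConfigurationError("lens radius and diameter must be > 0")
        if self.fluor_density < 0:
            raise ConfigurationError("fluor_density must be >= 0")


def slab_intensity(thickness_nm, amplitude, z0_nm,
                   excitation: ExcitationModel) -> np.ndarray:
    """Multi-angle intensity of a uniform slab [z0, z0 + t] of density A.

    Exact analytic integral of the exponential excitation over the slab;
    the p -> 0 (widefield) limit A * I0 * t is handled continuously via
    expm1.  Thickness and z0 in nm, p in 1/nm.
    """
    t = float(thickness_nm)
    if t < 0:
        raise ConfigurationError("thickness must be >= 0")
    p = excitation.p
    i0 = excitation.i0
    att = np.exp(-float(z0_nm) * p)
    with np.errstate(divide="ignore", invalid="ignore"):
        integ = np.where(p > 0, -np.expm1(-t * p) / np.where(p > 0, p, 1.0), t)
    return float(amplitude) * i0 * att * integ


def _fit_curve(y: np.ndarray, excitation: ExcitationModel, fix_z0: bool):
    """Fit one pixel curve; returns (t, A, z0, rms, at_boundary)."""
    p = excitation.p
    i0 = excitation.i0

    def model(x):
        if fix_z0:
            t, a = x
            z0 = 0.0
        else:
            t, a, z0 = x
        return slab_intensity(t, a, z0, excitation)

    def resid(x):
        return model(x) - y

    best = None
    for t0 in _T_STARTS:
        # variable projection for the amplitude start: best A for this t0
        c = i0 * np.where(p > 0, -np.expm1(-t0 * p) / p, t0)
        denom = float(c @ c)
        a0 = max(float(c @ y) / denom, 1e-12) if denom > 0 else 1e-12
        x0 = [t0, a0] if fix_z0 else [t0, a0, 0.0]
        lb = [0.0, 0.0] if fix_z0 else [0.0, 0.0, 0.0]
        ub = [_T_MAX, np.inf] if fix_z0 else [_T_MAX, np.inf, _Z0_MAX]
        sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    t_hat = float(best.x[0])
    a_hat = float(best.x[1])
    z0_hat = 0.0 if fix_z0 else float(best.x[2])
    rms = float(np.sqrt(2.0 * best.cost / y.size))
    at_boundary = t_hat >= _T_MAX * (1 - 1e-6)
    return t_hat, a_hat, z0_hat, rms, at_boundary


def fit_slab_per_pixel(images: np.ndarray, excitation: ExcitationModel,
                       fix_z0: bool = True) -> SlabFitResult:
    """Fit the top-hat slab model at every pixel of a background-subtracted stack.

    ``images`` is (M, ny, nx).  Requires at least as many angles as free
    parameters (2 with z0 fixed at the coverslip, else 3).  Each pixel runs
    a bounded trust-region least squares from three deterministic thickness
    starts, keeping the lowest-residual solution.  All-zero curves yield
    zero thickness/amplitude and are flagged.
    """
    images = np.asarray(images, dtype=float)
    if images.ndim != 3:
        raise ConfigurationError("images must be (M, ny, nx)")
    m, ny, nx = images.shape
    if m != excitation.n_angles:
        raise ConfigurationError(
            f"{m} pages for {excitation.n_angles} excitation angles"
        )
    n_params = 2 if fix_z0 else 3
    if m < n_params:
        raise ConfigurationError(
            f"need at least {n_params} angles to fit {n_params} parameters"
        )

    t_map = np.zeros((ny, nx))
    a_map = np.zeros((ny, nx))
    z0_map = np.zeros((ny, nx))
    r_map = np.zeros((ny, nx))
    flag = np.zeros((ny, nx), dtype=bool)
    for iy in range(ny):
        for ix in range(nx):
            y = images[:, iy, ix]
            if not np.any(y > 0):
                flag[iy, ix] = True
                continue
            t, a, z0, rms, bnd = _fit_curve(y, excitation, fix_z0)
            t_map[iy, ix] = t
            a_map[iy, ix] = a
            z0_map[iy, ix] = z0
            r_map[iy, ix] = rms
            flag[iy, ix] = bnd
    return SlabFitResult(thickness_map=t_map, amplitude_map=a_map,
                         start_depth_map=z0_map, residual_map=r_map,
                         boundary_mask=flag)


def lens_gap_profile(spec: LensPhantomSpec, lateral_positions_mm) -> np.ndarray:
    """Gap thickness t(r) = R - sqrt(R^2 - r^2) in nm at radial offsets (mm).

    Near the contact point t ~ r^2 / 2R; t(0) = 0.  Offsets beyond the lens
    radius (diameter / 2) are outside the phantom and raise.
    """
    r = np.asarray(lateral_positions_mm, dtype=float)
    if np.any(np.abs(r) > spec.diameter_mm / 2.0):
        raise ConfigurationError("lateral position beyond the lens radius")
    R = spec.radius_mm
    t_mm = R - np.sqrt(R * R - r * r)
    out = t_mm * 1e6  # mm -> nm
    return float(out) if np.isscalar(lateral_positions_mm) else out


def fit_lens_radius(thickness_map: np.ndarray, pixel_size_nm: float,
                    depth_window_nm: tuple[float, float] = (100.0, 400.0),
                    contact_px: tuple[float, float] | None = None) -> float:
    """Radius of curvature (mm) from a fitted thickness map.

    Pixels whose thickness lies inside ``depth_window_nm`` (default
    100–400 nm, the range over which the slab fit tracks the true gap
    linearly) are fitted with t = r^2 / (2 R) + c over radial distance
    from the contact point.  The contact point defaults to the minimum of
    the thickness map.  A non-curved map (slope <= 0) returns ``inf`` as
    an unbounded-radius flag; fewer than 10 usable pixels raise.
    """
    t = np.asarray(thickness_map, dtype=float)
    if contact_px is None:
        cy, cx = np.unravel_index(np.argmin(t), t.shape)
    else:
        cy, cx = contact_px
    iy, ix = np.indices(t.shape)
    r_mm = np.hypot(iy - cy, ix - cx) * pixel_size_nm * 1e-6
    lo, hi = depth_window_nm
    sel = (t >= lo) & (t <= hi)
    if sel.sum() < 10:
        raise ConfigurationError(
            f"only {int(sel.sum())} pixels inside the depth window; need >= 10"
        )
    # linear model t = a * r^2 + c  with  a = 1e6 / (2 R)  [nm per mm^2]
    a, c = np.polyfit(r_mm[sel] ** 2, t[sel], 1)
    if a <= 0.5:  # implied radius beyond 1e6 mm: no measurable curvature
        return float("inf")
    return float(1e6 / (2.0 * a))


def linear_tracking_range(thickness_est: np.ndarray, thickness_true: np.ndarray,
                          start_nm: float = 100.0, bin_nm: float = 20.0,
                          min_pixels: int = 3,
                          tol_nm: float | None = None) -> float:
    """Depth up to which the estimated thickness profile tracks the truth.

    Pixels are binned by true thickness in ``bin_nm`` steps from
    ``start_nm`` upward.  A bin tracks when the median estimated thickness
    deviates from the median true thickness by less than ``tol_nm``
    (default: one bin, i.e. one axial step) — the estimated profile
    following the expected slope, the aggregate statistic a thickness-vs-
    radius validation curve shows.  Returns the upper edge (nm) of the last
    bin in the unbroken run of tracking bins starting at ``start_nm``.
    """
    est = np.asarray(thickness_est, dtype=float).ravel()
    true = np.asarray(thickness_true, dtype=float).ravel()
    if est.shape != true.shape:
        raise ConfigurationError("estimate/truth shape mismatch")
    if tol_nm is None:
        tol_nm = bin_nm
    upper = start_nm
    lo = start_nm
    while True:
        sel = (true >= lo) & (true < lo + bin_nm)
        if sel.sum() < min_pixels:
            break
        dev = abs(float(np.median(est[sel])) - float(np.median(true[sel])))
        if dev >= tol_nm:
            break
        upper = lo + bin_nm
        lo += bin_nm
    return upper
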