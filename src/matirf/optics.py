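"""Evanescent-wave excitation physics.

Total internal reflection at a glass/sample interface produces an
evanescent field whose intensity decays exponentially with depth,

    I(z, alpha) = I0(alpha) * exp(-z * p(alpha)),

where ``alpha`` is the incident angle (measured from the optical axis),
``I0`` the intensity at the interface (z = 0) and ``1/p`` the penetration
depth — the depth at which the excitation has fallen to 1/e.  Multi-angle
TIRF encodes axial position in the per-angle intensity curve through the
angle dependence of ``p``.

This module provides the critical angle, the inverse penetration depth
p(alpha) = (4*pi/lambda) * sqrt(n1^2 sin^2(alpha) - n2^2), the interface
intensity I0(alpha) (unit or s-polarized Fresnel mode), and the relation
between incident angle and illumination-ring radius in the objective back
focal plane (Abbe sine condition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfigurationError",
    "SubCriticalAngleError",
    "OpticalConfig",
    "AngleSet",
    "ExcitationModel",
    "critical_angle",
    "max_objective_angle",
    "penetration_inverse",
    "penetration_depth",
    "interface_intensity",
    "angle_to_bfp_radius",
    "bfp_radius_to_angle",
    "build_excitation",
    "default_angle_set",
]


class ConfigurationError(ValueError):
    """Raised for physically invalid optical configurations or modes."""


class SubCriticalAngleError(ValueError):
    """Raised when an angle at or below the critical angle is used in the
    evanescent regime (no evanescent wave exists there)."""


@dataclass(frozen=True)
class OpticalConfig:
    """Optical configuration of the TIRF setup.

    Parameters
    ----------
    wavelength_nm : float
        Excitation wavelength in vacuum (nm).
    n_incident : float
        Refractive index on the glass/immersion side (n1).
    n_sample : float
        Refractive index of the sample medium (n2).  Total internal
        reflection requires ``n_incident > n_sample``.
    numerical_aperture : float
        Objective NA; bounds the largest accessible incident angle.
    pixel_size_nm : float
        Lateral sample-plane pixel size (nm).
    """

    wavelength_nm: float = 491.0
    n_incident: float = 1.515
    n_sample: float = 1.33
    numerical_aperture: float = 1.49
    pixel_size_nm: float = 107.0

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ConfigurationError("wavelength_nm must be > 0")
        if self.pixel_size_nm <= 0:
            raise ConfigurationError("pixel_size_nm must be > 0")
        if not (self.n_incident > self.n_sample > 0):
            raise ConfigurationError(
                "total internal reflection requires n_incident > n_sample > 0 "
                f"(got n_incident={self.n_incident}, n_sample={self.n_sample})"
            )
        if self.numerical_aperture > self.n_incident:
            raise ConfigurationError(
                "numerical_aperture cannot exceed n_incident "
                f"({self.numerical_aperture} > {self.n_incident})"
            )


@dataclass(frozen=True)
class AngleSet:
    """Ordered set of incident angles (degrees from the optical axis)."""

    angles_deg: tuple[float, ...]

    def __post_init__(self) -> None:
        angles = tuple(float(a) for a in self.angles_deg)
        object.__setattr__(self, "angles_deg", angles)
        if len(angles) < 2:
            raise ConfigurationError("an AngleSet needs at least two angles")
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ConfigurationError("angles must be strictly increasing")

    def __len__(self) -> int:
        return len(self.angles_deg)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.angles_deg, dtype=float)

    def validate(self, config: OpticalConfig) -> None:
        """Check every angle is supercritical and objective-accessible."""
        crit = critical_angle(config)
        amax = max_objective_angle(config)
        arr = self.as_array()
        if np.any(arr <= crit):
            raise SubCriticalAngleError(
                f"all angles must exceed the critical angle {crit:.3f} deg"
            )
        if np.any(arr > amax + 1e-9):
            raise ConfigurationError(
                f"angles beyond the objective aperture limit {amax:.3f} deg"
            )


@dataclass(frozen=True)
class ExcitationModel:
    """Per-angle excitation: interface intensity and inverse penetration depth.

    ``i0[m]`` is I0(alpha_m) in arbitrary units and ``p[m]`` the inverse
    penetration depth (1/nm); both arrays align with ``angle_set``.
    """

    angle_set: AngleSet
    i0: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        i0 = np.asarray(self.i0, dtype=float)
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "i0", i0)
        object.__setattr__(self, "p", p)
        m = len(self.angle_set)
        if i0.shape != (m,) or p.shape != (m,):
            raise ConfigurationError("i0 and p must have one entry per angle")
        if np.any(p <= 0):
            raise ConfigurationError("p must be strictly positive")
        if np.any(np.diff(p) <= 0):
            raise ConfigurationError("p must increase strictly with angle")
        if np.any(i0 <= 0):
            raise ConfigurationError("i0 must be strictly positive")

    @property
    def n_angles(self) -> int:
        return len(self.angle_set)

    def intensity(self, z_nm, m: int):
        """Excitation intensity I(z, alpha_m) at depth z (nm)."""
        return self.i0[m] * np.exp(-np.asarray(z_nm, dtype=float) * self.p[m])


def critical_angle(config: OpticalConfig) -> float:
    """Critical angle asin(n2/n1) in degrees."""
    return math.degrees(math.asin(config.n_sample / config.n_incident))


def max_objective_angle(config: OpticalConfig) -> float:
    """Largest incident angle accessible through the objective, asin(NA/n1)."""
    return math.degrees(math.asin(config.numerical_aperture / config.n_incident))


def penetration_inverse(config: OpticalConfig, angle_deg) -> np.ndarray | float:
    """Inverse penetration depth p(alpha) in 1/nm.

    p = (4*pi/lambda) * sqrt(n1^2 sin^2(alpha) - n2^2); 1/p is the depth at
    which the evanescent intensity falls to 1/e.  Only defined strictly
    above the critical angle.
    """
    angle = np.asarray(angle_deg, dtype=float)
    crit = critical_angle(config)
    if np.any(angle <= crit):
        raise SubCriticalAngleError(
            f"angle(s) must lie strictly above the critical angle {crit:.4f} deg"
        )
    s = config.n_incident * np.sin(np.radians(angle))
    p = (4.0 * np.pi / config.wavelength_nm) * np.sqrt(s * s - config.n_sample**2)
    return float(p) if np.isscalar(angle_deg) else p


def penetration_depth(config: OpticalConfig, angle_deg):
    """Penetration depth 1/p in nm."""
    return 1.0 / penetration_inverse(config, angle_deg)


def interface_intensity(config: OpticalConfig, angle_deg, mode: str = "unit"):
    """Evanescent intensity at the interface, I0(alpha), in arbitrary units.

    ``mode='unit'`` returns 1 for every angle (intensity units absorbed into
    the fluorophore density).  ``mode='fresnel_s'`` returns the s-polarized
    evanescent intensity transmission factor 4 cos^2(alpha) / (1 - (n2/n1)^2),
    which decreases from 4 at the critical angle to 0 at grazing incidence.
    """
    angle = np.asarray(angle_deg, dtype=float)
    crit = critical_angle(config)
    if np.any(angle <= crit):
        raise SubCriticalAngleError(
            f"angle(s) must lie strictly above the critical angle {crit:.4f} deg"
        )
    if mode == "unit":
        out = np.ones_like(angle)
    elif mode == "fresnel_s":
        n_rel = config.n_sample / config.n_incident
        out = 4.0 * np.cos(np.radians(angle)) ** 2 / (1.0 - n_rel**2)
    else:
        raise ConfigurationError(f"unknown interface-intensity mode {mode!r}")
    return float(out) if np.isscalar(angle_deg) else out


def angle_to_bfp_radius(angle_deg, objective_focal_mm: float,
                        config: OpticalConfig):
    """Back-focal-plane ring radius (um) for an incident angle.

    Abbe sine condition: r = f_obj * n1 * sin(alpha).
    """
    if objective_focal_mm <= 0:
        raise ConfigurationError("objective focal length must be positive")
    angle = np.asarray(angle_deg, dtype=float)
    r = objective_focal_mm * 1e3 * config.n_incident * np.sin(np.radians(angle))
    return float(r) if np.isscalar(angle_deg) else r


def bfp_radius_to_angle(radius_um, objective_focal_mm: float,
                        config: OpticalConfig):
    """Incident angle (deg) whose BFP ring has the given radius (um).

    Inverse of the sine condition; radii beyond f_obj * n1 fall outside the
    aperture and raise.
    """
    if objective_focal_mm <= 0:
        raise ConfigurationError("objective focal length must be positive")
    r = np.asarray(radius_um, dtype=float)
    if np.any(r < 0):
        raise ConfigurationError("radius must be nonnegative")
    rmax = objective_focal_mm * 1e3 * config.n_incident
    if np.any(r > rmax * (1 + 1e-12)):
        raise ConfigurationError(
            f"radius beyond the aperture limit f*n1 = {rmax:.3f} um"
        )
    s = np.clip(r / rmax, 0.0, 1.0)
    angle = np.degrees(np.arcsin(s))
    return float(angle) if np.isscalar(radius_um) else angle


def build_excitation(config: OpticalConfig, angle_set: AngleSet,
                     i0_mode: str = "unit") -> ExcitationModel:
    """Assemble the per-angle excitation model for a configuration."""
    angle_set.validate(config)
    angles = angle_set.as_array()
    p = penetration_inverse(config, angles)
    i0 = interface_intensity(config, angles, mode=i0_mode)
    return ExcitationModel(angle_set=angle_set, i0=np.atleast_1d(i0),
                           p=np.atleast_1d(p))


def default_angle_set(config: OpticalConfig, m: int = 10,
                      margin_deg: float = 0.5) -> AngleSet:
    """Evenly spaced supercritical angles spanning the accessible range.

    Angles run from ``critical + margin`` to just below the objective limit;
    ten angles is the acquisition count the setup is designed around.  The
    small default margin keeps the first angle close to critical, where the
    evanescent field penetrates deepest (~300 nm for glass/water at 491 nm)
    — without it, depth sensitivity dies well before 400 nm.
    """
    lo = critical_angle(config) + margin_deg
    hi = max_objective_angle(config) - 0.5
    if hi <= lo:
        raise ConfigurationError("no supercritical angular range available")
    return AngleSet(tuple(np.linspace(lo, hi, m)))
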