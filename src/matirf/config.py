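"""Run configuration: YAML parsing and validation.

A config file has top-level sections ``optical``, ``grid``, ``angles``,
``regularizer``, ``solver``, ``noise`` and ``paths``; unknown sections or
keys are rejected by name so typos never pass silently.  All component
invariants are enforced by the dataclasses they construct.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .forward_model import GridSpec
from .optics import AngleSet, ConfigurationError, OpticalConfig
from .phantoms import NoiseSpec
from .regularization import RegularizerSpec
from .solver import SolverOptions

__all__ = ["RunConfig", "parse_config"]

_SECTION_KEYS = {
    "optical": {"wavelength_nm", "n_incident", "n_sample",
                "numerical_aperture", "pixel_size_nm"},
    "grid": {"nx", "ny", "nz", "dz_nm", "pixel_size_nm", "z0_nm"},
    "angles": {"list_deg", "csv_path"},
    "regularizer": {"kind", "mu", "voxel_aspect"},
    "solver": {"n_iter", "rho1", "rho2", "rho3", "tol_primal",
               "deconvolve", "record_objective", "normalize", "seed"},
    "noise": {"model", "gaussian_sigma", "photon_scale", "seed"},
    "paths": None,  # free-form mapping of labels to paths
}


@dataclass
class RunConfig:
    optical: OpticalConfig
    grid: GridSpec | None = None
    angles: AngleSet | None = None
    angles_csv: str | None = None
    regularizer: RegularizerSpec | None = None
    solver: SolverOptions = field(default_factory=SolverOptions)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    paths: dict = field(default_factory=dict)


def _check_keys(section: str, mapping: dict) -> None:
    allowed = _SECTION_KEYS[section]
    if allowed is None:
        return
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}"
        )


def parse_config(path, require_mu: bool = False) -> RunConfig:
    """Parse and validate a YAML run configuration.

    ``require_mu`` makes a missing regularizer weight an error (the
    reconstruction command has no default for mu).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(raw) - set(_SECTION_KEYS)
    if unknown:
        raise ConfigurationError(f"unknown config section(s) {sorted(unknown)}")
    for sec, content in raw.items():
        if content is not None and not isinstance(content, dict):
            raise ConfigurationError(f"config section {sec!r} must be a mapping")
        _check_keys(sec, content or {})

    optical = OpticalConfig(**(raw.get("optical") or {}))

    grid = None
    if "grid" in raw:
        gkw = dict(raw["grid"] or {})
        gkw.setdefault("pixel_size_nm", optical.pixel_size_nm)
        grid = GridSpec(**gkw)

    angles = None
    angles_csv = None
    if "angles" in raw:
        akw = raw["angles"] or {}
        if "list_deg" in akw:
            angles = AngleSet(tuple(float(a) for a in akw["list_deg"]))
        elif "csv_path" in akw:
            angles_csv = str(akw["csv_path"])
        else:
            raise ConfigurationError(
                "angles section needs 'list_deg' or 'csv_path'"
            )

    regularizer = None
    if "regularizer" in raw:
        rkw = dict(raw["regularizer"] or {})
        if "mu" not in rkw:
            raise ConfigurationError("regularizer.mu is required (no default)")
        if "voxel_aspect" not in rkw and grid is not None:
            rkw["voxel_aspect"] = grid.voxel_aspect
        regularizer = RegularizerSpec(**rkw)
    elif require_mu:
        raise ConfigurationError(
            "a regularizer section with mu is required for reconstruction"
        )

    solver = SolverOptions(**(raw.get("solver") or {}))
    noise = NoiseSpec(**(raw.get("noise") or {}))
    paths = dict(raw.get("paths") or {})
    return RunConfig(optical=optical, grid=grid, angles=angles,
                     angles_csv=angles_csv, regularizer=regularizer,
                     solver=solver, noise=noise, paths=paths)
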