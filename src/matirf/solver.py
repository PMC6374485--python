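"""Joint deconvolution / axial reconstruction by ADMM.

The reconstruction solves

    f_hat = argmin_{f >= 0}  1/2 ||T H f - g||^2  +  mu R(L f)

by splitting with auxiliary variables u1 = H f, u2 = L f, u3 = f
(simultaneous-direction method of multipliers).  Every subproblem has a
direct solution — no inner iterations:

* u1: because T acts independently on each pixel's axial profile, the
  normal equations (Tz' Tz + rho1 I) u1 = Tz' g + rho1 (H f + d1) share one
  (nz, nz) Cholesky factorization across all pixels;
* u2: the exact prox of (mu/rho2) R — group soft-thresholding for TV,
  eigenvalue soft-thresholding for the Hessian nuclear norm;
* u3: componentwise projection onto the nonnegative orthant;
* f:  H and L are periodic convolutions, so the quadratic system
  (rho1 H'H + rho2 L'L + rho3 I) f = rhs is diagonal in the 3D DFT basis
  and solved by one FFT round trip per iteration.

To suppress wrap-around from the periodic convolutions, the solver works
on a lateral grid zero-padded by the PSF half-width; data only constrain
the interior pixels and the estimate is cropped on return.  The returned
volume is the u3 iterate, which is nonnegative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import linalg

from .forward_model import (
    AcquisitionStack,
    BackgroundModel,
    DimensionError,
    FluorophoreVolume,
    GridSpec,
    PSFModel,
    apply_H,
    apply_T,
)
from .optics import ConfigurationError
from .regularization import (
    RegularizerSpec,
    field_weights,
    fourier_symbol_sum,
    reg_operator,
    reg_operator_adjoint,
    reg_prox,
    reg_value,
)

__all__ = [
    "DivergenceError",
    "SolverOptions",
    "SolverState",
    "ReconstructionResult",
    "admm_reconstruct",
    "objective_value",
    "precompute_fourier_denominator",
]


class DivergenceError(RuntimeError):
    """Raised when iterates become non-finite."""


@dataclass(frozen=True)
class SolverOptions:
    """ADMM settings.

    ``n_iter`` defaults to 50, the iteration budget at which the
    reconstructions are run in practice.  The three penalties weight the
    constraints u1 = Hf, u2 = Lf, u3 = f; with data normalized so
    max(g) = 1 (the default), unit penalties are a serviceable choice.
    ``deconvolve=False`` replaces H by the identity (reconstruction
    without joint deconvolution).
    """

    n_iter: int = 50
    rho1: float = 1.0
    rho2: float = 1.0
    rho3: float = 1.0
    tol_primal: float | None = None
    deconvolve: bool = True
    record_objective: bool = False
    normalize: bool = True
    seed: int | None = None  # unused; kept for API symmetry with simulation

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ConfigurationError("n_iter must be >= 1")
        if min(self.rho1, self.rho2, self.rho3) <= 0:
            raise ConfigurationError("penalty parameters must be > 0")


@dataclass
class SolverState:
    """Final ADMM variables (on the internally padded grid)."""

    f: np.ndarray
    u1: np.ndarray
    u2: np.ndarray
    u3: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    d3: np.ndarray
    it: int
    objective_trace: list = dc_field(default_factory=list)
    primal_residuals: list = dc_field(default_factory=list)


@dataclass
class ReconstructionResult:
    """Reconstruction output: the estimate, solver state and settings echo."""

    volume: FluorophoreVolume
    state: SolverState
    settings: dict


def precompute_fourier_denominator(psf_hat_sq: np.ndarray | None,
                                   reg: RegularizerSpec,
                                   shape: tuple[int, int, int],
                                   opts: SolverOptions) -> np.ndarray:
    """Frequency multiplier rho1 |h|^2 + rho2 sum_k w_k |l_k|^2 + rho3.

    Strictly positive everywhere because rho3 > 0, so the f-update system
    is always invertible.  ``psf_hat_sq`` is the 2D lateral power spectrum
    of the PSF (None means delta PSF, |h|^2 = 1).
    """
    lsum = fourier_symbol_sum(reg, shape)
    if psf_hat_sq is None:
        hterm = np.ones(shape[1:])
    else:
        hterm = psf_hat_sq
    return opts.rho1 * hterm[None, :, :] + opts.rho2 * lsum + opts.rho3


def _kernel_fft(kernel: np.ndarray, lateral_shape: tuple[int, int]) -> np.ndarray:
    """2D DFT of the kernel embedded with its center at the origin."""
    ny, nx = lateral_shape
    ky, kx = kernel.shape
    emb = np.zeros((ny, nx))
    emb[:ky, :kx] = kernel
    emb = np.roll(emb, (-(ky // 2), -(kx // 2)), axis=(0, 1))
    return np.fft.fft2(emb)


def _padded_objective(f: np.ndarray, g: np.ndarray, tz: np.ndarray,
                      h_hat: np.ndarray | None, interior, reg: RegularizerSpec) -> float:
    """Objective of the padded problem at the nonnegative projection of f."""
    fp = np.maximum(f, 0.0)
    hf = _conv(fp, h_hat)
    resid = apply_T(tz, hf[interior]) - g
    return 0.5 * float((resid**2).sum()) + reg_value(reg, fp)


def _conv(vol: np.ndarray, h_hat: np.ndarray | None) -> np.ndarray:
    if h_hat is None:
        return vol
    return np.fft.ifft2(np.fft.fft2(vol, axes=(1, 2)) * h_hat[None], axes=(1, 2)).real


def admm_reconstruct(stack: AcquisitionStack, tz: np.ndarray, psf: PSFModel,
                     background: BackgroundModel, reg: RegularizerSpec,
                     opts: SolverOptions,
                     grid: GridSpec | None = None) -> ReconstructionResult:
    """Run the ADMM reconstruction.

    The background is subtracted from the data before solving (equivalent
    under the quadratic fidelity); negative residual pixels are kept to
    avoid bias.  With ``opts.normalize`` the background-subtracted data are
    scaled to unit maximum internally and the estimate rescaled on return,
    so ``mu`` and the penalties refer to the normalized problem.
    """
    m, ny, nx = stack.images.shape
    nz = tz.shape[1]
    if tz.shape[0] != m:
        raise DimensionError(f"Tz has {tz.shape[0]} rows for {m} angles")
    if background.level_per_angle.shape[0] != m:
        raise DimensionError("background/angle count mismatch")

    g = stack.images - background.level_per_angle[:, None, None]
    scale = 1.0
    if opts.normalize:
        peak = float(np.abs(g).max())
        if peak > 0:
            scale = peak
            g = g / scale

    use_h = opts.deconvolve and not psf.is_delta
    if use_h:
        ph, pw = psf.half_width
    else:
        ph = pw = 0
    pny, pnx = ny + 2 * ph, nx + 2 * pw
    shape = (nz, pny, pnx)
    interior = (slice(None), slice(ph, ph + ny), slice(pw, pw + nx))

    h_hat = _kernel_fft(psf.kernel, (pny, pnx)) if use_h else None
    psf_hat_sq = np.abs(h_hat) ** 2 if use_h else None
    denom = precompute_fourier_denominator(psf_hat_sq, reg, shape, opts)

    # one (nz, nz) factorization shared by every pixel and iteration
    gram = tz.T @ tz + opts.rho1 * np.eye(nz)
    cho = linalg.cho_factor(gram)
    ttg = np.einsum("mj,myx->jyx", tz, g)  # Tz' g on the interior grid

    w = field_weights(reg.kind)
    n_fields = w.shape[0]

    f = np.zeros(shape)
    u1 = np.zeros(shape)
    u2 = np.zeros((n_fields,) + shape)
    u3 = np.zeros(shape)
    d1 = np.zeros(shape)
    d2 = np.zeros((n_fields,) + shape)
    d3 = np.zeros(shape)

    trace: list[float] = []
    primal: list[float] = []
    tau2 = reg.mu / opts.rho2
    hf = _conv(f, h_hat)
    lf = reg_operator(reg, f)

    it = 0
    for it in range(1, opts.n_iter + 1):
        # (a) u1: data-coupled axial solve, one factorization for all pixels
        v1 = hf + d1
        u1 = v1.copy()
        rhs = ttg + opts.rho1 * v1[interior]
        sol = linalg.cho_solve(cho, rhs.reshape(nz, -1))
        u1[interior] = sol.reshape(nz, ny, nx)

        # (b) u2: exact prox of (mu/rho2) R
        u2 = reg_prox(reg, lf + d2, tau2)

        # (c) u3: nonnegativity projection
        u3 = np.maximum(f + d3, 0.0)

        # (d) f: direct Fourier solve of the normal equations
        rhs_f = opts.rho3 * (u3 - d3)
        if use_h:
            rhs_f = rhs_f + opts.rho1 * _conv(u1 - d1, np.conj(h_hat))
        else:
            rhs_f = rhs_f + opts.rho1 * (u1 - d1)
        rhs_f = rhs_f + opts.rho2 * reg_operator_adjoint(reg, u2 - d2, weighted=True)
        f = np.fft.ifftn(np.fft.fftn(rhs_f) / denom).real

        # (e) dual ascent
        hf = _conv(f, h_hat)
        lf = reg_operator(reg, f)
        d1 += hf - u1
        d2 += lf - u2
        d3 += f - u3

        if not np.all(np.isfinite(f)):
            raise DivergenceError(f"non-finite iterate at iteration {it}")

        r1 = np.linalg.norm(hf - u1)
        r2 = np.linalg.norm(lf - u2)
        r3 = np.linalg.norm(f - u3)
        nf = max(np.linalg.norm(f), 1e-30)
        res = float(np.sqrt(r1**2 + r2**2 + r3**2) / nf)
        primal.append(res)
        if opts.record_objective:
            trace.append(_padded_objective(f, g, tz, h_hat, interior, reg))
        if opts.tol_primal is not None and res < opts.tol_primal:
            break

    est = u3[interior] * scale
    out_grid = grid or GridSpec(nx=nx, ny=ny, nz=nz)
    volume = FluorophoreVolume(grid=out_grid, values=est)
    state = SolverState(f=f, u1=u1, u2=u2, u3=u3, d1=d1, d2=d2, d3=d3,
                        it=it, objective_trace=trace, primal_residuals=primal)
    settings = {
        "n_iter": opts.n_iter, "rho1": opts.rho1, "rho2": opts.rho2,
        "rho3": opts.rho3, "deconvolve": opts.deconvolve,
        "normalize": opts.normalize, "scale": scale,
        "regularizer": reg.kind, "mu": reg.mu,
        "voxel_aspect": reg.voxel_aspect, "pad": (ph, pw),
    }
    return ReconstructionResult(volume=volume, state=state, settings=settings)


def objective_value(f: np.ndarray, stack: AcquisitionStack, tz: np.ndarray,
                    psf: PSFModel, background: BackgroundModel,
                    reg: RegularizerSpec) -> float:
    """Objective 1/2 ||T H f - g||^2 + mu R(L f) + i_{>=0}(f).

    Returns +inf when f has a negative voxel (the indicator term); the
    data are background-subtracted before the fidelity term.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        return float("inf")
    g = stack.images - background.level_per_angle[:, None, None]
    resid = apply_T(tz, apply_H(f, psf)) - g
    return 0.5 * float((resid**2).sum()) + reg_value(reg, f)
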