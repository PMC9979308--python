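"""Analytic-dictionary reconstruction: total-variation regularized CS.

The analytic route sparsifies the image with a fixed transform — the
discrete gradient.  The reconstruction solves

    min_x  || F_u x - y ||_2^2  +  lambda * TV_phi(x)

where ``F_u`` is the undersampled unitary Fourier operator and ``TV_phi``
is the smoothed (differentiable) total variation

    TV_phi(x) = sum_ij sqrt( (Dx x)_ij^2 + (Dy x)_ij^2 + phi^2 ),

with forward differences and replicate (Neumann) boundaries.  ``phi > 0``
rounds the kink of the absolute value so plain gradient descent applies;
a backtracking line search makes the objective non-increasing by
construction.  Iterates start at the zero-filled reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fourier import fft2c, ifft2c
from .synthetic import KSpaceSample


@dataclass(frozen=True)
class TVSolveSpec:
    lambda_tv: float = 1e-3
    phi: float = 1e-3
    max_iters: int = 100
    step_size: float = 1.0
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lambda_tv < 0:
            raise ValueError("lambda_tv must be nonnegative")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.max_iters < 1 or self.step_size <= 0:
            raise ValueError("max_iters >= 1 and step_size > 0 required")


@dataclass
class ConvergenceLog:
    objective: list[float] = field(default_factory=list)
    step_sizes: list[float] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0


def _forward_diffs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # replicate boundary: the difference past the last row/column is zero
    dx = np.diff(x, axis=1, append=x[:, -1:])
    dy = np.diff(x, axis=0, append=x[-1:, :])
    return dx, dy


def _div_adjoint(px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Adjoint of the forward-difference pair (negative divergence)."""
    gx = np.empty_like(px)
    gx[:, 0] = -px[:, 0]
    gx[:, 1:] = px[:, :-1] - px[:, 1:]
    gx[:, -1] += px[:, -1]  # replicate-boundary column contributes nothing net
    gy = np.empty_like(py)
    gy[0, :] = -py[0, :]
    gy[1:, :] = py[:-1, :] - py[1:, :]
    gy[-1, :] += py[-1, :]
    return gx + gy


def tv_anisotropic(image: np.ndarray) -> float:
    """Anisotropic total variation: sum |Dx| + |Dy| (replicate boundary)."""
    dx, dy = _forward_diffs(np.asarray(image, dtype=float))
    return float(np.abs(dx).sum() + np.abs(dy).sum())


def tv_smoothed(image: np.ndarray, phi: float) -> float:
    """Smoothed isotropic TV: sum sqrt(Dx^2 + Dy^2 + phi^2)."""
    if phi <= 0:
        raise ValueError("phi must be positive")
    dx, dy = _forward_diffs(np.asarray(image, dtype=float))
    return float(np.sqrt(dx**2 + dy**2 + phi**2).sum())


def tv_smoothed_grad(image: np.ndarray, phi: float) -> np.ndarray:
    """Gradient of ``tv_smoothed`` with respect to the image.

    For complex images this is the Wirtinger-style gradient of
    ``sum sqrt(|Dx|^2 + |Dy|^2 + phi^2)`` over the real/imaginary pair,
    packed back into one complex array.
    """
    x = np.asarray(image)
    dx, dy = _forward_diffs(x)
    w = np.sqrt(np.abs(dx) ** 2 + np.abs(dy) ** 2 + phi**2)
    return _div_adjoint(dx / w, dy / w)


def _tv_smoothed_value(x: np.ndarray, phi: float) -> float:
    dx, dy = _forward_diffs(x)
    return float(np.sqrt(np.abs(dx) ** 2 + np.abs(dy) ** 2 + phi**2).sum())


def _objective(x: np.ndarray, sample: KSpaceSample, spec: TVSolveSpec) -> float:
    resid = np.where(sample.mask, fft2c(x) - sample.data, 0.0)
    data = float(np.sum(np.abs(resid) ** 2))
    return data + spec.lambda_tv * _tv_smoothed_value(x, spec.phi)


def _gradient(x: np.ndarray, sample: KSpaceSample, spec: TVSolveSpec) -> np.ndarray:
    # steepest descent over the (Re, Im) pair packed as a complex array:
    # the descent rate along -g is ||g||^2
    resid = np.where(sample.mask, fft2c(x) - sample.data, 0.0)
    grad_data = 2.0 * ifft2c(resid)
    return grad_data + spec.lambda_tv * tv_smoothed_grad(x, spec.phi)


def reconstruct_tv(
    sample: KSpaceSample, spec: TVSolveSpec = TVSolveSpec()
) -> tuple[np.ndarray, ConvergenceLog]:
    """Gradient descent with backtracking on the smoothed-TV CS objective.

    Iterates are complex, initialized at the inverse transform of the
    zero-filled data (the least-squares minimizer of the fidelity term);
    the real part, clipped to [0, 1], is returned.  The log records the
    objective per accepted iteration; non-convergence within ``max_iters``
    is reported through ``log.converged``, not an exception.
    """
    x = ifft2c(sample.data)
    log = ConvergenceLog()
    f = _objective(x, sample, spec)
    log.objective.append(f)
    step = spec.step_size
    for it in range(spec.max_iters):
        g = _gradient(x, sample, spec)
        gnorm2 = float(np.sum(np.abs(g) ** 2))
        if gnorm2 == 0.0:
            log.converged = True
            break
        # backtracking: Armijo with factor 1e-4, halving the step
        accepted = False
        for _ in range(30):
            x_new = x - step * g
            f_new = _objective(x_new, sample, spec)
            if f_new <= f - 1e-4 * step * gnorm2:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        rel_drop = (f - f_new) / max(f, 1e-30)
        x, f = x_new, f_new
        log.objective.append(f)
        log.step_sizes.append(step)
        log.iterations = it + 1
        step *= 1.5  # let the step grow back between iterations
        if rel_drop < spec.tol:
            log.converged = True
            break
    return np.clip(np.real(x), 0.0, 1.0), log
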