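"""Shared nonlinear least-squares machinery for the titration fitters.

Both the fluorescence and the ITC models are *separable*: given the binding
constants (iterated as log10 values, which keeps them positive and makes the
search landscape well scaled) the signal amplitudes / molar enthalpies enter
linearly.  The fitters therefore profile the linear parameters out with an
ordinary least-squares solve inside the residual (variable projection) and
run a deterministic multi-start trust-region search over the 1-2 remaining
nonlinear parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import least_squares

__all__ = ["FitOptions", "ParameterEstimate", "FitResult", "multistart_varpro"]

logger = logging.getLogger("coopbind.fit")


@dataclass(frozen=True)
class FitOptions:
    """Options shared by the titration fitters.

    ``n_starts`` initial guesses are spread evenly over ``log10K_bounds`` for
    every nonlinear parameter (full grid for two parameters, thinned to keep
    at most ``n_starts**2`` solves).
    """

    n_starts: int = 5
    log10K_bounds: tuple[float, float] = (3.0, 13.0)
    seed: int = 0
    xtol: float = 1e-10
    ftol: float = 1e-10
    #: run the nested-model (F-ratio) diagnostic after two-site fits
    model_check: bool = True


@dataclass(frozen=True)
class ParameterEstimate:
    value: float
    stderr: float | None = None


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics of one least-squares fit.

    ``parameters`` maps parameter name to the point estimate and (asymptotic)
    standard error; ``per_replicate`` holds the independent per-replicate
    estimates when several series were fitted, with ``parameters`` then the
    mean +/- sample SD across replicates (``stderr_source`` records which).
    """

    parameters: dict[str, ParameterEstimate]
    rss: float
    n_points: int
    converged: bool
    stderr_source: str = "covariance"
    per_replicate: list[dict[str, float]] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def value(self, name: str) -> float:
        return self.parameters[name].value


def _start_grid(n_theta: int, options: FitOptions) -> np.ndarray:
    lo, hi = options.log10K_bounds
    pts = np.linspace(lo, hi, options.n_starts)
    if n_theta == 1:
        return pts[:, None]
    # thinned grid over two nonlinear constants: the stepwise constants of a
    # two-site molecule usually satisfy K2 < K1 (statistical factor), so run
    # every start with the second constant offset below the first, plus a few
    # offset above to catch strongly cooperative solutions
    below = [(p, max(p - 1.5, lo)) for p in pts]
    above = [(p, min(p + 1.0, hi)) for p in pts[1:-1:2]]
    return np.asarray(below + above)


def multistart_varpro(
    design_fn: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
    y: np.ndarray,
    n_theta: int,
    options: FitOptions,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Minimize ||y - offset(theta) - B(theta) @ a||^2 over theta (and a).

    ``design_fn(theta)`` returns (B, offset); the linear coefficients ``a``
    are profiled out by ordinary least squares.  Returns (theta, a, rss,
    converged), choosing across starts by lowest residual norm then lowest
    first component of theta (deterministic tie-break).
    """
    y = np.asarray(y, dtype=float)

    def profiled_residual(theta):
        try:
            B, offset = design_fn(theta)
        except Exception:
            return np.full_like(y, 1e6)
        resid = y - offset
        if B.shape[1]:
            a, *_ = np.linalg.lstsq(B, resid, rcond=None)
            resid = resid - B @ a
        return resid

    lo, hi = options.log10K_bounds
    bounds = (np.full(n_theta, lo - 1.0), np.full(n_theta, hi + 1.0))

    def local_solve(theta0, max_nfev=None):
        return least_squares(
            profiled_residual,
            theta0,
            bounds=bounds,
            xtol=options.xtol,
            ftol=options.ftol,
            gtol=1e-14,
            max_nfev=max_nfev,
        )

    # scout every start with a capped iteration budget, then fully polish the
    # winner (best-of by residual norm, ties by lowest first constant)
    candidates = []
    for theta0 in _start_grid(n_theta, options):
        try:
            sol = local_solve(theta0, max_nfev=20 * n_theta)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        logger.debug("start %s -> theta %s rss %.6g", theta0, sol.x, rss)
        candidates.append((rss, float(sol.x[0]), sol))
    if not candidates:
        raise RuntimeError("all optimizer starts failed")
    candidates.sort(key=lambda t: (t[0], t[1]))
    best = local_solve(candidates[0][2].x)
    logger.debug("polished winner: theta %s rss %.6g", best.x, float(np.sum(best.fun**2)))
    rss = float(np.sum(best.fun**2))
    theta = best.x
    B, offset = design_fn(theta)
    if B.shape[1]:
        a, *_ = np.linalg.lstsq(B, y - offset, rcond=None)
    else:
        a = np.zeros(0)
    return theta, np.atleast_1d(a), rss, bool(best.success)


def covariance_stderr(
    design_fn: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
    y: np.ndarray,
    theta: np.ndarray,
    a: np.ndarray,
    rel_step: float = 1e-6,
) -> np.ndarray:
    """Asymptotic standard errors for the full (theta, a) parameter vector.

    Jacobian by forward differences on the full model, covariance
    s^2 (J^T J)^-1 with s^2 = RSS/(n-p); returns sqrt of the diagonal
    (NaN where the normal matrix is singular).
    """
    y = np.asarray(y, dtype=float)
    p = np.concatenate([theta, a])
    n_theta = len(theta)

    def model(pvec):
        B, offset = design_fn(pvec[:n_theta])
        return offset + (B @ pvec[n_theta:] if B.shape[1] else 0.0)

    f0 = model(p)
    J = np.empty((len(y), len(p)))
    for j in range(len(p)):
        h = rel_step * max(abs(p[j]), 1e-8)
        pj = p.copy()
        pj[j] += h
        J[:, j] = (model(pj) - f0) / h
    resid = y - f0
    dof = max(len(y) - len(p), 1)
    s2 = float(resid @ resid) / dof
    JTJ = J.T @ J
    try:
        cov = s2 * np.linalg.inv(JTJ)
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        return np.full(len(p), np.nan)
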