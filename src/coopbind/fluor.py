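"""Fluorescence titration curves under chelator competition.

A peptide carrying a single fluorescent reporter (Tyr or Trp in the binding
loop) is titrated with metal in the presence of a competing chelator that
buffers the free-metal concentration.  The baseline-subtracted intensity
change follows a one-site binding isotherm

    dF/C_P = dPhi * K1 [M] / (1 + K1 [M])

or, for a two-site peptide, the dinuclear form

    dF/C_P = (dPhi1 K1 [M] + dPhi2 K1 K2 [M]^2) / (1 + K1 [M] + K1 K2 [M]^2)

with [M] the *free* metal concentration obtained from the full speciation
(chelator complexes plus peptide complexes) at each titration point.
Fitting iterates the association constants as log10 values with the signal
amplitudes profiled out linearly, from a deterministic multi-start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import speciation as spec
from ._fitting import FitOptions, FitResult, ParameterEstimate, covariance_stderr, multistart_varpro

__all__ = [
    "FluorDesign",
    "FluorTitrationSeries",
    "FluorModelParams",
    "response_one_site",
    "response_two_site",
    "delta_F",
    "predict_series",
    "fit_series",
]


@dataclass(frozen=True)
class FluorDesign:
    """Cuvette composition and titrant schedule of one fluorescence titration.

    ``metal_totals`` are the cumulative total metal concentrations (mol/L) in
    the cuvette at each acquisition, already accounting for dilution.  If the
    per-step ``added_volumes_uL`` and ``initial_volume_uL`` are supplied, the
    peptide and chelator totals are rescaled per point by the dilution factor
    V0/V_i; otherwise dilution is assumed negligible.
    """

    peptide_total: float
    chelator_total: float
    pH: float
    metal_totals: tuple[float, ...]
    temperature: float = 298.0
    emission_wavelength_nm: float | None = None
    initial_volume_uL: float | None = None
    added_volumes_uL: tuple[float, ...] | None = None

    def __post_init__(self):
        totals = np.asarray(self.metal_totals, dtype=float)
        if np.any(np.diff(totals) < 0):
            raise ValueError("metal totals must be non-decreasing along the series")
        if np.any(totals < 0):
            raise ValueError("metal totals must be >= 0")
        if (self.added_volumes_uL is None) != (self.initial_volume_uL is None):
            raise ValueError("added_volumes_uL and initial_volume_uL must be given together")
        if self.added_volumes_uL is not None and len(self.added_volumes_uL) != len(self.metal_totals):
            raise ValueError("added_volumes_uL must have one entry per titration point")

    def dilution_factors(self) -> np.ndarray:
        """V0/V_i per point (all ones when no volumes were recorded)."""
        n = len(self.metal_totals)
        if self.added_volumes_uL is None:
            return np.ones(n)
        cum = np.cumsum(np.asarray(self.added_volumes_uL, dtype=float))
        return self.initial_volume_uL / (self.initial_volume_uL + cum)

    def totals_per_point(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(metal, chelator, peptide) total concentrations at every point."""
        f = self.dilution_factors()
        m = np.asarray(self.metal_totals, dtype=float)
        return m, self.chelator_total * f, self.peptide_total * f


@dataclass(frozen=True)
class FluorTitrationSeries:
    """Observed intensities along a titration; first point is the baseline."""

    design: FluorDesign
    intensities: tuple[float, ...]

    def __post_init__(self):
        if len(self.intensities) != len(self.design.metal_totals):
            raise ValueError("one intensity per titration point required")


@dataclass(frozen=True)
class FluorModelParams:
    """Binding-isotherm parameters; amplitudes are signed signal per mol/L."""

    kind: str  # "one-site" | "two-site"
    K1: float
    amp1: float
    K2: float | None = None
    amp2: float | None = None

    def __post_init__(self):
        if self.kind not in ("one-site", "two-site"):
            raise ValueError("kind must be 'one-site' or 'two-site'")
        if self.K1 <= 0:
            raise ValueError("K1 must be positive")
        if self.kind == "two-site":
            if self.K2 is None or self.K2 <= 0:
                raise ValueError("two-site model requires K2 > 0")
            if self.amp2 is None:
                raise ValueError("two-site model requires amp2")

    def peptide_model(self) -> spec.PeptideBindingModel:
        if self.kind == "one-site":
            return spec.PeptideBindingModel(1, self.K1)
        return spec.PeptideBindingModel(2, self.K1, self.K2)


def response_one_site(free_M, K1: float, amp: float):
    """dF/C_P of the 1:1 isotherm at free-metal concentration ``free_M``."""
    free_M = np.asarray(free_M, dtype=float)
    x = K1 * free_M
    return amp * x / (1.0 + x)


def response_two_site(free_M, K1: float, K2: float, amp1: float, amp2: float):
    """dF/C_P of the dinuclear isotherm; reduces to the 1:1 form as K2 -> 0."""
    free_M = np.asarray(free_M, dtype=float)
    x1 = K1 * free_M
    x2 = K1 * K2 * free_M**2
    return (amp1 * x1 + amp2 * x2) / (1.0 + x1 + x2)


def delta_F(series: FluorTitrationSeries) -> np.ndarray:
    """Baseline-subtracted responses dF_i = F_0 - F_i (quenching positive).

    The first point must be the metal-free baseline.
    """
    if series.design.metal_totals[0] != 0.0:
        raise ValueError("first titration point must be the metal-free baseline")
    F = np.asarray(series.intensities, dtype=float)
    return F[0] - F


def _make_free_metal_solver(design, chelator):
    """Per-design speciation solver; warm-starts from the previous solution
    so repeated solves along an optimizer trajectory converge in few steps."""
    m, l, p = design.totals_per_point()
    cache: dict[str, np.ndarray | None] = {"x0": None}

    def solve(peptide):
        free, _, _, _ = spec.solve_speciation_batch(
            m, l, p, design.pH, chelator, peptide, x0=cache["x0"]
        )
        cache["x0"] = free
        return free[:, 0]

    return solve


def _free_metal_profile(peptide, design, chelator, options=None):
    m, l, p = design.totals_per_point()
    free, _, _, _ = spec.solve_speciation_batch(
        m, l, p, design.pH, chelator, peptide, options
    )
    return free[:, 0]


def predict_series(
    params: FluorModelParams,
    design: FluorDesign,
    chelator: spec.ChelatorModel | None = None,
) -> np.ndarray:
    """Predicted dF at every design point (speciation + isotherm response)."""
    if chelator is None and design.chelator_total > 0:
        warnings.warn("chelator total > 0 but no chelator model given", stacklevel=2)
    try:
        free_M = _free_metal_profile(params.peptide_model(), design, chelator)
    except spec.SpeciationError as err:
        raise spec.SpeciationError(
            f"speciation failed while predicting titration point {err.point_index}",
            residuals=err.residuals,
            point_index=err.point_index,
        ) from err
    _, _, C_P = design.totals_per_point()
    if params.kind == "one-site":
        return response_one_site(free_M, params.K1, params.amp1) * C_P
    return response_two_site(free_M, params.K1, params.K2, params.amp1, params.amp2) * C_P


def _design_fn_factory(kind, design, chelator):
    """Basis-matrix builder for the separable least-squares fit."""
    _, _, C_P = design.totals_per_point()
    n = len(C_P)
    solve = _make_free_metal_solver(design, chelator)

    def design_fn(theta):
        if kind == "one-site":
            peptide = spec.PeptideBindingModel(1, 10.0 ** theta[0])
        else:
            peptide = spec.PeptideBindingModel(2, 10.0 ** theta[0], 10.0 ** theta[1])
        free_M = solve(peptide)
        x1 = peptide.K1 * free_M
        if kind == "one-site":
            B = (x1 / (1.0 + x1) * C_P)[:, None]
        else:
            x2 = peptide.K1 * peptide.K2 * free_M**2
            den = 1.0 + x1 + x2
            B = np.column_stack([x1 / den * C_P, x2 / den * C_P])
        return B, np.zeros(n)

    return design_fn


def _fit_single(series, kind, chelator, options) -> FitResult:
    y = delta_F(series)
    min_points = 4 if kind == "one-site" else 6
    if len(y) < min_points:
        raise ValueError(f"{kind} fit requires >= {min_points} points, got {len(y)}")
    design_fn = _design_fn_factory(kind, series.design, chelator)
    n_theta = 1 if kind == "one-site" else 2
    theta, amps, rss, converged = multistart_varpro(design_fn, y, n_theta, options)
    stderr = covariance_stderr(design_fn, y, theta, amps)
    if kind == "one-site":
        names = ["log10K1", "amp1"]
    else:
        names = ["log10K1", "log10K2", "amp1", "amp2"]
    values = np.concatenate([theta, amps])
    params = {nm: ParameterEstimate(float(v), float(s)) for nm, v, s in zip(names, values, stderr)}
    for i, knm in enumerate(["K1", "K2"][:n_theta]):
        K = 10.0 ** theta[i]
        se = K * np.log(10.0) * stderr[i]
        params[knm] = ParameterEstimate(float(K), float(se))
    result = FitResult(
        parameters=params,
        rss=rss,
        n_points=len(y),
        converged=converged,
        stderr_source="covariance",
    )
    if kind == "two-site" and options.model_check:
        _nested_model_check(series, chelator, options, result)
    return result


def _nested_model_check(series, chelator, options, result):
    """F-ratio check: flag a two-site fit that a one-site model explains."""
    from scipy.stats import f as f_dist

    y = delta_F(series)
    design_fn1 = _design_fn_factory("one-site", series.design, chelator)
    _, _, rss1, _ = multistart_varpro(design_fn1, y, 1, options)
    rss2 = result.rss
    dof2 = len(y) - 4
    if dof2 <= 0 or rss2 <= 0:
        return
    F = max((rss1 - rss2) / 2.0, 0.0) / (rss2 / dof2)
    p = float(f_dist.sf(F, 2, dof2))
    result.diagnostics["one_site_vs_two_site_F"] = float(F)
    result.diagnostics["one_site_vs_two_site_p"] = p
    if p > 0.05:
        result.diagnostics["warning"] = (
            "two-site model not supported over one-site (F-ratio p > 0.05); "
            "the fit may be unidentifiable"
        )


def fit_series(
    replicates,
    kind: str,
    chelator: spec.ChelatorModel | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit one or more replicate titrations; replicates are fitted independently.

    With >= 2 replicates the reported estimate of every parameter is the
    replicate mean +/- sample SD; with a single series the asymptotic
    covariance standard errors are reported (flagged in ``stderr_source``).
    """
    options = options or FitOptions()
    if isinstance(replicates, FluorTitrationSeries):
        replicates = [replicates]
    fits = [_fit_single(s, kind, chelator, options) for s in replicates]
    if len(fits) == 1:
        return fits[0]
    names = list(fits[0].parameters)
    per_rep = [{nm: f.parameters[nm].value for nm in names} for f in fits]
    parameters = {}
    for nm in names:
        vals = np.array([pr[nm] for pr in per_rep])
        parameters[nm] = ParameterEstimate(float(vals.mean()), float(vals.std(ddof=1)))
    diagnostics = {"replicate_diagnostics": [f.diagnostics for f in fits]}
    return FitResult(
        parameters=parameters,
        rss=float(sum(f.rss for f in fits)),
        n_points=sum(f.n_points for f in fits),
        converged=all(f.converged for f in fits),
        stderr_source="replicate-sd",
        per_replicate=per_rep,
        diagnostics=diagnostics,
    )
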