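"""ITC heat models and fitters for the reverse (peptide-into-metal) titration.

The calorimeter cell (volume V0) holds metal plus competing chelator; the
peptide is injected from the syringe.  In a perfusion cell each injection
displaces an equal volume, so with cumulative injected volume d_j the total
concentration of an injected component is C_syr (d_j/V0)/(1 + d_j/(2 V0)) and
of an initially present component C0 (1 - d_j/(2 V0))/(1 + d_j/(2 V0)).

Per injection the model heat is Q_j = sum_i dH_i dn_i over the complexes
formed, with dn taken over the fixed active volume V0.  For a cooperative
two-site peptide,

    Q_j = dH_I dn(MP_I) + dH_II dn(MP_II) + (dH_I + dH_II + dH_c) dn(M2P)

where the mononuclear pool [MP] is partitioned between the site-I-bound and
site-II-bound forms in the ratio K_I : K_II, and dH_c is the molar enthalpy
of the inter-site cooperative effect.  Speciation at every injection uses the
macroscopic constants (K1 = K_I + K_II, K2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import speciation as spec
from . import thermo
from ._fitting import FitOptions, FitResult, ParameterEstimate, covariance_stderr, multistart_varpro

__all__ = [
    "ITCDesign",
    "ITCSeries",
    "ITCModelParams",
    "ITCFitResult",
    "UCAL_TO_UJ",
    "injection_concentrations",
    "predict_heats_one_site",
    "predict_heats_two_site",
    "subtract_blank",
    "fit_itc_one_site",
    "fit_itc_two_site",
]

UCAL_TO_UJ = 4.184


@dataclass(frozen=True)
class ITCDesign:
    """Cell composition, syringe load and injection schedule (volumes in uL)."""

    cell_volume_uL: float
    syringe_peptide_concentration: float
    cell_metal_concentration: float
    cell_chelator_concentration: float
    injection_volumes_uL: tuple[float, ...]
    temperature: float = 298.0
    pH: float = 6.0

    def __post_init__(self):
        if self.cell_volume_uL <= 0 or any(v <= 0 for v in self.injection_volumes_uL):
            raise ValueError("volumes must be positive")
        if min(self.syringe_peptide_concentration, self.cell_metal_concentration,
               self.cell_chelator_concentration) < 0:
            raise ValueError("concentrations must be >= 0")
        if sum(self.injection_volumes_uL) > 0.5 * self.cell_volume_uL:
            warnings.warn(
                "cumulative injected volume exceeds half the cell volume; the "
                "displacement model becomes inaccurate",
                stacklevel=2,
            )

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes_uL)


@dataclass(frozen=True)
class ITCSeries:
    """Integrated per-injection heats with a unit tag ('uJ' or 'ucal')."""

    heats: tuple[float, ...]
    unit: str = "uJ"
    blank: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.unit not in ("uJ", "ucal"):
            raise ValueError("unit must be 'uJ' or 'ucal'")
        if self.blank is not None and len(self.blank) != len(self.heats):
            raise ValueError("blank must have one heat per injection")

    def heats_uJ(self) -> np.ndarray:
        factor = UCAL_TO_UJ if self.unit == "ucal" else 1.0
        return np.asarray(self.heats, dtype=float) * factor


@dataclass(frozen=True)
class ITCModelParams:
    """Microscopic constants/enthalpies of the cooperative two-site heat model."""

    KI: float
    KII: float
    K2: float
    dH_I: float
    dH_II: float
    dH_c: float

    def __post_init__(self):
        if min(self.KI, self.KII, self.K2) <= 0:
            raise ValueError("binding constants must be positive")

    @property
    def K1(self) -> float:
        return self.KI + self.KII

    def micro(self) -> thermo.MicroscopicConstants:
        beta2 = self.K1 * self.K2
        return thermo.MicroscopicConstants(
            KI=self.KI, KII=self.KII, KI_II=beta2 / self.KII, KII_I=beta2 / self.KI
        )


def injection_concentrations(design: ITCDesign) -> dict[str, np.ndarray]:
    """Component totals in the active cell volume after each injection.

    Returns arrays of length n_injections for keys 'peptide', 'metal',
    'chelator'; the pre-injection state is the cell composition itself.
    """
    d = np.cumsum(np.asarray(design.injection_volumes_uL, dtype=float))
    V0 = design.cell_volume_uL
    inj_factor = (d / V0) / (1.0 + d / (2.0 * V0))
    cell_factor = (1.0 - d / (2.0 * V0)) / (1.0 + d / (2.0 * V0))
    return {
        "peptide": design.syringe_peptide_concentration * inj_factor,
        "metal": design.cell_metal_concentration * cell_factor,
        "chelator": design.cell_chelator_concentration * cell_factor,
    }


def _make_trajectory_solver(design, chelator):
    """Per-design speciation solver over the injection sequence (j=0 included);
    warm-starts from the previous solution during optimizer trajectories."""
    totals = injection_concentrations(design)
    m = np.concatenate([[design.cell_metal_concentration], totals["metal"]])
    l = np.concatenate([[design.cell_chelator_concentration], totals["chelator"]])
    p = np.concatenate([[0.0], totals["peptide"]])
    cache: dict[str, np.ndarray | None] = {"x0": None}

    def solve(peptide):
        try:
            free, species, labels, _ = spec.solve_speciation_batch(
                m, l, p, design.pH, chelator, peptide, x0=cache["x0"]
            )
        except spec.SpeciationError as err:
            raise spec.SpeciationError(
                f"speciation failed at injection {err.point_index}",
                residuals=err.residuals,
                point_index=err.point_index,
            ) from err
        cache["x0"] = free
        idx = {lab: i for i, lab in enumerate(labels)}
        mp = species[:, idx["MP"]]
        m2p = species[:, idx["M2P"]] if "M2P" in idx else np.zeros_like(mp)
        return mp, m2p

    return solve


def _species_trajectory(design, peptide, chelator):
    """Concentration trajectories of MP (and M2P), including the j=0 state."""
    return _make_trajectory_solver(design, chelator)(peptide)


def _dn_uJ_scale(design):
    # dn over active volume: moles = V0[uL]*1e-6 * conc[M]; heats in uJ with
    # dH in kJ/mol: Q_uJ = dH * 1e9 uJ/mol * moles = dH * V0 * dconc * 1e3
    return design.cell_volume_uL * 1e3


def predict_heats_one_site(
    design: ITCDesign,
    K: float,
    dH: float,
    chelator: spec.ChelatorModel | None = None,
) -> np.ndarray:
    """Per-injection heats (uJ) of the 1:1 model, Q_j = dH * dn(MP)_j."""
    peptide = spec.PeptideBindingModel(1, K)
    mp, _ = _species_trajectory(design, peptide, chelator)
    return dH * np.diff(mp) * _dn_uJ_scale(design)


def _two_site_bases(design, KI, KII, K2, chelator, solver=None):
    """Delta-n bases (uJ per unit enthalpy) of the three heat channels."""
    peptide = spec.PeptideBindingModel(2, KI + KII, K2)
    if solver is None:
        solver = _make_trajectory_solver(design, chelator)
    mp, m2p = solver(peptide)
    fI = KI / (KI + KII)
    scale = _dn_uJ_scale(design)
    dn_I = np.diff(mp) * fI * scale
    dn_II = np.diff(mp) * (1.0 - fI) * scale
    dn_2 = np.diff(m2p) * scale
    return dn_I, dn_II, dn_2


def predict_heats_two_site(
    design: ITCDesign,
    params: ITCModelParams,
    chelator: spec.ChelatorModel | None = None,
) -> np.ndarray:
    """Per-injection heats (uJ) of the cooperative two-site model."""
    dn_I, dn_II, dn_2 = _two_site_bases(design, params.KI, params.KII, params.K2, chelator)
    return params.dH_I * dn_I + params.dH_II * dn_II + (params.dH_I + params.dH_II + params.dH_c) * dn_2


def subtract_blank(sample: ITCSeries, blank: ITCSeries) -> ITCSeries:
    """Element-wise dilution/mixing-heat correction; units must match."""
    if sample.unit != blank.unit:
        raise ValueError(f"unit mismatch: sample in {sample.unit}, blank in {blank.unit}")
    if len(sample.heats) != len(blank.heats):
        raise ValueError("sample and blank must have equal numbers of injections")
    corrected = tuple(s - b for s, b in zip(sample.heats, blank.heats))
    return ITCSeries(heats=corrected, unit=sample.unit)


def _corrected_heats(series: ITCSeries) -> np.ndarray:
    if series.blank is not None:
        series = subtract_blank(series, ITCSeries(series.blank, series.unit))
    return series.heats_uJ()


def _usable(y, skip_first):
    return np.arange(1 if skip_first else 0, len(y))


def fit_itc_one_site(
    series: ITCSeries,
    design: ITCDesign,
    chelator: spec.ChelatorModel | None = None,
    options: FitOptions | None = None,
    skip_first_injection: bool = True,
) -> FitResult:
    """Fit (K, dH) of the 1:1 model to blank-corrected heats.

    The (small) first injection is excluded by default.  dH is profiled out
    linearly; log10 K is scanned from a deterministic multi-start.
    """
    options = options or FitOptions()
    y = _corrected_heats(series)
    if len(y) != design.n_injections:
        raise ValueError("series length does not match the injection schedule")
    keep = _usable(y, skip_first_injection)
    if len(keep) < 6:
        raise ValueError("at least 6 usable injections are required")

    solver = _make_trajectory_solver(design, chelator)
    scale = _dn_uJ_scale(design)

    def design_fn(theta):
        mp, _ = solver(spec.PeptideBindingModel(1, 10.0 ** theta[0]))
        q = np.diff(mp) * scale
        return q[keep][:, None], np.zeros(len(keep))

    theta, a, rss, converged = multistart_varpro(design_fn, y[keep], 1, options)
    stderr = covariance_stderr(design_fn, y[keep], theta, a)
    K = 10.0 ** theta[0]
    params = {
        "log10K": ParameterEstimate(float(theta[0]), float(stderr[0])),
        "K": ParameterEstimate(float(K), float(K * np.log(10.0) * stderr[0])),
        "dH": ParameterEstimate(float(a[0]), float(stderr[1])),
    }
    result = FitResult(params, rss, len(keep), converged)
    c_value = K * design.cell_metal_concentration
    result.diagnostics["c_value"] = float(c_value)
    if not (1.0 <= c_value <= 1e4):
        result.diagnostics["warning"] = (
            f"c-value {c_value:.3g} outside the informative 1-1e4 window; "
            "K may be poorly identified"
        )
    if np.max(np.abs(y[keep])) < 1e-12 or abs(a[0]) < 1e-9:
        result.diagnostics["unidentifiable"] = "heats ~ 0: dH -> 0 and K is unidentifiable"
    return result


@dataclass
class ITCFitResult:
    """Two-site ITC fit: fitted (KI, dH_I, K2, dH_c), fixed (KII, dH_II) echoed.

    Derived quantities (K1, microscopic set, cooperativity, entropy terms) are
    recomputed from the estimates on access, never stored.
    """

    fit: FitResult
    fixed_KII: float
    fixed_dH_II: float
    temperature: float = 298.0

    @property
    def params(self) -> ITCModelParams:
        return ITCModelParams(
            KI=self.fit.value("KI"),
            KII=self.fixed_KII,
            K2=self.fit.value("K2"),
            dH_I=self.fit.value("dH_I"),
            dH_II=self.fixed_dH_II,
            dH_c=self.fit.value("dH_c"),
        )

    @property
    def K1(self) -> float:
        return self.params.K1

    def micro(self) -> thermo.MicroscopicConstants:
        return self.params.micro()

    def cooperativity(self) -> thermo.CooperativityResult:
        return thermo.cooperativity(self.micro(), thermo.Conditions(self.temperature))

    def entropy_terms(self) -> dict[str, float]:
        """T dS of site I, site II and the cooperative step, kJ/mol."""
        cond = thermo.Conditions(self.temperature)
        p = self.params
        coop = self.cooperativity()
        return {
            "TdS_I": thermo.entropy_term(p.KI, p.dH_I, cond),
            "TdS_II": thermo.entropy_term(p.KII, p.dH_II, cond),
            "TdS_c": thermo.entropy_term(coop.Kc, p.dH_c, cond),
        }


def fit_itc_two_site(
    series: ITCSeries,
    design: ITCDesign,
    fixed: tuple[float, float],
    chelator: spec.ChelatorModel | None = None,
    options: FitOptions | None = None,
    skip_first_injection: bool = True,
    sensitivity: bool = False,
) -> ITCFitResult:
    """Fit (KI, dH_I, K2, dH_c) with (KII, dH_II) fixed from a one-site peptide.

    (dH_I, dH_c) are profiled out linearly given (log10 KI, log10 K2); the
    macroscopic K1 = KI + KII and all thermodynamic terms are derived on the
    result object.  With ``sensitivity=True`` the fit is repeated with the
    fixed values perturbed by +10% and the relative KI shift recorded.
    """
    options = options or FitOptions()
    KII, dH_II = fixed
    if KII <= 0:
        raise ValueError("fixed KII must be positive")
    y = _corrected_heats(series)
    if len(y) != design.n_injections:
        raise ValueError("series length does not match the injection schedule")
    keep = _usable(y, skip_first_injection)
    if len(keep) < 8:
        raise ValueError("at least 8 usable injections are required")

    solver = _make_trajectory_solver(design, chelator)

    def design_fn(theta):
        dn_I, dn_II, dn_2 = _two_site_bases(
            design, 10.0 ** theta[0], KII, 10.0 ** theta[1], chelator, solver=solver
        )
        offset = dH_II * (dn_II + dn_2)
        B = np.column_stack([dn_I + dn_2, dn_2])
        return B[keep], offset[keep]

    theta, a, rss, converged = multistart_varpro(design_fn, y[keep], 2, options)
    stderr = covariance_stderr(design_fn, y[keep], theta, a)
    KI = 10.0 ** theta[0]
    K2 = 10.0 ** theta[1]
    params = {
        "log10KI": ParameterEstimate(float(theta[0]), float(stderr[0])),
        "log10K2": ParameterEstimate(float(theta[1]), float(stderr[1])),
        "KI": ParameterEstimate(float(KI), float(KI * np.log(10.0) * stderr[0])),
        "K2": ParameterEstimate(float(K2), float(K2 * np.log(10.0) * stderr[1])),
        "dH_I": ParameterEstimate(float(a[0]), float(stderr[2])),
        "dH_c": ParameterEstimate(float(a[1]), float(stderr[3])),
    }
    fit = FitResult(params, rss, len(keep), converged)
    # KI/K2 correlation from the profiled 2x2 normal matrix
    def profiled(th):
        B, offset = design_fn(th)
        resid = y[keep] - offset
        coef, *_ = np.linalg.lstsq(B, resid, rcond=None)
        return resid - B @ coef

    h = 1e-6
    g0 = profiled(theta)
    Jt = np.column_stack([(profiled(theta + h * e) - g0) / h for e in np.eye(2)])
    JTJ = Jt.T @ Jt
    denom = np.sqrt(JTJ[0, 0] * JTJ[1, 1])
    if denom > 0:
        fit.diagnostics["KI_K2_correlation"] = float(JTJ[0, 1] / denom)
    result = ITCFitResult(fit, KII, dH_II, design.temperature)
    if sensitivity:
        pert = fit_itc_two_site(
            series, design, (1.1 * KII, 1.1 * dH_II), chelator, options,
            skip_first_injection, sensitivity=False,
        )
        fit.diagnostics["KI_shift_for_10pct_fixed_perturbation"] = float(
            pert.fit.value("KI") / KI - 1.0
        )
    return result
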