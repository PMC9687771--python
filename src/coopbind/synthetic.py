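"""Synthetic titration generator mirroring the study's experimental designs.

Every scenario couples a published experimental design (cuvette or cell
composition, titrant schedule) with the published best-estimate binding
constants and enthalpies as ground truth, so that the full analysis chain —
speciation, fluorescence fit, one-site ITC fit, fixed-site two-site ITC fit,
microscopic-constant derivation — can be exercised end to end and checked
for parameter recovery without access to the raw instrument curves.

Designs emulated (all at I ~ 0.1 M, T = 298 K):

* fluorescence, one-site and two-site peptides: 10 uM peptide, 500 uM
  iminodiacetate (IDA), pH 6;
* fluorescence, phosphorylated two-site peptides: 5 uM peptide / 500 uM IDA
  or 0.5 uM peptide / 50 uM IDA, pH 6 and 7;
* ITC (reverse titration, peptide injected): 200 uL cell holding uranyl +
  IDA at a 1:2 ratio, 1 mM peptide syringe for one-site peptides (0.1 mM
  metal in the cell) and 2 mM for two-site peptides (0.2 mM metal), one
  0.4 uL then nineteen 2 uL injections.

Measurement noise is Gaussian; magnitudes are package defaults (1% of the
isotherm amplitude for fluorescence, 0.5 uJ per injection for ITC) since the
source experiments do not report them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import fluor as fl
from . import itc as itcmod
from . import speciation as spec
from ._fitting import FitOptions
from .config import default_chelator

__all__ = [
    "NoiseModel",
    "FluorScenario",
    "ITCScenario",
    "scenario_library",
    "fluor_titration_schedule",
    "gen_fluor",
    "gen_itc",
    "recovery_experiment",
]

#: baseline fluorescence intensity of the generator, arbitrary units
BASELINE_INTENSITY = 1000.0
#: default per-injection dilution/mixing heat, uJ
DEFAULT_DILUTION_HEAT = -1.0


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise; 'relative' scales sd by the signal amplitude."""

    kind: str = "relative"
    sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("absolute", "relative"):
            raise ValueError("kind must be 'absolute' or 'relative'")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class FluorScenario:
    name: str
    design: fl.FluorDesign
    params: fl.FluorModelParams


@dataclass(frozen=True)
class ITCScenario:
    """kind 'one-site' uses (KII, dH_II) of params as the 1:1 truth."""

    name: str
    kind: str
    design: itcmod.ITCDesign
    params: itcmod.ITCModelParams


def fluor_titration_schedule(
    peptide_total: float,
    chelator_total: float,
    n_points: int = 20,
    lo: float = 0.04,
    hi: float = 4.0,
) -> tuple[float, ...]:
    """Metal-free baseline plus log-spaced totals up to ``hi`` binding
    equivalents of the combined ligand pool (peptide + chelator)."""
    capacity = peptide_total + chelator_total
    grid = np.geomspace(lo, hi, n_points - 1) * capacity
    return tuple(np.concatenate([[0.0], grid]))


def _fluor_design(C_P, C_I, pH):
    return fl.FluorDesign(
        peptide_total=C_P,
        chelator_total=C_I,
        pH=pH,
        metal_totals=fluor_titration_schedule(C_P, C_I),
    )


_ITC_INJECTIONS = (0.4,) + (2.0,) * 19


def _itc_design(syringe, metal, ida, pH=6.0):
    return itcmod.ITCDesign(
        cell_volume_uL=200.0,
        syringe_peptide_concentration=syringe,
        cell_metal_concentration=metal,
        cell_chelator_concentration=ida,
        injection_volumes_uL=_ITC_INJECTIONS,
        pH=pH,
    )


def _one_site_fluor(name, K1, C_P=1e-5, C_I=5e-4, pH=6.0):
    amp = 0.8 * BASELINE_INTENSITY / C_P  # quench to 20% of baseline at saturation
    return FluorScenario(
        name, _fluor_design(C_P, C_I, pH), fl.FluorModelParams("one-site", K1, amp)
    )


def _two_site_fluor(name, K1, K2, C_P=1e-5, C_I=5e-4, pH=6.0):
    amp2 = 0.8 * BASELINE_INTENSITY / C_P
    return FluorScenario(
        name,
        _fluor_design(C_P, C_I, pH),
        fl.FluorModelParams("two-site", K1, 0.5 * amp2, K2, amp2),
    )


def _one_site_itc(name, K, dH):
    params = itcmod.ITCModelParams(KI=1.0, KII=K, K2=1.0, dH_I=0.0, dH_II=dH, dH_c=0.0)
    return ITCScenario(name, "one-site", _itc_design(1e-3, 1e-4, 2e-4), params)


def _two_site_itc(name, K1, K2, KII, dH_I, dH_II, dH_c):
    params = itcmod.ITCModelParams(
        KI=K1 - KII, KII=KII, K2=K2, dH_I=dH_I, dH_II=dH_II, dH_c=dH_c
    )
    return ITCScenario(name, "two-site", _itc_design(2e-3, 2e-4, 4e-4), params)


def scenario_library() -> dict[str, FluorScenario | ITCScenario]:
    """Named scenarios keyed 'fluor/<peptide>[ pH7]' and 'itc/<peptide>'.

    True constants are the published fluorescence-derived values for the
    fluorescence scenarios and the calorimetry-derived values (with the
    matching one-site (KII, dH_II)) for the ITC scenarios.
    """
    lib: dict[str, FluorScenario | ITCScenario] = {}
    for sc in [
        _one_site_fluor("CaM Y II", 3.7e6),
        _one_site_fluor("CaM1 Y II", 3.5e6),
        _one_site_fluor("CaM YW II", 5.1e6),
        _one_site_fluor("CaM1 YW II", 5.9e6),
        _one_site_fluor("CaM1 Y II P", 2.1e7),
        _one_site_fluor("CaM1 Y II P pH7", 1.8e8, pH=7.0),
        _two_site_fluor("CaM Y I-II", 3.5e7, 7.4e6),
        _two_site_fluor("CaM1 Y I-II", 3.0e7, 7.0e6),
        _two_site_fluor("CaM YW I-II", 7.4e7, 9.7e6),
        _two_site_fluor("CaM1 YW I-II", 7.8e7, 9.4e6),
        _two_site_fluor("CaM1 Y I-II P", 3.6e8, 7.8e7, C_P=5e-6),
        _two_site_fluor("CaM1 Y I-II P pH7", 1.0e11, 7.1e8, C_P=5e-6, pH=7.0),
        _two_site_fluor("CaM1 YW I-II P", 3.8e8, 1.3e8, C_P=5e-7, C_I=5e-5),
        _two_site_fluor("CaM1 YW I-II P pH7", 6.0e11, 5.1e9, C_P=5e-7, C_I=5e-5, pH=7.0),
    ]:
        lib[f"fluor/{sc.name}"] = sc
    for sc in [
        _one_site_itc("CaM Y II", 4.2e6, -2.0),
        _one_site_itc("CaM1 Y II", 3.9e6, -3.5),
        _one_site_itc("CaM YW II", 4.9e6, -8.9),
        _one_site_itc("CaM1 YW II", 9.0e6, -15.0),
        _two_site_itc("CaM Y I-II", 4.4e7, 5.7e6, 4.2e6, -40.2, -2.0, 25.0),
        _two_site_itc("CaM1 Y I-II", 4.5e7, 6.5e6, 3.9e6, -26.1, -3.5, 22.0),
        _two_site_itc("CaM YW I-II", 6.3e7, 7.8e6, 4.9e6, -34.8, -8.9, 3.8),
        _two_site_itc("CaM1 YW I-II", 7.0e7, 8.5e6, 9.0e6, -26.1, -15.0, 8.9),
    ]:
        lib[f"itc/{sc.name}"] = sc
    return lib


def _fluor_noise_sd(scenario: FluorScenario, noise: NoiseModel) -> float:
    if noise.kind == "absolute":
        return noise.sd
    amp = scenario.params.amp2 if scenario.params.kind == "two-site" else scenario.params.amp1
    return noise.sd * abs(amp) * scenario.design.peptide_total


def gen_fluor(
    scenario: FluorScenario,
    noise: NoiseModel = NoiseModel(),
    n_replicates: int = 1,
    chelator: spec.ChelatorModel | None = None,
) -> list[fl.FluorTitrationSeries]:
    """Replicate intensity series; noise-free curves equal ``predict_series``.

    Gaussian noise is added to every recorded intensity (baseline included);
    replicates differ only by their noise stream.
    """
    chelator = chelator or default_chelator()
    dF = fl.predict_series(scenario.params, scenario.design, chelator)
    sd = _fluor_noise_sd(scenario, noise)
    rng = np.random.default_rng(noise.seed)
    out = []
    for _ in range(n_replicates):
        F = BASELINE_INTENSITY - dF + rng.normal(0.0, sd, size=len(dF)) if sd > 0 else BASELINE_INTENSITY - dF
        out.append(fl.FluorTitrationSeries(scenario.design, tuple(float(v) for v in F)))
    return out


def _itc_model_heats(scenario: ITCScenario, chelator) -> np.ndarray:
    if scenario.kind == "one-site":
        return itcmod.predict_heats_one_site(
            scenario.design, scenario.params.KII, scenario.params.dH_II, chelator
        )
    return itcmod.predict_heats_two_site(scenario.design, scenario.params, chelator)


def _itc_noise_sd(heats: np.ndarray, noise: NoiseModel) -> float:
    if noise.kind == "absolute":
        return noise.sd
    return noise.sd * float(np.max(np.abs(heats)))


def gen_itc(
    scenario: ITCScenario,
    noise: NoiseModel = NoiseModel("absolute", 0.5),
    dilution_heat: float = DEFAULT_DILUTION_HEAT,
    n_replicates: int = 1,
    chelator: spec.ChelatorModel | None = None,
) -> list[itcmod.ITCSeries]:
    """Replicate heat series (uJ) with paired blanks.

    sample = model + dilution_heat + noise; blank = dilution_heat +
    independent noise, stored on the series so ``subtract_blank`` recovers
    the model heats in expectation.
    """
    chelator = chelator or default_chelator()
    q = _itc_model_heats(scenario, chelator)
    sd = _itc_noise_sd(q, noise)
    rng = np.random.default_rng(noise.seed)
    out = []
    for _ in range(n_replicates):
        eps_s = rng.normal(0.0, sd, size=len(q)) if sd > 0 else 0.0
        eps_b = rng.normal(0.0, sd, size=len(q)) if sd > 0 else 0.0
        sample = q + dilution_heat + eps_s
        blank = np.full(len(q), dilution_heat) + eps_b
        out.append(
            itcmod.ITCSeries(
                heats=tuple(float(v) for v in sample),
                unit="uJ",
                blank=tuple(float(v) for v in blank),
            )
        )
    return out


def _truth_parameters(scenario) -> dict[str, float]:
    if isinstance(scenario, FluorScenario):
        t = {"K1": scenario.params.K1}
        if scenario.params.kind == "two-site":
            t["K2"] = scenario.params.K2
        return t
    if scenario.kind == "one-site":
        return {"K": scenario.params.KII, "dH": scenario.params.dH_II}
    return {
        "KI": scenario.params.KI,
        "K2": scenario.params.K2,
        "dH_I": scenario.params.dH_I,
        "dH_c": scenario.params.dH_c,
    }


def _fit_one_experiment(scenario, noise, chelator, options, n_replicates):
    options = replace(options, model_check=False)  # bulk simulation: skip diagnostics
    if isinstance(scenario, FluorScenario):
        reps = gen_fluor(scenario, noise, n_replicates, chelator)
        res = fl.fit_series(reps, scenario.params.kind, chelator, options)
        return {nm: res.parameters[nm] for nm in _truth_parameters(scenario)}
    reps = gen_itc(scenario, noise, n_replicates=n_replicates, chelator=chelator)
    if scenario.kind == "one-site":
        fits = [itcmod.fit_itc_one_site(s, scenario.design, chelator, options) for s in reps]
        names = ["K", "dH"]
    else:
        fixed = (scenario.params.KII, scenario.params.dH_II)
        fits = [
            itcmod.fit_itc_two_site(s, scenario.design, fixed, chelator, options).fit
            for s in reps
        ]
        names = ["KI", "K2", "dH_I", "dH_c"]
    from ._fitting import ParameterEstimate

    out = {}
    for nm in names:
        vals = np.array([f.value(nm) for f in fits])
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        out[nm] = ParameterEstimate(float(vals.mean()), sd)
    return out


def recovery_experiment(
    scenario,
    n_seeds: int = 50,
    noise: NoiseModel | None = None,
    n_replicates: int = 3,
    chelator: spec.ChelatorModel | None = None,
    options: FitOptions | None = None,
    base_seed: int = 0,
) -> dict:
    """Repeat generate-and-fit cycles and summarize parameter recovery.

    For every true parameter reports the median relative bias, the relative
    RMSE, and the coverage of the +/- 2 SD replicate interval around each
    experiment's mean.  Deterministic given (scenario, base_seed).
    """
    chelator = chelator or default_chelator()
    options = options or FitOptions()
    if noise is None:
        noise = NoiseModel() if isinstance(scenario, FluorScenario) else NoiseModel("absolute", 0.5)
    truth = _truth_parameters(scenario)
    estimates: dict[str, list] = {nm: [] for nm in truth}
    covered: dict[str, list] = {nm: [] for nm in truth}
    covered3: dict[str, list] = {nm: [] for nm in truth}
    for i in range(n_seeds):
        noise_i = replace(noise, seed=base_seed + 7919 * i)
        ests = _fit_one_experiment(scenario, noise_i, chelator, options, n_replicates)
        for nm, est in ests.items():
            estimates[nm].append(est.value)
            if est.stderr is not None and np.isfinite(est.stderr):
                err = abs(est.value - truth[nm])
                covered[nm].append(err <= 2.0 * est.stderr)
                covered3[nm].append(err <= 3.0 * est.stderr)
    summary = {"scenario": getattr(scenario, "name", "?"), "n_seeds": n_seeds, "parameters": {}}
    for nm, vals in estimates.items():
        vals = np.asarray(vals)
        scale = abs(truth[nm]) if truth[nm] != 0 else 1.0
        rel_err = (vals - truth[nm]) / scale
        entry = {
            "truth": truth[nm],
            "median_rel_bias": float(np.median(rel_err)),
            "rmse_rel": float(np.sqrt(np.mean(rel_err**2))),
            "coverage_2sd": float(np.mean(covered[nm])) if covered[nm] else float("nan"),
            "coverage_3sd": float(np.mean(covered3[nm])) if covered3[nm] else float("nan"),
        }
        if nm in ("K", "K1", "K2", "KI"):
            entry["median_abs_log10_bias"] = float(
                np.median(np.abs(np.log10(vals / truth[nm])))
            )
        summary["parameters"][nm] = entry
    return summary
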