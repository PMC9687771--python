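"""End-to-end analysis workflow and report assembly.

The staged protocol mirrors how microscopic thermodynamics are extracted
from the titrations: (1) fit the 1:1 model to each one-site (site-II-only)
peptide's ITC series, giving (K_II, dH_II); (2) fit the cooperative two-site
model to the matching two-site peptide with those values fixed, giving
(K_I, dH_I, K_2, dH_c); (3) derive the macroscopic K_1 = K_I + K_II, the
complete microscopic set, the cooperativity (Kc, ddG) and the entropy
decomposition; (4) report everything in one table whose derived cells are
always recomputed from the stored primary estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import itc as itcmod
from . import speciation as spec
from . import thermo
from ._fitting import FitOptions
from .config import AnalysisConfig

__all__ = ["ITCExperiment", "derive_row", "derive_table", "run_workflow"]

logger = logging.getLogger("coopbind")


@dataclass(frozen=True)
class ITCExperiment:
    """One labelled ITC dataset: design + observed series (+ pairing key)."""

    label: str
    design: itcmod.ITCDesign
    series: itcmod.ITCSeries
    one_site_label: str | None = None  # pairing for two-site experiments


def derive_row(
    K1: float,
    K2: float,
    KII: float,
    temperature: float = 298.0,
    dH_I: float | None = None,
    dH_II: float | None = None,
    dH_c: float | None = None,
) -> dict[str, float]:
    """All derived quantities from primary constants (K1, K2, KII[, dH...]).

    Returns the microscopic constants, auto-scaled Kd values, cooperativity
    (Kc, ddG in kJ/mol) and — when enthalpies are supplied — the TdS terms.
    """
    cond = thermo.Conditions(temperature)
    micro = thermo.micro_from_macro(thermo.MacroscopicConstants(K1, K2), KII)
    coop = thermo.cooperativity(micro, cond)
    kd1, kd1_unit = thermo.kd_from_K(K1)
    kd2, kd2_unit = thermo.kd_from_K(K2)
    row = {
        "K1": K1,
        "Kd1": kd1,
        "Kd1_unit": kd1_unit,
        "K2": K2,
        "Kd2": kd2,
        "Kd2_unit": kd2_unit,
        "KI": micro.KI,
        "KII": micro.KII,
        "KI_II": micro.KI_II,
        "KII_I": micro.KII_I,
        "Kc": coop.Kc,
        "ddG_kJ_mol": coop.ddG,
    }
    if dH_I is not None:
        row["dH_I"] = dH_I
        row["TdS_I"] = thermo.entropy_term(micro.KI, dH_I, cond)
    if dH_II is not None:
        row["dH_II"] = dH_II
        row["TdS_II"] = thermo.entropy_term(micro.KII, dH_II, cond)
    if dH_c is not None:
        row["dH_c"] = dH_c
        row["TdS_c"] = thermo.entropy_term(coop.Kc, dH_c, cond)
    return row


def derive_table(table: pd.DataFrame, temperature: float = 298.0) -> pd.DataFrame:
    """Vectorized :func:`derive_row` over rows (peptide, pH, K1, K2, KII, ...).

    Mirrors the published macroscopic -> microscopic table derivation.
    """
    required = {"peptide", "pH", "K1", "K2", "KII"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"derive table missing columns: {sorted(missing)}")
    rows = []
    for _, r in table.iterrows():
        derived = derive_row(
            float(r["K1"]),
            float(r["K2"]),
            float(r["KII"]),
            temperature,
            dH_I=float(r["dH_I"]) if "dH_I" in table.columns and pd.notna(r.get("dH_I")) else None,
            dH_II=float(r["dH_II"]) if "dH_II" in table.columns and pd.notna(r.get("dH_II")) else None,
            dH_c=float(r["dH_c"]) if "dH_c" in table.columns and pd.notna(r.get("dH_c")) else None,
        )
        rows.append({"peptide": r["peptide"], "pH": r["pH"], **derived})
    return pd.DataFrame(rows)


def run_workflow(
    config: AnalysisConfig,
    one_site_data: list[ITCExperiment],
    two_site_data: list[ITCExperiment],
) -> tuple[pd.DataFrame, dict]:
    """Run the fixed-stage protocol over paired one-site / two-site ITC data.

    Returns (report table, JSON-compatible results record).  Fails with an
    explicit message if a two-site experiment has no one-site partner to
    supply the fixed (KII, dH_II).
    """
    chelator = config.system.chelator.to_model() if config.system.chelator else None
    options = FitOptions(
        n_starts=config.fit.n_starts,
        log10K_bounds=config.fit.log10K_bounds,
        seed=config.fit.seed,
    )
    results: dict = {"one_site": {}, "two_site": {}}
    one_site_fits = {}
    for exp in one_site_data:
        fit = itcmod.fit_itc_one_site(
            exp.series, exp.design, chelator, options,
            skip_first_injection=config.fit.skip_first_injection,
        )
        one_site_fits[exp.label] = fit
        logger.info(
            "one-site %s: K = %.3e M^-1, dH = %.2f kJ/mol (rss %.3g)",
            exp.label, fit.value("K"), fit.value("dH"), fit.rss,
        )
        results["one_site"][exp.label] = {
            "K": fit.value("K"),
            "dH": fit.value("dH"),
            "stderr_K": fit.parameters["K"].stderr,
            "stderr_dH": fit.parameters["dH"].stderr,
            "rss": fit.rss,
            "diagnostics": fit.diagnostics,
        }
    report_rows = []
    for exp in two_site_data:
        if exp.one_site_label is None or exp.one_site_label not in one_site_fits:
            raise ValueError(
                f"two-site experiment '{exp.label}' needs fixed (KII, dH_II): pair it "
                "with a one-site experiment via one_site_label or fit the one-site data first"
            )
        ref = one_site_fits[exp.one_site_label]
        fixed = (ref.value("K"), ref.value("dH"))
        res = itcmod.fit_itc_two_site(
            exp.series, exp.design, fixed, chelator, options,
            skip_first_injection=config.fit.skip_first_injection,
        )
        p = res.params
        macro = thermo.macro_from_micro(res.micro())
        logger.info(
            "two-site %s: KI = %.3e, K2 = %.3e, dH_I = %.2f, dH_c = %.2f (rss %.3g)",
            exp.label, p.KI, p.K2, p.dH_I, p.dH_c, res.fit.rss,
        )
        results["two_site"][exp.label] = {
            "KI": p.KI, "K2": p.K2, "dH_I": p.dH_I, "dH_c": p.dH_c,
            "fixed_KII": p.KII, "fixed_dH_II": p.dH_II,
            "stderr": {nm: res.fit.parameters[nm].stderr for nm in ("KI", "K2", "dH_I", "dH_c")},
            "rss": res.fit.rss,
            "diagnostics": res.fit.diagnostics,
        }
        row = derive_row(
            macro.K1, macro.K2, p.KII, config.report.temperature,
            dH_I=p.dH_I, dH_II=p.dH_II, dH_c=p.dH_c,
        )
        report_rows.append({"peptide": exp.label, "pH": exp.design.pH, **row})
    report = pd.DataFrame(report_rows)
    results["report"] = report.to_dict(orient="records")
    return report, results


def speciation_report(
    config: AnalysisConfig,
    total_metal: float,
    total_chelator: float,
    total_peptide: float,
) -> spec.SpeciationState:
    """Solve one composition under the configured chemical system."""
    chelator = config.system.chelator.to_model() if config.system.chelator else None
    peptide = config.system.peptide.to_model() if config.system.peptide else None
    totals = spec.ComponentTotals(
        total_metal, total_chelator, total_peptide,
        pH=config.system.conditions.pH, temperature=config.system.conditions.T,
    )
    return spec.solve_speciation(totals, chelator, peptide)
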