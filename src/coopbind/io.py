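"""Delimited-text readers/writers for titration data and results.

All files are comma-separated UTF-8 with a header row and "." decimals; unit
tags live in the header names (e.g. ``heat_uJ``).  Numeric fields round-trip
at 17 significant digits.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import fluor as fl
from . import itc as itcmod
from . import speciation as spec

__all__ = [
    "read_fluor_table",
    "write_fluor_series",
    "build_fluor_series",
    "read_itc_table",
    "write_itc_series",
    "build_itc_series",
    "write_speciation_table",
    "write_results_json",
    "read_results_json",
]

_FLOAT_FMT = "%.17g"


def read_fluor_table(path) -> pd.DataFrame:
    """Columns step, added_metal_total_M, intensity[, added_volume_uL]."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"step", "added_metal_total_M", "intensity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fluorescence table missing columns: {sorted(missing)}")
    return df.sort_values("step").reset_index(drop=True)


def build_fluor_series(
    df: pd.DataFrame,
    peptide_total: float,
    chelator_total: float,
    pH: float,
    initial_volume_uL: float | None = None,
) -> fl.FluorTitrationSeries:
    """Combine a data table with the cuvette composition into a series."""
    volumes = None
    if "added_volume_uL" in df.columns and df["added_volume_uL"].notna().all():
        volumes = tuple(float(v) for v in df["added_volume_uL"])
    design = fl.FluorDesign(
        peptide_total=peptide_total,
        chelator_total=chelator_total,
        pH=pH,
        metal_totals=tuple(float(v) for v in df["added_metal_total_M"]),
        initial_volume_uL=initial_volume_uL if volumes is not None else None,
        added_volumes_uL=volumes,
    )
    return fl.FluorTitrationSeries(design, tuple(float(v) for v in df["intensity"]))


def write_fluor_series(series: fl.FluorTitrationSeries, path) -> None:
    data = {
        "step": np.arange(len(series.intensities)),
        "added_metal_total_M": series.design.metal_totals,
        "intensity": series.intensities,
    }
    if series.design.added_volumes_uL is not None:
        data["added_volume_uL"] = series.design.added_volumes_uL
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_itc_table(path) -> tuple[pd.DataFrame, str]:
    """Columns injection, volume_uL, heat_uJ|heat_ucal; returns (table, unit)."""
    df = pd.read_csv(path, float_precision="round_trip")
    unit = None
    for candidate in ("uJ", "ucal"):
        if f"heat_{candidate}" in df.columns:
            unit = candidate
    if unit is None or not {"injection", "volume_uL"} <= set(df.columns):
        raise ValueError("ITC table requires columns injection, volume_uL, heat_uJ or heat_ucal")
    return df.sort_values("injection").reset_index(drop=True), unit


def build_itc_series(df: pd.DataFrame, unit: str, blank: pd.DataFrame | None = None) -> itcmod.ITCSeries:
    heats = tuple(float(v) for v in df[f"heat_{unit}"])
    blank_heats = None
    if blank is not None:
        blank_heats = tuple(float(v) for v in blank[f"heat_{unit}"])
    return itcmod.ITCSeries(heats=heats, unit=unit, blank=blank_heats)


def write_itc_series(series: itcmod.ITCSeries, design: itcmod.ITCDesign, path, blank_path=None) -> None:
    base = {
        "injection": np.arange(1, len(series.heats) + 1),
        "volume_uL": design.injection_volumes_uL,
    }
    pd.DataFrame({**base, f"heat_{series.unit}": series.heats}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    if blank_path is not None and series.blank is not None:
        pd.DataFrame({**base, f"heat_{series.unit}": series.blank}).to_csv(
            blank_path, index=False, float_format=_FLOAT_FMT
        )


def write_speciation_table(state: spec.SpeciationState, path) -> None:
    """One row per species (free components included), columns species,concentration_M."""
    rows = [
        ("M_free", state.free_metal),
        ("L_free", state.free_chelator),
        ("P_free", state.free_peptide),
    ]
    rows += list(state.species_concentrations.items())
    pd.DataFrame(rows, columns=["species", "concentration_M"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_results_json(results, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(results), indent=2, allow_nan=True) + "\n")


def read_results_json(path):
    return json.loads(Path(path).read_text())
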