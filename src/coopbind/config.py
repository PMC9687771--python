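"""Configuration schema for the chemical system and analysis options.

The configuration is JSON/YAML key-value text with three blocks: the chelator
(pKa list plus complex species), an optional peptide model, and the medium
conditions.  Validation is strict — unknown keys are rejected before any
computation runs.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import speciation as spec

__all__ = [
    "SpeciesConfig",
    "ChelatorConfig",
    "PeptideConfig",
    "ConditionsConfig",
    "SystemConfig",
    "FitConfig",
    "ReportConfig",
    "AnalysisConfig",
    "load_config",
    "default_chelator",
    "default_system",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class SpeciesConfig(_Strict):
    m: int = Field(1, ge=1)
    l: int = Field(1, ge=1)
    log10_beta: float


class ChelatorConfig(_Strict):
    pKa: tuple[float, ...]
    species: tuple[SpeciesConfig, ...]

    def to_model(self) -> spec.ChelatorModel:
        return spec.ChelatorModel(
            pKa_list=self.pKa,
            complex_species=tuple(
                spec.ComplexSpecies(s.m, s.l, s.log10_beta) for s in self.species
            ),
        )


class PeptideConfig(_Strict):
    n_sites: int = Field(ge=1, le=2)
    K1: float = Field(gt=0)
    K2: float | None = Field(None, gt=0)

    @model_validator(mode="after")
    def _check_K2(self):
        if self.n_sites == 2 and self.K2 is None:
            raise ValueError("two-site peptide requires K2")
        if self.n_sites == 1 and self.K2 is not None:
            raise ValueError("K2 given for a one-site peptide")
        return self

    def to_model(self) -> spec.PeptideBindingModel:
        return spec.PeptideBindingModel(self.n_sites, self.K1, self.K2)


class ConditionsConfig(_Strict):
    pH: float = Field(6.0, gt=0, lt=14)
    T: float = Field(298.0, gt=0)
    ionic_strength: float | None = None


class SystemConfig(_Strict):
    """Chemical system: chelator + optional peptide + conditions."""

    chelator: ChelatorConfig | None = None
    peptide: PeptideConfig | None = None
    conditions: ConditionsConfig = ConditionsConfig()
    comment: str | None = None


class FitConfig(_Strict):
    n_starts: int = Field(5, ge=1)
    seed: int = 0
    log10K_bounds: tuple[float, float] = (3.0, 13.0)
    skip_first_injection: bool = True


class ReportConfig(_Strict):
    temperature: float = Field(298.0, gt=0)
    sig_figs: int = Field(3, ge=1, le=17)
    heat_unit: str = "uJ"


class AnalysisConfig(_Strict):
    system: SystemConfig = SystemConfig()
    fit: FitConfig = FitConfig()
    report: ReportConfig = ReportConfig()


def load_config(path: str | Path) -> AnalysisConfig:
    """Read and validate an analysis configuration (JSON, or YAML by suffix)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    # a bare system block is accepted for convenience
    if "system" not in data and ("chelator" in data or "peptide" in data or "conditions" in data):
        data = {"system": data}
    return AnalysisConfig.model_validate(data)


def _default_payload() -> dict:
    with resources.files("coopbind.data").joinpath("ida_uranyl.json").open() as fh:
        return json.load(fh)


def default_chelator() -> spec.ChelatorModel:
    """The shipped uranyl–iminodiacetate model (literature placeholder values)."""
    payload = _default_payload()
    return ChelatorConfig.model_validate(payload["chelator"]).to_model()


def default_system() -> SystemConfig:
    payload = _default_payload()
    return SystemConfig.model_validate(payload)
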