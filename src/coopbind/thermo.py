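"""Macroscopic/microscopic binding-constant algebra and thermodynamics.

A two-site molecule binding a metal ion M has four microstates (apo, M at
site I, M at site II, both filled).  Site-specific (microscopic) association
constants K_I, K_II describe binding to the empty molecule and K_I,II, K_II,I
binding to the molecule with the other site already occupied.  They relate to
the stepwise macroscopic constants by

    K1 = K_I + K_II            K2 = K_I K_II,I / (K_I + K_II)

with the thermodynamic-cycle (detailed-balance) identity
K_I * K_II,I = K_II * K_I,II = K1 * K2.  Inter-site cooperativity is
quantified by the dimensionless constant Kc = K_II,I/K_II = K_I,II/K_I and
the free energy ddG = -RT ln Kc (negative for positive cooperativity), and
free energies decompose as dG = dH - T dS = -RT ln K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "R_GAS",
    "Conditions",
    "MacroscopicConstants",
    "MicroscopicConstants",
    "CooperativityResult",
    "ThermoDecomposition",
    "micro_from_macro",
    "macro_from_micro",
    "cooperativity",
    "gibbs_from_K",
    "entropy_term",
    "kd_from_K",
]

#: gas constant, J mol^-1 K^-1
R_GAS = 8.314

_DETAILED_BALANCE_RTOL = 1e-9


@dataclass(frozen=True)
class Conditions:
    """Temperature (K) plus medium metadata; energies use R = 8.314 J/mol/K."""

    temperature: float = 298.0
    pH: float | None = None
    ionic_strength: float | None = None

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @property
    def RT_kJ(self) -> float:
        """R*T in kJ/mol."""
        return R_GAS * self.temperature / 1000.0


@dataclass(frozen=True)
class MacroscopicConstants:
    K1: float
    K2: float | None = None

    def __post_init__(self):
        if self.K1 <= 0:
            raise ValueError("K1 must be positive")
        if self.K2 is not None and self.K2 <= 0:
            raise ValueError("K2 must be positive when present")


@dataclass(frozen=True)
class MicroscopicConstants:
    """Site-specific association constants of a two-site molecule (M^-1).

    KI, KII: binding to the apo molecule at site I / site II; KI_II: site I
    when site II is filled; KII_I: site II when site I is filled.  Instances
    must satisfy detailed balance KI*KII_I = KII*KI_II.
    """

    KI: float
    KII: float
    KI_II: float
    KII_I: float

    def __post_init__(self):
        if min(self.KI, self.KII, self.KI_II, self.KII_I) <= 0:
            raise ValueError("all microscopic constants must be positive")
        lhs = self.KI * self.KII_I
        rhs = self.KII * self.KI_II
        if abs(lhs - rhs) > _DETAILED_BALANCE_RTOL * max(lhs, rhs):
            raise ValueError(
                "detailed balance violated: KI*KII_I = "
                f"{lhs:.6e} but KII*KI_II = {rhs:.6e}"
            )

    @classmethod
    def from_three(cls, KI: float, KII: float, KII_I: float) -> "MicroscopicConstants":
        """Complete the cycle from three constants via KI_II = KI*KII_I/KII."""
        if min(KI, KII, KII_I) <= 0:
            raise ValueError("constants must be positive")
        return cls(KI=KI, KII=KII, KI_II=KI * KII_I / KII, KII_I=KII_I)

    @property
    def beta2(self) -> float:
        """Cumulative constant for loading both sites, = K1*K2."""
        return self.KI * self.KII_I


@dataclass(frozen=True)
class CooperativityResult:
    ddG: float  # kJ/mol
    Kc: float   # dimensionless


@dataclass(frozen=True)
class ThermoDecomposition:
    """dG = dH - T dS (all kJ/mol) at the stated temperature."""

    deltaG: float
    deltaH: float
    TdeltaS: float
    temperature: float

    def __post_init__(self):
        closure = self.deltaG - (self.deltaH - self.TdeltaS)
        scale = max(abs(self.deltaG), abs(self.deltaH), abs(self.TdeltaS), 1.0)
        if abs(closure) > 1e-9 * scale:
            raise ValueError(f"dG != dH - TdS (closure error {closure:.3e} kJ/mol)")


def micro_from_macro(macro: MacroscopicConstants, KII: float) -> MicroscopicConstants:
    """Microscopic constants from (K1, K2) plus an independently known KII.

    KI = K1 - KII, KI_II = K1*K2/KII, KII_I = K1*K2/KI.  In the assay this
    KII comes from the matching one-site (site-II-only) peptide.
    """
    if macro.K2 is None:
        raise ValueError("macroscopic K2 is required")
    if not (0.0 < KII < macro.K1):
        raise ValueError(
            f"KII must satisfy 0 < KII < K1 (= {macro.K1:.3e}); "
            f"got {KII:.3e} — site-I constant would be non-positive"
        )
    KI = macro.K1 - KII
    beta2 = macro.K1 * macro.K2
    return MicroscopicConstants(KI=KI, KII=KII, KI_II=beta2 / KII, KII_I=beta2 / KI)


def macro_from_micro(micro: MicroscopicConstants) -> MacroscopicConstants:
    """Inverse map: K1 = KI + KII, K2 = KI*KII_I/(KI + KII)."""
    K1 = micro.KI + micro.KII
    return MacroscopicConstants(K1=K1, K2=micro.KI * micro.KII_I / K1)


def cooperativity(micro: MicroscopicConstants, cond: Conditions = Conditions()) -> CooperativityResult:
    """Cooperativity constant Kc = KII_I/KII and free energy ddG = -RT ln Kc."""
    Kc = micro.KII_I / micro.KII
    return CooperativityResult(ddG=-cond.RT_kJ * math.log(Kc), Kc=Kc)


def gibbs_from_K(K: float, cond: Conditions = Conditions()) -> float:
    """Association free energy dG = -RT ln K, in kJ/mol (log-domain safe)."""
    if K <= 0:
        raise ValueError("K must be positive")
    return -cond.RT_kJ * math.log(K)


def entropy_term(K: float, deltaH: float, cond: Conditions = Conditions()) -> float:
    """T dS = RT ln K + dH (kJ/mol), closing dG = dH - T dS for dG = -RT ln K."""
    return cond.RT_kJ * math.log(K) + deltaH


def decompose(K: float, deltaH: float, cond: Conditions = Conditions()) -> ThermoDecomposition:
    """Full dG/dH/TdS decomposition for an association constant and enthalpy."""
    dG = gibbs_from_K(K, cond)
    return ThermoDecomposition(dG, deltaH, entropy_term(K, deltaH, cond), cond.temperature)


_KD_UNITS = (("M", 1.0), ("mM", 1e-3), ("uM", 1e-6), ("nM", 1e-9), ("pM", 1e-12))


def kd_from_K(K: float) -> tuple[float, str]:
    """Dissociation constant 1/K with an auto-scaled unit (M..pM).

    The unit is chosen so the mantissa falls in [1, 1000); values below 1 pM
    stay in pM.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    kd = 1.0 / K
    for unit, scale in _KD_UNITS:
        value = kd / scale
        if 1.0 <= value < 1000.0:
            return value, unit
    return kd / 1e-12, "pM"
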