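"""Chemical speciation for metal / chelator / peptide mixtures at fixed pH.

The mixture is described by three *components* — free metal ion M (here the
uranyl cation), a competing chelator L (iminodiacetate in the shipped
defaults) referenced to its total uncomplexed (protonated + deprotonated)
form, and a one- or two-site peptide P.  All complex-formation equilibria are
written with cumulative conditional constants at the stated pH; ligand
protonation is absorbed into a side-reaction coefficient so the proton balance
is never solved explicitly.  The coupled mass-balance equations

    C_M = [M] + sum_s a_s [species_s] + [MP] + 2 [M2P]
    C_L = L'  + sum_s q_s [species_s]
    C_P = [P] + [MP] + [M2P]

are solved by a damped Newton–Raphson iteration in log10 concentration space,
which guarantees positivity and converges quadratically near the root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ComponentTotals",
    "ComplexSpecies",
    "ChelatorModel",
    "PeptideBindingModel",
    "SpeciationState",
    "SolverOptions",
    "SpeciationError",
    "side_reaction_coefficient",
    "conditional_constants",
    "solve_speciation",
    "solve_speciation_batch",
    "mass_balance_residuals",
]

_LN10 = math.log(10.0)
#: relative-residual floor, prevents 0/0 for absent components
_RESIDUAL_FLOOR = 1e-30


class SpeciationError(RuntimeError):
    """Raised when the Newton iteration fails to converge.

    Carries the last relative mass-balance residuals in ``residuals`` and the
    index of the offending titration point (batch solves) in ``point_index``.
    """

    def __init__(self, message, residuals=None, point_index=None):
        super().__init__(message)
        self.residuals = residuals
        self.point_index = point_index


@dataclass(frozen=True)
class ComponentTotals:
    """Analytical (total) concentrations of the three components, in mol/L."""

    total_metal: float
    total_chelator: float = 0.0
    total_peptide: float = 0.0
    pH: float = 6.0
    temperature: float = 298.0

    def __post_init__(self):
        for name in ("total_metal", "total_chelator", "total_peptide"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not (0.0 < self.pH < 14.0):
            raise ValueError(f"pH must lie in (0, 14), got {self.pH}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")


@dataclass(frozen=True)
class ComplexSpecies:
    """One metal–chelator complex M_a L_q with cumulative formation constant.

    ``log10_beta`` refers to the fully deprotonated chelator and the free
    metal at the stated temperature and ionic strength.
    """

    metal_stoich: int
    chelator_stoich: int
    log10_beta: float

    def __post_init__(self):
        if self.metal_stoich < 1 or self.chelator_stoich < 1:
            raise ValueError("stoichiometries must be positive integers")
        if not math.isfinite(self.log10_beta):
            raise ValueError("log10_beta must be finite")

    @property
    def label(self) -> str:
        return f"M{self.metal_stoich}L{self.chelator_stoich}"


@dataclass(frozen=True)
class ChelatorModel:
    """Acid-dissociation exponents (highest first) plus complex species."""

    pKa_list: tuple[float, ...]
    complex_species: tuple[ComplexSpecies, ...]

    def __post_init__(self):
        object.__setattr__(self, "pKa_list", tuple(self.pKa_list))
        object.__setattr__(self, "complex_species", tuple(self.complex_species))
        _check_sorted_descending(self.pKa_list)
        if not self.complex_species:
            raise ValueError("a chelator model requires at least one complex species")


@dataclass(frozen=True)
class PeptideBindingModel:
    """Stepwise macroscopic association constants of a 1- or 2-site peptide.

    K1 governs M + P = MP and, for two-site peptides, K2 governs
    M + MP = M2P; both are conditional constants in M^-1.
    """

    n_sites: int
    K1: float
    K2: float | None = None

    def __post_init__(self):
        if self.n_sites not in (1, 2):
            raise ValueError("n_sites must be 1 or 2")
        if self.K1 <= 0:
            raise ValueError("K1 must be positive")
        if self.n_sites == 2:
            if self.K2 is None or self.K2 <= 0:
                raise ValueError("a two-site peptide requires K2 > 0")
        elif self.K2 is not None:
            raise ValueError("K2 given for a one-site peptide")


@dataclass
class SpeciationState:
    """Free concentrations and complex concentrations at one titration point."""

    free_metal: float
    free_chelator: float
    free_peptide: float
    species_concentrations: dict[str, float] = field(default_factory=dict)
    converged: bool = False
    iterations: int = 0


@dataclass(frozen=True)
class SolverOptions:
    tol: float = 1e-10          # convergence: max |Δlog10 c| per iteration
    max_iterations: int = 200
    step_clip: float = 0.5      # damping: max |Δlog10 c| applied per step


def _check_sorted_descending(pKa_list):
    if any(pKa_list[i] < pKa_list[i + 1] for i in range(len(pKa_list) - 1)):
        raise ValueError(
            "pKa_list must be sorted descending (highest, i.e. last-dissociating, first)"
        )


def side_reaction_coefficient(pKa_list, pH: float) -> float:
    """Ligand protonation side-reaction coefficient alpha_L(H) at fixed pH.

    alpha = [L']/[L] = 1 + sum_k 10^(sum_{i<=k} pKa_i - k*pH), the factor by
    which protonation inflates the uncomplexed-ligand pool over the free
    deprotonated form.  Always >= 1 and non-increasing in pH.
    """
    pKa_list = tuple(pKa_list)
    _check_sorted_descending(pKa_list)
    if not (0.0 < pH < 14.0):
        raise ValueError(f"pH must lie in (0, 14), got {pH}")
    alpha = 1.0
    cum = 0.0
    for k, pka in enumerate(pKa_list, start=1):
        cum += pka
        alpha += 10.0 ** (cum - k * pH)
    return alpha


def conditional_constants(chelator: ChelatorModel, pH: float) -> list[tuple[str, int, int, float]]:
    """Per-species conditional constants referenced to total uncomplexed chelator.

    Returns (label, metal_stoich, chelator_stoich, log10_beta_prime) with
    beta' = beta / alpha^q, alpha the side-reaction coefficient at ``pH``.
    """
    alpha = side_reaction_coefficient(chelator.pKa_list, pH)
    log_alpha = math.log10(alpha)
    return [
        (s.label, s.metal_stoich, s.chelator_stoich, s.log10_beta - s.chelator_stoich * log_alpha)
        for s in chelator.complex_species
    ]


def _species_table(chelator, peptide, pH):
    """Stoichiometry matrix (n_species, 3) over (M, L, P) and log10 beta'."""
    labels, stoich, logb = [], [], []
    if chelator is not None:
        for label, a, q, lb in conditional_constants(chelator, pH):
            labels.append(label)
            stoich.append((a, q, 0))
            logb.append(lb)
    if peptide is not None:
        labels.append("MP")
        stoich.append((1, 0, 1))
        logb.append(math.log10(peptide.K1))
        if peptide.n_sites == 2:
            labels.append("M2P")
            stoich.append((2, 0, 1))
            logb.append(math.log10(peptide.K1) + math.log10(peptide.K2))
    stoich = np.asarray(stoich, dtype=float).reshape(len(labels), 3)
    return labels, stoich, np.asarray(logb, dtype=float)


def _newton_batch(S, logb, totals, options, x_init=None):
    """Damped Newton–Raphson in log10 space, vectorized over titration points.

    ``S``: (n_species, n_comp) stoichiometries for the active components only;
    ``totals``: (n_points, n_comp), all strictly positive.  ``x_init``
    optionally warm-starts the iteration (log10 concentrations); the default
    initial guess is the component totals.
    Returns (free (n_points, n_comp), species conc (n_points, n_species),
    iterations).
    """
    n, k = totals.shape
    x = np.log10(totals) if x_init is None else x_init.copy()
    iterations = 0
    for iterations in range(1, options.max_iterations + 1):
        free = 10.0 ** x
        if S.shape[0]:
            expo = np.clip(logb[None, :] + x @ S.T, -300.0, 300.0)
            conc = 10.0 ** expo                       # (n, s)
            calc = free + conc @ S                    # (n, k)
            J = np.einsum("ns,si,sj->nij", conc, S, S)
        else:
            conc = np.zeros((n, 0))
            calc = free
            J = np.zeros((n, k, k))
        J[:, np.arange(k), np.arange(k)] += free
        J *= _LN10
        F = calc - totals
        try:
            dx = np.linalg.solve(J, -F[..., None])[..., 0]
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            raise SpeciationError("singular Jacobian in speciation solve")
        np.clip(dx, -options.step_clip, options.step_clip, out=dx)
        x += dx
        if np.max(np.abs(dx)) < options.tol:
            break
    free = 10.0 ** x
    conc = 10.0 ** np.clip(logb[None, :] + x @ S.T, -300.0, 300.0) if S.shape[0] else np.zeros((n, 0))
    return free, conc, iterations


def solve_speciation_batch(
    metal_totals,
    chelator_totals,
    peptide_totals,
    pH: float,
    chelator: ChelatorModel | None = None,
    peptide: PeptideBindingModel | None = None,
    options: SolverOptions | None = None,
    x0=None,
):
    """Solve the mass balances at many titration points at once.

    Returns (free (n,3) over [M, L', P], species (n, n_species), labels,
    iterations).  Components with zero total are excluded from the Newton
    solve (their free concentration and every species containing them are
    exactly zero).  ``x0`` optionally supplies free concentrations (n, 3)
    from a previous nearby solve to warm-start the iteration.
    Raises :class:`SpeciationError` (with the point index) on non-convergence.
    """
    options = options or SolverOptions()
    totals = np.column_stack([
        np.asarray(metal_totals, dtype=float),
        np.asarray(chelator_totals, dtype=float),
        np.asarray(peptide_totals, dtype=float),
    ])
    if np.any(totals < 0):
        raise ValueError("component totals must be >= 0")
    if chelator is None:
        totals[:, 1] = 0.0
    if peptide is None:
        totals[:, 2] = 0.0
    labels, S_full, logb_full = _species_table(chelator, peptide, pH)
    n = totals.shape[0]
    free = np.zeros((n, 3))
    species = np.zeros((n, len(labels)))
    total_iterations = 0

    # group points by which components are present
    patterns = totals > 0.0
    for pattern in np.unique(patterns, axis=0):
        rows = np.nonzero((patterns == pattern).all(axis=1))[0]
        comp_idx = np.nonzero(pattern)[0]
        if comp_idx.size == 0:
            continue  # empty system: everything zero
        # species composed only of present components survive
        absent = ~pattern
        sp_idx = np.nonzero((S_full[:, absent] == 0).all(axis=1))[0] if len(labels) else np.array([], int)
        S = S_full[np.ix_(sp_idx, comp_idx)]
        x_init = None
        if x0 is not None:
            guess = np.asarray(x0, dtype=float)[np.ix_(rows, comp_idx)]
            if np.all(guess > 0) and np.all(np.isfinite(guess)):
                x_init = np.log10(guess)
        f, c, iters = _newton_batch(S, logb_full[sp_idx], totals[np.ix_(rows, comp_idx)], options, x_init)
        resid = _relative_residuals(f, c, S, totals[np.ix_(rows, comp_idx)])
        worst = np.max(np.abs(resid), axis=1)
        if np.any(worst > 1e-10) and x_init is not None:
            # warm start led astray: retry from the default initial guess
            f, c, iters = _newton_batch(S, logb_full[sp_idx], totals[np.ix_(rows, comp_idx)], options)
            resid = _relative_residuals(f, c, S, totals[np.ix_(rows, comp_idx)])
            worst = np.max(np.abs(resid), axis=1)
        if np.any(worst > 1e-10):
            bad = int(rows[int(np.argmax(worst))])
            raise SpeciationError(
                f"speciation failed to converge at point {bad} after {iters} iterations "
                f"(max relative residual {worst.max():.3e})",
                residuals=resid[int(np.argmax(worst))],
                point_index=bad,
            )
        free[np.ix_(rows, comp_idx)] = f
        species[np.ix_(rows, sp_idx)] = c
        total_iterations = max(total_iterations, iters)
    return free, species, labels, total_iterations


def _relative_residuals(free, conc, S, totals):
    calc = free + (conc @ S if S.shape[0] else 0.0)
    return (calc - totals) / np.maximum(totals, _RESIDUAL_FLOOR)


def solve_speciation(
    totals: ComponentTotals,
    chelator: ChelatorModel | None = None,
    peptide: PeptideBindingModel | None = None,
    options: SolverOptions | None = None,
) -> SpeciationState:
    """Solve the coupled mass balances at a single composition.

    Deterministic for fixed inputs; raises :class:`SpeciationError` on
    non-convergence and ``ValueError`` on invalid inputs.
    """
    if totals.total_metal == totals.total_chelator == totals.total_peptide == 0.0:
        labels, _, _ = _species_table(chelator, peptide, totals.pH)
        return SpeciationState(0.0, 0.0, 0.0, {lab: 0.0 for lab in labels}, True, 0)
    free, species, labels, iterations = solve_speciation_batch(
        [totals.total_metal], [totals.total_chelator], [totals.total_peptide],
        totals.pH, chelator, peptide, options,
    )
    return SpeciationState(
        free_metal=float(free[0, 0]),
        free_chelator=float(free[0, 1]),
        free_peptide=float(free[0, 2]),
        species_concentrations={lab: float(c) for lab, c in zip(labels, species[0])},
        converged=True,
        iterations=iterations,
    )


def mass_balance_residuals(
    state: SpeciationState,
    totals: ComponentTotals,
    chelator: ChelatorModel | None = None,
    peptide: PeptideBindingModel | None = None,
) -> tuple[float, float, float]:
    """Relative conservation residuals (metal, chelator, peptide) of a state.

    Each residual is (total − reconstructed)/max(total, floor), so an excess
    of reconstructed material gives a negative residual; all three are ~0
    (|r| <= 1e-10) for a converged state.
    """
    labels, S, _ = _species_table(chelator, peptide, totals.pH)
    conc = np.array([state.species_concentrations.get(lab, 0.0) for lab in labels])
    free = np.array([state.free_metal, state.free_chelator, state.free_peptide])
    calc = free + (conc @ S if len(labels) else 0.0)
    tot = np.array([totals.total_metal, totals.total_chelator, totals.total_peptide])
    resid = (tot - calc) / np.maximum(tot, _RESIDUAL_FLOOR)
    return float(resid[0]), float(resid[1]), float(resid[2])
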