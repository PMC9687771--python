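# Methods

`coopbind` implements the complete computation behind a chelator-competition
titration study of uranyl (UO₂²⁺) binding to two-site EF-hand peptides
(calmodulin N-terminal domain variants): chemical speciation at fixed pH,
forward models and fitters for fluorescence and isothermal titration
calorimetry (ITC) data, the macroscopic ↔ microscopic constant algebra that
quantifies inter-site cooperativity, and a synthetic-data generator that
reproduces the study designs for validation.

## Chemical model and speciation

The system has three components: free metal M, a competing chelator L
(iminodiacetate, IDA, in the defaults) and a peptide P with one or two
binding sites. All equilibria are written with *conditional* constants at
the stated pH: ligand protonation is absorbed into the side-reaction
coefficient

    α_L(H) = 1 + Σ_k 10^(Σ_{i≤k} pKa_i − k·pH),

and a complex M_aL_q with cumulative constant β is given the effective
constant β′ = β/α^q referenced to the total uncomplexed chelator pool L′.
The proton balance is never solved explicitly — appropriate because the
titrations are performed in pH-statted buffer, and consistent with the
conditional-constant convention of the assay. Uranyl hydrolysis species are
not modeled; the chelator is present precisely to suppress hydroxo-complex
formation at pH ≥ 4.

The three mass balances (metal, chelator, peptide) are solved by a damped
Newton–Raphson iteration on the log₁₀ of the free concentrations, which
enforces positivity and gives an analytic, symmetric positive-definite
Jacobian, J_ij = ln10·Σ_s ν_is ν_js c_s (free species included). Numerical
choices: initial guess = component totals; per-iteration step clipped to
±0.5 log units; convergence when max |Δlog₁₀c| < 10⁻¹⁰ with iteration cap
200; a solve is accepted only if every relative mass-balance residual is
≤ 10⁻¹⁰. Components with zero total are excluded from the iteration (their
free concentrations and every species containing them are exactly zero),
which handles the metal-free baseline point of a titration without special
casing in callers. Batched solves across titration points share one
vectorized iteration, and the fitters warm-start each solve from the
previous optimizer step's solution (falling back to the default guess if
the warm start fails to converge). The solver is cross-validated against an
independent nested-bisection oracle on randomized systems (totals
10⁻⁷–10⁻³ M, log₁₀K 4–12) to ≤ 10⁻⁸ relative.

### Default chelator constants

The uranyl–IDA stability constants are configuration, not code: the shipped
file (`coopbind/data/ida_uranyl.json`; pKa 9.34/2.61, log β of 8.93 (ML),
16.2 (ML₂) and 18.5 (M₂L₂) at 25 °C, I = 0.1 M) holds literature-plausible
placeholder values and is explicitly user-replaceable. Every computation
takes the chelator model as input.

## Binding models

**Fluorescence.** The baseline-subtracted signal ΔF = F₀ − F (quenching
positive; amplitudes are signed so either convention fits) follows

    ΔF/C_P = ΔΦ K₁[M] / (1 + K₁[M])                       (one site)
    ΔF/C_P = (ΔΦ₁K₁[M] + ΔΦ₂K₁K₂[M]²) / (1 + K₁[M] + K₁K₂[M]²)   (two sites)

with [M] the free metal from the full speciation at each point's totals —
this is where the chelator competition enters. If per-step volumes are
recorded, C_P and C_L are rescaled by V₀/V_i per point; otherwise dilution
is assumed negligible and a warning is emitted.

**ITC (reverse titration).** The peptide is injected into metal + chelator.
Perfusion-cell displacement bookkeeping: with cumulative injected volume
d_j and cell volume V₀, an injected component has total
C_syr(d_j/V₀)/(1 + d_j/2V₀) and a resident component
C₀(1 − d_j/2V₀)/(1 + d_j/2V₀); Δn values are taken over the fixed active
volume V₀. Per injection,

    Q_j = ΔH_I Δn(MP_I) + ΔH_II Δn(MP_II) + (ΔH_I + ΔH_II + ΔH_c) Δn(M₂P),

where the mononuclear pool is partitioned between the site-I- and
site-II-bound forms as K_I : K_II and speciation uses the macroscopic
constants (K₁ = K_I + K_II, K₂). ΔH_c is the molar enthalpy of the
cooperative step. Heats are handled internally in µJ; µcal inputs are
converted at 4.184 J/cal. The model telescopes exactly (Σ_j Q_j equals the
final-minus-initial complex inventories) and reduces to the superposition
of two independent 1:1 binders when ΔH_c = 0 and K₂ = K_IK_II/(K_I+K_II);
both identities are enforced in tests.

## Thermodynamic algebra

Site-specific constants relate to the stepwise macroscopic ones by
K₁ = K_I + K_II and K₂ = K_I K_II,I/(K_I + K_II), with the thermodynamic
cycle K_I·K_II,I = K_II·K_I,II = K₁K₂. Given K_II from the matching
one-site (site-II-only) peptide, K_I = K₁ − K_II, K_I,II = K₁K₂/K_II and
K_II,I = K₁K₂/K_I. Cooperativity: K_c = K_II,I/K_II = K_I,II/K_I and
ΔΔG = −RT ln K_c (negative = positive cooperativity). Free energies close
as ΔG = ΔH − TΔS = −RT ln K; entropy terms as TΔS = RT ln K + ΔH with
TΔS_c = RT ln K_c + ΔH_c. R = 8.314 J mol⁻¹ K⁻¹ and T = 298 K are the
defaults and all energies are reported in kJ/mol. Dissociation constants
are reported with an auto-scaled unit (M…pM, mantissa in [1, 1000)).

When reproducing printed table values the comparisons use 5% relative
tolerance, because the printed inputs are themselves rounded to two
significant figures. Three of the four published two-site TΔS_I/TΔS_c
cells cannot be reproduced from any combination of the printed constants
and enthalpies under ΔG = ΔH − TΔS; the package reports its computed values
and those cells are excluded from validation. The one row that does close
does so with the site-I constant taken from the calorimetric K₁ and the
cooperativity constant from the fluorescence-derived microscopic set.

## Fitting

Both fitters are separable least-squares problems: given the binding
constants — iterated as log₁₀ values — the amplitudes (fluorescence) or
molar enthalpies (ITC) enter linearly and are profiled out by an ordinary
least-squares solve inside the residual (variable projection). The 1–2
remaining nonlinear parameters are optimized by a bounded trust-region
method from a deterministic multi-start spanning log₁₀K ∈ [3, 13] (5 starts
per axis; for two constants, starts are offset below the diagonal, where
stepwise constants usually lie, plus above-diagonal starts for strongly
cooperative solutions); every start is scouted with a capped iteration
budget and the best candidate (lowest residual norm, ties broken by lowest
log₁₀K₁) is polished to convergence. Fits are unweighted, matching the
assay's least-squares treatment. Standard errors come from the asymptotic
covariance s²(JᵀJ)⁻¹ of the full parameter vector; with replicates, each
series is fitted independently and parameters are reported as the replicate
mean ± sample SD (the protocol reports averages of three experiments).
Diagnostics include an F-ratio test flagging two-site fits that a one-site
model explains, the c-value of 1:1 ITC fits, and the K_I–K₂ correlation of
cooperative fits. The staged ITC protocol fits (K_II, ΔH_II) on the
one-site peptide, fixes them, fits (K_I, ΔH_I, K₂, ΔH_c) on the two-site
peptide, and derives everything else; the 0.4 µL first injection is modeled
but excluded from fitting by default.

## Synthetic data

The generator reproduces the study designs: fluorescence at C_P = 10 µM
with 500 µM IDA (5 µM/500 µM and 0.5 µM/50 µM for the phosphorylated
variants), pH 6 or 7; ITC with a 200 µL cell holding uranyl + IDA at 1:2,
peptide syringes of 1 mM (one-site; 0.1 mM cell metal) or 2 mM (two-site;
0.2 mM cell metal), one 0.4 µL plus nineteen 2 µL injections. True
parameters are the published best estimates for each peptide. Choices the
source experiments do not specify, fixed here once: the titrant schedule is
a metal-free baseline plus 19 log-spaced totals from 0.04 to 4 binding
equivalents of the combined ligand pool (C_P + C_IDA — relative to the
peptide alone the isotherm would never approach saturation under the
50-fold chelator excess); fluorescence baseline 1000 a.u. with saturation
quench to 20% of baseline and ΔΦ₁ = ΔΦ₂/2; Gaussian noise of 1% of the
isotherm amplitude (fluorescence) or 0.5 µJ per injection (ITC); blank
series carry an independent noise stream on a −1 µJ/injection mixing heat.
Identical seeds give bit-identical datasets.

What the generator does *not* emulate: spectral shape (single-wavelength
intensities only), inner-filter and photobleaching effects, baseline
integration of raw power traces, injection kinetics, or slow equilibration.
Passing recovery tests therefore demonstrate the correctness and
statistical behavior of the estimation chain under the assumed noise model,
not robustness to those instrumental systematics.

## Identifiability of the two-site fluorescence fit

Parameter recovery at the study designs is exact on noise-free data
(≤ 10⁻⁴ relative for every scenario) and meets few-percent bias bounds for
the one-site fluorescence and both ITC fits under the default noise. The
two-site fluorescence model is different: with all four of
(K₁, K₂, ΔΦ₁, ΔΦ₂) free and K₁/K₂ ratios of 4.7–7.6 — close to the
statistical factor of 4 of independent sites — the profiled residual
surface has two near-degenerate ridges, K₁ → ∞ with a small step amplitude
and K₂ → 0 with merged amplitudes. On the 20-point design their residual
cost above the true optimum is only ~1–25 noise variances at 1% amplitude
noise, so the maximum-likelihood fit escapes to a ridge in roughly half of
noisy replicates and the replicate-averaged K₁ is strongly biased even
though the fitted curves are visually indistinguishable. This is a genuine
property of the design, not of the optimizer (local fits started at the
truth drift to the same ridges); the corresponding recovery check is
reported as failing rather than weakened. In practice the cooperative
constants of such peptides are better determined by the ITC route, where
fixing (K_II, ΔH_II) from the one-site peptide and the distinct per-site
enthalpies break the degeneracy — exactly the staged protocol implemented
here. `analysis/05_recovery_study.py` reproduces these numbers.

## Problem sizes and determinism

Default study sizes: 20 titration points (fluorescence), 20 injections
(ITC), 3 replicates per experiment, 50 seeds per recovery study, 100
random systems for the solver oracle; the acceptance script uses 20-seed
recovery summaries for its reported bias metrics. All randomness flows
from explicit integer seeds through `numpy.random.default_rng`; identical
inputs give identical outputs across runs.

## Known limitations

- No activity-coefficient or ionic-strength corrections: all constants are
  conditional at the stated medium.
- No multi-metal competition, no explicit proton balance, no hydrolysis
  species.
- The shipped IDA constants are placeholders; quantitative reanalysis of
  real data requires the user's critically evaluated values.
- Asymptotic standard errors are first-order approximations; near the
  identifiability ridges described above they understate uncertainty, and
  the replicate-SD route is preferred.
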