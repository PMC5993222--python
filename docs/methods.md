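# Methods

## Model structure

`cocycle` integrates six prognostic cobalt tracers per vertical layer —
dissolved Co (dCo), scavenged Co (scCo), phytoplankton Co for diatoms and
nanophytoplankton, and small/large particulate organic Co — plus an implicit
zooplankton Co pool, in a closed box or a 1-D column. The host-ocean state
(temperature, O₂, PAR, bacterial biomass, silicic acid, phytoplankton biomass
and rates, boundary fluxes) is prescribed forcing, not simulated: the package
isolates the cobalt kinetics from the ecosystem model that would normally
supply these fields.

All tracers are carried in pM; process fluxes are pM/day per layer; boundary
fluxes are mol m⁻² day⁻¹ and convert through the receiving layer's thickness
(1 pM·m = 10⁻⁹ mol m⁻²). Phytoplankton biomass is carried in μM P so that
cellular quotas θ = phyCo/biomass come out directly in μmol Co (mol P)⁻¹.

## Process parameterizations and key parameters

Defaults are the control-model constants of the global cobalt-cycle
literature; every one is overridable
through a YAML document (`load_params`) and the CLI can dump the active set
for provenance.

- **Speciation.** Ligand-bound Co (CoL) is a diagnostic, not a seventh
  tracer: CoL = min(dCo, max(CoL_MIN, f_nano·dCo)) with f_nano the
  nanophytoplankton share of phytoplankton biomass, CoL_MIN = 25 pM, and a
  hard cap at dCo (no excess ligand). Co′ = dCo − CoL, clamped at zero. The
  linear-in-f_nano form is this package's choice; only the floor, the cap and
  the nanophytoplankton linkage are constrained by the literature.
- **Uptake.** Monod in the bioavailable pool (dCo for nanophytoplankton,
  Co′ for diatoms; half saturations 50/80 pM), hyperbolic quota regulation
  (1 − θ/θ_max)/(1.05 − θ/θ_max) with θ_max = 150 μmol Co (mol P)⁻¹ for both
  groups, and the diatom-only Zn scalar ξ_Zn = max(0.1, 1.3·(1 − Zn/(Zn +
  0.5 nM))), with Zn proxied from silicic acid as 0.065·Si + 0.183. Quotas
  above θ_max clamp uptake to zero (with a warning) rather than going
  negative. The ξ_Zn bounds imply at most a 1.3× enhancement of diatom uptake
  under Zn scarcity and a 90% reduction under Zn abundance; the quota
  denominator constant 1.05 (not a generic 0.5 shape factor) is used as the
  literal constant of the regulation term.
- **Scavenging.** Λ = Λ_min + Λ_Co·Q·kO₂·kBACT·(1 − kPAR), with
  Λ_min = 10⁻⁴ d⁻¹, Λ_Co = 10⁻² d⁻¹, Q a Q₁₀ = 2.75 factor referenced to
  20 °C (the reference temperature is a package choice — only 10 °C ratios
  are constrained — and is configurable), and squared-hyperbolic k-factors
  (thresholds/half-saturations: O₂ 100/25 μM, bacteria 2.5 μM C, PAR
  15 W m⁻²). kO₂ is one-sided (zero at or below the threshold): the printed
  squared-difference form is symmetric and would otherwise revive scavenging
  at very low O₂. Scav = Λ·Co′; above 100 pM Co′ the variable part of the
  rate is multiplied by 10, applied to the whole Co′ pool while above the
  threshold (whether only the excess is affected is not specified; an
  optional ±5 pM linear blend, off by default, smooths the discontinuity).
- **Dissolution.** λ = λ_max·max(kPAR, kO₂d) with λ_max = 0.1 d⁻¹ and kO₂d
  one-sided below the 50 μM dissolution threshold, so scCo redissolves only
  where light is high or O₂ genuinely low.
- **Remineralization.** Particulate organic Co regenerates φ = 1.5 times
  faster than organic carbon.
- **Zooplankton.** Grazers hold θ_ZOO = 20 μmol Co (mol P)⁻¹; grazed Co in
  excess of θ_ZOO times the grazed P is excreted to dCo immediately, the
  retained part enters the implicit zooplankton pool, which turns over to
  large particulate Co at 0.05 d⁻¹ (a stand-in for zooplankton mortality in
  the host ecology) so the budget closes.
- **Sources.** Dust: 17.3 μg Co per g of dust, 8% soluble. Rivers: Co/C =
  12 μmol/mol, injected into the surface layer of coastal columns (vertical
  placement is not otherwise constrained). Sediments: sed_Co = sed_Fe·M·1000
  for 2 < O₂_bw ≤ 50 μM, zero for O₂_bw ≤ 2 μM, sed_Fe·M·25 otherwise, with
  the benchmark sed_Fe flux treated as molar. M (crustal Co/Fe molar ratio)
  is not printed in the source literature; it is computed from the same
  crustal compilation used for the dust Co fraction — (17.3×10⁻⁶/58.933) ÷
  (0.0352/55.845) ≈ 4.66×10⁻⁴ — and exposed as a single configurable
  parameter.
- **Sinking.** scCo sinks at 1 m/day. The particulate-organic speeds are not
  printed (deferred to the host model); defaults of 2 and 50 m/day for the
  small and large classes are host-model-typical stand-ins, configurable, as
  is the 50/50 routing of mortality/aggregation losses between the two
  particle classes.

## Numerics

Explicit operator splitting per step: process kinetics with external sources
first, then upwind sinking, then explicit vertical diffusion. All losses from
a pool within a step are scaled by a common limiter factor so no pool is
overdrawn (positivity preservation); because the limited flux value is used
on both the donor and receiver side, internal transfers cancel exactly and
the per-step mass budget Δ(total Co) = (inputs − burial)·Δt closes to
floating-point round-off (measured ≲10⁻¹⁵ relative; the test suite requires
≤10⁻¹⁰). Transport is sub-cycled automatically so that the advective CFL
(max w·Δt ≤ min Δz) and the diffusive stability bound hold — necessary
because the 50 m/day large-particle speed exceeds the CFL of a 10 m grid at
the standard Δt = 0.25 day; requesting fewer sub-steps than stability demands
raises an error. Diffusion uses no-flux boundaries; the sinking flux through
the bottom interface is removed and recorded as burial. The scheme is
first-order in Δt (verified by a convergence test) and the steady states of
the split scheme coincide with the continuous ones for the linear
configurations used in testing.

Initial condition: uniform dCo (default 20 pM), all other pools empty — the
multi-century spin-up of a global configuration is not meaningful at column
scale, so runs should be read as transient-to-quasi-steady trajectories, not
equilibria. Non-finite tracer values abort the run with the offending step
reported.

## Synthetic forcing

Four archetypes, each a pure function of (name, grid spec, seed); the seed
applies ±2% multiplicative perturbations to biological and flux fields only,
never to the fields whose inequalities define the scenario. Profiles are
smooth analytic shapes so tests can assert the defining inequalities exactly:

- **omz_margin** (600 m, 10 m layers): warm surface; an oxycline into an
  O₂ minimum below 20 μM that reaches the seafloor, so the margin sediments
  sit in contact with the OMZ and bottom-water O₂ (~15 μM) falls between the
  two sediment thresholds; elevated sediment Fe benchmark flux
  (5×10⁻⁸ mol m⁻² d⁻¹, giving a suboxic Co source of ~2×10⁻⁸ mol m⁻² d⁻¹,
  within field-based margin estimates); vigorous effective mixing
  (30–60 m² d⁻¹) representing an upwelling margin, which is what lets the
  sediment signal reach the surface in a 1-D column.
- **oligotrophic_gyre** (4000 m): oxic throughout (≥170 μM), warm surface,
  low biomass and silicic acid, moderate dust, negligible sediment flux.
- **arctic_shelf** (100 m): < 2 °C everywhere (so the Q₁₀ factor is below
  one in every layer), strongly oxic, diatom-rich, high benchmark sediment
  Fe flux but oxic bottom water (so only the 25× leak operates).
- **closed_box** (one 50 m layer): all boundary fluxes zero. With sinking
  enabled, particles still exit through the floor; for a truly closed
  recycling loop (used in the production-balance tests) sinking is disabled
  via the run configuration.

Forcing is time-invariant by default, which isolates the cobalt kinetics; an
optional sinusoidal seasonal modulation (amplitude a, peaking near day 172)
scales PAR, phytoplankton biomass and growth rates for seasonal-depletion
demonstrations.

What the generator does *not* emulate: horizontal transport and upwelling as
advection (mixing is the only vertical exchange), interactive ecosystem
feedbacks (biomass does not respond to Co), realistic hydrography of any
particular section, and mesoscale variability. Passing tests therefore show
that the cobalt kinetics, sources and transport behave correctly and
consistently — not that the package reproduces observed ocean distributions.

## Run sizes and test design

The property suite runs every scenario for 20 model years at Δt = 0.25 day on
10 m layers — long enough for the OMZ column to develop its plume structure
and the box configurations to reach steady state, and small enough that the
complete suite (including the seven-member OMZ experiment suite) finishes in
a few minutes on one CPU. The closed-form steady state dCo* = S/Λ is checked
in a one-layer box with no biology, ligand floor zero, saturated O₂/bacteria
and zero light, run for 8 years (≈30 e-folding times of Λ ≈ 0.0101 d⁻¹) at
Δt = 0.1 day and required to match within 0.1%.

## Budgets and diagnostics

Budgets average the stored process-flux snapshots over the final 10% of a run
(window configurable), integrate over depth strata split at the 100 m and
250 m horizons by default, and report: per-process fluxes (mol m⁻² yr⁻¹),
dissolved-Co inventory per stratum, sinking flux across each horizon from the
window-mean particulate fields, burial, and residence times. The residence
time is inventory over total external input, reported both whole-column and
per stratum (the per-stratum value ignores vertical exchange, so upper-ocean
residence times are upper bounds). The experiment suite runs all toggle
configurations from identical forcing and initial state; the low-O₂
attribution of the sediment influence is (ΔNOSEDOX/ΔNOSED)×100 per layer.

## Known limitations

- No explicit Mn tracer, cobalamin pathway, or Co redox state; no coupling
  from Co back to phytoplankton growth.
- One-dimensional: margin columns accumulate dCo that a 3-D ocean would
  export laterally, so absolute concentrations at long run times should be
  read as upper bounds.
- The elevated-scavenging threshold introduces a rate discontinuity unless
  the optional smoothing is enabled.
- Per-stratum residence times ignore physical exchange between strata.
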