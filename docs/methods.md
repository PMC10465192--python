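# Methods

## Scope and model structure

`supfield` studies the evolution of two competitive traits — tolerance
(the ability to withstand suppression) and suppression (the ability to
harm competitors) — in large communities where each individual interacts
with many others at once.  Three model tiers share one survival law:

1. **Game scaffold** (`supfield.game`).  A two-player "kill-game"
   (an extreme Prisoner's Dilemma in which defectors kill their
   partners) plus the cooperation condition A₁·B > A₀ balancing the
   initiator benefit of killing (B) against kin-competition burdens
   (A₀ cooperators, A₁ defectors).  This tier fixes intuitions; all
   quantitative results come from the field model and the lattice.

2. **Suppression-field model** (`supfield.core`, `supfield.dynamics`).
   A deterministic mean-field model over k genotypes.  Survival is
   P̂ᵢ = Pᵢ − Pᵢ ŝᵢ Bᵢ (1 − Tᵢ); the felt field ŝᵢ aggregates the
   population's suppression weighted by encounter odds, and the
   initiator term Bᵢ ∈ [β, 1] discounts future competition for genotypes
   that suppress their neighbours.  Densities follow a discrete
   replicator update with fitness equal to survival.  The population is
   a fixed trait grid: evolution is density change only — no mutation,
   no sex, no within-genotype trait change (reproduction is clonal).

3. **Lattice ABM** (`supfield.abm`).  A stochastic 100×100 torus of
   sessile agents, at most one per cell, with the same survival law
   applied locally: the field an agent feels is the mean age-effective
   suppression of its 8 Moore neighbours (empty cells contribute zero,
   which is how local density enters).  Nothing corresponding to α, ρ,
   β or φ is imposed; those arise from the age structure, occupancy,
   reproduction and dispersal, and are *measured* each step as
   `alpha_hat` (mean age-ramp multiplier), `rho_hat` (occupancy),
   `beta_hat` (fraction of death-vacated cells re-occupied by the next
   state) and `phi_hat` (odds ratio of same-genotype neighbour pairs
   versus the random-mixing expectation Σ Dᵢ²).

## Parameters

| symbol | meaning | range | default |
|---|---|---|---|
| Tᵢ, Sᵢ | tolerance / suppression traits | [0, 1] | grid 0.2–0.8, 13 levels |
| Pᵢ | maximum survival per step | [0, 1] | 0.8 |
| α | effective maturity of the population | [0, 1] | 1 |
| ρ | relative population density | [0, 1] | 1 |
| β | replacement rate of killed competitors | [0, 1] | 1 |
| n | neighbourhood size | ≥ 1 | 8 (Moore) |
| φᵢᵢ | self-encounter odds ratio | ≥ 0 | 1 |

Only the product αρ enters the field equations; the "tuned" presets
(`tuned_age`: αρ = 0.6, β = 0.85; `tuned_age_fig`: αρ = 0.96,
β = 0.85; `tuned_noage`: αρ = 0.975, β = 0.755) mirror the two
published with-age estimates — which disagree with one another — and
the no-age estimate; both with-age values are therefore exposed rather
than reconciled.  φ = 0 (complete kin avoidance) is valid whenever the
focal density is below one; φ = 0 with Dᵢ = 1 is a domain error.

Lattice species defaults: fecundity F = 4 offspring per fully mature
agent per step, maturity age M = 25 steps with linear age ramps on T, S
and F (trait_eff = trait·min(age/M, 1)), initial occupancy 0.2, agents
seeded uniformly at age 1.  F, M and occupancy are not dictated by the
field model; they were calibrated once so that the emergent quantities
of 200-step lattice runs land in the ranges the field model is compared
against — windowed `beta_hat` minimum ≈ 0.85 (reference range
0.74–1.00) and limited-dispersal `phi_hat` overshooting to ≈ 180 before
declining to ≈ 90–100 by the end of a 200-step run.  These three
parameters trade off: raising fecundity raises the replacement rate but
mixes families faster (lower `phi_hat`); raising maturity age does the
opposite.  A mean-agent-age ceiling of about 5 steps (set by P = 0.8)
makes `alpha_hat` small at M = 25, so the tuned αρ ≈ 0.6 estimate
cannot be matched simultaneously; the directly measured emergent ranges
were given priority.  All three are plain config fields and can be
recalibrated freely.

## Dispersal modes and update order

One lattice update is synchronous: (1) survival decisions for every
agent from the pre-update state; (2) deaths applied; (3) every survivor
draws Binomial(F, age-ramp) offspring which disperse into empty cells —
including cells vacated in this same update, which is what produces an
emergent replacement rate below one without an explicit β; (4) all
agents age one step.  Offspring order is randomized before settlement.
Modes: `random` = offspring matched uniformly to empty cells anywhere;
`limited` = uniform over empty cells within Chebyshev radius 1 of the
parent, offspring lost if none; `overdispersed` = uniform over empty
cells at torus Chebyshev distance ≥ 10 (rejection-sampled), modelling
complete over-dispersal.

## Numerical choices

- Densities are renormalized each step; genotypes below 1e-12 are
  removed (prevents denormal drift on the 10 201-genotype grid without
  affecting 200-step trait means at reported precision).
- The initiator term is asserted, never clamped: for in-range inputs it
  stays in [β, 1]; leaving [0, 1] raises with diagnostics.
- Selection gradients are analytic partials of the assembled survival
  law (the focal trait also moves T̄, S̄ with weight Dᵢ); unit tests
  cross-check them against central finite differences (h = 1e-6) to
  1e-6 relative.
- Threshold densities are reported two ways: the closed form with the
  initiator coefficients frozen at the evaluation point, and an
  independent scan oracle — 10⁴ evenly spaced densities plus log-spaced
  points below the first node (thresholds are characteristically tiny),
  bisected to 1e-6, on the fully self-consistent differential
  ŝᵢ(D)Bᵢ(D) − E(ŝB)(D).  Differentials below 1e-13 are treated as
  degenerate (no crossing), not noise-level sign changes.
- Invasion outcomes classify growth past `growth_factor`× the
  introduction density as invasion and symmetric shrinkage (or the
  extinction floor) as repulsion; equilibration stops at max |ΔD| <
  1e-9 or 200 steps.
- Strategy sweeps scale the tolerance grid with the maximum under test
  (span [max_T/4, max_T], mirroring the canonical 0.2–0.8 span), keep
  the suppression span fixed, and label cells by the sign of the net
  mean-suppression change after 200 steps (tolerance ±1e-9 → neutral).
- Lattice RNG streams derive from (master seed, replicate index) via
  `SeedSequence`, so replicate counts can grow without perturbing
  earlier replicates; trajectories are bit-identical under a fixed seed.
- The weighted T–S correlation is abundance-weighted over genotypes in
  both tiers (not over individuals), for comparability.
- The two-sided exact binomial p-value uses the standard minimum-
  likelihood convention (sum of point probabilities not exceeding the
  observed one), via `scipy.stats.binomtest`.

## What the generator emulates — and what it does not

The lattice emulates dense stands of sessile competitors with local
interference, clonal reproduction and age-dependent trait expression.
It does not model motile organisms, explicit resources, fecundity–
survival trade-offs, kin recognition, learning, or higher trophic
levels; encounter rates are strictly local and linear in occupancy.
Passing tests therefore show that the mean-field theory predicts its
own stochastic, finite, spatial counterpart — not that either tier
describes any particular empirical system.

## Known limitations

- The suppression-only replicate design (S varies, T fixed) shows a
  *stronger* suppression benefit at shared T = 0.8 (≈ 86% of replicates
  increasing, mean ≈ +7%) than the barely-positive reference values
  (55.4%, +1.1%).  The main driver is an age-structure initiator
  channel: a killed mature neighbour is replaced by a juvenile whose
  suppression ramps up over M steps, so even at `beta_hat` = 1 killing
  buys a real reprieve.  The effect's strength varies with M, F and
  occupancy but stays well above the reference under every calibration
  tried; the printed lattice details leave this channel unconstrained.
  The T = 0.2 design lands inside its reference ranges.
- The per-step |ΔS̄|/|ΔT̄| ratio at very high assortativity is of order
  100%, not ~33%: with 169 genotypes and φ ≥ 1000 the self-encounter
  weight Dφ/(Dφ+1) is 0.86–0.98, making the suppression and tolerance
  selection differentials comparable from the first step, and the
  max-over-steps statistic is further inflated once T̄ saturates at the
  grid maximum while S̄ is still declining.
- The closed-form threshold (frozen coefficients) and the scan oracle
  agree in order of magnitude but not to high precision — the initiator
  term varies with the focal density, which the closed form ignores.
- `phi_hat` has no true plateau: it declines slowly as genotype
  richness collapses; "equilibrium" values are read at the end of
  200-step runs (the horizon of the reference trajectories).
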