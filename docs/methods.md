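# Methods

## Scope and model class

`syntroflux` implements steady-state, constraint-based community
modelling for a CO₂-methanating biofilm. Every organism is a flux-balance
model: reaction fluxes `v` satisfy `S·v = 0` with bounds
`lb ≤ v ≤ ub` (mmol/gDW/h; biomass flux in 1/h). No kinetics,
thermodynamics, regulation, or spatial structure is represented; the
biofilm is treated as a well-mixed community at steady state.

## Community coupling

Species models are merged with a shared environment pool. Each species
keeps a private, namespaced copy of its metabolites, including a boundary
copy of every environment metabolite, so species-internal mass balances
are untouched by the merge. A species exchange reaction moves metabolite
from the species boundary into the pool with stoichiometric weight equal
to the species' relative abundance `aᵢ`; one community exchange per pool
metabolite crosses the outer boundary. The pool steady state then encodes
the coupling `v_EX(c,m) = Σᵢ aᵢ·v_EX(i,m)` inside the ordinary
stoichiometric matrix, so a single LP/QP over the merged matrix is exact —
no special constraint machinery is needed. Species fluxes remain per gDW
of that species; community exchanges and growth are per gDW of community.
Internal species fluxes are deliberately *not* rescaled by abundance:
this is the formulation under which the regularized growth allocation
reproduces growth proportional to abundance. No per-species minimum
growth ("dilution") constraint is imposed.

Reweighting a built community (`set_abundances`) only rewrites the
abundance-scaled coupling coefficients and objective weights; species at
abundance zero keep their reactions but contribute nothing to community
exchanges or growth.

## Cooperative tradeoff

Growth allocation is a three-stage program:

1. `max μ_c = Σ aᵢμᵢ` (LP) giving `μ_c^max`.
2. `min Σ μᵢ²` subject to stage-1 constraints and
   `Σ aᵢμᵢ ≥ f·μ_c^max` (QP). The objective is strictly convex in the
   `μᵢ`, so the species growth rates are unique. The *unweighted* square
   sum is used: its KKT conditions give `μᵢ ∝ aᵢ` whenever no
   species-specific constraint binds, the qualitative behaviour expected
   of abundant taxa. `f` defaults to 0.5 everywhere.
3. With the `μᵢ` pinned (±1e-7), `min Σ v_EX²` over all species and
   community exchange fluxes. Flux vectors of community FBA are otherwise
   degenerate; this reporting stage makes the extracted cross-feeding
   network unique and reproducible. A ridge of 1e-9 on the remaining flux
   directions regularizes the QP without measurably moving the optimum.

LPs are solved with HiGHS (`scipy.optimize.linprog`); the QPs with SLSQP
(`scipy.optimize.minimize`) on the dense system — community models here
have O(100) reactions, where SLSQP converges to ~1e-9 stationarity in
under a second. Feasibility tolerance is 1e-6, LP optimality tolerance
1e-8. Correctness is cross-checked in the test suite against an
independent brute-force vertex enumeration (stage 1), a zooming grid
search over the growth simplex (stage 2), the closed form
`μ = f·μ*·a/‖a‖²` for uncoupled capped species, and cobrapy/GLPK for
plain FBA.

## Medium and reactor constraints

A medium recipe lists component concentrations (mmol/L). Concentrations
act as *relative* weights only: the largest non-water solute maps to an
uptake bound of 100 mmol/gDW/h, others scale linearly and are clamped
into [1, 100]; water alone gets 1000. The linear-with-clamping map is the
simplest rule consistent with the two stated anchors (a [1, 100] range
and proportionality to relative concentration); the mapping is invariant
to rescaling all concentrations. Environment metabolites absent from the
medium get import bound 0 with export free. A volumetric-to-specific unit
conversion per component is intentionally not attempted — recipe
concentrations are treated as dimensionless weights, keeping the LP in a
single unit system.

Reactor gas measurements convert to specific fluxes as
`q_in·x_gas·1000/(V_m·ρ_X·24)` with the ideal-gas molar volume
`V_m = R·T/P` (24.46 L/mol at 298.15 K — the printed two-decimal value is
truncated) and biomass density 1.17 gDW/L. The operating point pins the
community exchanges with the uptake-negative convention: CO₂ and H₂ lower
= upper = −1.20 and −5.11 mmol/gDW/h (the stated numeric values are used;
the nominal "1:4" ratio, which equals 4.26 here, is treated as
descriptive), CH₄ lower bound +1.15, and each volatile fatty acid's
community exchange fixed to (0, 0) so that species may still exchange VFA
through the pool while none accumulates in the medium.

## The synthetic community

The generator emulates the five dominant biofilm members with lumped toy
networks: an acetogen (33 %), a methanogen (26 %), an acetate/propionate
consumer (20 %) and two fermenters (11 %, 10 %) — the dominance ordering
observed in the reactors, configurable per blueprint. Reactions are
balanced exactly for carbon and nitrogen; hydrogen and oxygen are only
loosely tracked, as usual in lumped toy models, so electron bookkeeping
follows the H₂ stoichiometries as written. Seeds make every generator
output bit-identical; the community models themselves are deterministic
functions of the blueprint.

Structural guarantees, and how they are engineered:

* **Only the methanogen exports CH₄ / imports formate** — no other model
  contains those reactions.
* **The formate shuttle is obligatory.** The methanogen's H₂ uptake is
  transport-capped at 2 mmol/gDW/h, far below what the reactor CH₄ demand
  requires; the deficit must arrive as formate (4 HCOO⁻ → CH₄ + 3 CO₂).
* **Every species imports H₂.** All bacterial ATP sources and the biomass
  reactions consume H₂; any growing species therefore shows net uptake.
* **Acetate cross-feeding survives the 0.3 mmol/gDW/h plotting
  threshold.** The acetogen's own formate export is capped at
  2 mmol/gDW/h, so most of the formate highway must run through the
  other bacteria's acetate-to-formate conversion, which forces
  substantial acetate import from the acetogen's Wood–Ljungdahl output.
* **Zero net VFA accumulation with live VFA exchange.** Butyrate and
  propionate flow in closed producer/consumer loops (chain elongation in
  the fermenters, salvage in the acetogen and VFA consumer); only the
  H₂-consuming direction conserves energy, so no loop is a free energy
  source.
* **Electron overflow.** With H₂ fed above the 4:1 stoichiometric ratio
  to CO₂ (5.11/1.20), some electrons cannot end up in CH₄; dissimilatory
  sulfate reduction in the VFA consumer absorbs the surplus.
* **Amino-acid economy.** The seven cross-fed amino acids (l-Glutamate,
  l-Aspartate, l-Glutamine, l-Serine, l-Threonine, l-Alanine, glycine)
  are produced from CO₂/H₂/NH₄⁺ at one ATP each. Auxotrophies create the
  exchanges: the methanogen needs glutamate, the acetogen threonine, the
  VFA consumer glycine, fermenter A serine, fermenter B alanine and
  glutamine. The two-species (acetogen + methanogen) reduction stays
  viable because the acetogen covers glutamate and the methanogen
  threonine.

The mineral medium mirrors a basal anaerobic recipe: water, dissolved
CO₂ (the only carbon source), dissolved H₂, macro-ions and trace metals
spanning five orders of magnitude of concentration. Chloride is carried
as a deliberately inert tracer — it enters no reaction, pinning the
zero-elasticity baseline.

What the toys do **not** capture: genome-scale pathway redundancy,
growth-condition-dependent biomass composition, gas–liquid mass transfer,
thermodynamic feasibility windows, and any quantitative correspondence
with the deposited reconstructions. Passing tests therefore validate the
pipeline's mechanics and qualitative community structure, not numerical
predictions for the real reactors.

## Cross-feeding networks

FBA defines only species ↔ pool fluxes. Species-to-species arrows are
attributed by proportional allocation: for metabolite `m`, edge
`p → c = export_p · import_c / max(total export, total import)`, residual
to/from a distinguished medium node. This conserves flow exactly, is
deterministic, and is symmetric in producers and consumers. Edge fluxes
are reported in abundance-weighted community units; edges at or below the
threshold (default 0.3 mmol/gDW/h) are dropped. Metabolites are
categorized as methanogenesis-related (CO₂, H₂, CH₄, acetate, pyruvate,
formate), proteinogenic amino acid, or other.

## Elasticities

The elasticity of export flux `v` to parameter `θ` is the one-sided
multiplicative finite difference
`E = Δln(|v| + ε)/Δln θ` with `ε = 1e-8` and step factor 2 (configurable).
Medium effectors scale the community import bound; abundance effectors
scale one species then renormalize the profile (abundances are
compositional). Fluxes below 1e-6 in both states give exactly zero.
Because bound changes switch LP bases, coefficients are only locally
meaningful; the tests assert signs and the two exactly-known cases
(proportional regime → 1, non-binding bound → 0). The intervention
pipeline runs on the medium-constrained community *without* the pinned
reactor gas uptake, which would otherwise null most gas responses by
construction.

## Co-occurrence screen

Coverage matrices are MAG × sample; replicates average arithmetically
into experiment-level profiles; experiments with less than 1 % summed
dominant-species abundance are dropped (boundary inclusive). Correlation
is plain Pearson with two-sided p-values from the t transform, masked at
α = 0.05 (pairs with p ≥ 0.05 are non-significant; a centered-log-ratio
pre-transform is available but off by default). Constant rows yield
undefined correlations, reported as missing.

The synthetic coverage generator uses a Gaussian copula: correlated
standard normals pushed through `exp(σ·z)` with per-MAG depth scales, so
coverages are non-negative and right-skewed. Correlation targets are
pre-amplified to compensate both the independent-noise attenuation
(factor `1 + noise_sd²`) and the lognormal transform (inverted
analytically), so planted blocks land within ±0.05 of target by
n ≈ 100 samples. Jointly infeasible blocks (non-PSD latent correlation,
or `|r|·(1+noise_sd²) > 1`) raise errors.

## Problem sizes and numerical choices

The default community model has ~140 reactions and ~110 metabolites;
tradeoff solves take ~1–2 s. The nine-point gas sweep and the
intervention matrix are the heaviest steps (tens of solves). The oracle
comparisons run on communities of ≤ 6 reactions (vertex enumeration is
exponential) and two species (grid search). Coverage fixtures use 500
synthetic experiments for recovery tests and the 59 × 134 default shape
for the screen. Ties in the LP are resolved by HiGHS deterministically;
the QP stages remove the scientifically relevant degeneracy (growth
rates, exchange fluxes). All tolerances (feasibility 1e-6, optimality
1e-8, plateau detection 1e-3 relative) are configurable at the call
sites.

## Known limitations

* SBML support covers the constraint-based subset via cobrapy; groups,
  annotations and gene associations are ignored.
* Proportional edge allocation is one of several flow attributions
  consistent with pool-mediated exchange; pairwise arrows are an
  interpretation, not an observable of the LP.
* Elasticities are finite-difference, one-sided, and step-size dependent
  near basis changes.
* Pearson on relative abundances inherits compositional biases; the CLR
  option mitigates but does not remove them.
* The toy stoichiometries are carbon/nitrogen-exact but energy-lumped;
  absolute growth rates are not comparable to genome-scale
  reconstructions.
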