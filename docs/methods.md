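# Methods

`emkin` implements a two-layer description of fermentative central
metabolism of the kind used for *Clostridium thermocellum*: a stoichiometric
layer for steady-state flux analysis and a kinetic layer built by Ensemble
Modeling (EM). This note records the models, the numerical choices, and
what the synthetic test beds do and do not establish.

## Stoichiometric layer

Flux balance analysis solves max/min cᵀv subject to S·v = 0 and
lb ≤ v ≤ ub; flux variability analysis re-solves the LP per target
reaction. All LPs and MILPs go through HiGHS (scipy.optimize.linprog/milp).
Numerical conventions: feasibility tolerance 10⁻⁹, reported fluxes rounded
below 10⁻⁶ to zero, and bounds beyond ±1000 mmol/gDW/h truncated at ±1000
(truncated reactions are recorded on the problem object). GAM is embedded
in the biomass reaction's ATP hydrolysis stoichiometry; NGAM is a fixed
flux (lb = ub) on a dedicated ATP-maintenance reaction.

### Thermodynamically infeasible cycles

A TIC is a set of internal reactions that carries flux with every exchange
closed. Detection is definitional: close all exchanges (relaxing positive
demands so v = 0 stays feasible), run FVA, and collect reactions whose
range is nonzero; connected components of the metabolite-sharing graph are
reported as cycles with direction signs read from a feasible circulation.

Elimination uses a marker-metabolite constraint rather than deleting
reactions: for each cycle a marker metabolite i (ideally unique to the
cycle, e.g. hydrogen for hydrogenase loops) and the cycle set J_i^c are
declared, and every cycle member's absolute flux is bounded by the absolute
*net* flux of all non-cycle reactions involving i:

    | Σ_{j ∉ J_i^c} S_ij v_j |  ≥  | v_{j*} |,  ∀ j* ∈ J_i^c.

The net-sum reading (not a sum of absolute fluxes) is deliberate: it makes
the closed-exchange circulation infeasible while still allowing all
alternate-cofactor reactions to be active simultaneously under open
exchanges. The disjunction on the sign of the net term is encoded as a
MILP with one binary per marker and a relaxation constant scaled to the
term's worst-case magnitude; when direction hints (or the model bounds)
pin the sign of every contributing term, the constraint collapses to a
pure LP. A helper suggests markers (the metabolite shared by all cycle
reactions that appears in the fewest others), but marker choice remains a
modeling input.

Yield ranges fix the substrate exchange at one unit of uptake (the LP is
scale-invariant, so yields equal fluxes at that scale), convert measured
yield boxes to flux bounds, and run FVA on the product exchange. An
infeasible measurement set is diagnosed by leave-one-out relaxation, which
names the mass-imbalanced measurements.

## Kinetic layer (Ensemble Modeling)

Each net reaction is decomposed into an ordered sequential elementary
mechanism: one binding step per distinct substrate (stoichiometric
coefficients become exponents of the mass-action term), a central
conversion between the fully loaded complexes, and one release step per
distinct product; a uni-uni reaction gives 3 steps, a bi-bi reaction 5.
More than four distinct species on one side is refused (lump first).
Substrate-level regulation adds dead-end steps: effector binding to the
free enzyme (competitive and product inhibition) or to the loaded complex
(uncompetitive).

Concentrations are nondimensionalized to the reference state (reference
pool ≡ 1, wild-type total enzyme ẽ_tot ≡ 1), since absolute pools are
unknown; all reported pools are fold-changes and all fluxes are normalized
to substrate uptake (mol per mol). Enzyme dosage enters through the
conserved total of each reaction's enzyme forms: ẽ_tot = 0 is a deletion,
[0.1, 1] the downregulation band, [1, 10] the upregulation band; an
unreported twofold change is simulated at 0.5 or 2.0.

### Reference-anchored sampling

For each ensemble member and reaction with reference flux v: enzyme-form
fractions are drawn from a flat Dirichlet simplex (redrawn if any fraction
falls below 10⁻⁴), each step's reversibility R = v_backward/v_forward is
drawn uniformly on (0,1), and the elementary constants are back-computed so
the step's net rate equals v at reference concentrations:
k_f = v/(1−R)/Π[reactants], k_r = R·v/(1−R)/Π[products]. R is clipped into
[10⁻³, 0.99] so back-computed constants stay finite and the ODE system
integrable — a numerical guard, not a thermodynamic statement. Reactions
with zero reference flux (and all dead-end regulatory steps) are sampled at
equilibrium with exchange rates drawn from (0.1, 2), keeping their
constants perturbable. Every member therefore reproduces the reference flux
state exactly at ẽ_tot ≡ 1; perturbation data alone discriminate members.
`anchored_parameter_set` exposes the same back-computation with explicit
fractions and reversibilities, which is how the test suite plants designed
saturation margins.

### Steady states

The mass-action ODE system (species = free metabolite pools + enzyme
forms; clamped boundary pools enter as constants) is compiled to
numba-jitted rate and Jacobian kernels. The solver tries a damped
Levenberg–Marquardt Newton on the augmented system [dC/dt; L(C − C₀)]
first — the conservation rows L (left null space of the step
stoichiometry) pin the compatibility class and make the singular system
well posed — accepting a root only if the Jacobian has no positive real
eigenvalue (the dynamically stable branch). Otherwise it integrates with
lsoda over geometrically growing windows (rtol 10⁻⁸, atol 10⁻¹², horizon
10⁶ normalized time units, 3000 steps per window so a pathological member
cannot consume unbounded time), polishing with Newton whenever the
trajectory gets close. Convergence means ‖dC/dt‖∞ < 10⁻⁹.

Non-convergence is a result, not an error: species beyond 10⁶ or below
10⁻⁹ with a monotone trend are reported as divergent, with a trend-based
fallback (pool above 100× reference and still growing monotonically at the
horizon, or symmetrically draining) so that a blow-up that has not yet
crossed the hard watermark is still named. This signal drives the
robustness analysis: each reaction's ẽ_tot is perturbed by 0.5× and 2×,
and a divergent run names the runaway species and its adjacent consumer
(accumulation) or producer (depletion) — the non-robust node.

Lumped Michaelis–Menten constants are derived from the elementary chain
via the quasi-steady-state enzyme distribution (linear in the forms at
fixed metabolite concentrations): initial-rate curves with co-substrates
saturating and products absent are exactly hyperbolic for this mechanism,
so a double-reciprocal regression recovers Km and Vmax (kcat = Vmax at
ẽ_tot = 1); the closed-form King–Altman expressions for the uni-uni chain
serve as the oracle in tests.

## Training layer

The fitting objective is the CV-scaled relative deviation,

    D = (1/M) Σ_m (1/N_m) Σ_i (1/CV_i) |v_i − v_i^exp| / |v_i^exp|,

averaged within and then across datasets. The magnitude convention is the
default (signed residuals would cancel); a signed variant exists behind a
flag. Measurements with a zero reference value are scored on the absolute
difference over CV and flagged. Unreported CVs default to 0.5 (a ~50%
measurement error is typical of pooled fermentation libraries).

The genetic algorithm selects, per reaction, one member of that reaction's
sampled parameter pool — anchoring is per reaction, so recombination
preserves the reference state — plus a free ẽ_tot gene for each
up/down-regulated enzyme without a reported level. Defaults: population
100, generations 200, uniform crossover 0.8, per-gene mutation 0.05,
tournament size 3, elitism 2, stop after 20 stagnant generations.
Non-convergent members take a 10³ penalty so fitness stays total, and
fitness evaluations integrate to a 10⁴ horizon (a member that has not
settled by then is treated as non-convergent). When the incumbent stalls
for 3 generations, a coordinate-descent sweep over its pool indices runs
one gene at a time — this memetic step sharply accelerates convergence on
the near-separable landscapes these pools produce. Everything is
deterministic given the config seed.

Leave-one-out cross-validation refits each fold with the same seed and
config; the held-out dataset is scored with the fold's model (free ẽ_tot
levels of the held-out genotype fall back to the twofold defaults, since
they were never fitted), next to the full-fit deviation of the same
dataset; the difference is the accuracy reduction attributable to that
dataset.

## Synthetic ground truth

The generator builds a branched fermentation analog: one lumped glycolysis
reaction (sugar + 2 NAD → 2 pyruvate + 2 NADH), two to four terminal
product branches with NADH stoichiometries 1/2/0/3 (lactate-, ethanol-,
acetate-, butanol-like), an amino-acid branch fed by a nitrogen transporter
and NADPH, a biomass drain, and a transhydrogenase pair with swapped
cofactor specificity planted as a TIC. Three product-inhibition loops
(amino acid on its dehydrogenase, NADPH on the transhydrogenase, lactate on
its dehydrogenase) stand in for the curated regulatory interactions of a
real model. The reference flux split is a fixed table per branch count
solving the pyruvate and NADH balances at unit uptake; formulas are
synthetic but elementally balanced (placeholder elements R/Q for the
cofactor scaffolds), so balance checking is exercised honestly. True
kinetics are sampled with the ensemble machinery (reference stability is
verified; the rare unstable draw is resampled with a deterministically
derived seed).

Mutant libraries simulate each genotype's true steady state and apply
multiplicative lognormal noise with σ² = ln(1 + CV²), which is unbiased in
log space and reproduces the configured CV; every measurement is tagged
with that CV. The default 19-genotype design (knockouts, two-fold up/down
regulations, doubles, and two unique-phenotype mutants — the
transhydrogenase and amino-branch deletions, whose information no other
mutant backs up) emits 19 measurements per mutant (7 yields + 12 pool
fold-changes) on the four-branch network. Companion datasets mirror the
other evidence shapes: one intracellular-concentration vector for a
downregulation mutant, and a noisy Km/kcat table for a few enzymes.

### Scale of the shipped analyses

The test suite and the acceptance script run desk-scale problems chosen as
the package's own study conditions: ground-truth recovery uses the
two-branch network (11 reactions), six mutants, CV 0.2, pools of 6 members
(plus the injected truth for the oracle-in-pool case), GA population 30
with 60–80 generations; cross-validation uses four datasets with population
16. Property suites (anchoring, LP/MILP equivalence, TIC definition,
elitism, robustness) are exact and cheap. What passing shows: the
machinery recovers known kinetics from data with the statistical shape of
real mutant libraries. What it does not show: identifiability or predictive
accuracy on a real 118-reaction network with 21 heterogeneous datasets —
real metabolism has unmodeled regulation, shared-subunit enzymes, and
measurement structure the lognormal model does not emulate.

## Known limitations

- The ordered sequential mechanism is a convention; random-order or
  ping-pong enzymes are projected onto it.
- Divergence classification is operational (watermarks and trends), not a
  proof of unboundedness; a sufficiently slow blow-up inside the horizon
  with a sub-threshold trend would be reported as merely non-converged.
- The LP path of the cycle constraint requires the non-cycle net term's
  sign to be deducible; mixed-sign hint sets fall back to the MILP
  encoding silently.
- Free ẽ_tot levels of held-out genotypes are not identifiable in
  cross-validation and default to the twofold points.
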