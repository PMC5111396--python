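# Methods

## Scope and model

`picogem` implements the constraint-based analysis layer used to study
phosphorus economy in picocyanobacterial genome-scale metabolic models
(GEMs): flux balance analysis (FBA) with dual-based sensitivity,
stoichiometric-matrix topology, biomass-objective analytics, phenotype
screens, and reporter-metabolite inference. All analyses run on any
model expressed in the package's tabular dialect; a generated toy
photoautotroph ships with the package so that every analysis is
exercisable and testable without external data.

### Flux balance analysis

The metabolic state is a flux vector `v` (mmol gDW⁻¹ h⁻¹) over the
`m x n` stoichiometric matrix `S`. FBA maximizes an objective flux
(usually the biomass reaction, giving the growth rate `Z` in h⁻¹)
subject to

    S v = b,    LB <= v <= UB,

with `b = 0` at steady state; nonzero entries of `b` force net
accumulation of single metabolites (used by the shadow-price
finite-difference checks and the succinate-costing procedure). The LP
is solved with HiGHS dual simplex (`scipy.optimize.linprog`,
feasibility tolerance 10⁻⁹). Metabolite duals `lambda`, and bound duals
`q1 <= 0` (lower) and `q2 >= 0` (upper), are read from the same optimal
basis.

**Shadow-price orientation.** We fix `lambda_i = dZ/db_i`: forcing
accumulation of a valuable intermediate costs growth, so a *negative*
shadow price marks a growth-limiting metabolite. Because textbook dual
statements leave the orientation ambiguous, `calibrate_dual_sign()`
checks the installed solver's marginals against a central finite
difference on a two-reaction chain; the test suite also verifies
`lambda` against finite differences for every toy metabolite (5%
tolerance at step 10⁻⁶).

**Degeneracy.** At a degenerate optimum the basic dual solution is not
unique. `solve_fba(..., check_degenerate_duals=True)` re-solves with
the right-hand side perturbed by 10⁻⁷ and flags metabolites whose dual
moves by more than 10⁻⁴. Reported duals are always the solver's basic
solution.

### Flux sums and elemental turnover

Metabolite turnover is `Phi_i = 1/2 sum_j |S_ij v_j|`. Elemental
turnover aggregates atom-weighted metabolite flux sums,
`Phi_e = sum_i A_ei Phi_i`, over *internal* reactions only (exchanges,
sinks, transporters and pseudo-reactions excluded), where `A` is the
element-by-metabolite atom matrix built from molecular formulas. Two
normalized variants are reported — per unit growth and quota
(`Phi_e / (mu q_e)`) and per unit transport influx — because the three
normalizers can be composed in more than one defensible order;
undefined normalizations (zero quota, zero influx) are reported as
`None` rather than infinities.

### Network topology

*Participation* is the fraction of internal reactions containing a
compound, with compartment-duplicated species merged first and
exchange/transport/sink columns excluded from both numerator and
denominator (transporters otherwise inflate the degree of every medium
compound). H₂O and H⁺ are excluded by default, as is conventional when
ranking currency metabolites.

The *systems-reaction* analysis is the SVD `S = U Sigma V^T` of the
internal+transport columns (pseudo-reactions excluded — the
biomass column's maintenance coefficients are an order of magnitude
larger than any chemistry and would otherwise own the first mode).
Rank is cut at `sigma_k > 1e-10 sigma_1`; fractional weights are
`sigma_k / sum(sigma)`. A compound is attributed to the smallest mode
index at which it enters the top 5 compounds by compartment-merged
root-sum-square |U| loading; the threshold is configurable because no
canonical attribution rule exists.

### Biomass objective function

A composition maps crude fractions (DNA, RNA, protein, lipid, pigments,
cell wall, carbohydrate, soluble pool, ...) to compounds with mass
fractions of ash-free dry weight summing to 1. Assembly converts mass
to `1000 * w / MW` mmol gDW⁻¹ coefficients and adds growth-associated
maintenance (GAM) as an ATP+H₂O → ADP+Pi term; non-growth maintenance
(NGAM) is a separate ATP-hydrolysis reaction with a fixed lower bound.
Defaults GAM = 30 mmol gDW⁻¹ and NGAM = 0.3 mmol gDW⁻¹ h⁻¹ are
documented placeholders for when no measured growth/uptake pair is
available to fit them.

*Enthalpy budget.* Heats of combustion use a Thornton-type estimate:
115 kJ per mole of transferable electrons, with the degree of reduction
computed from valences H +1, C +4, N −3, O −2, P +5, S +6 (combustion
products as reference states); negative degrees clamp to zero with a
warning, and the estimator is pluggable. The energy/cost regression is
ordinary least squares through the origin of `DeltaH_c` against
ATP-equivalent synthesis cost, and the aggregate energy density is the
mass-weighted `DeltaH_c` per gram.

*Growth sensitivity (Psi).* Each target pool is perturbed
multiplicatively by ±1 ppm **without** re-normalizing total biomass
mass (the perturbation acts on the biomass column directly); a
re-normalizing variant is available behind a flag. The sign convention
is growth gain per unit pool decrease, so a positive Psi means growth
rises when the pool shrinks. Reported shares are |Psi| percentages.
Step-halving changes toy Psi values by < 1%.

*C/P-constrained search.* Five variable fractions are scaled over a
multiplicative grid (default 7 levels on [0.1, 1.5]), each candidate is
re-normalized to unit mass, its molar C/P computed from formulas, and
candidates are binned over [0.9 x min, 1.1 x max] of the achievable
range (default 8 bins). Each candidate is grown under a suboptimal
constraint — the orthophosphate transporter (PLG mode) or the
carboxylation reaction (CLG mode) capped at 50% of its unconstrained
optimum flux by default (the fraction is configurable, as no canonical
value exists). Per-bin count, mean growth, CV, the best composition and
its phosphorus partition are reported; empty bins report n = 0.

*Quota arithmetic.* With baseline P normalized to 1,
`C' = (1 + c_increase) * (C/P)_base`, `P' = C' / (C/P)_target`, and the
non-static pools must shrink by `1 − (P' − s)/(1 − s)` where `s` is the
static share (e.g. DNA through G₁). `P' < s` is reported as infeasible;
results outside [0, 1] clamp with a warning.

### Phenotype screens

*Essentiality.* A knockout disables exactly the reactions in which
every enzyme complex contains the gene (complex-complete rule; isozymes
rescue). Lethality is growth below max(10⁻⁶, 0.1% of wild type) —
essential if lethal on all media, variable-essential if lethal on some.

*Substrate screens* open a transient exchange (default 10 mmol gDW⁻¹
h⁻¹) for each candidate on a medium stripped of the element's default
source; candidates without the element are excluded with a note.

*Variants.* Presets add the PQ-coupled succinate dehydrogenase
(SDH, reversible), 2-oxoglutarate decarboxylase (2OGDC) and succinic
semialdehyde dehydrogenase (SSADH). Application copies the model;
application followed by removal restores a byte-identical archive.

*Succinate NAD(P)H cost.* The steady state is solved, growth is then
pinned at 90% of the optimum (at 100% every resource is committed and
forcing by-product accumulation is infeasible whenever the limiting
uptake is saturated; the fraction is configurable), and the succinate
row of `dX/dt` is forced to `epsilon` (default 10⁻³). The cost is the
change in summed NAD(P)H-consuming fluxes per unit epsilon with a
per-reaction breakdown; it is stable to < 2% over a decade of epsilon
because the LP basis does not change in that range.

*Phase planes.* FBA on a grid of two exchange uptake bounds, recording
growth, tracked fluxes, the PSI/PSII photon-absorption ratio (photon
stoichiometry x flux) and ATP/NADPH production ratio. A cell lies on
the line of optimality when both uptake constraints are genuinely
active; because the basic dual at the ridge is degenerate and free
dissipation can park a flux at its bound, activeness is probed by
minimizing each uptake at fixed optimal growth — an irreducible uptake
equal to the bound is active.

*Diel simulation.* Quasi-steady-state FBA at each timestep (default
0.5 h) with the photon bound following the irradiance profile times a
configurable absorption factor (default 0.5 mmol photons gDW⁻¹ h⁻¹ per
µmol photons m⁻² s⁻¹). In the dark — and at twilight steps where
photosynthesis cannot cover maintenance — growth is held at zero and
NGAM is paid from a bounded glycogen-drawdown sink (default 0.5 mmol
gDW⁻¹ h⁻¹); a step where even that fails is a dark-survival failure.
The reported growth rate is the 24-h trapezoidal integral of µ(t)
(day⁻¹), not the instantaneous maximum. GPP is the carboxylation flux
and NPP the net CO₂ influx, per cell at a configurable cell mass
(default 60 fg DW).

### Reporter metabolites

Gene scores are `Z = Phi^-1(1 - p)` with p clamped to
[10⁻¹⁵, 1 − 10⁻¹⁵]; the default is one-tailed and direction-blind, a
signed variant uses the fold-change sign. A metabolite with k scored
neighbor genes (union over its reactions' GPRs; unscored genes are
dropped, not imputed) gets raw score `sum(Z)/sqrt(k)`, corrected by the
mean/SD of that statistic over 10⁴ seeded random k-gene draws from the
scored gene set. Sampling (rather than a closed form) matches the
published algorithm's behavior for duplicated genes; for an i.i.d.
standard-normal gene set the background reproduces the exact
finite-population moments (mean `sqrt(k) zbar`, SD with the
without-replacement correction). Note that on very small gene sets the
finite-population correction makes corrected scores slightly
underdispersed; calibration approaches N(0, 1) as the gene set grows.

Subnetworks grow greedily from the top reporter metabolites over the
shared-reaction adjacency graph, accepting the neighbor that most
increases the background-corrected aggregate Z of the member-gene
union, capped at a size limit; accepted metabolites are not reused by
later seeds, so reported subnetworks are disjoint. Greedy search (not
simulated annealing) keeps results reproducible bit-for-bit under a
fixed seed; on planted-module benchmarks it attains the exhaustive
connected-subset optimum.

The shadow-price comparison merges compartment species (maximum
magnitude per compound) and reports the Spearman correlation of
reporter Z against `|−lambda|` plus top-k overlap.

## The toy photoautotroph

The generator emulates a small compartmentalized oxygenic phototroph
(33 metabolites, 35 reactions, 31 genes, 4 compartments by default;
well under the brute-force budget of 40 x 35 so that vertex-enumeration
and subset oracles run in seconds):

* **Electron transport** — PSII (4 photons → 2 PQH₂, 4 H⁺ pumped),
  cytochrome b6f (2 H⁺ per PQH₂), PSI, FdR, the cyclic routes NDH
  (NADPH → PQ, pumping) and FQR (Fd → PQ), the pseudocyclic oxidase COX
  (bd-type), and a 3 H⁺/ATP synthase, wired through PQ/PQH₂,
  plastocyanin and ferredoxin pools in membrane/lumen compartments.
  Pure linear flow yields ATP/NADPH = 4/3, below the ~3/2 demand of
  carbon fixation, so alternative electron flow is always engaged —
  reproducing the qualitative flux-partitioning behavior of real
  cyanobacterial photosynthesis with one-electron bookkeeping rather
  than photochemistry.
* **Carbon** — Rubisco-like carboxylation plus a three-step CBB loop
  (reduction, lumped regeneration 5 GAP + 3 ATP → 3 RuBP), glycogen
  interconversion, an oxidative pentose phosphate shunt (the dark
  catabolic route), and lower glycolysis.
* **Branched TCA** — an oxidative branch to 2-oxoglutarate (feeding
  glutamate/protein) and a reductive branch to fumarate and succinate;
  no 2-oxoglutarate → succinate route exists unless 2OGDC+SSADH are
  knocked in, and succinate is a dead end in the wild type (its
  reduction step is deliberately the toy's one blocked reaction).
* **Biomass** — eight crude fractions drain precursors with real or
  realistic formulas (AMP, dAMP, glutamate, glucose, a P-free
  glycolipid — picocyanobacteria substitute glycolipids for
  phospholipids — a P-carrying cell-wall unit, a pigment, and ATP as
  the P-bearing soluble pool). Lumped syntheses solve their CO₂, H₂O
  and H⁺ coefficients from the element-balance linear system, so every
  internal reaction is elementally balanced by construction and
  asserted at generation time. Fraction masses are
  Prochlorococcus-flavored (protein 0.55, lipid 0.12, DNA 0.015,
  pigments 0.04, cell wall 0.05, soluble pool 0.01 g/gDW); the
  RNA/carbohydrate remainder is split in closed form so the molar C/P
  of the composition equals the configured baseline (default 121).
* **GPRs** — four multi-subunit complexes (PSII, PSI, ATP synthase,
  Rubisco, and a lumped two-enzyme conjunction on the reductive TCA
  branch), one isozyme pair on lower glycolysis, and single-gene
  reactions elsewhere; pangenome classes are assigned core/flexible/
  unknown. Optional mass-balanced filler isomerizations scale the
  network for topology tests without altering growth.

Charges are tracked but advisory (the lumped syntheses are not charge
consistent); elemental balance is the enforced invariant, matching
practice for models whose ion bookkeeping is acknowledged to be
approximate.

**Default medium.** Photon uptake 100 mmol gDW⁻¹ h⁻¹ (binding;
growth 0.28 h⁻¹), Pi 10, NH₃ 10, CO₂ effectively unlimited. Phosphorus
limitation for screens uses a Pi bound of 0.05 unless stated.

**What passing toy tests do and do not show.** The toy reproduces the
*mechanisms* — duality structure, P-limitation signatures, electron
flow partitioning, composition/growth trade-offs — not any published
organism's numbers (gene counts, mode indices, percent weights).
Results on real GEMs depend on curation quality, cofactor specificity
and medium realism that the toy deliberately omits; the toy also lacks
photorespiration, the Mehler reaction, photodamage, and ion transport.

## Problem sizes and numerical choices

The default test suite solves a few thousand LPs of size ~33 x 35 and
runs in well under a minute; the reporter null-calibration suite pools
60 independent null tables at 10⁴ background draws each. LP
feasibility tolerance is 10⁻⁹; balance checks use 10⁻⁶ on atom counts;
SVD rank cut 10⁻¹⁰ relative; sensitivity steps 10⁻⁶ (±1 ppm);
C/P-search enumerations in tests use 3–5 levels on 2–3 fractions so the
exhaustive oracle stays exact and fast. Ties in greedy subnetwork
growth break toward the lexicographically first candidate via sorted
frontiers, making results order-independent.

## Known limitations

* Duals at degenerate optima are basis-dependent; the perturbation
  probe flags but does not resolve them.
* The SBML importer covers Level 3 + fbc (bounds, GPRs, objective) but
  not annotations, groups, or notes-field metadata round-trips; the
  tabular dialect is the canonical archive.
* BioOpt format is not supported.
* The enthalpy estimator is a group-free electron-counting
  approximation; compound-specific heats of combustion should be
  supplied through the pluggable method when available.
* `cp_search` enumerates a full factorial grid; 7 levels on 5 fractions
  is ~17k LP solves (about a minute on one core) and grows
  exponentially with the number of variable fractions.
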