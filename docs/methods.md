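# Methods

## Model representation and conventions

A model is a list of metabolites (compartment-suffixed ids, e.g. `hco3_e`)
and reactions (stoichiometry map, bounds, GPR string, subsystem label) with
one designated biomass objective. Uptake through an exchange reaction is a
negative flux; a bound pair with `lb == ub` is a forced (equality) uptake,
which is how the nutrient constraint tables are read — the printed tables
give identical lower and upper bounds for the carbon and nitrogen
exchanges, and the simulations require the available carbon to actually be
taken up. `block_others` closes every exchange not named in a constraint
table, matching the convention that unlisted exchanges are blocked.

Two formats round-trip exactly: SBML Level 3 + fbc (through cobrapy /
libsbml; the subsystem label is carried in the reaction notes, which SBML
preserves) and a flat JSON dialect used for fixtures. A gene "participates"
in a reaction if it appears anywhere in the GPR regardless of the and/or
structure — mapping counts use bare association, which is what
gene-to-reaction tallies in this kind of analysis mean.

Currency metabolites (h2o, atp, adp, amp, nad(h), nadp(h), h, o2, pi, ppi,
co2) are matched by exact compartment-stripped base id, not by prefix —
`hco3` must not match the currency id `h` or `co2`. The list is
configurable per model.

## LP engine

All programs go through `scipy.optimize.linprog` (HiGHS), isolated behind
one `_solve_lp` call so the backend is swappable. Infeasibility is reported
as a solution status, not an exception, because scenario code needs to
distinguish "no steady state under these constraints" from bugs.

* pFBA splits `v = p − q`, `p, q ≥ 0`, minimizes `Σ(p+q)` with the
  objective pinned to its optimum (±1e-9 slack to absorb solver noise);
  the result is clipped to the original bounds, since the slack can leave
  fluxes a solver-tolerance below zero on demand reactions. pFBA is the
  canonical single flux vector wherever one is reported; sampling is the
  primary tool for distribution-level statements.
* Blocked-reaction pruning uses feasibility FVA (objective fraction 0) with
  tolerance 1e-9 — the solver-noise floor; pruning is idempotent, never
  removes the objective reaction, and preserves the optimum (asserted in
  tests).

## Uptake scenarios

A scenario forces carbon uptake along a strictly increasing grid, sets
nitrogen per rule (constant, or +`ramp_step` per grid point once carbon
reaches `ramp_threshold`), opens/closes the storage and release demands,
and solves parsimoniously at each step. The limitation breakpoint is the
*last grid point at which biomass still increased* (the start of the
plateau, detected with tol 1e-8 in flux units); its resolution is one grid
step, and the default grid step is 0.3 mM on the toy sweeps (0.1 mM for the
fine C/N sweep). The breakpoint C/N ratio equals the biomass C:N
stoichiometry in closed form, which is what the tests pin.

## Flux-space sampling

Artificially-centered hit-and-run (ACHR): warmup points are the 2·n FVA
extreme LP solutions plus their centroid; each chain step picks a stored
point, takes the direction from the running center towards it, and lands
uniformly on the feasible chord. Two numerical choices matter:

* Directions are projected onto an orthonormal basis of the null space of
  `S` restricted to non-fixed coordinates. Without this, normalizing a
  short direction (target near the center) amplifies the LP residual and
  the chain drifts off the stoichiometric subspace multiplicatively; with
  it, the worst mass-balance residual over 2000 samples stays below 1e-13.
* Bound overshoot below 1e-9 is repaired by clipping; anything larger
  aborts (it would indicate broken chord arithmetic, not float noise).

The published "step count" convention (a total mixing parameter of twice
the reaction count) is mapped to a per-sample thinning of
`ceil(step_count / n_points)`, minimum 1. Desk-scale defaults are 2000
points; uniformity is validated against a rejection-sampling oracle on 1-D
and 2-D polytopes where rejection sampling is exact (two-sample KS p > 0.01
per marginal at n = 2000, thinning 20 on the 2-D case to tame chain
autocorrelation). Runs are pure functions of (model, n_points, step_count,
seed).

## The distribution-shift test

Per reaction with condition vectors `v_low, v_high` of length n: per repeat
draw independent permutations π, σ, form `d = v_low[π] − v_high[σ]`, count
`m = min(#{d>0}, #{d<0})` (exact zeros count toward neither sign), average
m over 100 repeats, and set `p = min(1, 2·mean(m)/n)`. A pair of
elementwise-identical vectors is assigned p = 1 directly — otherwise two
identical constant columns (e.g. a forced exchange compared with itself)
would yield the degenerate p = 0. Direction is the sign of
`median(high) − median(low)`; BH-FDR runs across all tested reactions at
threshold 0.05.

Power profile (derived, and verified by simulation in the tests): the
minority-sign fraction for two unit normals a distance δ apart concentrates
at Φ(−δ/√2), so p ≈ 2Φ(−δ/√2) nearly deterministically for large n. The
test therefore flags a reaction only once the two flux distributions are
nearly disjoint — p < 0.05 needs δ ≳ 2.8 sd — and a 2-sd mean shift sits at
p ≈ 0.157 regardless of sample size. This is a property of the statistic
itself, not of the implementation: it is exactly what makes the test
conservative on broad overlapping flux ranges while instantly flagging
reactions whose feasible ranges separate (forced uptakes, their transport
chain). Type-I error is far below nominal (p concentrates near 1 under the
null). The planted-shift generator's default displacement of 2 sd is kept
as the stated study condition; tests document that such shifts fall below
the detection floor while well-separated columns (≥ 6 sd in fixtures) are
recovered exactly.

## Cluster metrics

Enrichment is the exact hypergeometric tail per (cluster, term):
`P(X ≥ k)` for over-representation, `P(X ≤ k)` for under-representation
("purified"), the smaller tail deciding the direction, BH across all pairs,
no term-hierarchy propagation. The universe defaults to the union of
cluster genes.

Connectivity of two clusters is shared metabolites over "the total in both
clusters", read as the set union (Jaccard): with a summed denominator no
pair could exceed 0.5 and the stated 0.9 threshold would be unreachable.
The denominator remains selectable (`union`/`sum`). The threshold is
strict: a pair at exactly 0.9 (|∩| = 9, |∪| = 10) gets no edge.
Reversible reactions contribute their metabolites to both the substrate and
product sets. Betweenness is computed on the unweighted topology; edge
scores are carried as weights but module statements are qualitative.

## Synthetic fixtures

The toy network (14 reactions, 9 metabolites, compartments e/c) book-keeps
carbon in integer units (1 `cfix` = 1 carbon) so conservation closes
exactly: 6·biomass + 5·DMSP + 50·TAG + 7·chrysolaminarin = carbon uptake at
every steady state. The chrysolaminarin route carries one extra carbon per
unit so that parsimonious FBA deterministically prefers the TAG store —
a modeling device to make the storage-preference prediction reproducible,
not a biological claim. Default stoichiometry (6 C, 1 N per biomass; 5 C
per DMSP; 50 C per TAG) keeps the breakpoint at C/N = 6 and the demand
fluxes at hand-computable values.

Planted flux-sample fixtures are i.i.d. normal (or lognormal) matrices with
a subset of columns mean-shifted in the high condition; they are
intentionally not mass-balanced — the statistic is distribution-level, and
sampler feasibility is validated separately. Planted cluster fixtures
extend a model copy with one private-source, multi-product reaction per
cluster so the genes → reactions → product-sets path realizes requested
pairwise Jaccard overlaps (±0.02; interacting high targets on a path are
reported as unachievable rather than silently missed), plus a term table in
which each cluster is enriched 8-of-10 against ~40 carriers in a
400-gene universe.

What the fixtures do *not* emulate: real sampling distributions are
correlated across reactions and highly non-normal; real cluster product
sets overlap through shared pathways rather than designed pools; and the
toy network has none of the compartmental redundancy of a genome-scale
reconstruction. Passing tests therefore certify the machinery (LP, chain,
statistic, set arithmetic) against oracles, not biological fidelity at
genome scale.

## Known limitations

* The shift test cannot detect moderate overlapping shifts by
  construction (see the power profile above).
* Quantities tied to the published genome-scale reconstruction (pruned
  model size, the 10.28 C/N breakpoint, the 175-reaction hit count, the
  2/20/44 module sizes) require that external model and are out of scope
  here; the corresponding machinery is exercised on the toy network with
  closed-form expectations instead.
* No thermodynamic or enzyme-capacity constraints, no MILP designs, no
  biclustering or TF-influence inference — cluster assignments and DE gene
  lists are inputs.
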