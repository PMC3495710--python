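# Methods

## Model representation

A model is an ordered list of species with non-negative initial amounts
and an ordered list of irreversible reactions, each with positive integer
reactant/product stoichiometries and one non-negative mass-action rate
constant. Species order is part of the model: it fixes the coordinates of
every state vector, which makes all outputs (CSV columns, PRISM variable
order, state enumeration) deterministic.

Amounts are molecule-count-like numbers in both semantics (volume factor
1). This is deliberate: the worked enzymatic example uses the same values
(S0=12, E0=10, k1=0.184, k2=0.016, k3=0.211) deterministically and
stochastically, and keeping a single amount scale lets rate constants be
shared verbatim. For stochastic analyses initial amounts must be integers;
the deterministic side accepts any non-negative reals.

The native format is JSON with explicit ordering. The SBML reader
supports a deliberately small Level-2 subset — one compartment, species
as amounts, irreversible reactions whose kinetic law is literally
`k * reactants` (with `power` for stoichiometries > 1) — and rejects
everything else loudly rather than approximating. Reversibility must be
declared `reversible="false"`; SBML's default of `true` is treated as an
error, not silently split.

## Conservation analysis

Bounds for PRISM variables and state-space safety come from non-negative
left-null vectors y of the net stoichiometric matrix N (yᵀN = 0, y ≥ 0):
y·x is then invariant, and species i is bounded by min over laws of
⌊y·x0 / y_i⌋. These vectors are enumerated exactly over the integers with
a Farkas-style column elimination: start from the identity, and at each
reaction column replace positive/negative pairs by their cancelling
combinations, reducing each vector by its gcd. A signed rational
nullspace basis (as returned by generic linear algebra) is not enough
here, because non-negativity of the combination is what makes the bound
valid; hence the dedicated routine. Intermediate growth is capped at
2·10⁵ rows — far beyond desk-scale networks. Species covered by no law
are reported unbounded (∞) rather than raising, so callers can decide;
the PRISM exporter refuses to emit unbounded variables.

## Deterministic semantics

ODEs dx_i/dt = Σ_r n_ir k_r Π_j x_j^{s_jr} and their analytic Jacobian
are generated directly from the stoichiometry. Integration uses LSODA
(stiff-capable, automatic method switching) with the supplied Jacobian on
a uniform output grid. Defaults: horizon 30 s with 301 grid points (the
display window in which the enzymatic system both peaks and settles), and
rtol = 1e-8, atol = 1e-10, comparable to a production CVODES setup.
State is clipped at 0 inside the right-hand side so that round-off
excursions below zero cannot produce invalid powers; mass-action
positivity guarantees trajectories stay non-negative up to solver
tolerance.

`peak_time` reports the grid time of the maximum, earliest on ties, with
no interpolation; comparisons to the worked example's "2nd second" are
made at one-second resolution, since that claim is a rounded reading.
`trajectory_mse` requires bit-identical time grids (including t = 0) and
averages the squared difference over all grid points; the grid is a
reproducibility choice, not a numerical one.

## Stochastic semantics and expected-reward queries

The reachable state space is the breadth-first closure of the initial
state under all reactions with positive propensity; propensities use
falling factorials per reactant stoichiometry. BFS discovery order is the
canonical state ordering. A cap (default 10⁶ states) guards against
accidental infinite or huge spaces.

The limiting amount of a species is defined as its almost-sure long-run
value: the chain is absorbed into some bottom strongly connected
component (BSCC), so the limit exists as a constant only if the species
is constant within every BSCC and the constant is the same across BSCCs;
anything else raises rather than returning an average. For the enzymatic
model every absorbing state has S = ES = 0, so P's limit is the conserved
total 12.

The query class is the expected accumulated impulse reward — 1 per firing
of a designated reaction — until a target predicate (one species ≥ or > a
threshold) first holds. Timing is irrelevant to such counts, so the
computation lives on the embedded jump chain: with transition
probabilities p = rate / exit-rate, the expectations x_s satisfy
x_s = Σ p·(1[counted] + x_dst) over non-target states, x = 0 on targets,
solved with a sparse direct method (CSC LU). The reward counted on the
transition that *enters* the target is included, matching standard
reward-reachability semantics. If any reachable state cannot reach the
target (including deadlocks), the target is reached with probability < 1
and the query's value is +∞; this is detected by reverse graph reachability
before solving, so the answer never depends on a numerical singularity.
The half-max query builder reads "reaches 50% of its maximum" non-strictly
(threshold ⌈½·limit⌉, i.e. P ≥ 6 for the fixture) by default because that
reading matches the worked example's reported value (≈ 6.455, "slightly
more than 6"); a strict mode (P ≥ ⌊½·limit⌋+1) is available.

Two independent routes exist to every such value: the linear solve and a
Gillespie direct-method estimator (seeded, reproducible), and the test
suite keeps them within 3 standard errors of each other at 10,000 runs.
For one enzyme there is also a closed form — each complex converts with
probability k3/(k2+k3), so the association count to the 6th conversion is
negative binomial with mean 6·(k2+k3)/k3 — which the solver reproduces to
machine precision.

## Multi-parameter sensitivity analysis

The procedure: (1) pick rate constants; (2) give each the range
nominal × [¼, 4]; (3) draw n = 400 Latin-hypercube samples, uniform per
coordinate on the linear scale (log-uniform is available but off by
default — the symmetric ¼×–4× interval is already log-symmetric around
the nominal); (4) score each sample against the nominal model with one of
two error functions: the MSE of the product trajectory (ODE backend) or
the absolute difference of the half-max expected-reward query (PMC
backend, target threshold frozen from the nominal model since rate
changes do not move conservation-determined limits); (5) classify samples
as acceptable iff their error is strictly below the median — strictness
gives an exact n/2 split for even n with distinct errors, and ties,
which the median rule otherwise leaves ambiguous, land on the
unacceptable side; (6) per parameter, compare the ECDFs of acceptable
vs unacceptable sample values with two indices: the two-sample KS
statistic, and 1 − Pearson correlation of the two ECDFs evaluated on the
pooled unique values (a parameter-free, symmetric grid). Larger index =
more sensitive; the result carries one ranking per index.

Samples whose evaluation fails (solver failure, infinite reward) are
excluded and counted; more than 10% failures aborts the analysis.
Evaluation is sequential and the result is a pure function of
(model, config, seed) — byte-identical reports on rerun.

The raw KS statistic, not a p-value, is the index: the two groups have
deterministic sizes (n/2 each), so the statistic is comparable across
parameters, which is all a ranking needs. As a sanity anchor, a parameter
with no influence at all stays below the 5% two-sample critical value
1.36·√(4/n) at n = 400.

## What the built-in fixture does and does not show

The enzymatic model is the package's reference workload: 4 species, 3
reactions, 88 reachable states, two exact conservation laws, analytically
checkable reward values. Passing tests on it demonstrate correctness of
the machinery — ODE derivation, exact enumeration, BSCC analysis, linear
reward solves, the MPSA pipeline — on a model where every answer has an
independent oracle. It does not demonstrate scalability (CTMC state
spaces grow combinatorially; the enumeration cap exists precisely because
realistic signalling models overflow desk memory), nor behavior under
non-mass-action kinetics, which the toolkit deliberately refuses to
import.

## Numerical and design choices

* Exact integer arithmetic for conservation laws; everything downstream
  of them (bounds, PRISM guards) is exact.
* Sparse LU (scipy spsolve) for reward systems; the infinity case is
  decided by graph analysis, never by the solver.
* Determinism: species order fixes coordinates; BFS fixes state order;
  seeds fix LHS and SSA; JSON reports are written with sorted keys and
  repr-precision floats.
* The worked example's sweep grid E(0) = 1..12 is the CLI default and is
  configurable; both total reward and reward per enzyme are reported,
  since both readings of "efficiency" are in use.
* Problem sizes in the test suite (10,000 SSA runs, 400-sample MPSA over
  20 seeds) were chosen as the smallest sizes at which the statistical
  assertions have comfortable margins.

## Known limitations

* Only the reward-until-target query class is implemented — no
  time-bounded operators, no transient distributions (uniformization),
  no general CSL parser.
* Full SBML (events, rules, function definitions, units, reversible-rate
  laws) is out of scope; the importer is a strict subset reader.
* MPSA offers the median-threshold Monte Carlo filtering variant only; no
  Sobol or Morris methods.
* The per-enzyme efficiency sweep re-enumerates the chain per E(0);
  acceptable at desk scale, wasteful for large chains.
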