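# Methods

## The model

A network architecture is a hypergraph 𝒢 = {O₁, …, O_m} over a finite
variable set *L*, required to be a *reduced cover*: every variable occurs in
some edge and no edge contains another. Each edge is one jointly-acting
element of the network context; an architecture therefore encodes which
subsets of the subnetwork are constrained together, not which variables
physically interact. Given a directed network with a designated focal
subset, the architecture is derived by taking, for each focal node, its
non-focal ancestors (all context nodes with a directed path to it),
collapsing connected components of the induced context subgraph into single
abstract-influence nodes, mapping each component to the edge of focal nodes
it reaches, adding singleton edges for focal nodes without context
ancestors, and reducing to an antichain. Focal-internal arcs are ignored:
the architecture describes the context's grip on the subnetwork.

Each variable takes values in a finite level set (coarse-grained molecule
counts). Joint states are indexed lexicographically with the first variable
slowest; the same rule indexes edge states. The marginalization operator
*G* has one row per (edge, edge state) and one column per joint state, with
entry 1 exactly when the joint state restricts to the edge state. An
edge-marginal family *v* (one table per edge) is globally consistent iff
{*Gx* = *v*, *x* ≥ 0} is feasible; normalization of *x* is implied because
each edge block of *Gx* sums to the total mass of *x*.

Local consistency is the pairwise-overlap condition: for every pair of
edges with intersection *S* and every state of *S*, the two marginalizations
onto *S* agree, together with per-edge normalization. Over the rationals
this is exactly orthogonality to coker(*G*) plus one overall normalization
(a property test asserts the equivalence on random vectors). Only pairwise
overlaps are emitted; higher-order overlap conditions are implied.

## Acyclicity and the junction-tree witness

Acyclicity is Graham/GYO reducibility: repeatedly delete variables occurring
in exactly one edge and edges contained in another; acyclic means the
hypergraph empties. The reduction is confluent (tested over randomized
deletion orders) and isomorphism-invariant. This is the notion under which
local consistency implies global consistency: a reduced GYO-acyclic
hypergraph is exactly the set of maximal cliques of a chordal graph, so a
maximum-weight spanning tree of the edge-intersection graph (weights
|Oᵢ ∩ Oⱼ|) is a junction tree, and the joint

x(e) = p_root(e_root) · ∏_child p_child(e_child) / p_sep(e_sep),  0/0 := 0

reproduces every table exactly (`extend_acyclic` verifies *Gx* = *v* in
exact arithmetic before returning). Cyclic architectures instead admit
frustrated families; perfect pairwise anticorrelation around the binary
triangle is the canonical certificate that 𝕄(𝒢) ⊊ 𝕃(𝒢).

## Deciding global consistency

Two routes, selected by input type:

* exact tables (Fractions) and ≤ 256 joint states: a hand-written Phase-I
  simplex over `fractions.Fraction` with Bland's rule. Boundary families
  (vertices of 𝕄(𝒢)) are decided exactly and reported feasible — closed
  polytope semantics. No installed library offers exact rational LP, which
  is why this primitive is implemented here.
* float tables, or larger spaces: scipy's HiGHS LP minimizing the L1
  residual of *Gx* = *v* over *x* ≥ 0; feasible iff the optimum is ≤ 1e-9.
  Float input is itself rounded, so demanding exact feasibility would
  spuriously reject families that are locally consistent only to machine
  precision; the tolerance absorbs that rounding.

## The inequality description of 𝕄(𝒢)

On a transverse complement *T* of ker(*G*) (the coordinate subspace of the
rref pivot columns), *v* = *Gx* has a unique solution *x*(*v*), linear in
*v*. Every candidate joint is then *y* = *x*(*v*) + Σⱼ cⱼkⱼ over a kernel
basis, and Fourier–Motzkin elimination of the cⱼ from *y* ≥ 0 leaves
inequalities in *v* alone; the equalities are the cokernel conditions plus
one normalization. Rows are canonicalized to coprime integer vectors and
deduplicated at every elimination step; a final LP pass
(`minimal_inequality_set`) removes every inequality implied by the rest.
The choice of transverse complement does not change the described set
(tested with two pivot orders), and membership in the description agrees
with LP feasibility on uniform samples of 𝕃(𝒢). A guard refuses
elimination beyond 64 joint states, where LP membership is the right tool.

For the binary triangle the elimination yields the four cycle inequalities
on top of non-negativity; for acyclic architectures it yields nothing
beyond the local equalities and *v* ≥ 0 (asserted by LP implication).

## Volumes

𝕃(𝒢) and 𝕄(𝒢) share an affine hull (both contain the uniform family;
dim = rank(*G*) − 1 on both sides, asserted class by class), so their
volume ratio under Lebesgue measure on that hull is well defined and
invariant under affine reparametrization — any chart rescales both volumes
identically. The chart used keeps the free coordinates of the rref-reduced
equality system, exactly over the rationals.

* **Monte Carlo**: hit-and-run over the chart polytope, started at the
  uniform family (always relative-interior), burn-in 10³, thinning equal to
  the dimension, seeded. The ratio is the fraction of samples that are
  LP-feasible, with binomial standard error. Acyclic architectures
  short-circuit to exactly 1; a `method="monte_carlo"` override disables the
  short-circuit so the analytic value can be verified by sampling.
* **Exact** (dimension ≤ 8): vertices of 𝕃(𝒢) by exhausting d-subsets of
  tight constraints with exact rational solves; vertices of 𝕄(𝒢) as the
  images under *G* of deterministic joints (columns of *G*). Both volumes
  come from a Delaunay triangulation computed in floats whose simplex
  determinants are recomputed exactly over the rational vertex coordinates,
  so the returned ratio is an exact Fraction. For the binary triangle this
  gives 12 local vertices (8 deterministic, 4 half-integral frustrated) and
  a ratio of exactly 2/3.

The Bayes posterior for "the model is merely locally consistent" given
globally consistent observations is ratio·prior / (ratio·prior + 1 − prior),
using unit likelihood under a globally consistent model; the degenerate
prior = 1, ratio = 0 case returns 0 with a warning.

Hit-and-run samples are autocorrelated at the default thinning; the
binomial standard error treats them as independent, so it mildly
understates the true error. The symmetry test of the sampler therefore
uses heavier thinning; ratio estimates were additionally checked against
the exact triangle value over independent seeds.

## Belief propagation

Flooding-schedule sum-product with uniform initial messages, per-pass
normalization, damping 0.5, tolerance 1e-10, at most 10⁴ iterations;
non-convergence is reported, not raised. Using each edge's table as its
factor gives the "ostensible" marginals an observer would infer from
per-edge data. BP is exact when the bipartite factor graph is a forest.
Note that this is stronger than hypergraph acyclicity: two edges
overlapping in two or more variables create a factor-graph cycle even
though the hypergraph reduces (e.g. {l1,l2,l3}, {l1,l2,l4}), and plain
sum-product is then only approximate; exactness tests are restricted to
factor-graph forests accordingly.

## Synthetic data

The generator emulates the study conditions end to end with no external
data:

* **Master equations** on a truncated count lattice {0..N}^k (default
  N = 30), with reactions given as (state-change, propensity) pairs and
  rate constants folded into the propensity. Transitions leaving the
  lattice are dropped; the stationary law solves the generator's null space
  via a sparse linear solve with one balance row replaced by normalization.
  Reducible generators raise, listing closed classes; if truncation clipped
  any transition and the stationary boundary mass exceeds 1e-6, a warning
  asks for a larger lattice. The truncated birth–death chain reproduces the
  truncated Poisson law to 1e-10, its closed form by detailed balance.
* **Coarse-graining** by per-species count thresholds: level =
  number of thresholds strictly below the count; a single threshold *T*
  gives the binary map (≤ *T* → 0, > *T* → 1). Coarse-graining commutes
  exactly with marginalization onto edges.
* **Datasets**: a joint source simulates one shared measurement campaign —
  every edge records the same draws — so the empirical family is exactly
  the marginal family of the empirical joint and always extendable. A
  family source simulates independent per-edge campaigns, the observation
  protocol under which inconsistency can arise at all. Defaults follow the
  study conditions (binary levels, a few hundred samples per edge in the
  CLI simulation).
* **Frustrated families** by rejection: uniform 𝕃(𝒢) samples until one is
  LP-infeasible; expected tries are 1/(1 − ratio), verified for the
  triangle. Acyclic inputs are refused with an explanatory message.

What the generator does not emulate: real measurement noise models beyond
multinomial sampling, non-stationary dynamics, and mechanistic couplings
between species (the product-of-birth-death CLI model is deliberately
independent). Passing tests therefore show correctness of the consistency
machinery on the stated observation protocols, not that any particular
biological dataset is well described by them.

## Enumeration and the lattice

Architecture classes are enumerated by recursive antichain-cover search
(candidates in decreasing size, pruning branches that cannot cover), then
grouped by canonical form — the lexicographic minimum over all variable
permutations of the sorted edge list. Brute force over all n! permutations
is acceptable at the guard n ≤ 6; tests verify against an independent
power-set-filter oracle at n ≤ 4. On three variables exactly one class is
cyclic (the triangle); on four variables with edges of size ≥ 2 exactly
nine of the fifteen classes are cyclic. The lattice order is edge-wise
refinement up to isomorphism (every edge of *A* inside some edge of *B*);
the Hasse diagram is its transitive reduction.

## Problem sizes and defaults

Binary levels throughout the standard runs; the exact simplex path engages
up to 256 joint states, Fourier–Motzkin up to 64, exact volumes up to
dimension 8, enumeration up to n = 6. Survey and acceptance runs use 2×10³
hit-and-run samples per cyclic class (standard errors ~0.01) and 10³
LP-membership checks per acyclic class; these sizes put every Monte-Carlo
conclusion at ≥ 3 standard errors while keeping a full run in minutes on
one CPU. All samplers are seeded, and seeds are echoed into outputs.

## Known limitations

* Fourier–Motzkin row counts can grow quickly when dim ker(*G*) is large;
  beyond the guard, membership questions should go through the LP.
* The refinement order on classes is computed by permutation search, fine
  at n ≤ 6 but not beyond.
* Hit-and-run standard errors assume independent draws (see above).
* The float LP tolerance (1e-9) means families within ~1e-9 of the
  boundary of 𝕄(𝒢) may be classified either way on the float path; the
  exact path has no such band.
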