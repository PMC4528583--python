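# netsat

**Can the constraints a network context places on a subnetwork actually be
satisfied?**

When a biological subnetwork (genes, metabolites, signalling species, ...)
is studied in isolation, its context — everything upstream that was abstracted
away — still constrains it. Each independent element of the context
constrains one subset of the subnetwork's variables jointly, so the
constraint structure is a hypergraph 𝒢 over the variable set *L*: a
*network architecture*. Observations are coarse-grained into finitely many
levels per variable, and each hyperedge *O* ∈ 𝒢 carries a probability table
over its joint states.

Such a family of edge tables *v* can be

* **locally consistent** (*v* ∈ 𝕃(𝒢)): any two tables agree on every shared
  variable subset after marginalization; or
* **globally consistent** (*v* ∈ 𝕄(𝒢)): one joint distribution *x* over all
  variables reproduces every table, i.e. *v* = *Gx* for the 0/1
  marginalization matrix *G*, with *x* ≥ 0.

Global always implies local, and for Graham/GYO-**acyclic** architectures
the converse holds too (a junction-tree factorization builds the joint).
Cyclic architectures admit *frustrated* families — pairwise satisfiable yet
jointly unsatisfiable, the classic example being perfect anticorrelation
around a triangle. The a-priori probability that uniformly drawn locally
consistent constraints are satisfiable is the **global:local volume ratio**
Vol(𝕄(𝒢))/Vol(𝕃(𝒢)), measured on the common affine hull of the two
polytopes; it is exactly 1 for acyclic architectures and strictly below 1
for every cyclic one. `netsat` computes all of the above:

* `architectures` — reduced-cover hypergraphs, abstract-influence derivation
  from directed networks, GYO acyclicity, exhaustive enumeration of
  isomorphism classes, the refinement lattice;
* `marginalization` — the operator *G*, exact rational kernel/cokernel,
  local consistency conditions, transverse complements;
* `consistency` — local/global consistency decisions (exact rational
  Phase-I simplex or float LP), joint witnesses, Fourier–Motzkin derivation
  of the 𝕄(𝒢) inequalities, LP-based irredundancy;
* `geometry` — polytope dimensions, hit-and-run sampling of 𝕃(𝒢),
  Monte-Carlo and exact (vertex enumeration + triangulation) volume ratios,
  the Bayes posterior for "is my model merely locally consistent?",
  whole-lattice surveys;
* `belief_propagation` — loopy sum-product on the architecture's factor
  graph, against exact marginals;
* `synthetic_dynamics` — truncated chemical master equations, stationary
  distributions, threshold coarse-graining, per-edge measurement datasets,
  and certified locally-but-not-globally-consistent families;
* a `netsat` command-line interface over all of it.

## Worked example

```python
from fractions import Fraction
from netsat import (
    Hypergraph, StateSpace, EdgeMarginalFamily,
    check_family, exact_volume_ratio, posterior_local_model,
)

triangle = Hypergraph(["l1", "l2", "l3"],
                      [["l1", "l2"], ["l2", "l3"], ["l3", "l1"]])
space = StateSpace.binary(triangle.variables)

# perfect pairwise anticorrelation on every edge
h, z = Fraction(1, 2), Fraction(0)
anti = EdgeMarginalFamily(
    triangle, space,
    ({(0, 0): z, (0, 1): h, (1, 0): h, (1, 1): z},) * 3,
)
report = check_family(anti)
print(report.local, report.global_)      # True False

est = exact_volume_ratio(space, triangle)
print(est.exact_ratio)                   # 2/3
print(posterior_local_model(0.5, est.ratio).posterior)  # 0.4
```

The anticorrelated family is locally consistent (every single-variable
marginal is uniform) but no joint distribution has these pairwise marginals:
around a cycle, three pairwise disagreements cannot all be certain. The
exact global:local volume ratio of the binary triangle is 2/3 — one third of
the locally consistent constraint families on a triangle are unsatisfiable —
and observing globally consistent data moves an even prior on
"merely locally consistent model" down to a posterior of 0.4.

From the shell:

```
$ netsat enumerate --n 4 --min-edge-size 2
15 classes (9 cyclic) on 4 variables
...
$ netsat volume-ratio triangle.json --exact
ratio = 0.666667 ± 0 (exact)
```

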