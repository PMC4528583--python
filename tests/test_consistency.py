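import random
from fractions import Fraction

import numpy as np
import pytest

from netsat.architectures import Hypergraph
from netsat.consistency import (
    EdgeMarginalFamily,
    JointDistribution,
    check_family,
    extend_acyclic,
    global_inequalities,
    is_globally_consistent,
    is_locally_consistent,
    local_polytope,
    minimal_inequality_set,
)
from netsat.geometry import sample_local_polytope
from netsat.marginalization import StateSpace, build_marginalization_matrix

from conftest import random_rational_joint

MIXED_CYCLIC = Hypergraph(
    ["l1", "l2", "l3", "l4"],
    [["l1", "l2", "l3"], ["l1", "l2", "l4"], ["l3", "l4"]],
)


class TestLocalConsistency:
    def test_uniform_family_is_locally_consistent(self, binary3, triangle):
        assert is_locally_consistent(EdgeMarginalFamily.uniform(binary3, triangle))

    def test_anticorrelated_triangle_is_locally_consistent(
        self, anticorrelated_triangle
    ):
        assert is_locally_consistent(anticorrelated_triangle)

    def test_node_marginal_mismatch_detected(self, binary3, triangle):
        t_biased = {
            (0, 0): Fraction(7, 10), (0, 1): Fraction(0),
            (1, 0): Fraction(0), (1, 1): Fraction(3, 10),
        }
        uniform = {k: Fraction(1, 4) for k in t_biased}
        fam = EdgeMarginalFamily(
            triangle, binary3, (t_biased, dict(uniform), dict(uniform))
        )
        assert not is_locally_consistent(fam)

    def test_mismatched_architecture_rejected(self, binary3, triangle, path3):
        fam = EdgeMarginalFamily.uniform(binary3, triangle)
        with pytest.raises(ValueError):
            EdgeMarginalFamily(path3, binary3, fam.tables)


class TestGlobalConsistency:
    def test_anticorrelated_triangle_infeasible(self, anticorrelated_triangle):
        feasible, witness = is_globally_consistent(anticorrelated_triangle)
        assert not feasible and witness is None

    def test_marginals_of_joints_are_feasible_with_exact_witness(
        self, binary3, triangle
    ):
        rng = random.Random(11)
        G = build_marginalization_matrix(binary3, triangle)
        for _ in range(10):
            joint = random_rational_joint(binary3, rng)
            fam = joint.marginal_family(triangle)
            feasible, witness = is_globally_consistent(fam)
            assert feasible
            assert G.apply(witness.weights) == fam.as_vector()  # exact

    def test_vertex_of_marginal_polytope_reported_feasible(self, binary3, triangle):
        # closed-polytope semantics: a deterministic joint's marginals lie on
        # the boundary of M and must be accepted
        weights = [Fraction(0)] * 8
        weights[5] = Fraction(1)
        fam = JointDistribution(binary3, tuple(weights)).marginal_family(triangle)
        feasible, _ = is_globally_consistent(fam)
        assert feasible

    def test_float_path_agrees_with_exact_path(self, binary3, triangle):
        rng = random.Random(2)
        joint = random_rational_joint(binary3, rng)
        fam = joint.marginal_family(triangle)
        fam_float = EdgeMarginalFamily(
            triangle, binary3,
            tuple({k: float(p) for k, p in t.items()} for t in fam.tables),
        )
        assert not fam_float.exact
        feasible, witness = is_globally_consistent(fam_float)
        assert feasible
        G = build_marginalization_matrix(binary3, triangle)
        resid = np.array(G.apply(witness.weights)) - np.array(
            [float(x) for x in fam.as_vector()]
        )
        assert np.abs(resid).max() < 1e-8

    def test_locally_consistent_on_path_always_feasible(self, binary3, path3):
        for fam in sample_local_polytope(binary3, path3, 50, seed=8):
            feasible, _ = is_globally_consistent(fam)
            assert feasible

    @pytest.mark.parametrize(
        "h",
        [
            Hypergraph(["l1", "l2", "l3"], [["l1", "l2"], ["l2", "l3"], ["l3", "l1"]]),
            Hypergraph(["l1", "l2", "l3"], [["l1", "l2"], ["l1", "l3"]]),
            MIXED_CYCLIC,
        ],
        ids=["triangle", "path", "mixed"],
    )
    def test_global_implies_local(self, h):
        space = StateSpace.binary(h.variables)
        rng = random.Random(len(h.edges))
        for _ in range(100):
            fam = random_rational_joint(space, rng).marginal_family(h)
            assert is_locally_consistent(fam)


class TestExtendAcyclic:
    def test_single_edge_witness_is_the_table(self, binary3):
        h = Hypergraph(["l1", "l2", "l3"], [["l1", "l2", "l3"]])
        rng = random.Random(5)
        joint = random_rational_joint(binary3, rng)
        fam = joint.marginal_family(h)
        witness = extend_acyclic(fam)
        assert witness.weights == joint.weights

    def test_disjoint_edges_give_product_distribution(self):
        space = StateSpace.binary(["a", "b", "c", "d"])
        h = Hypergraph("abcd", [["a", "b"], ["c", "d"]])
        t1 = {(0, 0): Fraction(1, 2), (0, 1): Fraction(1, 4),
              (1, 0): Fraction(1, 8), (1, 1): Fraction(1, 8)}
        t2 = {(0, 0): Fraction(1, 3), (0, 1): Fraction(1, 3),
              (1, 0): Fraction(1, 6), (1, 1): Fraction(1, 6)}
        fam = EdgeMarginalFamily(h, space, (t1, t2))
        witness = extend_acyclic(fam)
        for st, w in zip(space.joint_states(), witness.weights):
            assert w == t1[st[:2]] * t2[st[2:]]

    def test_path_factorizes_through_shared_variable(self, binary3, path3):
        # p(l1,l2,l3) = p(l1) p(l2|l1) p(l3|l1): hand-checkable rational family
        t12 = {(0, 0): Fraction(1, 4), (0, 1): Fraction(1, 4),
               (1, 0): Fraction(3, 8), (1, 1): Fraction(1, 8)}
        t13 = {(0, 0): Fraction(1, 2), (0, 1): Fraction(0),
               (1, 0): Fraction(1, 4), (1, 1): Fraction(1, 4)}
        fam = EdgeMarginalFamily(path3, binary3, (t12, t13))
        witness = extend_acyclic(fam)
        w = dict(zip(binary3.joint_states(), witness.weights))
        # p(l1=1,l2=0,l3=1) = p(l2=0|l1=1) p(l1=1,l3=1) = (3/8)/(1/2) * 1/4
        assert w[(1, 0, 1)] == Fraction(3, 16)
        assert w[(0, 1, 1)] == Fraction(0)  # p(l3=1|l1=0) = 0
        assert sum(witness.weights) == 1

    def test_cyclic_architecture_rejected(self, anticorrelated_triangle):
        with pytest.raises(ValueError, match="not acyclic"):
            extend_acyclic(anticorrelated_triangle)

    def test_locally_inconsistent_rejected(self, binary3, path3):
        bad = EdgeMarginalFamily(
            path3, binary3,
            (
                {(0, 0): Fraction(1), (0, 1): Fraction(0),
                 (1, 0): Fraction(0), (1, 1): Fraction(0)},
                {(0, 0): Fraction(0), (0, 1): Fraction(0),
                 (1, 0): Fraction(0), (1, 1): Fraction(1)},
            ),
        )
        with pytest.raises(ValueError, match="not locally consistent"):
            extend_acyclic(bad)


class TestGlobalInequalities:
    def test_path_reduces_to_nonnegativity(self, binary3, path3):
        # acyclic case: the eliminated system imposes nothing beyond the
        # local equalities and v >= 0, so every derived inequality must be
        # implied by the local description (checked by LP)
        from scipy.optimize import linprog

        desc = global_inequalities(binary3, path3)
        loc = local_polytope(binary3, path3)
        A_eq = np.array([[float(c) for c in eq.coefficients] for eq in loc.equalities])
        b_eq = np.array([float(eq.rhs) for eq in loc.equalities])
        for iq in desc.inequalities:
            c = np.array([float(x) for x in iq.coefficients])
            res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
            assert res.status == 0
            assert res.fun >= float(iq.rhs) - 1e-9

    def test_triangle_needs_conditions_beyond_nonnegativity(
        self, binary3, triangle, anticorrelated_triangle
    ):
        desc = global_inequalities(binary3, triangle)
        nontrivial = [
            iq for iq in desc.inequalities
            if sum(1 for c in iq.coefficients if c) > 1
        ]
        assert nontrivial
        vec = anticorrelated_triangle.as_vector()
        assert not desc.contains(vec)
        # ... while the family satisfies the local description
        assert local_polytope(binary3, triangle).contains(vec)

    @pytest.mark.parametrize("h", [None, MIXED_CYCLIC], ids=["triangle", "mixed"])
    def test_membership_agrees_with_lp_oracle(self, h, binary3, triangle):
        h = triangle if h is None else h
        space = StateSpace.binary(h.variables)
        desc = global_inequalities(space, h)
        disagreements = 0
        for fam in sample_local_polytope(space, h, 200, seed=17):
            lp, _ = is_globally_consistent(fam)
            fm = desc.contains(fam.as_vector(), tol=1e-8)
            disagreements += lp != fm
        assert disagreements == 0

    def test_transverse_choice_does_not_change_feasible_set(self, binary3, triangle):
        desc_a = global_inequalities(binary3, triangle)
        order = list(range(8))[::-1]
        desc_b = global_inequalities(binary3, triangle, column_order=order)
        for fam in sample_local_polytope(binary3, triangle, 200, seed=23):
            vec = fam.as_vector()
            assert desc_a.contains(vec, tol=1e-8) == desc_b.contains(vec, tol=1e-8)

    def test_guard_refusal(self):
        space = StateSpace.binary([f"l{i}" for i in range(7)])
        h = Hypergraph(space.variables, [list(space.variables)])
        with pytest.raises(ValueError, match="guard"):
            global_inequalities(space, h)


class TestMinimalInequalitySet:
    def test_duplicate_survives_once(self, binary3, path3):
        desc = global_inequalities(binary3, path3)
        doubled = desc.inequalities + desc.inequalities[:1]
        from dataclasses import replace

        fat = replace(desc, inequalities=doubled)
        mini = minimal_inequality_set(fat)
        sigs = [tuple(iq.coefficients) for iq in mini.inequalities]
        assert len(sigs) == len(set(sigs))

    def test_implied_inequality_removed(self, binary3, path3):
        from dataclasses import replace

        from netsat.consistency import LinearInequality

        desc = global_inequalities(binary3, path3)
        n = len(desc.coordinates)
        # sum of all coordinates >= 0 is implied by coordinate-wise bounds
        weak = LinearInequality(tuple([Fraction(1)] * n), Fraction(0), "weak")
        fat = replace(desc, inequalities=desc.inequalities + (weak,))
        mini = minimal_inequality_set(fat)
        assert all(iq.label != "weak" for iq in mini.inequalities)

    def test_minimized_triangle_defines_same_set(self, binary3, triangle):
        desc = global_inequalities(binary3, triangle)
        mini = minimal_inequality_set(desc)
        assert len(mini.inequalities) <= len(desc.inequalities)
        for fam in sample_local_polytope(binary3, triangle, 300, seed=29):
            vec = fam.as_vector()
            assert desc.contains(vec, tol=1e-8) == mini.contains(vec, tol=1e-8)


class TestReport:
    def test_anticorrelated_report(self, anticorrelated_triangle):
        rep = check_family(anticorrelated_triangle)
        assert rep.local and not rep.global_
        assert rep.witness is None
        assert rep.violated

    def test_feasible_report_carries_witness(self, binary3, triangle):
        rng = random.Random(1)
        fam = random_rational_joint(binary3, rng).marginal_family(triangle)
        rep = check_family(fam)
        assert rep.local and rep.global_
        assert rep.witness is not None and not rep.violated
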