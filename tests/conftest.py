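import random
from fractions import Fraction

import pytest
from hypothesis import settings

from netsat.architectures import Hypergraph
from netsat.consistency import EdgeMarginalFamily, JointDistribution
from netsat.marginalization import StateSpace

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def binary3():
    return StateSpace.binary(["l1", "l2", "l3"])


@pytest.fixture
def triangle():
    return Hypergraph(["l1", "l2", "l3"], [["l1", "l2"], ["l2", "l3"], ["l3", "l1"]])


@pytest.fixture
def path3():
    """The two-edge acyclic architecture sharing one variable."""
    return Hypergraph(["l1", "l2", "l3"], [["l1", "l2"], ["l1", "l3"]])


@pytest.fixture
def anticorrelated_triangle(binary3, triangle):
    """Perfect pairwise anticorrelation: locally but not globally consistent."""
    h = Fraction(1, 2)
    z = Fraction(0)
    table = {(0, 0): z, (0, 1): h, (1, 0): h, (1, 1): z}
    return EdgeMarginalFamily(triangle, binary3, (dict(table),) * 3)


def random_rational_joint(space: StateSpace, rng: random.Random) -> JointDistribution:
    """A random exact-rational joint distribution (strictly positive)."""
    n = space.n_joint_states
    raw = [rng.randint(1, 20) for _ in range(n)]
    tot = sum(raw)
    return JointDistribution(space, tuple(Fraction(r, tot) for r in raw))
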