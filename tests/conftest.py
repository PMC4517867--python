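import numpy as np
import pytest

from kgsample import fixtures, kinematics, nullspace


@pytest.fixture(scope="session")
def helix12():
    """Ideal 12-residue polyalanine helix with all i->i+4 hydrogen bonds."""
    return fixtures.make_ideal_helix(12)


@pytest.fixture(scope="session")
def chain20():
    """Generic single-cycle serial chain with 20 cycle DoFs."""
    return fixtures.make_single_cycle_chain(20)


@pytest.fixture(scope="session")
def hinge():
    """Two-domain hinge: two constrained helices plus a free linker."""
    return fixtures.make_two_domain_hinge()


def make_tree(topo, coords, constraints=None, root_spec=None):
    bodies = kinematics.build_rigid_bodies(topo)
    tree = kinematics.build_tree(bodies, topo, root_spec=root_spec,
                                 coords0=coords)
    if constraints is not None:
        kinematics.classify_dofs(tree, constraints)
    return tree


def basis_for(tree, coords, constraints):
    cycles = nullspace.find_cycles(tree, constraints)
    J = nullspace.compute_jacobian(tree, coords, cycles)
    return nullspace.nullspace_basis(J, tree.n_dofs), J, cycles


@pytest.fixture(scope="session")
def helix_tree(helix12):
    topo, coords, cons = helix12
    return make_tree(topo, coords, cons)


@pytest.fixture(scope="session")
def chain_tree(chain20):
    topo, coords, cons = chain20
    return make_tree(topo, coords, cons)
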