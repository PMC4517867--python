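"""Closure Jacobian, SVD nullspace, projection and rigidification."""

import numpy as np
import pytest

from kgsample import fixtures, nullspace
from kgsample.nullspace import (closure_residual, compute_jacobian,
                                constraint_violation, find_cycles, max_drift,
                                nullspace_basis, project, rigidified_dofs)

from conftest import basis_for, make_tree


def fd_jacobian(tree, cycles, columns, eps=1e-6):
    """Central finite differences of the branch-difference endpoint maps."""
    J = np.zeros((6 * len(cycles), len(columns)))
    for cyc in cycles:
        for c, dof in enumerate(columns):
            q = np.zeros(tree.n_dofs)
            q[dof] = eps
            gp = closure_residual(tree, q, cyc)
            q[dof] = -eps
            gm = closure_residual(tree, q, cyc)
            J[6 * cyc.index: 6 * cyc.index + 6, c] = (gp - gm) / (2 * eps)
    return J


def test_one_cycle_per_constraint(helix12, helix_tree):
    _, _, cons = helix12
    cycles = find_cycles(helix_tree, cons)
    assert len(cycles) == len(cons)
    for cyc in cycles:
        assert not set(cyc.left_path) & set(cyc.right_path)


def test_common_ancestor_matches_independent_lca(chain20, chain_tree):
    import networkx as nx

    _, _, cons = chain20
    tree = chain_tree
    cycles = find_cycles(tree, cons)
    g = nx.DiGraph((d.parent_body, d.child_body) for d in tree.dofs)
    lca = nx.lowest_common_ancestor(
        g, int(tree.body_of_atom[cons[0].hydrogen]),
        int(tree.body_of_atom[cons[0].acceptor]))
    assert cycles[0].common_ancestor == lca


def test_intra_body_constraint_dropped_with_warning(helix12, helix_tree):
    topo, coords, _ = helix12
    ix = topo.atom_index
    # HA and CB share the CA rigid body: the "bond" can never break
    from kgsample.structure_io import HydrogenBond
    vacuous = HydrogenBond(ix("A", 5, "CA"), ix("A", 5, "HA"),
                           ix("A", 5, "CB"), 2.0, 2.5)
    with pytest.warns(UserWarning, match="intra-body"):
        cycles = find_cycles(helix_tree, [vacuous])
    assert cycles == []


def test_off_path_dofs_have_zero_entries(helix12, helix_tree):
    _, coords, cons = helix12
    cycles = find_cycles(helix_tree, cons)
    J = compute_jacobian(helix_tree, coords, cycles)
    col_of = J.column_of
    for cyc in cycles:
        on_path = set(cyc.left_path) | set(cyc.right_path)
        block = J.matrix[6 * cyc.index: 6 * cyc.index + 6]
        for dof in J.columns:
            if dof not in on_path:
                assert np.all(block[:, col_of[dof]] == 0.0)


def test_two_dof_planar_toy_matches_manual_cross_products():
    """Hand-built geometry: entries equal u_j x (r - r_Oj) exactly."""
    topo, coords, cons = fixtures.make_single_cycle_chain(6, jitter=0.0)
    tree = make_tree(topo, coords, cons)
    from kgsample.kinematics import classify_dofs
    classify_dofs(tree, cons)
    cycles = find_cycles(tree, cons)
    J = compute_jacobian(tree, coords, cycles)
    hb = cons[0]
    for c, dof_id in enumerate(J.columns):
        d = tree.dofs[dof_id]
        u = coords[d.head_atom] - coords[d.tail_atom]
        u = u / np.linalg.norm(u)
        sign = 1.0 if dof_id in cycles[0].left_path else -1.0
        np.testing.assert_allclose(
            J.matrix[0:3, c], sign * np.cross(u, coords[hb.hydrogen] - coords[d.tail_atom]),
            atol=1e-12)
        np.testing.assert_allclose(
            J.matrix[3:6, c], sign * np.cross(u, coords[hb.acceptor] - coords[d.tail_atom]),
            atol=1e-12)


@pytest.mark.parametrize("fixture_name", ["chain20", "helix12"])
def test_jacobian_matches_finite_differences(fixture_name, request):
    item = request.getfixturevalue(fixture_name)
    topo, coords, cons = item[0], item[1], item[2]
    tree = make_tree(topo, coords, cons)
    cycles = find_cycles(tree, cons)
    J = compute_jacobian(tree, coords, cycles)
    fd = fd_jacobian(tree, cycles, J.columns)
    scale = np.abs(fd).max()
    assert np.abs(J.matrix - fd).max() / scale < 1e-5


def test_empty_constraint_set_gives_identity_projection(helix_tree):
    J = compute_jacobian(helix_tree, helix_tree.coords0, [])
    basis = nullspace_basis(J, helix_tree.n_dofs)
    x = np.arange(helix_tree.n_dofs, dtype=float)
    np.testing.assert_array_equal(project(x, basis), x)
    assert rigidified_dofs(basis) == set()


def test_single_cycle_rank_five(chain20):
    """One generic closure removes exactly five DoFs: the h-A spin stays."""
    topo, coords, cons = chain20
    tree = make_tree(topo, coords, cons)
    basis, J, _ = basis_for(tree, coords, cons)
    n_cycle = len(J.columns)
    assert n_cycle == 20
    assert J.matrix.shape == (6, 20)
    assert n_cycle - basis.nullity == 5


def test_nullspace_algebra(chain20):
    topo, coords, cons = chain20
    tree = make_tree(topo, coords, cons)
    basis, J, _ = basis_for(tree, coords, cons)
    d = basis.nullity
    assert np.abs(basis.N.T @ basis.N - np.eye(d)).max() < 1e-10
    assert np.linalg.norm(J.matrix @ basis.N, axis=0).max() <= basis.rank_tolerance
    rng = np.random.default_rng(5)
    for _ in range(100):
        x = rng.standard_normal(tree.n_dofs)
        p = project(x, basis)
        assert np.linalg.norm(project(p, basis) - p) <= 1e-12 * max(1.0, np.linalg.norm(x))


def test_nullspace_vector_passes_through_unchanged(chain20):
    topo, coords, cons = chain20
    tree = make_tree(topo, coords, cons)
    basis, J, _ = basis_for(tree, coords, cons)
    x = np.zeros(tree.n_dofs)
    x[basis.columns] = basis.N[:, 0]
    np.testing.assert_allclose(project(x, basis), x, atol=1e-12)
    # a row-space vector is annihilated on the cycle components
    y = np.zeros(tree.n_dofs)
    y[basis.columns] = J.matrix[0]
    assert np.abs(project(y, basis)[basis.columns]).max() <= 1e-10 * np.linalg.norm(y)


def test_rank_additivity_for_separated_cycles():
    """Two geometrically separated closures each remove five DoFs."""
    topo, coords, cons = fixtures.make_ideal_helix(16)
    separated = [cons[0], cons[-1]]  # 1->5 and 12->16: disjoint paths
    tree = make_tree(topo, coords, separated)
    basis, J, _ = basis_for(tree, coords, separated)
    n_cycle = len(J.columns)
    assert n_cycle - basis.nullity == 10


def test_helix_interior_backbone_rigidified(helix12):
    """The full i->i+4 network freezes every interior phi/psi."""
    topo, coords, cons = helix12
    tree = make_tree(topo, coords, cons)
    basis, _, _ = basis_for(tree, coords, cons)
    rigid = rigidified_dofs(basis)
    interior = {d.id for d in tree.dofs
                if d.kind in ("phi", "psi") and d.designation == "cycle"}
    assert interior and interior <= rigid
    free = {d.id for d in tree.dofs if d.designation == "free"}
    assert not rigid & free


def test_rigidified_set_invariant_to_root_and_constraint_order(helix12):
    topo, coords, cons = helix12
    def rigid_bonds(root_spec, constraints):
        tree = make_tree(topo, coords, constraints, root_spec=root_spec)
        basis, _, _ = basis_for(tree, coords, constraints)
        rigid = rigidified_dofs(basis)
        return {frozenset((tree.dofs[i].tail_atom, tree.dofs[i].head_atom))
                for i in rigid}
    base = rigid_bonds(None, cons)
    assert rigid_bonds(topo.atom_index("A", 12, "C"), cons) == base
    assert rigid_bonds(None, list(reversed(cons))) == base


def test_drift_zero_at_start_and_small_after_projected_step(chain20):
    topo, coords, cons = chain20
    tree = make_tree(topo, coords, cons)
    basis, _, _ = basis_for(tree, coords, cons)
    assert max_drift(constraint_violation(coords, cons)) == 0.0
    from kgsample.kinematics import forward_kinematics
    rng = np.random.default_rng(2)
    cap = np.radians(0.29)
    proj_drifts, raw_drifts = [], []
    for _ in range(25):
        dq = rng.standard_normal(tree.n_dofs)
        p = project(dq, basis)
        p *= cap / np.abs(p).max()
        proj_drifts.append(max_drift(constraint_violation(
            forward_kinematics(tree, p), cons)))
        r = dq * (cap / np.abs(dq).max())
        raw_drifts.append(max_drift(constraint_violation(
            forward_kinematics(tree, r), cons)))
    assert max(proj_drifts) < 1e-3
    # an unprojected step of the same size violates the bonds far more
    assert np.mean(raw_drifts) >= 10 * np.mean(proj_drifts)


def test_drift_scales_quadratically_with_step(chain20):
    """Halving the cap cuts the first-order-projected drift ~4x."""
    topo, coords, cons = chain20
    tree = make_tree(topo, coords, cons)
    basis, _, _ = basis_for(tree, coords, cons)
    from kgsample.kinematics import forward_kinematics
    rng = np.random.default_rng(4)
    dirs = [project(rng.standard_normal(tree.n_dofs), basis) for _ in range(50)]

    def mean_drift(cap_deg):
        cap = np.radians(cap_deg)
        out = []
        for p in dirs:
            step = p * (cap / np.abs(p).max())
            out.append(max_drift(constraint_violation(
                forward_kinematics(tree, step), cons)))
        return np.mean(out)

    ratio = mean_drift(0.29) / mean_drift(0.145)
    assert 3.0 <= ratio <= 5.0
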