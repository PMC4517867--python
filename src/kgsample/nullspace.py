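"""Closure-constraint Jacobians, SVD nullspace, and projected perturbations.

Each hydrogen bond closes a kinematic cycle through the spanning tree: the
donor hydrogen ``h`` and the acceptor ``A`` are reached through two branches
stemming from their lowest common ancestor body.  Keeping the bond intact
means keeping the positions of ``h`` and ``A`` fixed relative to the frame
on the opposite branch, which yields six holonomic constraints per bond::

    f_h_L(q) - f_h_R(q) = 0,    f_A_L(q) - f_A_R(q) = 0

Differentiating gives the 6m x n_cycle Jacobian J with entries
``u_j x (r - r_Oj)`` (u_j: unit bond axis of DoF j, r_Oj: its tail atom,
r: the constrained atom), positive for DoFs on the hydrogen-side branch and
negative on the acceptor side.  The right-singular vectors of J with
(numerically) zero singular value form an orthonormal basis N of Ker(J);
``N N^T`` is the orthogonal projector onto the tangent space of the
constraint manifold, and cycle DoFs whose unit vector projects to ~0 are
rigidified: no constraint-compatible motion can move them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .kinematics import KinematicTree, body_transforms, forward_kinematics

__all__ = [
    "Cycle",
    "ConstraintJacobian",
    "NullspaceBasis",
    "find_cycles",
    "compute_jacobian",
    "nullspace_basis",
    "project",
    "rigidified_dofs",
    "constraint_violation",
    "closure_residual",
]


@dataclass
class Cycle:
    """One closure cycle: a constraint plus its two tree branches."""

    index: int
    constraint: object          # HydrogenBond
    common_ancestor: int        # body id
    left_path: list             # DoF ids, ancestor -> hydrogen-side body
    right_path: list            # DoF ids, ancestor -> acceptor-side body


@dataclass
class ConstraintJacobian:
    """6m x n_cycle Jacobian over the cycle DoFs (Å per radian).

    Row block 6i..6i+2 is the h-closure of cycle i, 6i+3..6i+5 the
    A-closure.  ``columns`` maps column index -> DoF id.
    """

    matrix: np.ndarray
    columns: list[int]

    @property
    def column_of(self):
        return {dof_id: c for c, dof_id in enumerate(self.columns)}


@dataclass
class NullspaceBasis:
    """Orthonormal basis N of Ker(J) over the cycle DoFs."""

    N: np.ndarray                  # n_cycle x d
    columns: list[int]             # column c of J / row c of N -> DoF id
    singular_values: np.ndarray
    rank_tolerance: float
    n_dofs: int                    # total DoFs of the tree

    @property
    def nullity(self) -> int:
        return self.N.shape[1]


def find_cycles(tree: KinematicTree, constraints) -> list[Cycle]:
    """One cycle per constraint, decomposed at the lowest common ancestor.

    Constraints whose hydrogen and acceptor sit in the same rigid body are
    vacuous (the bond can never break) and are dropped with a warning.
    """
    cycles = []
    for hb in constraints:
        bh = int(tree.body_of_atom[hb.hydrogen])
        ba = int(tree.body_of_atom[hb.acceptor])
        if bh == ba:
            warnings.warn(
                f"constraint {hb.hydrogen}-{hb.acceptor} is intra-body; "
                "dropped as vacuous")
            continue
        ancestor, left, right = tree.path_between(bh, ba)
        cycles.append(Cycle(index=len(cycles), constraint=hb,
                            common_ancestor=ancestor,
                            left_path=left, right_path=right))
    return cycles


def cycle_dof_ids(tree: KinematicTree) -> list[int]:
    """Ids of DoFs designated ``cycle``, in DoF order."""
    return [d.id for d in tree.dofs if d.designation == "cycle"]


def compute_jacobian(tree: KinematicTree, coordinates: np.ndarray,
                     cycles) -> ConstraintJacobian:
    """Analytic closure Jacobian at the given (current) coordinates."""
    coords = np.asarray(coordinates, dtype=float)
    columns = sorted({d for c in cycles for d in c.left_path + c.right_path})
    col_of = {dof_id: c for c, dof_id in enumerate(columns)}
    J = np.zeros((6 * len(cycles), len(columns)))
    for cyc in cycles:
        hb = cyc.constraint
        r_h = coords[hb.hydrogen]
        r_a = coords[hb.acceptor]
        for sign, path in ((1.0, cyc.left_path), (-1.0, cyc.right_path)):
            for dof_id in path:
                d = tree.dofs[dof_id]
                tail = coords[d.tail_atom]
                u = coords[d.head_atom] - tail
                u = u / np.linalg.norm(u)
                c = col_of[dof_id]
                J[6 * cyc.index: 6 * cyc.index + 3, c] += sign * np.cross(u, r_h - tail)
                J[6 * cyc.index + 3: 6 * cyc.index + 6, c] += sign * np.cross(u, r_a - tail)
    return ConstraintJacobian(matrix=J, columns=columns)


def nullspace_basis(jacobian: ConstraintJacobian, n_dofs: int,
                    rank_tolerance: float | None = None) -> NullspaceBasis:
    """SVD nullspace of the closure Jacobian.

    The numerical rank counts singular values above
    ``eps * max(rows, cols) * sigma_max`` (LAPACK-style relative policy)
    unless an absolute tolerance is supplied.
    """
    J = jacobian.matrix
    n_cycle = J.shape[1]
    if J.size == 0:
        return NullspaceBasis(N=np.eye(n_cycle), columns=list(jacobian.columns),
                              singular_values=np.zeros(0),
                              rank_tolerance=0.0, n_dofs=n_dofs)
    _, s, Vt = scipy.linalg.svd(J, full_matrices=True)
    if rank_tolerance is None:
        rank_tolerance = float(np.finfo(float).eps * max(J.shape) * s[0])
    rank = int(np.sum(s > rank_tolerance))
    N = Vt[rank:].T  # right-singular vectors of (numerically) zero sigma
    return NullspaceBasis(N=np.ascontiguousarray(N),
                          columns=list(jacobian.columns),
                          singular_values=s, rank_tolerance=rank_tolerance,
                          n_dofs=n_dofs)


def project(delta_q: np.ndarray, basis: NullspaceBasis) -> np.ndarray:
    """Project a full trial move onto the constraint tangent space.

    The cycle-DoF subvector is replaced by ``N N^T`` applied to it; free-DoF
    components pass through unchanged.
    """
    dq = np.asarray(delta_q, dtype=float)
    if dq.shape != (basis.n_dofs,):
        raise ValueError(
            f"delta_q has shape {dq.shape}, expected ({basis.n_dofs},)")
    out = dq.copy()
    cols = basis.columns
    if cols:
        sub = dq[cols]
        out[cols] = basis.N @ (basis.N.T @ sub)
    return out


def rigidified_dofs(basis: NullspaceBasis, threshold: float = 1e-8) -> set[int]:
    """Cycle DoFs immobilized by the constraint network.

    DoF j is rigidified iff ``|N^T e_j| < threshold``: its unit move has no
    component in the nullspace, so every constraint-compatible perturbation
    leaves it untouched.  Free DoFs are never rigidified.
    """
    norms = np.linalg.norm(basis.N, axis=1)
    return {dof_id for dof_id, nrm in zip(basis.columns, norms)
            if nrm < threshold}


def constraint_violation(coordinates: np.ndarray, constraints):
    """Per-bond drift of the constrained distances, in Å.

    Returns a list of dicts with ``drift_HA``/``drift_DA`` (absolute change
    of the H···A and donor···A distances from their recorded initial values)
    plus the ensemble ``max`` under key access via :func:`max_drift`.
    """
    coords = np.asarray(coordinates, dtype=float)
    records = []
    for hb in constraints:
        d_ha = float(np.linalg.norm(coords[hb.hydrogen] - coords[hb.acceptor]))
        d_da = float(np.linalg.norm(coords[hb.donor] - coords[hb.acceptor]))
        records.append({
            "donor": hb.donor, "hydrogen": hb.hydrogen, "acceptor": hb.acceptor,
            "distance_HA": d_ha, "distance_DA": d_da,
            "drift_HA": abs(d_ha - hb.initial_distance_HA),
            "drift_DA": abs(d_da - hb.initial_distance_DA),
        })
    return records


def max_drift(records) -> float:
    if not records:
        return 0.0
    return max(max(r["drift_HA"], r["drift_DA"]) for r in records)


def closure_residual(tree: KinematicTree, q: np.ndarray, cycle: Cycle) -> np.ndarray:
    """Branch-difference endpoint maps of one cycle at torsions ``q``.

    Returns the 6-vector ``(f_h_L - f_h_R, f_A_L - f_A_R)`` where the left
    map carries an atom through the hydrogen-side body frame and the right
    map through the acceptor-side frame.  Zero at ``q = 0`` by construction;
    its Jacobian is what :func:`compute_jacobian` builds analytically.
    """
    hb = cycle.constraint
    Rs, ts = body_transforms(tree, q)
    bh = int(tree.body_of_atom[hb.hydrogen])
    ba = int(tree.body_of_atom[hb.acceptor])
    x_h0 = tree.coords0[hb.hydrogen]
    x_a0 = tree.coords0[hb.acceptor]
    f_h_L = Rs[bh] @ x_h0 + ts[bh]
    f_h_R = Rs[ba] @ x_h0 + ts[ba]
    f_a_L = Rs[bh] @ x_a0 + ts[bh]
    f_a_R = Rs[ba] @ x_a0 + ts[ba]
    return np.concatenate([f_h_L - f_h_R, f_a_L - f_a_R])
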