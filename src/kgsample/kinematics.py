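"""Kinematic model of a molecule: rigid bodies, spanning tree, forward
kinematics.

The molecule is viewed as a linkage whose links are rigid bodies (maximal
atom groups with no internal rotatable bond) and whose revolute joints are
the rotatable torsions (phi, psi, chi, ...).  The linkage is represented as
a rooted directed spanning tree over the rigid bodies; a conformation is the
vector ``q`` of torsion offsets (radians) from the input structure, and
Cartesian coordinates are recovered by composing rotations about the bond
axes along root-to-leaf paths.  Bond lengths, bond angles and the peptide
omega torsion are fixed at their input values by construction.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .geometry import rotation_about_line, compose
from .structure_io import Topology

__all__ = [
    "RigidBody",
    "DoF",
    "KinematicTree",
    "Conformation",
    "build_rigid_bodies",
    "build_tree",
    "forward_kinematics",
    "body_transforms",
    "classify_dofs",
]


@dataclass(frozen=True)
class RigidBody:
    id: int
    atom_ids: frozenset[int]


@dataclass
class DoF:
    """A rotatable bond of the tree: a right-handed rotation about the
    tail->head bond vector, stored as an offset from the input structure."""

    id: int
    tail_atom: int
    head_atom: int
    parent_body: int
    child_body: int
    kind: str = "other"           # phi | psi | chi | other
    designation: str = "free"     # free | cycle


class KinematicTree:
    """Rooted directed spanning tree of rigid bodies with DoF edges."""

    def __init__(self, bodies, dofs, root, body_of_atom, coords0):
        self.bodies: list[RigidBody] = bodies
        self.dofs: list[DoF] = dofs
        self.root: int = root
        self.body_of_atom: np.ndarray = body_of_atom
        self.coords0: np.ndarray = np.asarray(coords0, dtype=float)
        # parent bookkeeping
        self.parent_dof = [None] * len(bodies)   # body id -> incoming DoF id
        self.depth = [0] * len(bodies)
        for d in dofs:
            self.parent_dof[d.child_body] = d.id
        order = [root]
        self.depth[root] = 0
        for d in dofs:  # dofs are stored in BFS order: parent precedes child
            self.depth[d.child_body] = self.depth[d.parent_body] + 1
        # per-body atom index arrays for vectorized application
        self._body_atoms = [np.fromiter(sorted(b.atom_ids), dtype=int)
                            for b in bodies]

    @property
    def n_dofs(self) -> int:
        return len(self.dofs)

    @property
    def n_bodies(self) -> int:
        return len(self.bodies)

    def path_to_root(self, body: int) -> list[int]:
        """DoF ids on the path from ``body`` up to the root (body side first)."""
        out = []
        while body != self.root:
            d = self.parent_dof[body]
            out.append(d)
            body = self.dofs[d].parent_body
        return out

    def ancestors(self, body: int) -> list[int]:
        """Bodies on the path ``body`` -> root, inclusive."""
        out = [body]
        while body != self.root:
            body = self.dofs[self.parent_dof[body]].parent_body
            out.append(body)
        return out

    def path_between(self, body_a: int, body_b: int):
        """(lowest common ancestor body, dofs ancestor->a, dofs ancestor->b)."""
        b_anc = set(self.ancestors(body_b))
        a_side = []
        body = body_a
        while body not in b_anc:
            d = self.parent_dof[body]
            a_side.append(d)
            body = self.dofs[d].parent_body
        ancestor = body
        b_side = []
        cur = body_b
        while cur != ancestor:
            d = self.parent_dof[cur]
            b_side.append(d)
            cur = self.dofs[d].parent_body
        return ancestor, list(reversed(a_side)), list(reversed(b_side))

    def subtree_atoms(self, dof_id: int) -> np.ndarray:
        """Atom ids moved by a rotation of ``dof_id`` (its child subtree)."""
        children = {}
        for d in self.dofs:
            children.setdefault(d.parent_body, []).append(d.child_body)
        out = []
        stack = [self.dofs[dof_id].child_body]
        while stack:
            b = stack.pop()
            out.extend(self._body_atoms[b])
            stack.extend(children.get(b, []))
        return np.array(sorted(out), dtype=int)

    def dump_edges(self):
        """Tab-separated edge list for debugging."""
        lines = ["parent_body\tchild_body\ttail_atom\thead_atom\tkind\tdesignation"]
        for d in self.dofs:
            lines.append(f"{d.parent_body}\t{d.child_body}\t{d.tail_atom}\t"
                         f"{d.head_atom}\t{d.kind}\t{d.designation}")
        return "\n".join(lines)


@dataclass
class Conformation:
    """Torsion offsets plus the Cartesian coordinates they generate."""

    tree: KinematicTree
    q: np.ndarray
    coordinates: np.ndarray = None

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (self.tree.n_dofs,):
            raise ValueError(
                f"q length {self.q.shape} does not match {self.tree.n_dofs} DoFs")
        if self.coordinates is None:
            self.coordinates = forward_kinematics(self.tree, self.q)


def build_rigid_bodies(topology: Topology) -> list[RigidBody]:
    """Partition atoms into rigid bodies by merging across fixed bonds."""
    n = topology.n_atoms
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (i, j), rotatable in topology.bonds.items():
        if not rotatable:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj

    groups = {}
    for a in range(n):
        groups.setdefault(find(a), []).append(a)
    # deterministic ids: order bodies by their smallest atom id
    bodies = []
    for k, atoms in enumerate(sorted(groups.values(), key=min)):
        bodies.append(RigidBody(id=k, atom_ids=frozenset(atoms)))
    return bodies


def _dof_kind(topology: Topology, i: int, j: int) -> str:
    ai, aj = topology.atoms[i], topology.atoms[j]
    names = {ai.name, aj.name}
    if ai.residue_index == aj.residue_index and ai.chain == aj.chain:
        if names == {"N", "CA"}:
            return "phi"
        if names == {"CA", "C"}:
            return "psi"
        backbone = {"N", "CA", "C", "O", "OXT"}
        if not (names <= backbone):
            return "chi"
    return "other"


def build_tree(bodies, topology: Topology, root_spec=None,
               coords0=None) -> KinematicTree:
    """Directed spanning tree over rigid bodies by BFS from the root.

    ``root_spec`` is a root atom id (default: atom 0, the first atom of the
    first chain, i.e. the N-terminus).  Each DoF edge stores the parent-side
    (tail) and child-side (head) atoms of its rotatable bond.
    """
    n_bodies = len(bodies)
    body_of_atom = np.empty(topology.n_atoms, dtype=int)
    for b in bodies:
        for a in b.atom_ids:
            body_of_atom[a] = b.id

    # body adjacency via rotatable bonds
    adj: list[list[tuple[int, int, int]]] = [[] for _ in range(n_bodies)]
    for (i, j), rotatable in sorted(topology.bonds.items()):
        if not rotatable:
            continue
        bi, bj = body_of_atom[i], body_of_atom[j]
        if bi == bj:
            continue
        adj[bi].append((bj, i, j))
        adj[bj].append((bi, j, i))

    root_atom = 0 if root_spec is None else int(root_spec)
    root = int(body_of_atom[root_atom])

    dofs, visited = [], {root}
    queue = deque([root])
    while queue:
        b = queue.popleft()
        for (nb, tail, head) in adj[b]:
            if nb in visited:
                continue
            visited.add(nb)
            dofs.append(DoF(id=len(dofs), tail_atom=tail, head_atom=head,
                            parent_body=b, child_body=nb,
                            kind=_dof_kind(topology, tail, head)))
            queue.append(nb)
    if len(visited) != n_bodies:
        missing = sorted(set(range(n_bodies)) - visited)
        raise ValueError(
            f"disconnected body graph: {len(missing)} bodies unreachable "
            f"from root (ids {missing[:10]}...)")
    if coords0 is None:
        raise ValueError("build_tree requires the input coordinates (coords0)")
    return KinematicTree(bodies, dofs, root, body_of_atom, coords0)


def body_transforms(tree: KinematicTree, q: np.ndarray):
    """Affine transform (R, t) of every rigid body for torsion offsets q.

    The root body is fixed; a child's transform is its parent's composed with
    a rotation by q_j about the DoF bond axis, expressed in the input frame.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (tree.n_dofs,):
        raise ValueError(f"q has length {q.shape}, expected {tree.n_dofs}")
    I = np.eye(3)
    Rs = [None] * tree.n_bodies
    ts = [None] * tree.n_bodies
    Rs[tree.root], ts[tree.root] = I, np.zeros(3)
    c0 = tree.coords0
    for d in tree.dofs:  # BFS order: parent transform already available
        p_tail = c0[d.tail_atom]
        axis = c0[d.head_atom] - p_tail
        axis = axis / np.linalg.norm(axis)
        Rl, tl = rotation_about_line(p_tail, axis, q[d.id])
        Rs[d.child_body], ts[d.child_body] = compose(
            Rs[d.parent_body], ts[d.parent_body], Rl, tl)
    return Rs, ts


def forward_kinematics(tree: KinematicTree, q: np.ndarray) -> np.ndarray:
    """Cartesian coordinates generated by torsion offsets ``q``."""
    Rs, ts = body_transforms(tree, q)
    out = np.empty_like(tree.coords0)
    for b in range(tree.n_bodies):
        idx = tree._body_atoms[b]
        out[idx] = tree.coords0[idx] @ Rs[b].T + ts[b]
    return out


def classify_dofs(tree: KinematicTree, constraints) -> int:
    """Mark every DoF on a constraint's closure path as a cycle DoF.

    A DoF is a cycle DoF iff it lies on the tree path between the rigid
    bodies holding any constraint's hydrogen and acceptor atoms; the
    designation does not depend on the root choice.  Returns n_cycle.
    """
    for d in tree.dofs:
        d.designation = "free"
    for hb in constraints:
        bh = int(tree.body_of_atom[hb.hydrogen])
        ba = int(tree.body_of_atom[hb.acceptor])
        if bh == ba:
            continue
        _, left, right = tree.path_between(bh, ba)
        for did in left + right:
            tree.dofs[did].designation = "cycle"
    return sum(d.designation == "cycle" for d in tree.dofs)
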