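"""Hydrogen-bond networks rigidify an alpha-helix.

Builds an ideal 12-residue polyalanine helix with its eight i -> i+4
backbone hydrogen bonds declared as closure constraints, assembles the
6m x n_cycle Jacobian and reports which torsions survive in the nullspace.
"""

import numpy as np

from kgsample.fixtures import make_ideal_helix
from kgsample.kinematics import build_rigid_bodies, build_tree, classify_dofs
from kgsample.nullspace import (compute_jacobian, find_cycles,
                                nullspace_basis, rigidified_dofs)

topo, coords, constraints = make_ideal_helix(12)
tree = build_tree(build_rigid_bodies(topo), topo, coords0=coords)
n_cycle = classify_dofs(tree, constraints)

cycles = find_cycles(tree, constraints)
jac = compute_jacobian(tree, coords, cycles)
basis = nullspace_basis(jac, tree.n_dofs)
rigid = rigidified_dofs(basis)

print(f"{topo.n_atoms} atoms, {tree.n_bodies} rigid bodies, "
      f"{tree.n_dofs} torsional DoFs")
print(f"{len(constraints)} hydrogen bonds -> Jacobian {jac.matrix.shape}, "
      f"rank {n_cycle - basis.nullity}, nullity {basis.nullity}")
print(f"cycle DoFs: {n_cycle}, rigidified: {len(rigid)}")
interior = [d.id for d in tree.dofs
            if d.kind in ("phi", "psi") and d.designation == "cycle"]
print(f"interior backbone phi/psi: {len(interior)}, "
      f"all rigidified: {set(interior) <= rigid}")
# A nullity of zero means the constraint network leaves NO collective
# torsion motion that preserves every hydrogen bond: the helix core is
# rigid, exactly the behavior expected of helical secondary structure.
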